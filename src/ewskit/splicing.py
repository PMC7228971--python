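"""Exon-level (PSR) splicing statistic: the additional fold change.

If a transcript is not alternatively spliced, every probe-selection region
(PSR) of a gene should change with knockdown exactly as the gene does.
The *additional FC* of a PSR is its control-corrected fold change minus
the corrected fold change of its gene; nonzero values indicate
differential exon usage. PSRs are screened by a consistency rule (same
sign in every (cell line, construct) pair with a magnitude floor,
default 0.3 log2 units) and tested by a two-sided one-sample t on
replicate-level additional FCs, with Bonferroni correction over the PSRs
actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import one_sample_t_pvalues
from .contrasts import PAIR_SEP, ContrastTable
from .matrix import DOX_MINUS, DOX_PLUS, DesignSheet, ExpressionMatrix

RULE_ALL_PAIRS = "all_pairs"
RULE_MEAN = "mean"


def _check_map(psr_map: pd.DataFrame, psr_index, gene_index) -> pd.Series:
    mapping = psr_map.set_index("psr_id")["gene_id"]
    missing_psr = [p for p in psr_index if p not in mapping.index]
    if missing_psr:
        raise ValueError(f"PSRs missing from psr->gene map: {missing_psr[:5]}")
    orphans = sorted(set(mapping.loc[list(psr_index)]) - set(gene_index))
    if orphans:
        raise ValueError(f"PSRs map to genes absent from the gene table: {orphans[:5]}")
    return mapping


def psr_additional_fc(
    psr_contrasts: ContrastTable,
    gene_contrasts: ContrastTable,
    psr_map: pd.DataFrame,
) -> pd.DataFrame:
    """Per-PSR additional FC for every (cell line, target construct) pair.

    additional(psr; c, s) = corrected FC(psr; c, s) - corrected FC(gene(psr); c, s).
    """
    mapping = _check_map(psr_map, psr_contrasts.corrected.index, gene_contrasts.corrected.index)
    genes = mapping.loc[psr_contrasts.corrected.index]
    gene_fc = gene_contrasts.corrected.loc[genes.to_numpy()]
    gene_fc.index = psr_contrasts.corrected.index
    common = [c for c in psr_contrasts.corrected.columns if c in gene_fc.columns]
    if not common:
        raise ValueError("no shared (cell line, construct) pairs between PSR and gene tables")
    return psr_contrasts.corrected[common] - gene_fc[common]


def psr_consistency_filter(
    additional: pd.DataFrame,
    threshold: float = 0.3,
    rule: str = RULE_ALL_PAIRS,
    psr_map: pd.DataFrame | None = None,
) -> tuple[pd.Series, int, int | None]:
    """Consistency screen over per-pair additional FCs.

    ``all_pairs`` (default, strictest reading): every pair shares one sign
    and every |additional FC| >= threshold. ``mean``: every pair shares one
    sign and the mean |additional FC| >= threshold.

    Returns (pass flags, passing-PSR count, distinct-gene count when a
    psr->gene map is supplied, else None).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if additional.shape[1] < 1:
        raise ValueError("need at least one (cell line, construct) pair per PSR")
    vals = additional.to_numpy()
    same_sign = (vals > 0).all(axis=1) | (vals < 0).all(axis=1)
    if rule == RULE_ALL_PAIRS:
        magnitude = (np.abs(vals) >= threshold).all(axis=1)
    elif rule == RULE_MEAN:
        magnitude = np.abs(vals).mean(axis=1) >= threshold
    else:
        raise ValueError(f"unknown consistency rule {rule!r}")
    flags = pd.Series(same_sign & magnitude, index=additional.index, name="consistent")
    n_genes = consistent_counts(flags, psr_map)[1] if psr_map is not None else None
    return flags, int(flags.sum()), n_genes


def consistent_counts(flags: pd.Series, psr_map: pd.DataFrame) -> tuple[int, int]:
    """Headline counts: passing PSRs and the distinct genes they map to."""
    mapping = psr_map.set_index("psr_id")["gene_id"]
    passing = flags.index[flags]
    n_genes = int(mapping.loc[[p for p in passing]].nunique()) if len(passing) else 0
    return int(flags.sum()), n_genes


def replicate_additional_fc(
    psr_m: ExpressionMatrix,
    gene_m: ExpressionMatrix,
    design: DesignSheet,
    psr_map: pd.DataFrame,
) -> pd.DataFrame:
    """Replicate-level additional FCs, paired by replicate index.

    For each (cell line, target construct) pair and replicate r:

        a_r = (psr_plus_r - gene_plus_r) - (psr_minus_r - gene_minus_r)

    Subtracting the gene-level signal sample-by-sample removes any
    sample-wide artifact (including the Dox artifact the control construct
    would otherwise correct), and pairing Dox+ with Dox- by replicate
    index keeps the values independent across replicates and pairs, so the
    one-sample t test on them is calibrated. Requires equal Dox+/Dox-
    replicate counts per pair; replicates are matched after sorting by
    replicate index.
    """
    mapping = _check_map(psr_map, psr_m.values.index, gene_m.values.index)
    genes = mapping.loc[psr_m.values.index].to_numpy()
    gene_vals = gene_m.values.loc[genes]
    gene_vals.index = psr_m.values.index
    rel = psr_m.values - gene_vals  # PSR signal relative to its gene, per sample

    cols = {}
    for line in design.cell_lines:
        for construct in design.target_constructs:
            sub = design.table[
                (design.table["cell_line"] == line) & (design.table["construct"] == construct)
            ]
            plus = sub[sub["dox"] == DOX_PLUS].sort_values("replicate")
            minus = sub[sub["dox"] == DOX_MINUS].sort_values("replicate")
            if len(plus) == 0 and len(minus) == 0:
                continue
            if len(plus) != len(minus):
                raise ValueError(
                    f"unequal Dox+/Dox- replicate counts for {line!r}/{construct!r}; "
                    "replicate-paired additional FCs need a balanced design"
                )
            for (_, rp), (_, rm) in zip(plus.iterrows(), minus.iterrows()):
                label = f"{line}{PAIR_SEP}{construct}{PAIR_SEP}{rp['replicate']}"
                cols[label] = rel[rp["sample_id"]] - rel[rm["sample_id"]]
    return pd.DataFrame(cols)


@dataclass
class SplicingResult:
    """Per-PSR splicing statistics and significance flags."""

    table: pd.DataFrame  # gene_id, mean_additional_fc, consistent, p, significant, bonferroni_significant
    per_pair: pd.DataFrame
    n_consistent_psrs: int
    n_consistent_genes: int
    alpha: float
    m_tested: int

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("psr_id").to_csv(path, sep="\t")

    def summary(self) -> dict:
        return {
            "n_psrs_tested": self.m_tested,
            "n_consistent_psrs": self.n_consistent_psrs,
            "n_consistent_genes": self.n_consistent_genes,
            "n_significant_raw": int(self.table["significant"].sum()),
            "n_significant_bonferroni": int(self.table["bonferroni_significant"].sum()),
            "alpha": self.alpha,
        }


def psr_significance(
    replicate_additional: pd.DataFrame, alpha: float = 0.05, m: int | None = None
) -> pd.DataFrame:
    """Two-sided one-sample t of mean 0 on replicate-level additional FCs.

    Raw significance at p <= alpha; Bonferroni flag at p <= alpha / m,
    where m defaults to the number of PSRs tested (the tests performed
    define the family).
    """
    if m is None:
        m = replicate_additional.shape[0]
    if m < 1:
        raise ValueError("m must be >= 1")
    p = one_sample_t_pvalues(replicate_additional.to_numpy())
    return pd.DataFrame(
        {
            "p": p,
            "significant": p <= alpha,
            "bonferroni_significant": p <= alpha / m,
        },
        index=replicate_additional.index,
    )


def analyze_splicing(
    psr_m: ExpressionMatrix,
    gene_m: ExpressionMatrix,
    design: DesignSheet,
    psr_map: pd.DataFrame,
    psr_contrasts: ContrastTable,
    gene_contrasts: ContrastTable,
    threshold: float = 0.3,
    rule: str = RULE_ALL_PAIRS,
    alpha: float = 0.05,
) -> SplicingResult:
    """End-to-end PSR splicing analysis for one knockdown experiment."""
    per_pair = psr_additional_fc(psr_contrasts, gene_contrasts, psr_map)
    flags, n_psr, n_gene = psr_consistency_filter(
        per_pair, threshold=threshold, rule=rule, psr_map=psr_map
    )
    reps = replicate_additional_fc(psr_m, gene_m, design, psr_map).loc[per_pair.index]
    sig = psr_significance(reps, alpha=alpha)
    mapping = psr_map.set_index("psr_id")["gene_id"]
    table = pd.DataFrame(
        {
            "gene_id": mapping.loc[per_pair.index].to_numpy(),
            "mean_additional_fc": per_pair.mean(axis=1),
            "consistent": flags,
        }
    ).join(sig)
    return SplicingResult(
        table=table,
        per_pair=per_pair,
        n_consistent_psrs=n_psr,
        n_consistent_genes=n_gene,
        alpha=alpha,
        m_tested=len(per_pair),
    )
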