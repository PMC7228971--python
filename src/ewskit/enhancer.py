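"""GGAA-microsatellite enhancer analytics and locus association.

Covers the analysis half of a dual-luciferase reporter experiment on a
GGAA-microsatellite enhancer: counting consecutive GGAA repeats in cloned
allele sequences, normalising firefly to renilla luminescence, averaging
the two alleles per cell line, and correlating activity / repeat count /
marker-gene expression across lines. Also the locus-level associations:
copy-number segment means vs expression, and CpG methylation ratios
(coverage-gated) vs expression.

Repeat counting scans the given orientation only by default (cloned
fragments have a fixed orientation); a flag adds the reverse-complement
(TTCC) strand. A single non-GGAA base (including N) terminates a run; no
mismatch tolerance. Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import pearson_r_p

DNA_ALPHABET = set("ACGTN")


@dataclass
class GgaaRuns:
    """Tandem GGAA runs of one sequence: unit counts and 0-based starts."""

    max_run: int
    runs: list[tuple[int, int]]  # (start, n_units)


def count_consecutive_ggaa(seq: str, both_strands: bool = False) -> GgaaRuns:
    """Longest tandem GGAA run (in repeat units) and all run positions.

    Scans for maximal in-frame tandem repeats of the 4-mer GGAA; a run of
    k units spans the half-open interval [start, start + 4k). With
    ``both_strands`` the reverse-complement motif TTCC is scanned too and
    the longer of the two strand-wise maxima is reported (runs remain in
    given-strand coordinates).
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid DNA characters: {sorted(bad)}")
    runs = _scan_motif(seq, "GGAA")
    if both_strands:
        runs += _scan_motif(seq, "TTCC")
    max_run = max((n for _, n in runs), default=0)
    return GgaaRuns(max_run=max_run, runs=sorted(runs))


def _scan_motif(seq: str, motif: str) -> list[tuple[int, int]]:
    w = len(motif)
    runs = []
    i, n = 0, len(seq)
    while i <= n - w:
        if seq[i : i + w] == motif:
            k = 1
            while seq[i + k * w : i + (k + 1) * w] == motif:
                k += 1
            runs.append((i, k))
            i += k * w
        else:
            i += 1
    return runs


def read_allele_fasta(path: str | Path) -> pd.DataFrame:
    """Alleles from FASTA with record ids ``cellline|allele``.

    Sequences are uppercase-normalised on read.
    """
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"allele record id must be 'cellline|allele', got {rec.id!r}")
        line, allele = rec.id.rsplit("|", 1)
        rows.append(
            {"cell_line": line, "allele": int(allele), "sequence": str(rec.seq).upper()}
        )
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    return pd.DataFrame(rows)


DOX_DIFFERENTIAL = "differential"
DOX_PLAIN = "plain"


def reporter_activity(
    measurements: pd.DataFrame,
    reference_line: str,
    dox_mode: str = DOX_PLAIN,
) -> pd.DataFrame:
    """Per-allele normalised enhancer activity.

    Per replicate, activity = firefly / renilla; per allele, the mean over
    replicates. In ``differential`` mode the per-allele activity is the
    Dox- / Dox+ ratio of those means (isolating the dependence on the
    fusion protein switched off by Dox). All activities are rescaled so
    the reference line's allele-average equals 1.

    ``measurements`` columns: cell_line, allele, condition, replicate,
    firefly, renilla.
    """
    req = {"cell_line", "allele", "replicate", "firefly", "renilla"}
    missing = req - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    if (measurements["renilla"] <= 0).any():
        raise ValueError("renilla luminescence must be > 0")
    df = measurements.copy()
    if "condition" not in df.columns:
        df["condition"] = DOX_PLAIN
    df["raw"] = df["firefly"] / df["renilla"]
    means = df.groupby(["cell_line", "allele", "condition"])["raw"].mean()

    if dox_mode == DOX_PLAIN:
        per_allele = means.groupby(["cell_line", "allele"]).mean()
    elif dox_mode == DOX_DIFFERENTIAL:
        minus = means.xs("minus", level="condition")
        plus = means.xs("plus", level="condition")
        per_allele = minus / plus
    else:
        raise ValueError(f"unknown dox_mode {dox_mode!r}")

    out = per_allele.rename("activity").reset_index()
    ref = out[out["cell_line"] == reference_line]
    if ref.empty:
        raise ValueError(f"reference line {reference_line!r} absent from measurements")
    out["activity"] = out["activity"] / ref["activity"].mean()
    return out


def allele_average_and_correlate(
    activities: pd.DataFrame,
    repeat_counts: pd.DataFrame,
    expression: pd.Series,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Per-line allele averages and the three pairwise correlations.

    ``activities``: cell_line, allele, activity (from reporter_activity).
    ``repeat_counts``: cell_line, allele, repeats. ``expression``: per-line
    marker levels. Lines with only one measured allele are excluded with a
    warning (a homozygous line may be supplied as two identical allele
    rows, which average to themselves).

    Returns (per-line table, correlations {pair: {r, p, n}}) where pairs
    are activity_vs_expression, repeats_vs_activity, repeats_vs_expression.
    """
    import warnings

    act = activities.groupby("cell_line").agg(
        activity=("activity", "mean"), n_alleles=("allele", "nunique")
    )
    incomplete = act.index[act["n_alleles"] < 2]
    if len(incomplete):
        warnings.warn(
            f"excluding cell line(s) with a single measured allele: {list(incomplete)}",
            stacklevel=2,
        )
        act = act.drop(index=incomplete)
    reps = repeat_counts.groupby("cell_line")["repeats"].mean()
    table = act.join(reps.rename("repeats")).join(expression.rename("expression"))
    table = table.dropna(subset=["activity", "repeats", "expression"])
    if len(table) < 3:
        raise ValueError("need >= 3 cell lines with both alleles measured")
    pairs = {
        "activity_vs_expression": ("activity", "expression"),
        "repeats_vs_activity": ("repeats", "activity"),
        "repeats_vs_expression": ("repeats", "expression"),
    }
    corr = {}
    for name, (a, b) in pairs.items():
        r, p = pearson_r_p(table[a], table[b])
        corr[name] = {"r": r, "p": p, "n": int(len(table))}
    return table, corr


def cnv_expression_association(associations: pd.DataFrame) -> dict[str, float]:
    """Pearson r and two-sided p between segment mean and log2 expression.

    ``associations`` columns: segment_mean (log2 copy ratio per tumor),
    expression (log2 signal). A zero-variance input (e.g. all tumors
    diploid at the locus) yields an undefined association, reported as NaN.
    """
    req = {"segment_mean", "expression"}
    if not req <= set(associations.columns):
        raise ValueError(f"association table needs columns {sorted(req)}")
    if len(associations) < 3:
        raise ValueError("need >= 3 tumors")
    r, p = pearson_r_p(associations["segment_mean"], associations["expression"])
    return {"r": r, "p": p, "n": int(len(associations)), "defined": bool(np.isfinite(r))}


def cpg_methylation_ratio(
    counts: pd.DataFrame,
    expression: pd.Series | None = None,
    min_coverage: int = 4,
    ratio_mode: str = "fraction",
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Per-site methylation ratios with a read-coverage gate.

    ``counts`` columns: tumor_id, site, methylated, unmethylated (read
    counts). The ratio is methylated / (methylated + unmethylated)
    (``fraction``, bounded in [0, 1]); ``odds`` gives methylated /
    unmethylated instead. Sites covered by fewer than ``min_coverage``
    reads in a tumor carry no ratio there. When an expression vector is
    supplied, each site's ratios are Pearson-correlated with expression
    over the tumors that have a ratio.
    """
    req = {"tumor_id", "site", "methylated", "unmethylated"}
    if not req <= set(counts.columns):
        raise ValueError(f"count table needs columns {sorted(req)}")
    if (counts[["methylated", "unmethylated"]] < 0).any().any():
        raise ValueError("read counts must be >= 0")
    df = counts.copy()
    total = df["methylated"] + df["unmethylated"]
    covered = total >= min_coverage
    with np.errstate(divide="ignore", invalid="ignore"):
        if ratio_mode == "fraction":
            ratio = df["methylated"] / total
        elif ratio_mode == "odds":
            ratio = df["methylated"] / df["unmethylated"]
        else:
            raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    df["coverage"] = total
    df["ratio"] = ratio.where(covered)
    corr: dict[str, dict[str, float]] = {}
    if expression is not None:
        for site, sub in df.dropna(subset=["ratio"]).groupby("site"):
            expr = expression.reindex(sub["tumor_id"])
            r, p = pearson_r_p(sub["ratio"].to_numpy(), expr.to_numpy())
            corr[str(site)] = {"r": r, "p": p, "n": int(expr.notna().sum())}
    return df, corr
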