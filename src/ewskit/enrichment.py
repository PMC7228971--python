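"""Pre-ranked gene-set enrichment (weighted Kolmogorov-Smirnov statistic).

Genes are ranked by a score (here: mean control-corrected fold change) and
a running sum walks the ranking: hits increment proportionally to
|score|^weight (normalised by the in-set total), misses decrement by
1/(N - set size). The enrichment score (ES) is the maximum-magnitude
deviation of the running sum; the null is built by permuting gene labels
(pre-ranked mode has no phenotype labels to permute), the normalised score
(NES) divides ES by the mean magnitude of same-signed permutation scores,
and the nominal p is one-sided against same-signed null values with a +1
pseudocount so it is always positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets in GMT tab format (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def _running_es(weights_hit: np.ndarray, in_set: np.ndarray, miss_dec: float) -> np.ndarray:
    """Running sum over a ranking; weights_hit already normalised to sum 1."""
    steps = np.where(in_set, weights_hit, -miss_dec)
    return np.cumsum(steps)


def enrichment_score(
    scores: pd.Series, gene_set: set[str], weight: float = 1.0
) -> tuple[float, list[str]]:
    """ES for one set against a ranked score vector, plus the leading edge.

    ``scores`` is sorted descending internally; ties are broken by stable
    feature-id order. The leading edge is the in-set genes up to (and
    including) the running-sum extremum.
    """
    ranked = scores.sort_values(ascending=False, kind="stable")
    genes = ranked.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    n, n_hit = genes.size, int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set is empty or covers the whole universe after intersection")
    w = np.abs(ranked.to_numpy()) ** weight
    total = w[in_set].sum()
    if total == 0:  # all in-set scores exactly 0: fall back to unweighted hits
        hit_w = np.where(in_set, 1.0 / n_hit, 0.0)
    else:
        hit_w = np.where(in_set, w / total, 0.0)
    running = _running_es(hit_w, in_set, 1.0 / (n - n_hit))
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        leading = [g for g, hit in zip(genes[: peak + 1], in_set[: peak + 1]) if hit]
    else:
        leading = [g for g, hit in zip(genes[peak:], in_set[peak:]) if hit]
    return es, leading


def _permutation_es(
    sorted_abs_w: np.ndarray, n_hit: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES values from gene-label permutation, vectorised over draws."""
    n = sorted_abs_w.size
    # random set positions per permutation: argsort of uniforms
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_hit]
    in_set = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(in_set, pos, True, axis=1)
    w = np.where(in_set, sorted_abs_w[None, :], 0.0)
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        w[zero] = np.where(in_set[zero], 1.0 / n_hit, 0.0)
        totals[zero] = 1.0
    steps = w / totals - np.where(in_set, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


@dataclass
class GseaResult:
    """Per-set enrichment results (ES, NES, nominal p, leading edge)."""

    table: pd.DataFrame
    leading_edges: dict[str, list[str]]
    skipped: dict[str, str]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["leading_edge_size"] = [
            len(self.leading_edges[s]) for s in out.index
        ]
        out.rename_axis("gene_set").to_csv(path, sep="\t")


def preranked_gsea(
    scores: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> GseaResult:
    """Pre-ranked GSEA over a collection of gene sets.

    Sets empty after intersection with the ranked universe, or covering the
    whole universe, are skipped with a recorded reason. The permutation
    null is drawn once per distinct set size and shared across sets of that
    size (label permutation depends on the set only through its size).
    """
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("scores must be finite")
    rng = np.random.default_rng(seed)
    ranked = scores.sort_values(ascending=False, kind="stable")
    universe = set(ranked.index)
    sorted_abs_w = np.abs(ranked.to_numpy()) ** weight

    sizes_needed = {}
    members: dict[str, set[str]] = {}
    skipped: dict[str, str] = {}
    for name, genes in gene_sets.items():
        inter = set(genes) & universe
        if not inter:
            skipped[name] = "empty after intersection with ranked universe"
        elif len(inter) == len(universe):
            skipped[name] = "covers the whole ranked universe"
        else:
            members[name] = inter
            sizes_needed[len(inter)] = None
    null_by_size = {
        k: _permutation_es(sorted_abs_w, k, n_perm, rng) for k in sorted(sizes_needed)
    }

    rows, leading_edges = [], {}
    for name, inter in members.items():
        es, leading = enrichment_score(ranked, inter, weight=weight)
        null = null_by_size[len(inter)]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        extreme = int((same_sign >= es).sum()) if es >= 0 else int((same_sign <= es).sum())
        nom_p = (extreme + 1) / (same_sign.size + 1)
        mean_same = float(np.abs(same_sign).mean()) if same_sign.size else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan
        rows.append({"gene_set": name, "es": es, "nes": nes, "nom_p": nom_p, "size": len(inter)})
        leading_edges[name] = leading
    table = (
        pd.DataFrame(rows).set_index("gene_set")
        if rows
        else pd.DataFrame(columns=["es", "nes", "nom_p", "size"])
    )
    return GseaResult(table=table, leading_edges=leading_edges, skipped=skipped)
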