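"""Differential-expression calling with q-value FDR estimation.

A gene is called differentially expressed when it passes the expression
floor and its mean control-corrected fold change reaches the call
threshold (|log2 FC| >= 1 by default; the bound is inclusive). A per-gene
two-sided one-sample t test on the replicate-level corrected FCs supplies
p-values, and the false discovery rate is estimated with the q-value
procedure (pi0 from a lambda grid or a fixed lambda).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import one_sample_t_pvalues


def per_gene_pvalues(replicate_fcs: pd.DataFrame) -> pd.Series:
    """Two-sided one-sample t test of mean 0 on replicate-level corrected FCs.

    The underlying location test is the minimal-assumption choice for an
    FC-centric procedure; see the methods note for the construction of the
    replicate-level values.
    """
    p = one_sample_t_pvalues(replicate_fcs.to_numpy())
    return pd.Series(p, index=replicate_fcs.index, name="p")


def estimate_pi0(
    p: np.ndarray, lambda_grid=None, method: str = "fixed", fixed_lambda: float = 0.5
) -> float:
    """Estimate the null proportion pi0 from the p-value distribution.

    ``fixed``: pi0 = #{p > lambda} / (m * (1 - lambda)) at one lambda
    (default 0.5), the deterministic default. ``smoother``: evaluate the
    same estimate over the lambda grid and take a monotone (cummin)
    smoothed value at the largest lambda. Both are capped into (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if method == "fixed":
        lam = float(fixed_lambda)
        pi0 = (p > lam).sum() / (m * (1.0 - lam))
    elif method == "smoother":
        grid = np.asarray(
            lambda_grid if lambda_grid is not None else np.arange(0.05, 0.95, 0.05)
        )
        est = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
        pi0 = float(np.minimum.accumulate(est[np.argsort(grid)])[-1])
    else:
        raise ValueError(f"unknown pi0 method {method!r}")
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalue(
    p,
    lambda_grid=None,
    pi0: float | None = None,
    method: str = "fixed",
    fixed_lambda: float = 0.5,
) -> np.ndarray:
    """q-values: per-feature estimated FDR.

    q_i = min over j with p_j >= p_i of (pi0 * m * p_j / rank(p_j)),
    capped at 1. With ``pi0=1`` this reduces to the rank-based step-up
    adjustment of Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid, method=method, fixed_lambda=fixed_lambda)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DegResult:
    """Per-gene differential-expression calls.

    ``table`` columns: mean_fc, p, q, is_deg. ``n_up`` / ``n_down`` count
    the called up- and downregulated genes.
    """

    table: pd.DataFrame
    fc_threshold: float
    n_up: int
    n_down: int

    @property
    def deg_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_deg"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("gene_id").to_csv(path, sep="\t")


def call_degs(
    mean_fc: pd.Series,
    p: pd.Series | None = None,
    q: np.ndarray | pd.Series | None = None,
    fc_threshold: float = 1.0,
) -> DegResult:
    """Flag genes with |mean corrected FC| >= ``fc_threshold`` (inclusive).

    Input genes are expected to be floor-filtered already. The call depends
    only on the FC rule; p and q are reported alongside for the reader.
    """
    if fc_threshold < 0:
        raise ValueError("fc_threshold must be >= 0")
    table = pd.DataFrame({"mean_fc": mean_fc})
    if p is not None:
        table["p"] = p
        if q is None:
            q = storey_qvalue(p.to_numpy())
        table["q"] = np.asarray(q)
    table["is_deg"] = table["mean_fc"].abs() >= fc_threshold
    up = int(((table["mean_fc"] >= fc_threshold)).sum())
    down = int(((table["mean_fc"] <= -fc_threshold)).sum())
    return DegResult(table=table, fc_threshold=fc_threshold, n_up=up, n_down=down)
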