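"""Expression vs drug-sensitivity correlation screen and IC50 fitting.

For every drug in a panel, the Pearson correlation between a marker gene's
expression and log10 IC50 is computed over pairwise-complete cell lines
(two-sided p from the exact t transform). Candidate vulnerabilities are
drugs with a negative coefficient at p <= alpha, ranked by r ascending,
annotated with median IC50 and a potency flag. A four-parameter logistic
fit on log10 dose supplies relative IC50s from viability curves.

No multiple-testing adjustment is applied across drugs in the screen (the
selection deliberately mirrors an exploratory screen); q-values are still
emitted for the reader.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._stats import pearson_r_p
from .deg import storey_qvalue

SCALE_LINEAR = "linear"
SCALE_LOG10 = "log10"


@dataclass
class DrugResponseTable:
    """Drug x cell-line IC50 table with an explicit concentration scale.

    ``linear``: molar concentrations (> 0). ``log10``: log10 molar.
    Missing entries (NaN) are permitted.
    """

    values: pd.DataFrame
    scale: str = SCALE_LOG10

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_LINEAR, SCALE_LOG10):
            raise ValueError(f"unknown IC50 scale {self.scale!r}")
        if self.scale == SCALE_LINEAR and (self.values <= 0).any().any():
            raise ValueError("linear-scale IC50 values must be > 0")

    def log10(self) -> "DrugResponseTable":
        if self.scale == SCALE_LOG10:
            return self
        return DrugResponseTable(np.log10(self.values), scale=SCALE_LOG10)

    def linear(self) -> "DrugResponseTable":
        if self.scale == SCALE_LINEAR:
            return self
        return DrugResponseTable(10.0 ** self.values, scale=SCALE_LINEAR)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# ic50_scale: {self.scale}\n")
            self.values.rename_axis("drug_id").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str | None = None) -> "DrugResponseTable":
        import io

        text = Path(path).read_text()
        lines = text.splitlines(keepends=True)
        start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            if "ic50_scale:" in line:
                scale = line.split(":", 1)[1].strip()
            start += 1
        df = pd.read_csv(io.StringIO("".join(lines[start:])), sep="\t", index_col=0)
        return cls(df, scale=scale or SCALE_LOG10)


def correlate_expression_vs_ic50(
    expression: pd.Series,
    responses: DrugResponseTable,
    use_log10: bool = True,
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-drug Pearson screen of marker expression against IC50.

    IC50 values are correlated on the log10 scale by default (potency spans
    orders of magnitude). Each drug uses its pairwise-complete cell lines;
    drugs with fewer than ``min_n`` shared lines or zero variance in either
    vector are skipped with a recorded reason. Median IC50 (linear molar)
    is reported per drug over its non-missing lines.
    """
    work = responses.log10() if use_log10 else responses.linear()
    linear_vals = responses.linear().values
    shared = [c for c in work.values.columns if c in expression.index]
    if len(shared) < min_n:
        raise ValueError("fewer than min_n cell lines shared between expression and panel")
    expr = expression.loc[shared]
    rows = []
    for drug, row in work.values[shared].iterrows():
        ok = row.notna() & expr.notna()
        n = int(ok.sum())
        reason = None
        r = p = np.nan
        if n < min_n:
            reason = f"only {n} pairwise-complete lines"
        else:
            r, p = pearson_r_p(expr[ok].to_numpy(), row[ok].to_numpy())
            if not np.isfinite(r):
                reason = "zero variance in expression or IC50"
        med = float(np.nanmedian(linear_vals.loc[drug])) if linear_vals.loc[drug].notna().any() else np.nan
        rows.append(
            {"drug_id": drug, "r": r, "p": p, "n": n, "median_ic50": med, "skipped": reason}
        )
    out = pd.DataFrame(rows).set_index("drug_id")
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = storey_qvalue(out.loc[tested, "p"].to_numpy(), pi0=1.0)
    return out


def select_candidate_drugs(
    results: pd.DataFrame,
    alpha: float = 0.05,
    top_k: int = 7,
    potency_threshold: float = 1e-6,
) -> pd.DataFrame:
    """Shortlist drugs with r < 0 and p <= alpha, ranked by r ascending.

    Ties in r break by drug id (lexicographic). Each shortlisted drug is
    annotated with its median IC50 and a ``potent`` flag (median IC50 <=
    ``potency_threshold``, default 1 uM — a configurable convention, not a
    universal constant). An empty shortlist is a valid outcome.
    """
    if results.empty:
        raise ValueError("empty screen results")
    passing = results[(results["r"] < 0) & (results["p"] <= alpha)].copy()
    passing = passing.sort_index(kind="stable").sort_values("r", kind="stable").head(top_k)
    passing["rank"] = np.arange(1, len(passing) + 1)
    passing["potent"] = passing["median_ic50"] <= potency_threshold
    return passing


def _four_pl(logx: np.ndarray, top: float, bottom: float, hill: float, log_mid: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - log_mid)))


@dataclass
class DoseResponseFit:
    """4PL fit of a viability curve; ``ok`` is False when no fit converged."""

    ok: bool
    ic50: float | None = None
    top: float | None = None
    bottom: float | None = None
    hill: float | None = None
    failure: str | None = None


def fit_dose_response_ic50(doses, viability) -> DoseResponseFit:
    """Four-parameter logistic fit on log10 dose; relative IC50 = midpoint.

    ``doses`` are concentrations (> 0, any consistent unit); ``viability``
    is percent of control (control = 100). The relative IC50 is the fitted
    midpoint: the dose at the half-way response between fitted top and
    bottom. Flat or non-sigmoidal data yield ``ok=False`` with a failure
    code rather than a value.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.size != viability.size:
        raise ValueError("doses and viability must have equal length")
    if np.unique(doses).size < 4:
        raise ValueError("need at least 4 distinct dose levels")
    if (doses <= 0).any():
        raise ValueError("doses must be positive concentrations")
    logx = np.log10(doses)
    span = viability.max() - viability.min()
    if span < 1e-9:
        return DoseResponseFit(ok=False, failure="flat curve: no dose response")
    p0 = [viability.max(), viability.min(), 1.0, float(np.median(logx))]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _four_pl, logx, viability, p0=p0, maxfev=20000,
                bounds=([-np.inf, -np.inf, 0.0, logx.min() - 3],
                        [np.inf, np.inf, np.inf, logx.max() + 3]),
            )
    except (RuntimeError, ValueError) as exc:
        return DoseResponseFit(ok=False, failure=f"fit did not converge: {exc}")
    top, bottom, hill, log_mid = map(float, popt)
    resid = viability - _four_pl(logx, *popt)
    if abs(top - bottom) < 0.05 * span or np.sqrt(np.mean(resid**2)) > span:
        return DoseResponseFit(ok=False, failure="no sigmoidal dose response")
    return DoseResponseFit(ok=True, ic50=10.0 ** log_mid, top=top, bottom=bottom, hill=hill)
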