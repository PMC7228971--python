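"""Quantification formulas for phenotype readouts.

Immunoreactivity scoring (IRS), sphere and clonogenicity indices, caliper
tumor volume, relative qPCR expression (2^-ddCt) and percent-of-control
normalisation — the small closed-form computations behind figure panels.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

#: Closed percentage bins for the staining-extent grade: grade 0 = 0-19%,
#: 1 = 20-39%, 2 = 40-59%, 3 = 60-79%, 4 = 80-100%.
_PERCENT_BIN_EDGES = (20, 40, 60, 80)


def percent_positive_grade(percent_positive: float) -> int:
    """Staining-extent grade (0-4) from percent positive cells.

    The percentage is floored before binning, so e.g. 19.5% stays in
    grade 0 (the printed bins are closed integer ranges).
    """
    if not 0 <= percent_positive <= 100:
        raise ValueError("percent_positive must lie in [0, 100]")
    p = math.floor(percent_positive)
    return sum(p >= edge for edge in _PERCENT_BIN_EDGES)


def irs_score(percent_positive: float, intensity: int) -> int:
    """Immunoreactive score: extent grade (0-4) x intensity grade (0-3).

    Range 0-12; nondecreasing in both inputs.
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity grade must be an integer in {0, 1, 2, 3}")
    return percent_positive_grade(percent_positive) * intensity


def irs_per_section(readings: pd.DataFrame) -> pd.Series:
    """IRS per section with a per-sample median summary.

    ``readings`` columns: sample_id, percent_positive, intensity. Returns
    the median IRS per sample (sections are scored individually first).
    """
    scores = readings.apply(
        lambda row: irs_score(row["percent_positive"], int(row["intensity"])), axis=1
    )
    return scores.groupby(readings["sample_id"]).median()


def sphere_volume(diameter: float) -> float:
    """V = 4/3 * pi * r^3 with r = diameter / 2."""
    r = diameter / 2.0
    return 4.0 / 3.0 * math.pi * r**3


def sphere_index(
    diameters, min_diameter: float = 500.0, mode: str = "mean"
) -> dict[str, float]:
    """Sphere-formation index from sphere diameters (um).

    Spheres strictly larger than ``min_diameter`` are counted; the index is
    count x mean volume of the counted spheres (``mode='mean'``, default)
    — which equals their total volume under ``mode='total'`` divided by
    count; both variants are reported in the returned dict. Empty input or
    no qualifying sphere gives index 0.
    """
    d = np.asarray(list(diameters), dtype=float)
    if d.size and (d <= 0).any():
        raise ValueError("diameters must be positive")
    kept = d[d > min_diameter]
    if kept.size == 0:
        return {"index": 0.0, "index_mean": 0.0, "index_total": 0.0, "count": 0}
    vols = np.array([sphere_volume(x) for x in kept])
    idx_mean = kept.size * float(vols.mean())
    idx_total = float(vols.sum())
    return {
        "index": idx_mean if mode == "mean" else idx_total,
        "index_mean": idx_mean,
        "index_total": idx_total,
        "count": int(kept.size),
    }


def clonogenicity_index(count: int, area: float) -> float:
    """Colony count x colony area."""
    if count < 0 or area < 0:
        raise ValueError("count and area must be >= 0")
    return count * area


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume V = L * l^2 / 2 (mm^3).

    L is the longer axis; if the inputs arrive swapped they are exchanged
    with a warning (caliper convention).
    """
    if length <= 0 or width <= 0:
        raise ValueError("axes must be positive")
    if width > length:
        warnings.warn("width > length; swapping axes (caliper convention)", stacklevel=2)
        length, width = width, length
    return length * width**2 / 2.0


def ddct_expression(
    ct_target: float, ct_ref: float, ct_target_control: float, ct_ref_control: float
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_ref) - (Ct_target_control - Ct_ref_control),
    with the reference a housekeeping gene and the control the untreated
    sample; returns 2 ** -ddCt.
    """
    for ct in (ct_target, ct_ref, ct_target_control, ct_ref_control):
        if ct <= 0:
            raise ValueError("Ct values must be positive cycle numbers")
    ddct = (ct_target - ct_ref) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def percent_of_control(
    values, control_values=None, groups=None, control_group=None
) -> np.ndarray | pd.Series:
    """Normalise values to percent of the control-group mean (control = 100%).

    Either pass ``control_values`` directly, or pass parallel ``groups``
    labels plus the ``control_group`` name; in the latter case each value
    is scaled by 100 / mean(control group). For multi-experiment tables,
    call once per experiment.
    """
    values = pd.Series(values, dtype=float)
    if control_values is not None:
        ctrl_mean = float(np.mean(np.asarray(control_values, dtype=float)))
    else:
        if groups is None or control_group is None:
            raise ValueError("pass control_values, or groups with control_group")
        groups = pd.Series(list(groups))
        mask = (groups == control_group).to_numpy()
        if not mask.any():
            raise ValueError(f"control group {control_group!r} not present")
        ctrl_mean = float(values.to_numpy()[mask].mean())
    if ctrl_mean <= 0:
        raise ValueError("control mean must be > 0")
    return values * 100.0 / ctrl_mean
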