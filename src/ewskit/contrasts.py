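"""Knockdown fold-change machinery with control correction.

The contrast scheme for a doxycycline-inducible shRNA experiment:

1. per (cell line, construct), raw FC = mean log2(Dox+) - mean log2(Dox-);
2. the matched non-targeting-control FC of the same cell line is
   subtracted, removing Dox artifacts shared by all constructs;
3. corrected FCs are averaged over all (cell line, target construct)
   pairs to a single mean FC per feature.

Replicate-level corrected FCs (each Dox+ replicate's log2 value minus its
arm's Dox- mean, minus the cell line's control FC) are carried alongside so
a downstream significance test has within-gene variability to work with.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .matrix import DOX_MINUS, DOX_PLUS, LOG2, DesignSheet, ExpressionMatrix

PAIR_SEP = "|"


def pair_label(cell_line: str, construct: str) -> str:
    return f"{cell_line}{PAIR_SEP}{construct}"


@dataclass
class ContrastTable:
    """Per-feature fold changes of one knockdown experiment.

    Attributes
    ----------
    raw
        Raw FCs, one column per ``cell_line|construct`` (controls included).
    corrected
        Control-corrected FCs, one column per ``cell_line|target_construct``.
    mean_fc
        Arithmetic mean of the corrected FCs across pairs.
    replicate_fcs
        Replicate-level corrected FCs, one column per
        ``cell_line|construct|replicate`` Dox+ sample.
    """

    raw: pd.DataFrame
    corrected: pd.DataFrame
    mean_fc: pd.Series
    replicate_fcs: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        out = self.corrected.copy()
        out.columns = [f"corrected_fc:{c}" for c in out.columns]
        out["mean_fc"] = self.mean_fc
        out.rename_axis("feature_id").to_csv(path, sep="\t")


def knockdown_fc(
    m: ExpressionMatrix, design: DesignSheet, cell_line: str, construct: str
) -> pd.Series:
    """Raw per-feature FC for one (cell line, construct).

    FC(g) = mean log2 over Dox+ samples - mean log2 over Dox- samples.
    """
    if m.scale != LOG2:
        raise ValueError("fold changes are computed on the log2 scale")
    plus = design.samples(cell_line, construct, DOX_PLUS)
    minus = design.samples(cell_line, construct, DOX_MINUS)
    for arm, name in ((plus, DOX_PLUS), (minus, DOX_MINUS)):
        if not arm:
            raise ValueError(
                f"missing Dox {name} samples for cell line {cell_line!r}, "
                f"construct {construct!r}"
            )
    return m.values[plus].mean(axis=1) - m.values[minus].mean(axis=1)


def raw_fc_table(m: ExpressionMatrix, design: DesignSheet) -> pd.DataFrame:
    """Raw FCs for every (cell line, construct) pair, controls included."""
    design.check_against(m)
    cols = {}
    for line in design.cell_lines:
        for construct in design.constructs:
            if design.samples(line, construct):
                cols[pair_label(line, construct)] = knockdown_fc(m, design, line, construct)
    return pd.DataFrame(cols)


def control_correct_fc(raw: pd.DataFrame, design: DesignSheet) -> pd.DataFrame:
    """Subtract each cell line's control FC from its target-construct FCs.

    The control construct's corrected FC is identically 0 and is therefore
    not emitted; only ``cell_line|target_construct`` columns appear.
    """
    out = {}
    for line in design.cell_lines:
        ctrl_col = pair_label(line, design.control)
        if ctrl_col not in raw.columns:
            raise ValueError(f"missing control FC for cell line {line!r}")
        for construct in design.target_constructs:
            col = pair_label(line, construct)
            if col in raw.columns:
                out[col] = raw[col] - raw[ctrl_col]
    return pd.DataFrame(out)


def mean_corrected_fc(corrected: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of corrected FCs across (cell line, construct) pairs."""
    if corrected.shape[1] == 0:
        raise ValueError("no (cell line, target construct) pairs to average")
    return corrected.mean(axis=1)


def replicate_corrected_fc(m: ExpressionMatrix, design: DesignSheet) -> pd.DataFrame:
    """Replicate-level corrected FCs for every target-construct Dox+ sample.

    Each Dox+ replicate's log2 value, minus its arm's Dox- mean, minus the
    cell line's control FC. Column labels: ``cell_line|construct|replicate``.
    """
    if m.scale != LOG2:
        raise ValueError("fold changes are computed on the log2 scale")
    raw = raw_fc_table(m, design)
    cols = {}
    for line in design.cell_lines:
        ctrl_fc = raw[pair_label(line, design.control)]
        for construct in design.target_constructs:
            minus = design.samples(line, construct, DOX_MINUS)
            plus = design.samples(line, construct, DOX_PLUS)
            if not plus or not minus:
                continue
            minus_mean = m.values[minus].mean(axis=1)
            sub = design.table
            sub = sub[
                (sub["cell_line"] == line)
                & (sub["construct"] == construct)
                & (sub["dox"] == DOX_PLUS)
            ]
            for _, row in sub.iterrows():
                label = f"{pair_label(line, construct)}{PAIR_SEP}{row['replicate']}"
                cols[label] = m.values[row["sample_id"]] - minus_mean - ctrl_fc
    return pd.DataFrame(cols)


def build_contrast_table(
    m: ExpressionMatrix, design: DesignSheet, features: list[str] | None = None
) -> ContrastTable:
    """Full contrast computation (raw, corrected, mean, replicate-level).

    ``features`` restricts the table (e.g. to floor-filtered genes) while
    preserving the given order.
    """
    raw = raw_fc_table(m, design)
    corrected = control_correct_fc(raw, design)
    reps = replicate_corrected_fc(m, design)
    if features is not None:
        raw = raw.loc[features]
        corrected = corrected.loc[features]
        reps = reps.loc[features]
    return ContrastTable(
        raw=raw,
        corrected=corrected,
        mean_fc=mean_corrected_fc(corrected),
        replicate_fcs=reps,
    )
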