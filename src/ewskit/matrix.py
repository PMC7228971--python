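"""Expression data model: signal matrices and the knockdown design sheet.

An :class:`ExpressionMatrix` is a features x samples table carrying an
explicit scale flag (``linear`` or ``log2``); microarray pipelines work on
the log2 scale throughout, and keeping the flag on the container prevents
double transformation. A :class:`DesignSheet` annotates each sample with its
cell line, shRNA construct (one designated non-targeting control) and
doxycycline condition; it defines the Dox+/Dox- knockdown contrasts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2 = "log2"

DOX_MINUS = "minus"
DOX_PLUS = "plus"


@dataclass
class ExpressionMatrix:
    """Features x samples signal table with an explicit scale flag."""

    values: pd.DataFrame
    scale: str = LINEAR

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes[:5])}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix must be complete (no missing values)")
        if self.scale == LINEAR:
            bad = self.values.le(0.0)
            if bad.any().any():
                feat = self.values.index[bad.any(axis=1)][0]
                samp = self.values.columns[bad.loc[feat]][0]
                raise ValueError(
                    f"linear-scale signal must be > 0; offending entry "
                    f"feature={feat!r} sample={samp!r}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV with the scale recorded in a leading comment line."""
        with open(path, "w") as fh:
            fh.write(f"# scale: {self.scale}\n")
            self.values.rename_axis("feature_id").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str | None = None) -> "ExpressionMatrix":
        """Read a TSV written by :meth:`to_tsv` (or any conforming table).

        The scale is taken from a ``# scale:`` comment header when present,
        else from the ``scale`` argument (default ``linear``).
        """
        text = Path(path).read_text()
        lines = text.splitlines(keepends=True)
        body_start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            if line[1:].strip().lower().startswith("scale:"):
                scale = line.split(":", 1)[1].strip()
            body_start += 1
        df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
        return cls(df, scale=scale or LINEAR)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Element-wise log2 of a linear-scale matrix.

    Rejects matrices already on the log2 scale and any nonpositive entry
    (naming the offending feature/sample).
    """
    if m.scale != LINEAR:
        raise ValueError("matrix is not on the linear scale")
    return ExpressionMatrix(np.log2(m.values), scale=LOG2)


def inverse_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """Back-transform a log2 matrix to the linear scale (2**x)."""
    if m.scale != LOG2:
        raise ValueError("matrix is not on the log2 scale")
    return ExpressionMatrix(np.exp2(m.values), scale=LINEAR)


@dataclass
class DesignSheet:
    """Per-sample annotations defining the knockdown contrasts.

    ``table`` columns: sample_id, cell_line, construct, dox (minus/plus),
    replicate. ``control`` names the non-targeting construct.
    """

    table: pd.DataFrame
    control: str = "shCtrl"

    _required = ("sample_id", "cell_line", "construct", "dox", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self._required if c not in self.table.columns]
        if missing:
            raise ValueError(f"design sheet missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design sheet")
        bad_dox = set(self.table["dox"]) - {DOX_MINUS, DOX_PLUS}
        if bad_dox:
            raise ValueError(f"dox must be 'minus' or 'plus', got {bad_dox}")
        for line in self.cell_lines:
            sub = self.table[self.table["cell_line"] == line]
            if self.control not in set(sub["construct"]):
                raise ValueError(f"control construct {self.control!r} absent in cell line {line!r}")

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.table["cell_line"].unique())

    @property
    def constructs(self) -> list[str]:
        return sorted(self.table["construct"].unique())

    @property
    def target_constructs(self) -> list[str]:
        return [c for c in self.constructs if c != self.control]

    def samples(self, cell_line=None, construct=None, dox=None) -> list[str]:
        """Sample ids matching the given (partial) condition."""
        t = self.table
        if cell_line is not None:
            t = t[t["cell_line"] == cell_line]
        if construct is not None:
            t = t[t["construct"] == construct]
        if dox is not None:
            t = t[t["dox"] == dox]
        return list(t["sample_id"])

    def check_against(self, m: ExpressionMatrix) -> None:
        unknown = set(self.table["sample_id"]) - set(m.sample_ids)
        if unknown:
            raise ValueError(f"design samples missing from matrix: {sorted(unknown)[:5]}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# control: {self.control}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, control: str | None = None) -> "DesignSheet":
        text = Path(path).read_text()
        lines = text.splitlines(keepends=True)
        body_start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            if line[1:].strip().lower().startswith("control:"):
                control = line.split(":", 1)[1].strip()
            body_start += 1
        df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t")
        df["sample_id"] = df["sample_id"].astype(str)
        return cls(df, control=control or "shCtrl")


def expression_floor_filter(
    m: ExpressionMatrix, design: DesignSheet, floor: float = 7.0
) -> list[str]:
    """Features whose mean log2 signal over all Dox- samples is >= ``floor``.

    Minimally expressed genes produce false-discovery artifacts in
    fold-change analyses; the default floor of 7 (log2 signal units) sits
    just above the signal of a gene known to be silent in the assayed cells.
    The bound is inclusive; input order is preserved.
    """
    if m.scale != LOG2:
        raise ValueError("floor filter operates on log2-scale matrices")
    minus = design.samples(dox=DOX_MINUS)
    if not minus:
        raise ValueError("design sheet has no Dox- samples")
    design.check_against(m)
    means = m.values[minus].mean(axis=1)
    return list(m.values.index[means >= floor])


def baseline_signal(m: ExpressionMatrix, design: DesignSheet, feature_id: str) -> float:
    """Mean Dox- log2 signal of one named feature.

    Exposed as a calibration helper: the floor can be anchored on the
    observed baseline of a gene known to be unexpressed in the system.
    """
    if feature_id not in m.values.index:
        raise KeyError(feature_id)
    minus = design.samples(dox=DOX_MINUS)
    if not minus:
        raise ValueError("design sheet has no Dox- samples")
    return float(m.values.loc[feature_id, minus].mean())
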