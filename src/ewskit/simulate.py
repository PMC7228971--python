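"""Synthetic-data generator with known ground truth.

Emulates three experiment families so every downstream stage is testable
without external downloads:

* a Dox-inducible knockdown microarray experiment (2 cell lines x
  {control shRNA, two target shRNAs} x {Dox-, Dox+} x replicates) with
  gene-level differential effects and PSR-level splicing shifts;
* an 18-line x 264-drug sensitivity panel in which exactly one drug's
  log10 IC50 is an affine decreasing function of a marker gene's
  expression;
* a GGAA-microsatellite reporter panel: two alleles per cell line with
  tandem GGAA runs of recorded length, dual-luciferase measurements whose
  mean activity is affine in repeat count, and an expression readout
  affine in mean allele activity.

Signals live on the log2 scale with additive i.i.d. Gaussian noise, the
simplest model consistent with log-scale microarray analysis. All
randomness flows through a single seeded generator, so equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import DOX_MINUS, DOX_PLUS, LOG2, DesignSheet, ExpressionMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiments.

    Defaults mirror the knockdown design actually analysed: 2 cell lines,
    one control and two target shRNAs, 3 replicates per condition, 2,000
    genes with 50 injected differential effects of |log2 FC| in [1.2, 3]
    and measurement noise sd 0.15 (log2 units); an 18-line x 264-drug panel
    with one expression-coupled drug (slope -0.5 log10-IC50 per log2
    expression unit, noise sd 0.3); 8 reporter cell lines with GGAA runs
    of 8-25 units.
    """

    n_genes: int = 2000
    psr_per_gene_range: tuple[int, int] = (2, 5)
    cell_lines: tuple[str, ...] = ("CL1", "CL2")
    constructs: tuple[str, ...] = ("shCtrl", "shT1", "shT2")
    control_construct: str = "shCtrl"
    n_replicates: int = 3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    low_expressed_fraction: float = 0.2
    low_expressed_mean: float = 6.0
    low_expressed_sd: float = 0.5
    noise_sd: float = 0.15
    n_true_degs: int = 50
    deg_effect_range: tuple[float, float] = (1.2, 3.0)
    n_spliced_genes: int = 30
    splice_shift_range: tuple[float, float] = (0.5, 1.5)
    effect_floor: float = 7.5
    # cell-line panel
    n_lines_panel: int = 18
    n_drugs: int = 264
    coupled_drug_slope: float = -0.5
    coupled_drug_intercept: float = -7.6
    ic50_noise_sd: float = 0.3
    missing_fraction: float = 0.1
    panel_expr_mean: float = 8.0
    panel_expr_sd: float = 1.5
    # microsatellite reporter panel
    n_msat_lines: int = 8
    repeat_range: tuple[int, int] = (8, 25)
    activity_slope: float = 0.1
    activity_intercept: float = 0.5
    reporter_noise_sd: float = 0.05
    n_reporter_replicates: int = 3
    flank_length: int = 150
    expr_coupling_slope: float = 1.0
    expr_coupling_intercept: float = 6.0
    expr_coupling_noise_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_replicates", "n_true_degs", "n_spliced_genes",
                     "n_lines_panel", "n_drugs", "n_msat_lines"):
            if getattr(self, name) < 0 or (name in ("n_genes",) and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (variance needed for tests)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.deg_effect_range[0] < 1.0:
            raise ValueError(
                "deg_effect_range lower bound must be >= 1 so injected effects "
                "clear the DEG call threshold"
            )
        if self.deg_effect_range[0] <= 0 or self.splice_shift_range[0] <= 0:
            raise ValueError("effect ranges must not overlap zero")
        if self.control_construct not in self.constructs:
            raise ValueError("control_construct must be listed in constructs")
        if len(self.constructs) < 2:
            raise ValueError("need the control plus at least one target shRNA")
        if not (1 <= self.repeat_range[0] <= self.repeat_range[1] <= 100):
            raise ValueError("repeat_range must lie within [1, 100]")
        if self.psr_per_gene_range[0] < 1:
            raise ValueError("psr_per_gene_range lower bound must be >= 1")


@dataclass
class TruthTable:
    """Ground truth recorded during simulation, for recovery tests."""

    true_deg_effects: dict[str, float] = field(default_factory=dict)
    spliced_psr_shifts: dict[str, float] = field(default_factory=dict)
    coupled_drug_id: str | None = None
    coupled_drug_slope: float | None = None
    coupled_drug_intercept: float | None = None
    activity_slope: float | None = None
    activity_intercept: float | None = None
    allele_repeats: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        return cls(**json.loads(Path(path).read_text()))


def _draw_baseline(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    low = rng.random(cfg.n_genes) < cfg.low_expressed_fraction
    base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_genes)
    base[low] = rng.normal(cfg.low_expressed_mean, cfg.low_expressed_sd, int(low.sum()))
    return base


def simulate_knockdown_experiment(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, DesignSheet, pd.DataFrame, TruthTable]:
    """Simulate the knockdown microarray experiment.

    Returns (gene matrix, PSR matrix, design sheet, psr->gene map, truth).
    Target-shRNA Dox+ samples carry the injected gene effects; spliced PSRs
    carry an extra shift beyond their gene's effect; control-shRNA and Dox-
    samples carry noise only. Unspliced PSR signal equals the gene-level
    signal plus independent noise.

    Effects are injected only into genes whose baseline clears
    ``cfg.effect_floor``: a knockdown effect in an unexpressed gene is
    undetectable by construction, and the expression-floor filter would
    (correctly) drop it.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    baseline = _draw_baseline(rng, cfg)

    eligible = np.flatnonzero(baseline >= cfg.effect_floor)
    n_pick = cfg.n_true_degs + cfg.n_spliced_genes
    if n_pick > eligible.size:
        raise ValueError(
            f"cannot draw {n_pick} effect genes from {eligible.size} genes "
            f"above the effect floor"
        )
    picked = rng.choice(eligible, size=n_pick, replace=False)
    deg_idx = picked[: cfg.n_true_degs]
    spliced_gene_idx = picked[cfg.n_true_degs:]

    lo, hi = cfg.deg_effect_range
    deg_effects = rng.uniform(lo, hi, cfg.n_true_degs) * rng.choice([-1.0, 1.0], cfg.n_true_degs)
    effect = np.zeros(cfg.n_genes)
    effect[deg_idx] = deg_effects

    # design sheet
    rows = []
    for line in cfg.cell_lines:
        for construct in cfg.constructs:
            for dox in (DOX_MINUS, DOX_PLUS):
                for rep in range(1, cfg.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{line}_{construct}_{dox}_r{rep}",
                            "cell_line": line,
                            "construct": construct,
                            "dox": dox,
                            "replicate": rep,
                        }
                    )
    design = DesignSheet(pd.DataFrame(rows), control=cfg.control_construct)

    # PSR structure
    k_lo, k_hi = cfg.psr_per_gene_range
    n_psr_per_gene = rng.integers(k_lo, k_hi + 1, cfg.n_genes)
    psr_ids, psr_gene_idx = [], []
    for gi, k in enumerate(n_psr_per_gene):
        for j in range(k):
            psr_ids.append(f"{genes[gi]}_psr{j + 1}")
            psr_gene_idx.append(gi)
    psr_gene_idx = np.asarray(psr_gene_idx)
    psr_map = pd.DataFrame(
        {"psr_id": psr_ids, "gene_id": [genes[gi] for gi in psr_gene_idx]}
    )

    # one spliced PSR per spliced gene
    s_lo, s_hi = cfg.splice_shift_range
    spliced_psr_shift = np.zeros(len(psr_ids))
    spliced_shifts: dict[str, float] = {}
    for gi in spliced_gene_idx:
        candidates = np.flatnonzero(psr_gene_idx == gi)
        pi = int(rng.choice(candidates))
        shift = float(rng.uniform(s_lo, s_hi) * rng.choice([-1.0, 1.0]))
        spliced_psr_shift[pi] = shift
        spliced_shifts[psr_ids[pi]] = shift

    # signals
    sample_ids = list(design.table["sample_id"])
    is_target_plus = (
        (design.table["construct"] != cfg.control_construct)
        & (design.table["dox"] == DOX_PLUS)
    ).to_numpy()
    gene_signal = baseline[:, None] + np.where(is_target_plus[None, :], effect[:, None], 0.0)
    gene_values = gene_signal + rng.normal(0.0, cfg.noise_sd, gene_signal.shape)

    psr_signal = gene_signal[psr_gene_idx, :] + np.where(
        is_target_plus[None, :], spliced_psr_shift[:, None], 0.0
    )
    psr_values = psr_signal + rng.normal(0.0, cfg.noise_sd, psr_signal.shape)

    gene_m = ExpressionMatrix(
        pd.DataFrame(gene_values, index=genes, columns=sample_ids), scale=LOG2
    )
    psr_m = ExpressionMatrix(
        pd.DataFrame(psr_values, index=psr_ids, columns=sample_ids), scale=LOG2
    )
    truth = TruthTable(
        true_deg_effects={genes[gi]: float(e) for gi, e in zip(deg_idx, deg_effects)},
        spliced_psr_shifts=spliced_shifts,
        seed=cfg.seed,
    )
    return gene_m, psr_m, design, psr_map, truth


def simulate_cellline_panel(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, TruthTable]:
    """Simulate the drug-sensitivity panel.

    Returns (panel expression matrix, drug x cell-line log10 IC50 table,
    truth). Exactly one drug's log10 IC50 is affine in the marker gene's
    expression (slope ``coupled_drug_slope``, centred on the panel mean
    expression) plus noise; all other drugs are independent of expression.
    A ``missing_fraction`` of IC50 entries is blanked completely at random
    to exercise pairwise-complete correlation.
    """
    cfg.validate()
    if cfg.n_lines_panel < 4:
        raise ValueError("n_lines_panel must be >= 4")
    if cfg.n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    lines = [f"LINE{i + 1:02d}" for i in range(cfg.n_lines_panel)]
    drugs = [f"drug{i + 1:03d}" for i in range(cfg.n_drugs)]

    marker = rng.normal(cfg.panel_expr_mean, cfg.panel_expr_sd, cfg.n_lines_panel)
    n_filler = 19
    filler = rng.normal(cfg.panel_expr_mean, cfg.panel_expr_sd, (n_filler, cfg.n_lines_panel))
    expr = pd.DataFrame(
        np.vstack([marker[None, :], filler]),
        index=["MARKER"] + [f"filler{i + 1:02d}" for i in range(n_filler)],
        columns=lines,
    )

    coupled = int(rng.integers(cfg.n_drugs))
    drug_means = rng.normal(-6.0, 1.0, cfg.n_drugs)
    ic50 = drug_means[:, None] + rng.normal(0.0, cfg.ic50_noise_sd, (cfg.n_drugs, cfg.n_lines_panel))
    ic50[coupled, :] = (
        cfg.coupled_drug_intercept
        + cfg.coupled_drug_slope * (marker - cfg.panel_expr_mean)
        + rng.normal(0.0, cfg.ic50_noise_sd, cfg.n_lines_panel)
    )
    table = pd.DataFrame(ic50, index=drugs, columns=lines)
    if cfg.missing_fraction > 0:
        mask = rng.random(table.shape) < cfg.missing_fraction
        # keep at least 3 observed lines per drug so every drug stays testable
        for i in range(cfg.n_drugs):
            if (~mask[i]).sum() < 3:
                mask[i, :] = False
        table = table.mask(mask)

    truth = TruthTable(
        coupled_drug_id=drugs[coupled],
        coupled_drug_slope=cfg.coupled_drug_slope,
        coupled_drug_intercept=cfg.coupled_drug_intercept,
        seed=cfg.seed,
    )
    return ExpressionMatrix(expr, scale=LOG2), table, truth


_GGAA_RUN = re.compile(r"(?:GGAA)+")


def _random_flank(rng: np.random.Generator, length: int, max_run: int) -> str:
    """Random flank with accidental GGAA runs capped below max_run.

    Flanks also never start or end with a full GGAA unit, so they cannot
    extend the embedded run across the junction and the recorded repeat
    count stays unambiguous.
    """
    while True:
        seq = "".join(rng.choice(_BASES, size=length))
        worst = max((len(m.group()) // 4 for m in _GGAA_RUN.finditer(seq)), default=0)
        if worst < max_run and not seq.startswith("GGAA") and not seq.endswith("GGAA"):
            return seq


def simulate_msat_panel(
    cfg: SimulationConfig,
) -> tuple[dict[str, str], pd.DataFrame, pd.Series, TruthTable]:
    """Simulate the GGAA-microsatellite reporter panel.

    Returns (allele sequences keyed ``cellline|allele``, reporter
    measurement table, per-line expression vector, truth). Each cell line
    has two alleles embedding a tandem GGAA run of recorded length in
    random flank sequence; firefly/renilla measurements have mean activity
    = intercept + slope * repeats; expression is affine in mean allele
    activity.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lines = [f"MS{i + 1:02d}" for i in range(cfg.n_msat_lines)]
    r_lo, r_hi = cfg.repeat_range

    sequences: dict[str, str] = {}
    repeats: dict[str, int] = {}
    rows = []
    mean_activity = {}
    for line in lines:
        per_allele = []
        for allele in (1, 2):
            k = int(rng.integers(r_lo, r_hi + 1))
            key = f"{line}|{allele}"
            repeats[key] = k
            sequences[key] = (
                _random_flank(rng, cfg.flank_length, r_lo)
                + "GGAA" * k
                + _random_flank(rng, cfg.flank_length, r_lo)
            )
            activity = cfg.activity_intercept + cfg.activity_slope * k
            if activity <= 0:
                raise ValueError("activity model yields nonpositive mean activity")
            for rep in range(1, cfg.n_reporter_replicates + 1):
                renilla = float(rng.uniform(80.0, 120.0))
                noise = (
                    float(np.exp(rng.normal(0.0, cfg.reporter_noise_sd)))
                    if cfg.reporter_noise_sd > 0
                    else 1.0
                )
                rows.append(
                    {
                        "cell_line": line,
                        "allele": allele,
                        "condition": "plain",
                        "replicate": rep,
                        "firefly": activity * noise * renilla,
                        "renilla": renilla,
                    }
                )
            per_allele.append(activity)
        mean_activity[line] = float(np.mean(per_allele))

    expr = pd.Series(
        {
            line: cfg.expr_coupling_intercept
            + cfg.expr_coupling_slope * mean_activity[line]
            + (rng.normal(0.0, cfg.expr_coupling_noise_sd) if cfg.expr_coupling_noise_sd > 0 else 0.0)
            for line in lines
        },
        name="expression",
    )
    truth = TruthTable(
        activity_slope=cfg.activity_slope,
        activity_intercept=cfg.activity_intercept,
        allele_repeats=repeats,
        seed=cfg.seed,
    )
    return sequences, pd.DataFrame(rows), expr, truth


def write_allele_fasta(sequences: dict[str, str], path: str | Path) -> None:
    """Write allele sequences as FASTA (record id = ``cellline|allele``)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
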