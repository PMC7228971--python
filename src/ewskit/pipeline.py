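"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the enabled stages in order (simulate -> deg ->
splice -> screen -> enhancer -> report) on a single config, writes each
stage's TSV/JSON outputs plus a provenance block (parameters, seed, config
hash), and aggregates headline numbers — DEG up/down counts, consistent-PSR
count, drug shortlist, enhancer correlations, truth-recovery metrics —
into one machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import contrasts, deg, drugscreen, enhancer, enrichment, matrix, simulate, splicing

log = logging.getLogger("ewskit")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "ewskit_out",
    "stages": {
        "simulate": True,
        "deg": True,
        "splice": True,
        "screen": True,
        "enhancer": True,
    },
    "floor": 7.0,
    "fc_threshold": 1.0,
    "psr_threshold": 0.3,
    "psr_rule": splicing.RULE_ALL_PAIRS,
    "alpha": 0.05,
    "n_perm": 1000,
    "gsea_weight": 1.0,
    "top_k": 7,
    "potency_threshold": 1e-6,
    "both_strands": False,
    "min_coverage": 4,
    "simulation": {},  # overrides for SimulationConfig fields
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML/JSON config file <- explicit overrides."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            loaded = yaml.safe_load(text)
        else:
            loaded = json.loads(text)
        _deep_update(cfg, loaded or {})
    if overrides:
        _deep_update(cfg, overrides)
    _validate_config(cfg)
    return cfg


def _deep_update(base: dict, new: dict) -> None:
    for k, v in new.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    unknown_stage = set(cfg["stages"]) - set(DEFAULT_CONFIG["stages"])
    if unknown_stage:
        raise ValueError(f"unknown stages: {sorted(unknown_stage)}")
    if any(cfg["stages"].values()) and not isinstance(cfg["seed"], int):
        raise ValueError("seed (integer) is mandatory when any stage is enabled")
    for field in ("floor", "fc_threshold", "psr_threshold", "alpha"):
        if not isinstance(cfg[field], (int, float)):
            raise ValueError(f"config field {field!r} must be numeric")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    # fixed scientific formatting for byte-reproducible reruns
    df.rename_axis(index_label).to_csv(path, sep="\t", float_format="%.6e")


def run_pipeline(config: dict) -> dict:
    """Run the enabled stages; returns (and writes) the summary report."""
    cfg = json.loads(json.dumps(config))
    _validate_config(cfg)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    summary: dict = {"config_hash": chash, "seed": cfg["seed"], "stages_run": []}
    stages = cfg["stages"]
    if not any(stages.values()):
        _write_summary(summary, outdir)
        return summary

    sim_cfg = simulate.SimulationConfig(**cfg["simulation"], seed=cfg["seed"])
    gene_m = psr_m = design = psr_map = truth = None

    if stages.get("simulate"):
        log.info("stage simulate: knockdown experiment, panel, reporter panel")
        gene_m, psr_m, design, psr_map, truth = simulate.simulate_knockdown_experiment(sim_cfg)
        gene_m.to_tsv(outdir / "gene_expression.tsv")
        psr_m.to_tsv(outdir / "psr_expression.tsv")
        design.to_tsv(outdir / "design.tsv")
        psr_map.to_csv(outdir / "psr_map.tsv", sep="\t", index=False)
        truth.to_json(outdir / "truth_knockdown.json")
        summary["stages_run"].append("simulate")

    if stages.get("deg"):
        if gene_m is None:
            raise RuntimeError("deg stage requires the simulate stage (or file inputs via the CLI)")
        log.info("stage deg: contrasts, calls, q-values, enrichment")
        kept = matrix.expression_floor_filter(gene_m, design, floor=cfg["floor"])
        ct = contrasts.build_contrast_table(gene_m, design, features=kept)
        p = deg.per_gene_pvalues(ct.replicate_fcs)
        q = deg.storey_qvalue(p.to_numpy())
        result = deg.call_degs(ct.mean_fc, p=p, q=q, fc_threshold=cfg["fc_threshold"])
        _write_tsv(result.table, outdir / "deg_results.tsv", "gene_id")
        called = set(result.deg_ids)
        truth_set = set(truth.true_deg_effects) & set(kept)
        negatives = set(kept) - truth_set
        sens = len(called & truth_set) / len(truth_set) if truth_set else float("nan")
        spec = 1.0 - len(called & negatives) / len(negatives) if negatives else float("nan")
        down_truth = [g for g, e in truth.true_deg_effects.items() if e < 0 and g in kept]
        gsea_summary = None
        if down_truth:
            sets = {"injected_down": down_truth}
            gres = enrichment.preranked_gsea(
                ct.mean_fc, sets, n_perm=cfg["n_perm"], weight=cfg["gsea_weight"],
                seed=cfg["seed"],
            )
            _write_tsv(gres.table, outdir / "gsea_results.tsv", "gene_set")
            row = gres.table.loc["injected_down"]
            gsea_summary = {"es": float(row["es"]), "nes": float(row["nes"]),
                            "nom_p": float(row["nom_p"])}
        summary["deg"] = {
            "n_genes_kept": len(kept),
            "n_up": result.n_up,
            "n_down": result.n_down,
            "sensitivity": sens,
            "specificity": spec,
            "gsea_injected_down": gsea_summary,
        }
        summary["stages_run"].append("deg")

    if stages.get("splice"):
        if psr_m is None:
            raise RuntimeError("splice stage requires the simulate stage")
        log.info("stage splice: PSR additional FCs, consistency, significance")
        kept = matrix.expression_floor_filter(gene_m, design, floor=cfg["floor"])
        gene_ct = contrasts.build_contrast_table(gene_m, design, features=kept)
        keep_psr = psr_map[psr_map["gene_id"].isin(kept)]["psr_id"]
        psr_ct = contrasts.build_contrast_table(psr_m, design, features=list(keep_psr))
        sres = splicing.analyze_splicing(
            psr_m, gene_m, design, psr_map, psr_ct, gene_ct,
            threshold=cfg["psr_threshold"], rule=cfg["psr_rule"], alpha=cfg["alpha"],
        )
        _write_tsv(sres.table, outdir / "splicing_results.tsv", "psr_id")
        truth_spliced = set(truth.spliced_psr_shifts) & set(sres.table.index)
        called = set(sres.table.index[sres.table["consistent"]])
        neg = set(sres.table.index) - truth_spliced
        summary["splice"] = {
            **sres.summary(),
            "sensitivity": (
                len(called & truth_spliced) / len(truth_spliced) if truth_spliced else float("nan")
            ),
            "specificity": 1.0 - len(called & neg) / len(neg) if neg else float("nan"),
        }
        (outdir / "splicing_summary.json").write_text(json.dumps(sres.summary(), indent=2))
        summary["stages_run"].append("splice")

    if stages.get("screen"):
        log.info("stage screen: expression vs IC50 correlation screen")
        panel, responses, ptruth = simulate.simulate_cellline_panel(sim_cfg)
        table = drugscreen.DrugResponseTable(responses, scale=drugscreen.SCALE_LOG10)
        table.to_tsv(outdir / "drug_response.tsv")
        screen = drugscreen.correlate_expression_vs_ic50(panel.values.loc["MARKER"], table)
        shortlist = drugscreen.select_candidate_drugs(
            screen, alpha=cfg["alpha"], top_k=cfg["top_k"],
            potency_threshold=cfg["potency_threshold"],
        )
        _write_tsv(screen.sort_values("r"), outdir / "screen_results.tsv", "drug_id")
        _write_tsv(shortlist, outdir / "screen_shortlist.tsv", "drug_id")
        by_r = screen.dropna(subset=["r"]).sort_values("r", kind="stable")
        coupled_rank = int(np.flatnonzero(by_r.index == ptruth.coupled_drug_id)[0]) + 1
        summary["screen"] = {
            "n_drugs_tested": int(screen["p"].notna().sum()),
            "shortlist": list(shortlist.index),
            "coupled_drug": ptruth.coupled_drug_id,
            "coupled_drug_rank": coupled_rank,
            "coupled_in_shortlist": ptruth.coupled_drug_id in set(shortlist.index),
        }
        summary["stages_run"].append("screen")

    if stages.get("enhancer"):
        log.info("stage enhancer: GGAA repeats, reporter activity, correlations")
        seqs, meas, expr, etruth = simulate.simulate_msat_panel(sim_cfg)
        simulate.write_allele_fasta(seqs, outdir / "alleles.fasta")
        meas.to_csv(outdir / "reporter_measurements.tsv", sep="\t", index=False)
        alleles = enhancer.read_allele_fasta(outdir / "alleles.fasta")
        alleles["repeats"] = [
            enhancer.count_consecutive_ggaa(s, both_strands=cfg["both_strands"]).max_run
            for s in alleles["sequence"]
        ]
        reference = sorted(alleles["cell_line"].unique())[0]
        act = enhancer.reporter_activity(meas, reference_line=reference)
        per_line, corr = enhancer.allele_average_and_correlate(act, alleles, expr)
        _write_tsv(per_line, outdir / "enhancer_per_line.tsv", "cell_line")
        recovered = {
            f"{r.cell_line}|{r.allele}": int(r.repeats) for r in alleles.itertuples()
        }
        summary["enhancer"] = {
            "correlations": corr,
            "repeat_recovery_fraction": float(
                np.mean([recovered[k] == v for k, v in etruth.allele_repeats.items()])
            ),
            "reference_line": reference,
        }
        summary["stages_run"].append("enhancer")

    _write_summary(summary, outdir)
    return summary


def _write_summary(summary: dict, outdir: Path) -> None:
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
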