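import numpy as np
import pandas as pd
import pytest

from ewskit import contrasts, matrix, splicing
from ewskit.simulate import SimulationConfig, simulate_knockdown_experiment


def _contrast_pair(psr_fc: float, gene_fc: float):
    psr = pd.DataFrame({"CL1|shT1": [psr_fc]}, index=["g0_psr1"])
    gene = pd.DataFrame({"CL1|shT1": [gene_fc]}, index=["g0"])
    mk = lambda c: contrasts.ContrastTable(
        raw=c, corrected=c, mean_fc=c.mean(axis=1), replicate_fcs=c
    )
    psr_map = pd.DataFrame({"psr_id": ["g0_psr1"], "gene_id": ["g0"]})
    return mk(psr), mk(gene), psr_map


class TestAdditionalFc:
    @pytest.mark.parametrize(
        "psr_fc,gene_fc,expected", [(-1.5, -1.5, 0.0), (-0.5, -1.5, 1.0)]
    )
    def test_pointwise_difference(self, psr_fc, gene_fc, expected):
        psr_ct, gene_ct, psr_map = _contrast_pair(psr_fc, gene_fc)
        add = splicing.psr_additional_fc(psr_ct, gene_ct, psr_map)
        assert add.loc["g0_psr1", "CL1|shT1"] == pytest.approx(expected)

    def test_orphan_psr_rejected(self):
        psr_ct, gene_ct, _ = _contrast_pair(0.0, 0.0)
        bad_map = pd.DataFrame({"psr_id": ["g0_psr1"], "gene_id": ["missing_gene"]})
        with pytest.raises(ValueError, match="absent"):
            splicing.psr_additional_fc(psr_ct, gene_ct, bad_map)

    def test_noise_free_construction(self, knockdown_noisefree):
        kd = knockdown_noisefree
        gene_ct = contrasts.build_contrast_table(kd["gene"], kd["design"])
        psr_ct = contrasts.build_contrast_table(kd["psr"], kd["design"])
        add = splicing.psr_additional_fc(psr_ct, gene_ct, kd["psr_map"])
        shifts = kd["truth"].spliced_psr_shifts
        for psr_id, shift in shifts.items():
            assert add.loc[psr_id].to_numpy() == pytest.approx(shift)
        unspliced = add.index.difference(shifts)
        assert np.abs(add.loc[unspliced].to_numpy()).max() < 1e-12

    def test_gene_level_invariance(self, knockdown_default):
        # shifting a gene and all its PSRs by a constant leaves additional FCs unchanged
        kd = knockdown_default
        gene = kd["psr_map"]["gene_id"].iloc[0]
        psrs = kd["psr_map"][kd["psr_map"]["gene_id"] == gene]["psr_id"]
        g2 = matrix.ExpressionMatrix(kd["gene"].values.copy(), scale=matrix.LOG2)
        p2 = matrix.ExpressionMatrix(kd["psr"].values.copy(), scale=matrix.LOG2)
        g2.values.loc[gene] += 1.23
        p2.values.loc[psrs] += 1.23
        base = splicing.psr_additional_fc(
            contrasts.build_contrast_table(kd["psr"], kd["design"]),
            contrasts.build_contrast_table(kd["gene"], kd["design"]),
            kd["psr_map"],
        )
        moved = splicing.psr_additional_fc(
            contrasts.build_contrast_table(p2, kd["design"]),
            contrasts.build_contrast_table(g2, kd["design"]),
            kd["psr_map"],
        )
        assert np.allclose(base.to_numpy(), moved.to_numpy())


class TestConsistencyFilter:
    def _frame(self, values):
        return pd.DataFrame([values], index=["psr"], columns=["A|1", "A|2", "B|1", "B|2"])

    def test_all_pairs_rule(self):
        flags, n, _ = splicing.psr_consistency_filter(self._frame([0.4, 0.35, 0.5, 0.31]))
        assert flags["psr"] and n == 1

    def test_sign_flip_fails(self):
        flags, n, _ = splicing.psr_consistency_filter(self._frame([0.4, -0.4, 0.4, 0.4]))
        assert not flags["psr"] and n == 0

    def test_rule_variants_differ_on_borderline_case(self):
        vals = self._frame([0.31, 0.29, 0.4, 0.4])
        strict, _, _ = splicing.psr_consistency_filter(vals, rule=splicing.RULE_ALL_PAIRS)
        lenient, _, _ = splicing.psr_consistency_filter(vals, rule=splicing.RULE_MEAN)
        assert not strict["psr"]
        assert lenient["psr"]

    def test_gene_counts_and_negative_threshold(self):
        add = pd.DataFrame(
            {"A|1": [0.5, 0.6, -0.1]}, index=["g0_psr1", "g0_psr2", "g1_psr1"]
        )
        psr_map = pd.DataFrame(
            {"psr_id": add.index, "gene_id": ["g0", "g0", "g1"]}
        )
        flags, n_psr, n_gene = splicing.psr_consistency_filter(add, psr_map=psr_map)
        assert (n_psr, n_gene) == (2, 1)
        with pytest.raises(ValueError):
            splicing.psr_consistency_filter(add, threshold=-0.1)


class TestSignificance:
    def test_all_zero_replicates_not_significant(self):
        reps = pd.DataFrame([[0.0] * 6], index=["psr"])
        out = splicing.psr_significance(reps)
        assert out.loc["psr", "p"] == 1.0
        assert not out.loc["psr", "significant"]

    def test_m_one_bonferroni_equals_alpha(self):
        reps = pd.DataFrame([[0.5, 0.52, 0.48, 0.51]], index=["psr"])
        out = splicing.psr_significance(reps, alpha=0.05, m=1)
        assert out.loc["psr", "significant"] == out.loc["psr", "bonferroni_significant"]

    def test_null_type_one_error_calibrated(self):
        # no splicing, noise only: raw positive rate ~ alpha, Bonferroni clean
        rates, bonf_clean = [], 0
        for seed in range(5):
            cfg = SimulationConfig(
                n_genes=1000, psr_per_gene_range=(4, 4), n_true_degs=0,
                n_spliced_genes=0, low_expressed_fraction=0.0, seed=seed,
            )
            gene_m, psr_m, design, psr_map, _ = simulate_knockdown_experiment(cfg)
            reps = splicing.replicate_additional_fc(psr_m, gene_m, design, psr_map)
            sig = splicing.psr_significance(reps)
            rates.append(sig["significant"].mean())
            bonf_clean += int(sig["bonferroni_significant"].sum() == 0)
        pooled = float(np.mean(rates))
        n_total = 4000 * 5
        band = 3.5 * np.sqrt(0.05 * 0.95 / n_total)
        assert abs(pooled - 0.05) < band
        assert bonf_clean >= 4

    def test_unbalanced_design_rejected(self, knockdown_default):
        kd = knockdown_default
        drop = kd["design"].table["sample_id"].iloc[-1]
        table = kd["design"].table[kd["design"].table["sample_id"] != drop]
        design = matrix.DesignSheet(table, control=kd["design"].control)
        with pytest.raises(ValueError, match="balanced"):
            splicing.replicate_additional_fc(kd["psr"], kd["gene"], design, kd["psr_map"])


class TestEndToEnd:
    def test_default_recovery_is_strong_but_noise_limited(self, knockdown_default):
        kd = knockdown_default
        kept = matrix.expression_floor_filter(kd["gene"], kd["design"])
        gene_ct = contrasts.build_contrast_table(kd["gene"], kd["design"], features=kept)
        keep_psr = list(kd["psr_map"][kd["psr_map"]["gene_id"].isin(kept)]["psr_id"])
        psr_ct = contrasts.build_contrast_table(kd["psr"], kd["design"], features=keep_psr)
        res = splicing.analyze_splicing(
            kd["psr"], kd["gene"], kd["design"], kd["psr_map"], psr_ct, gene_ct
        )
        truth = set(kd["truth"].spliced_psr_shifts) & set(res.table.index)
        called = set(res.table.index[res.table["consistent"]])
        negatives = set(res.table.index) - truth
        sens = len(called & truth) / len(truth)
        spec = 1.0 - len(called & negatives) / len(negatives)
        # the 0.3 consistency margin is ~1 sd of the per-pair additional-FC
        # noise at the smallest injected shifts, so recovery is high, not exact
        assert sens >= 0.8
        assert spec >= 0.99
        assert res.summary()["n_consistent_psrs"] == len(called)

    def test_noise_free_recovery_is_exact(self, knockdown_noisefree):
        kd = knockdown_noisefree
        gene_ct = contrasts.build_contrast_table(kd["gene"], kd["design"])
        psr_ct = contrasts.build_contrast_table(kd["psr"], kd["design"])
        res = splicing.analyze_splicing(
            kd["psr"], kd["gene"], kd["design"], kd["psr_map"], psr_ct, gene_ct
        )
        called = set(res.table.index[res.table["consistent"]])
        assert called == set(kd["truth"].spliced_psr_shifts)
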