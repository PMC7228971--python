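import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewskit import enhancer
from ewskit.simulate import SimulationConfig, simulate_msat_panel


def _regex_max_run(seq: str, motif: str = "GGAA") -> int:
    runs = re.findall(f"(?:{motif})+", seq)
    return max((len(r) // len(motif) for r in runs), default=0)


class TestGgaaScanner:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GGAAGGAAGGAA", 3),
            ("GGAAGGAGGAA", 1),  # frame break
            ("TTTT", 0),
            ("GGAANGGAA", 1),  # N terminates a run
        ],
    )
    def test_known_sequences(self, seq, expected):
        assert enhancer.count_consecutive_ggaa(seq).max_run == expected

    def test_run_positions_are_zero_based_half_open(self):
        runs = enhancer.count_consecutive_ggaa("TTGGAAGGAACC").runs
        assert runs == [(2, 2)]  # units at [2, 10)

    def test_empty_and_invalid_sequences_rejected(self):
        with pytest.raises(ValueError):
            enhancer.count_consecutive_ggaa("")
        with pytest.raises(ValueError, match="invalid"):
            enhancer.count_consecutive_ggaa("GGXA")

    def test_both_strands_flag_sees_ttcc_runs(self):
        seq = "TTCCTTCCTTCC" + "GGAA"
        assert enhancer.count_consecutive_ggaa(seq).max_run == 1
        assert enhancer.count_consecutive_ggaa(seq, both_strands=True).max_run == 3

    def test_embedded_runs_match_regex_oracle(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            k = int(rng.integers(6, 26))
            flank1 = "".join(rng.choice(bases, 60))
            flank2 = "".join(rng.choice(bases, 60))
            seq = flank1 + "GGAA" * k + flank2
            assert enhancer.count_consecutive_ggaa(seq).max_run == _regex_max_run(seq)

    @settings(derandomize=True, max_examples=300)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=120))
    def test_scanner_equals_regex_oracle_on_arbitrary_dna(self, seq):
        assert enhancer.count_consecutive_ggaa(seq).max_run == _regex_max_run(seq)

    def test_recorded_repeats_recovered_from_simulated_alleles(self):
        cfg = SimulationConfig(seed=11)
        seqs, _, _, truth = simulate_msat_panel(cfg)
        for key, seq in seqs.items():
            assert enhancer.count_consecutive_ggaa(seq).max_run == truth.allele_repeats[key]


def _measurements(activity_by_line, reps=3):
    rows = []
    for line, per_allele in activity_by_line.items():
        for allele, act in enumerate(per_allele, start=1):
            for rep in range(1, reps + 1):
                rows.append(
                    {
                        "cell_line": line,
                        "allele": allele,
                        "condition": "plain",
                        "replicate": rep,
                        "firefly": act * 100.0,
                        "renilla": 100.0,
                    }
                )
    return pd.DataFrame(rows)


class TestReporterActivity:
    def test_firefly_over_renilla(self):
        meas = _measurements({"REF": (5.0, 5.0)})
        act = enhancer.reporter_activity(meas, reference_line="REF")
        assert np.allclose(act["activity"], 1.0)  # rescaled to reference = 1

    def test_reference_rescaling_identity(self):
        meas = _measurements({"REF": (2.0, 2.0), "OTHER": (2.0, 2.0)})
        act = enhancer.reporter_activity(meas, reference_line="REF")
        assert np.allclose(act["activity"], 1.0)

    def test_rescaling_invariant_to_joint_global_scaling(self):
        meas = _measurements({"REF": (2.0, 3.0), "OTHER": (4.0, 1.0)})
        scaled = meas.assign(firefly=meas["firefly"] * 7.0, renilla=meas["renilla"] * 7.0)
        a = enhancer.reporter_activity(meas, reference_line="REF")
        b = enhancer.reporter_activity(scaled, reference_line="REF")
        assert np.allclose(a["activity"], b["activity"])

    def test_differential_mode_takes_dox_ratio(self):
        rows = []
        for cond, act in (("minus", 6.0), ("plus", 2.0)):
            rows.append(
                {"cell_line": "REF", "allele": 1, "condition": cond,
                 "replicate": 1, "firefly": act * 100, "renilla": 100.0}
            )
        meas = pd.DataFrame(rows)
        act = enhancer.reporter_activity(
            meas, reference_line="REF", dox_mode=enhancer.DOX_DIFFERENTIAL
        )
        # single line, rescaled to itself = 1; the raw ratio was 3
        assert act["activity"].iloc[0] == pytest.approx(1.0)

    def test_missing_reference_and_nonpositive_renilla_rejected(self):
        meas = _measurements({"A": (1.0, 1.0)})
        with pytest.raises(ValueError, match="reference"):
            enhancer.reporter_activity(meas, reference_line="NOPE")
        bad = meas.assign(renilla=0.0)
        with pytest.raises(ValueError, match="renilla"):
            enhancer.reporter_activity(bad, reference_line="A")


class TestAlleleAveragingAndCorrelations:
    def test_allele_average(self):
        act = pd.DataFrame(
            {"cell_line": ["A", "A"], "allele": [1, 2], "activity": [0.8, 1.2]}
        )
        single = act.groupby("cell_line")["activity"].mean()
        assert single["A"] == pytest.approx(1.0)

    def test_single_allele_line_excluded_with_warning(self):
        act = pd.DataFrame(
            {
                "cell_line": ["A", "A", "B", "C", "C", "D", "D"],
                "allele": [1, 2, 1, 1, 2, 1, 2],
                "activity": [1.0, 1.2, 0.9, 1.5, 1.4, 2.0, 2.2],
            }
        )
        reps = act.assign(repeats=[10, 12, 9, 15, 14, 20, 22])[
            ["cell_line", "allele", "repeats"]
        ]
        expr = pd.Series({"A": 7.0, "B": 6.5, "C": 8.0, "D": 9.0})
        with pytest.warns(UserWarning, match="single measured allele"):
            table, corr = enhancer.allele_average_and_correlate(act, reps, expr)
        assert "B" not in table.index
        assert set(corr) == {
            "activity_vs_expression", "repeats_vs_activity", "repeats_vs_expression"
        }

    def test_noise_free_panel_perfect_correlation(self):
        cfg = SimulationConfig(
            reporter_noise_sd=0.0, expr_coupling_noise_sd=0.0, seed=1
        )
        seqs, meas, expr, truth = simulate_msat_panel(cfg)
        alleles = pd.DataFrame(
            [
                {"cell_line": k.split("|")[0], "allele": int(k.split("|")[1]),
                 "repeats": truth.allele_repeats[k]}
                for k in seqs
            ]
        )
        act = enhancer.reporter_activity(meas, reference_line="MS01")
        _, corr = enhancer.allele_average_and_correlate(act, alleles, expr)
        assert corr["activity_vs_expression"]["r"] == pytest.approx(1.0)
        assert corr["repeats_vs_activity"]["r"] == pytest.approx(1.0)


class TestLocusAssociation:
    def test_affine_cnv_gives_r_one_and_diploid_is_undefined(self):
        seg = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
        df = pd.DataFrame({"segment_mean": seg, "expression": 7.0 + 2.0 * seg})
        out = enhancer.cnv_expression_association(df)
        assert out["r"] == pytest.approx(1.0)
        diploid = pd.DataFrame({"segment_mean": np.zeros(5), "expression": seg})
        out2 = enhancer.cnv_expression_association(diploid)
        assert not out2["defined"]

    def test_null_cnv_p_uniform(self):
        rng = np.random.default_rng(0)
        hits, n_null = 0, 600
        for _ in range(n_null):
            df = pd.DataFrame(
                {"segment_mean": rng.normal(size=32), "expression": rng.normal(size=32)}
            )
            hits += enhancer.cnv_expression_association(df)["p"] <= 0.05
        frac = hits / n_null
        assert abs(frac - 0.05) < 3.5 * np.sqrt(0.05 * 0.95 / n_null)

    @pytest.mark.parametrize(
        "meth,unmeth,expected",
        [(3, 1, 0.75), (0, 4, 0.0)],
    )
    def test_methylation_ratio(self, meth, unmeth, expected):
        counts = pd.DataFrame(
            {"tumor_id": ["t1"], "site": ["cpg1"], "methylated": [meth],
             "unmethylated": [unmeth]}
        )
        out, _ = enhancer.cpg_methylation_ratio(counts)
        assert out["ratio"].iloc[0] == pytest.approx(expected)

    def test_coverage_gate_and_monotonicity(self):
        counts = pd.DataFrame(
            {
                "tumor_id": ["t1", "t2", "t3"],
                "site": ["cpg1"] * 3,
                "methylated": [2, 3, 5],
                "unmethylated": [1, 1, 5],
            }
        )
        out4, _ = enhancer.cpg_methylation_ratio(counts, min_coverage=4)
        assert out4["ratio"].isna().tolist() == [True, False, False]
        out6, _ = enhancer.cpg_methylation_ratio(counts, min_coverage=6)
        # raising the coverage bound never adds sites
        assert set(out6.dropna(subset=["ratio"]).index) <= set(
            out4.dropna(subset=["ratio"]).index
        )
        with pytest.raises(ValueError, match=">= 0"):
            enhancer.cpg_methylation_ratio(counts.assign(methylated=[-1, 1, 1]))
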