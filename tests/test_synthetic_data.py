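"""Generator contracts: composition, determinism, moments, round-trips."""

import numpy as np
import pandas as pd
import pytest

from mrdenrich import enrichment
from mrdenrich.molecule_counter import count_reads
from mrdenrich.synthetic_data import (
    INDEL_TYPES,
    SNV_TYPES,
    SimConfig,
    score_to_step_efficiency,
    simulate_counts,
    simulate_panel,
    simulate_reads,
)


class TestConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(n_probes=10, snv_fraction=0.8, indel_fraction=0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duplex_probability": 0.0},
            {"ss_to_duplex_error_ratio": 0.5},
            {"input_mass_pg": -1.0},
            {"vaf_levels": (0.1, 1.5)},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(n_probes=10, **kwargs)

    def test_haploid_copies_arithmetic(self):
        cfg = SimConfig(n_probes=1)
        assert cfg.haploid_copies == pytest.approx(6333, abs=1)


class TestPanelComposition:
    def test_default_split_1800(self):
        panel, _ = simulate_panel(SimConfig(n_probes=1800, seed=1))
        probes = panel[~panel["is_control"]]
        assert (probes["variant_class"] == "SNV").sum() == 1620
        assert (probes["variant_class"] == "InDel").sum() == 180

    def test_indel_classes_split_equally(self):
        panel, _ = simulate_panel(
            SimConfig(n_probes=4, snv_fraction=0.0, indel_fraction=1.0, seed=1)
        )
        probes = panel[~panel["is_control"]]
        assert sorted(probes["substitution_type"]) == sorted(INDEL_TYPES)

    def test_indel_lengths_capped_at_40(self):
        panel, _ = simulate_panel(
            SimConfig(n_probes=400, snv_fraction=0.0, indel_fraction=1.0, seed=2)
        )
        assert panel.loc[~panel["is_control"], "indel_length"].max() <= 40

    def test_determinism(self):
        cfg = SimConfig(n_probes=50, seed=11)
        a, _ = simulate_panel(cfg)
        b, _ = simulate_panel(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_score_link_anchor(self):
        """A score of 200 maps to the calibrated 0.47 step efficiency."""
        assert float(score_to_step_efficiency(200.0)) == pytest.approx(0.47, abs=1e-9)

    def test_truth_accompanies_panel(self):
        panel, truth = simulate_panel(SimConfig(n_probes=10, seed=3))
        assert {"epsilon", "selectivity", "lambda_duplex", "lambda_single"} <= set(
            truth.probes.columns
        )
        noncontrol = truth.probes[~truth.probes["is_control"]]
        assert (noncontrol["lambda_single"] >= noncontrol["lambda_duplex"]).all()


class TestCounts:
    def test_determinism(self, small_config, small_panel):
        panel, truth = small_panel
        a, ca, _ = simulate_counts(panel, truth, small_config)
        b, cb, _ = simulate_counts(panel, truth, small_config)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ca, cb)

    def test_no_signal_no_noise_gives_zero_alt(self):
        cfg = SimConfig(
            n_probes=10, vaf_levels=(0.0,), replicates_per_level=3,
            dropout_probability=0.0, seed=5,
        )
        panel, truth = simulate_panel(cfg)
        panel = panel.assign(lambda_duplex=0.0, lambda_single=0.0)
        counts, _, _ = simulate_counts(panel, truth, cfg)
        assert (counts["total_alt"] == 0).all()

    def test_empirical_mean_matches_model(self):
        """Mean simulated alternate counts sit within 3 SE of s*eps*C*f + lambda."""
        cfg = SimConfig(
            n_probes=1, vaf_levels=(0.01,), replicates_per_level=10_000,
            sample_sd=0.0, dropout_probability=0.0, seed=8,
        )
        panel, truth = simulate_panel(cfg)
        counts, _, truth = simulate_counts(panel, truth, cfg)
        probe = truth.probes[~truth.probes["is_control"]].iloc[0]
        mu = probe["epsilon"] * cfg.haploid_copies * 0.01 \
            + probe["lambda_duplex"] + probe["lambda_single"]
        obs = counts["total_alt"].to_numpy(float)
        se = obs.std(ddof=1) / np.sqrt(obs.size)
        assert abs(obs.mean() - mu) < 3 * se

    def test_expected_recovery_at_ten_percent(self):
        """A probe at the 0.19 end-to-end rate recovers ~120 of 633 input molecules."""
        cfg = SimConfig(
            n_probes=1, vaf_levels=(0.10,), replicates_per_level=4000,
            sample_sd=0.0, dropout_probability=0.0, seed=9,
        )
        panel, truth = simulate_panel(cfg)
        panel = panel.copy()
        panel.loc[~panel["is_control"], "epsilon"] = 0.40 * 0.47
        panel.loc[~panel["is_control"], "lambda_duplex"] = 0.0
        panel.loc[~panel["is_control"], "lambda_single"] = 0.0
        counts, _, _ = simulate_counts(panel, truth, cfg)
        assert counts["total_alt"].mean() == pytest.approx(120, abs=2)

    def test_unit_selectivity_panel_estimates_near_one(self):
        cfg = SimConfig(
            n_probes=30, vaf_levels=(0.01, 0.1), replicates_per_level=3,
            dropout_probability=0.0, seed=10,
        )
        panel, truth = simulate_panel(cfg)
        panel = panel.copy()
        panel["selectivity"] = 1.0
        counts, _, _ = simulate_counts(panel, truth, cfg)
        s_g = enrichment.global_selectivity(counts)
        assert s_g == pytest.approx(1.0, rel=0.05)

    def test_dropout_forces_a_failing_control(self):
        cfg = SimConfig(
            n_probes=5, vaf_levels=(0.01,), replicates_per_level=30,
            dropout_probability=1.0, seed=12,
        )
        panel, truth = simulate_panel(cfg)
        _, controls, truth = simulate_counts(panel, truth, cfg)
        for sid in truth.samples["sample_id"]:
            sample_controls = controls[controls["sample_id"] == sid]
            assert (sample_controls["count"] < 100).any()

    def test_contaminated_blanks_carry_phased_snps(self):
        cfg = SimConfig(
            n_probes=50, vaf_levels=(0.0,), replicates_per_level=20,
            dropout_probability=0.0, contamination=(1.0, True), seed=13,
        )
        panel, truth = simulate_panel(cfg)
        counts, _, truth = simulate_counts(panel, truth, cfg)
        assert truth.samples["contaminated"].all()
        per_sample = counts.groupby("sample_id")[["phased_both", "duplex_alt"]].sum()
        assert (per_sample["phased_both"] > 0).all()


class TestReads:
    def test_single_duplex_molecule_layout(self):
        cfg = SimConfig(n_probes=1, seed=1, reads_per_strand=2)
        counts = pd.DataFrame(
            [{"probe_id": "P0000", "sample_id": "S000", "duplex_alt": 1,
              "single_strand_alt": 0, "duplex_wt": 0, "single_strand_wt": 0}]
        )
        reads = simulate_reads(counts, cfg)
        assert len(reads) == 4
        assert len({(r.start, r.end) for r in reads}) == 1
        assert len({r.umi for r in reads}) == 1
        assert {r.strand_of_origin for r in reads} == {"top", "bottom"}

    def test_roundtrip_without_errors(self, small_config, small_cohort):
        panel, counts, _, _ = small_cohort
        sub = counts[counts["vaf"] == 0.01].head(20)
        reads = simulate_reads(sub, small_config)
        table, _ = count_reads(reads)
        merged = sub.merge(table, on=["probe_id", "sample_id"], suffixes=("_in", "_out"))
        assert len(merged) == (sub[["duplex_alt", "single_strand_alt",
                                    "duplex_wt", "single_strand_wt"]].sum(axis=1) > 0).sum()
        for col in ["duplex_alt", "single_strand_alt", "duplex_wt", "single_strand_wt"]:
            assert (merged[f"{col}_in"] == merged[f"{col}_out"]).all()

    def test_umi_errors_within_distance_recovered(self):
        """100 molecules with UMI edits <= 2 still collapse to 100 bundles."""
        cfg = SimConfig(n_probes=1, seed=4, reads_per_strand=3)
        counts = pd.DataFrame(
            [{"probe_id": "P0000", "sample_id": "S000", "duplex_alt": 100,
              "single_strand_alt": 0, "duplex_wt": 0, "single_strand_wt": 0}]
        )
        reads = simulate_reads(counts, cfg, umi_error_rate=0.3, max_umi_edits=2)
        table, _ = count_reads(reads)
        assert int(table.iloc[0]["duplex_alt"]) == 100
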