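"""Candidate enumeration, Tm, features, scoring and panel sampling."""

import numpy as np
import pandas as pd
import pytest

from mrdenrich import probe_design as pdsn
from mrdenrich.probe_design import (
    ProbeDesign,
    VariantTarget,
    compute_features,
    design_probe,
    enumerate_candidates,
    melting_temperature,
    sample_panel,
    score_probes,
    select_best,
    train_default_scorer,
)

RNG = np.random.default_rng(123)
CONTEXT = "".join(RNG.choice(list("ACGT"), 200))


def make_target(variant_class="C>T", alt="T", nearby_snps=(), context=None, offset=100):
    ctx = context if context is not None else CONTEXT
    return VariantTarget(
        chrom="chr1", pos=1000, ref=ctx[offset], alt=alt,
        variant_class=variant_class, context=ctx, context_offset=offset,
        nearby_snps=tuple(nearby_snps), variant_id="v1",
    )


class TestEnumeration:
    def test_cartesian_product_count(self):
        designs = enumerate_candidates(
            make_target(), upstream_range=(3, 10), downstream_range=(20, 30)
        )
        assert len(designs) == 8 * 11

    def test_single_combination(self):
        designs = enumerate_candidates(
            make_target(), upstream_range=(5, 5), downstream_range=(25, 25)
        )
        assert len(designs) == 1
        d = designs[0]
        assert d.length == 5 + 25 + 1
        assert d.variant_offset_from_3prime == 5

    def test_both_strands_doubles(self):
        one = enumerate_candidates(make_target(), (3, 5), (20, 22))
        two = enumerate_candidates(make_target(), (3, 5), (20, 22), both_strands=True)
        assert len(two) == 2 * len(one)

    def test_short_context_raises_with_shortfall(self):
        target = make_target(context="ACGTACGTACGT", offset=6)
        with pytest.raises(ValueError, match="context too short"):
            enumerate_candidates(target, (3, 5), (20, 30))

    def test_probe_contains_alternate_allele(self):
        target = make_target(alt="A" if CONTEXT[100] != "A" else "G")
        (d,) = enumerate_candidates(target, (4, 4), (20, 20))
        assert d.sequence[-5] == target.alt  # 4 bases from the 3' end


class TestMeltingTemperature:
    def test_frozen_reference_value(self):
        """Fixed 30-mer against the nearest-neighbour reference value."""
        assert melting_temperature("ATGCGTACGTTAGCCGGATCATGCAGGTCC") == pytest.approx(
            68.27, abs=0.5
        )

    def test_reverse_complement_symmetry(self):
        seq = "ATGCGTACGTTAGCCGGATCATGCAGGTCC"
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert melting_temperature(seq) == pytest.approx(melting_temperature(rc), abs=1e-6)

    def test_gc_extension_raises_tm(self):
        seq = "ATGCGTACGTTAGC"
        assert melting_temperature(seq + "GCGCGC") > melting_temperature(seq)

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ATGCNTACGTTAGC")


class TestFeatures:
    def test_gc_content(self):
        target = make_target()
        (d,) = enumerate_candidates(target, (4, 4), (20, 20))
        expected = (d.sequence.count("G") + d.sequence.count("C")) / d.length
        assert compute_features(d)["gc_content"] == pytest.approx(expected)

    def test_snp_within_window_flagged(self):
        near = make_target(nearby_snps=[(-10, "A/G")])  # 10 bases 5' of variant
        (d,) = enumerate_candidates(near, (5, 5), (25, 25))
        assert d.snp_within_25bp_of_3prime  # sits 15 bases from the 3' end

    def test_snp_outside_window_not_flagged(self):
        far = make_target(nearby_snps=[(-40, "A/G")])
        (d,) = enumerate_candidates(far, (5, 5), (60, 60))
        assert not d.snp_within_25bp_of_3prime  # 45 bases from the 3' end

    @pytest.mark.parametrize(
        "seq, flagged",
        [
            ("ACGTAAAAAAGTCG", True),     # homopolymer run of 6
            ("AACACACACGTGTC", True),     # >=3 tandem copies of CA
            ("ATGCGTTACGGATC", False),
        ],
    )
    def test_ms_homopolymer_rule(self, seq, flagged):
        assert pdsn._has_ms_or_homopolymer(seq) is flagged


@pytest.fixture(scope="module")
def scorer():
    return train_default_scorer(n_train=1500, seed=0)


class TestScoringAndSelection:
    def test_identical_designs_identical_scores(self, scorer):
        designs = enumerate_candidates(make_target(), (4, 4), (25, 25)) * 2
        scored = score_probes(designs, scorer)
        assert scored[0].score == scored[1].score

    def test_heldout_r2(self):
        _, r2 = train_default_scorer(n_train=1500, seed=1, return_r2=True)
        assert r2 >= 0.6

    def test_gc_monotone_sanity(self, scorer):
        """Raising GC from 0.30 to 0.50 (others fixed) never lowers the score."""
        base = dict(tm=66.0, length=50.0, upstream_length=6.0,
                    downstream_length=43.0, variant_offset_from_3prime=6.0,
                    snp_within_25bp_of_3prime=0.0, ms_or_homopolymer_flag=0.0)
        rows = []
        for gc in (0.30, 0.50):
            feats = dict(base, gc_content=gc, low_gc_flag=float(gc < 0.35))
            rows.append([feats[c] for c in pdsn.FEATURE_COLUMNS])
        lo, hi = scorer.predict(np.array(rows))
        assert hi >= lo

    def test_select_best_and_tiebreaks(self):
        def mk(score, seq):
            return ProbeDesign(
                probe_id="p", sequence=seq, tm=70.0, gc_content=0.5,
                upstream_length=5, downstream_length=len(seq) - 6,
                variant_offset_from_3prime=5, snp_within_25bp_of_3prime=False,
                ms_or_homopolymer_flag=False, score=score,
            )
        a, b, c = mk(10, "A" * 30), mk(30, "C" * 28), mk(20, "G" * 30)
        assert select_best([a, b, c]) is b
        tie_short = mk(30, "T" * 26)
        assert select_best([b, tie_short]) is tie_short

    def test_no_design_passes_tm_names_best_rejected(self):
        low = ProbeDesign(
            probe_id="p", sequence="AT" * 10, tm=52.3, gc_content=0.0,
            upstream_length=5, downstream_length=14,
            variant_offset_from_3prime=5, snp_within_25bp_of_3prime=False,
            ms_or_homopolymer_flag=False, score=1.0,
        )
        with pytest.raises(ValueError, match="52.3"):
            select_best([low], tm_min=65.0)

    def test_design_probe_end_to_end(self, scorer):
        best = design_probe(make_target(), scorer, tm_min=60.0,
                            upstream_range=(4, 8), downstream_range=(25, 45))
        assert best.tm >= 60.0
        assert np.isfinite(best.score)


class TestPanelSampling:
    @staticmethod
    def _pool(n=6000, seed=0):
        rng = np.random.default_rng(seed)
        classes = list(pdsn.SNV_CLASSES) + list(pdsn.INDEL_CLASSES)
        rows = []
        for i in range(n):
            sub = classes[int(rng.integers(len(classes)))]
            is_indel = sub in pdsn.INDEL_CLASSES
            rows.append({
                "variant_id": f"v{i}",
                "variant_class": "InDel" if is_indel else "SNV",
                "substitution_type": sub,
                "score": float(rng.uniform(0, 400)),
                "indel_length": int(rng.integers(1, 60)) if is_indel else 0,
            })
        return pd.DataFrame(rows)

    def test_composition_split(self):
        panel = sample_panel(self._pool(), panel_size=200, snv_fraction=0.90, seed=1)
        assert (panel["variant_class"] == "SNV").sum() == 180
        assert (panel["variant_class"] == "InDel").sum() == 20
        assert panel["indel_length"].max() <= 40

    def test_equal_indel_classes(self):
        panel = sample_panel(self._pool(), panel_size=200, snv_fraction=0.90, seed=1)
        counts = panel[panel["variant_class"] == "InDel"]["substitution_type"].value_counts()
        assert set(counts) == {5}

    def test_median_threshold_mode(self):
        pool = self._pool()
        panel = sample_panel(pool, panel_size=100, median_threshold_mode=True, seed=2)
        for klass, grp in panel.groupby("variant_class"):
            med = pool.loc[pool["variant_class"] == klass, "score"].median()
            assert (grp["score"] > med).all()

    def test_long_indels_never_selected(self):
        pool = self._pool()
        panel = sample_panel(pool, panel_size=400, seed=3)
        assert panel["indel_length"].max() <= 40

    def test_seeded_reproducibility(self):
        pool = self._pool()
        a = sample_panel(pool, panel_size=120, seed=9)
        b = sample_panel(pool, panel_size=120, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_stratum_named(self):
        pool = self._pool(n=60)
        with pytest.raises(ValueError, match="SNVs|indels"):
            sample_panel(pool, panel_size=2000, seed=0)


class TestScoreRecoveryCorrelation:
    def test_score_predicts_recovery_at_high_vaf(self):
        """Mean recovered alternate molecules at 10% VAF track the design score."""
        from mrdenrich.synthetic_data import SimConfig, simulate_counts, simulate_panel

        cfg = SimConfig(n_probes=150, vaf_levels=(0.10,), replicates_per_level=4,
                        dropout_probability=0.0, seed=77)
        panel, truth = simulate_panel(cfg)
        counts, _, _ = simulate_counts(panel, truth, cfg)
        mean_alt = counts.groupby("probe_id")["total_alt"].mean()
        probes = panel[~panel["is_control"]].set_index("probe_id")
        joined = probes.join(mean_alt)
        r = np.corrcoef(joined["score"], joined["total_alt"])[0, 1]
        assert r >= 0.7
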