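"""Closed-form expectation, weight maps, Monte-Carlo oracle and overdispersion."""

import numpy as np
import pandas as pd
import pytest

from hotprop import expected_model as em
from hotprop.reference_model import CHANNELS, ContextCensus, Genome
from hotprop.study import _toy_census


def single_channel_profile(channel="A[C>T]G"):
    p = pd.Series(0.0, index=list(CHANNELS))
    p[channel] = 1.0
    return p


class TestChunkRates:
    def test_normalization(self):
        r = em.chunk_relative_rates(pd.Series({"b0": 3, "b1": 1}))
        assert r["b0"] == 0.75 and r["b1"] == 0.25
        r = em.chunk_relative_rates(pd.Series({"a": 5, "b": 5, "c": 5, "d": 5}))
        assert np.allclose(r, 0.25)
        assert r.sum() == pytest.approx(1.0)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            em.chunk_relative_rates(pd.Series({"b0": 0}))


class TestWeightMap:
    def test_single_channel(self):
        cen = _toy_census([("ACG", ".", ".", 10)])
        wm = em.position_weight_map(cen, single_channel_profile())
        row = wm[wm["q"] > 0].iloc[0]
        assert row["q"] == pytest.approx(0.1)
        assert row["N"] == 10

    def test_normalized_in_every_mode(self):
        prof = single_channel_profile() * 0.6
        prof["A[T>G]T"] = 0.4
        gw = em.position_weight_map(
            _toy_census([("ACG", ".", ".", 50), ("ATT", ".", ".", 70)]), prof
        )
        assert (gw["N"] * gw["q"]).sum() == pytest.approx(1.0)
        ch = em.position_weight_map(
            _toy_census(
                [("ACG", "b0", ".", 30), ("ATT", "b0", ".", 20),
                 ("ACG", "b1", ".", 20), ("ATT", "b1", ".", 50)]
            ),
            prof,
            rates=pd.Series({"b0": 0.6, "b1": 0.4}),
        )
        assert (ch["N"] * ch["q"]).sum() == pytest.approx(1.0)
        meth = em.position_weight_map(
            _toy_census(
                [("ACG", ".", "meth", 30), ("ACG", ".", "unmeth", 20),
                 ("ATT", ".", ".", 70)]
            ),
            prof,
            methylation_fold=3.0,
        )
        assert (meth["N"] * meth["q"]).sum() == pytest.approx(1.0)

    def test_rho_one_equals_unsplit(self):
        prof = single_channel_profile()
        split = _toy_census([("ACG", ".", "meth", 30), ("ACG", ".", "unmeth", 20)])
        plain = _toy_census([("ACG", ".", ".", 50)])
        wm_split = em.position_weight_map(split, prof, methylation_fold=1.0)
        wm_plain = em.position_weight_map(plain, prof)
        qs = wm_split[wm_split["q"] > 0]["q"].unique()
        assert np.allclose(qs, wm_plain[wm_plain["q"] > 0]["q"].iloc[0])

    def test_chunk_rate_ratio(self):
        # identical composition, rates (0.75, 0.25) -> per-position q ratio 3:1
        prof = single_channel_profile()
        cen = _toy_census([("ACG", "b0", ".", 40), ("ACG", "b1", ".", 40)])
        wm = em.position_weight_map(cen, prof, rates=pd.Series({"b0": 0.75, "b1": 0.25}))
        q = wm[wm["q"] > 0].set_index("bin")["q"]
        assert q["b0"] / q["b1"] == pytest.approx(3.0)

    def test_chunkwise_profile_renormalization(self):
        # chunk b1 lacks ATT entirely: f renormalizes within the chunk so its
        # total mass still equals r_k
        prof = single_channel_profile() * 0.5
        prof["A[T>G]T"] = 0.5
        cen = _toy_census(
            [("ACG", "b0", ".", 40), ("ATT", "b0", ".", 40), ("ACG", "b1", ".", 40)]
        )
        wm = em.position_weight_map(cen, prof, rates=pd.Series({"b0": 0.5, "b1": 0.5}))
        mass = (wm["N"] * wm["q"]).groupby(wm["bin"]).sum()
        assert mass["b0"] == pytest.approx(0.5)
        assert mass["b1"] == pytest.approx(0.5)

    def test_missing_context_raises(self):
        cen = _toy_census([("ATT", ".", ".", 10)])
        with pytest.raises(ValueError):
            em.position_weight_map(cen, single_channel_profile())


class TestExpectedHotspots:
    def test_single_sample_is_zero(self):
        cen = _toy_census([("ACG", ".", ".", 10)])
        wm = em.position_weight_map(cen, single_channel_profile())
        assert em.expected_hotspots(wm, S=1, n=5).total == 0.0

    def test_forced_collision(self):
        # one position, q = 1, n = 1, S = 2: both samples must hit it
        cen = _toy_census([("ACG", ".", ".", 1)])
        wm = em.position_weight_map(cen, single_channel_profile())
        assert em.expected_hotspots(wm, S=2, n=1).total == pytest.approx(1.0)

    def test_breakdown_sums_to_total(self):
        prof = single_channel_profile() * 0.7
        prof["A[T>G]T"] = 0.3
        cen = _toy_census([("ACG", ".", ".", 500), ("ATT", ".", ".", 900)])
        res = em.expected_hotspots(em.position_weight_map(cen, prof), S=20, n=10)
        assert (res.breakdown["N"] * res.breakdown["h"]).sum() == pytest.approx(res.total)

    def test_monotone_in_cohort_and_burden(self):
        prof = single_channel_profile()
        cen = _toy_census([("ACG", ".", ".", 2000)])
        wm = em.position_weight_map(cen, prof)
        grid_s = [em.expected_hotspots(wm, S=s, n=10).total for s in (2, 5, 10, 50)]
        assert grid_s == sorted(grid_s)
        grid_n = [em.expected_hotspots(wm, S=10, n=n).total for n in (1, 5, 20, 60)]
        assert grid_n == sorted(grid_n)

    def test_finer_partition_never_decreases_expectation(self):
        # heterogeneous rates: splitting a chunk with skewed rates raises the
        # expectation relative to the pooled (homogeneous) model
        prof = single_channel_profile()
        pooled = em.position_weight_map(
            _toy_census([("ACG", ".", ".", 2000)]), prof
        )
        split = em.position_weight_map(
            _toy_census([("ACG", "b0", ".", 1000), ("ACG", "b1", ".", 1000)]),
            prof,
            rates=pd.Series({"b0": 0.8, "b1": 0.2}),
        )
        e_pooled = em.expected_hotspots(pooled, S=30, n=20).total
        e_split = em.expected_hotspots(split, S=30, n=20).total
        assert e_split >= e_pooled

    def test_closed_form_matches_oracle_small(self):
        prof = single_channel_profile()
        cen = _toy_census([("ACG", ".", ".", 1000)])
        wm = em.position_weight_map(cen, prof)
        analytic = em.expected_hotspots(wm, S=10, n=5).total
        mean, se = em.monte_carlo_expected(wm, S=10, n=5, R=2000, seed=0)
        assert abs(analytic - mean) <= 3 * se


class TestMonteCarlo:
    def test_single_sample_always_zero(self):
        cen = _toy_census([("ACG", ".", ".", 100)])
        wm = em.position_weight_map(cen, single_channel_profile())
        mean, se, counts = em.monte_carlo_expected(
            wm, S=1, n=5, R=50, seed=1, return_counts=True
        )
        assert mean == 0.0 and (counts == 0).all()

    def test_seed_reproducible(self):
        cen = _toy_census([("ACG", ".", ".", 200)])
        wm = em.position_weight_map(cen, single_channel_profile())
        a = em.monte_carlo_expected(wm, S=5, n=5, R=100, seed=7)
        b = em.monte_carlo_expected(wm, S=5, n=5, R=100, seed=7)
        assert a == b

    def test_burden_exceeding_positions_raises(self):
        cen = _toy_census([("ACG", ".", ".", 3)])
        wm = em.position_weight_map(cen, single_channel_profile())
        with pytest.raises(ValueError):
            em.monte_carlo_expected(wm, S=2, n=50, R=10, seed=0)


class TestMethylationFold:
    def test_equal_rates_give_one(self):
        rho, corrected = em.infer_methylation_foldchange(90, 910, 90, 910)
        assert rho == pytest.approx(1.0) and not corrected

    def test_hand_arithmetic(self):
        rho, _ = em.infer_methylation_foldchange(90, 910, 10, 990)
        assert rho == pytest.approx((90 / 910) / (10 / 990))

    def test_zero_cell_corrected(self):
        rho, corrected = em.infer_methylation_foldchange(5, 95, 0, 100)
        assert corrected and np.isfinite(rho)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            em.infer_methylation_foldchange(0, 0, 10, 90)

    def test_cpg_counts_cover_both_strands(self):
        g = Genome({"c": "AACGAA"})
        meth = pd.DataFrame({"CONTIG": ["c"], "POS": [3], "FRACTION": [0.9]})
        # a mutation on the G of the CpG marks the same site as one on the C
        muts = pd.DataFrame(
            [dict(CHROMOSOME="c", POSITION=4, REF="G", ALT="A", SAMPLE="s")]
        )
        cells = em.cpg_mutation_counts(meth, muts, g)
        assert cells["mutated_meth"] == 1 and cells["unmutated_meth"] == 0


class TestExplainedFraction:
    def test_arithmetic(self):
        assert em.explained_fraction(40.0, 27.3) == pytest.approx(68.25)
        assert em.explained_fraction(10.0, 10.0) == 100.0
        assert em.explained_fraction(10.0, 0.0) == 0.0

    def test_zero_observed_raises(self):
        with pytest.raises(ValueError):
            em.explained_fraction(0.0, 5.0)


class TestOverdispersion:
    def test_constant_counts_alpha_zero(self):
        alpha, _ = em.fit_overdispersion(np.full(200, 20))
        assert alpha < 0.02

    def test_validation(self):
        with pytest.raises(ValueError):
            em.fit_overdispersion([1, 2, 3])  # too few bins
        with pytest.raises(ValueError):
            em.fit_overdispersion(np.full(20, -1))
        with pytest.raises(ValueError):
            em.fit_overdispersion(np.full(20, 1.5))
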