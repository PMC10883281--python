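"""Propensity subsampling, conversion rates and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest

from hotprop import propensity as pr
from hotprop.reference_model import Genome


def mut(contig, pos, ref, alt, sample):
    return dict(CHROMOSOME=contig, POSITION=pos, REF=ref, ALT=alt, SAMPLE=sample)


class TestEligiblePairs:
    def test_boundary_thresholds(self):
        hc = {("S", "C"): pd.Series([301] * 101)}
        assert pr.eligible_pairs({("S", "C"): 450}, hc) == [("S", "C")]
        assert pr.eligible_pairs({("S", "C"): 449}, hc) == []
        hc_short = {("S", "C"): pd.Series([301] * 100)}
        assert pr.eligible_pairs({("S", "C"): 450}, hc_short) == []
        hc_exact = {("S", "C"): pd.Series([300] * 101)}  # "more than 300" is strict
        assert pr.eligible_pairs({("S", "C"): 450}, hc_exact) == []


class TestObservedPropensity:
    def _cohort(self, n_samples=8, per_sample=30, n_positions=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_samples):
            pos = rng.choice(n_positions, size=per_sample, replace=False)
            rows.extend(mut("c", int(p) + 1, "C", "T", f"s{s}") for p in pos)
        return pd.DataFrame(rows)

    def test_seed_reproducible(self):
        df = self._cohort()
        spec = pr.SubsampleSpec(n_samples=5, mutations_per_sample=10,
                                iterations=20, seed=3)
        a = pr.observed_propensity(df, spec)
        b = pr.observed_propensity(df, spec)
        assert np.array_equal(a.counts, b.counts)

    def test_insufficient_mutations_raises(self):
        df = self._cohort(per_sample=5)
        spec = pr.SubsampleSpec(n_samples=5, mutations_per_sample=10, iterations=5)
        with pytest.raises(ValueError):
            pr.observed_propensity(df, spec)

    def test_median_monotone_in_burden(self):
        # raising mutations/sample must not decrease the median hotspot count
        df = self._cohort(n_samples=10, per_sample=30, n_positions=60, seed=1)
        medians = []
        for m in (5, 15, 30):
            spec = pr.SubsampleSpec(n_samples=8, mutations_per_sample=m,
                                    iterations=60, seed=5)
            medians.append(pr.observed_propensity(df, spec).median)
        assert medians == sorted(medians)

    def test_pooled_mode_counts_multiplicity(self):
        # pool where every draw is forced: 3 rows at one event, 1 elsewhere
        df = pd.DataFrame(
            [
                mut("c", 1, "C", "T", "a"),
                mut("c", 1, "C", "T", "b"),
                mut("c", 1, "C", "T", "c"),
                mut("c", 9, "C", "T", "a"),
            ]
        )
        spec = pr.SubsampleSpec(n_samples=2, mutations_per_sample=2,
                                iterations=5, grouping="pooled", seed=0)
        res = pr.observed_propensity(df, spec)
        assert (res.counts == 1).all()

    def test_one_hotspot_per_position(self):
        # two alternates both recurrent at one position: still a single hotspot
        df = pd.DataFrame(
            [
                mut("c", 1, "C", "T", "a"), mut("c", 1, "C", "T", "b"),
                mut("c", 1, "C", "G", "a"), mut("c", 1, "C", "G", "b"),
            ]
        )
        spec = pr.SubsampleSpec(n_samples=2, mutations_per_sample=2,
                                iterations=3, seed=0)
        res = pr.observed_propensity(df, spec)
        assert (res.counts == 1).all()


class TestConversionRate:
    def test_exact_linear_response(self, monkeypatch):
        # deterministic cohort: response = 0.01 x burden exactly
        rng = np.random.default_rng(0)
        rows = []
        # shared hotspot positions: each sample hits `k` shared positions where
        # k = 0.01 * burden; plus private filler mutations
        burdens = rng.integers(200, 800, size=120)
        next_private = 10_000
        for i, b in enumerate(burdens):
            k = int(round(0.01 * b))
            for j in range(k):  # shared events (every sample hits them)
                rows.append(mut("c", j + 1, "C", "T", f"s{i}"))
            for j in range(b - k):
                rows.append(mut("c", next_private, "C", "T", f"s{i}"))
                next_private += 1
        df = pd.DataFrame(rows)
        res = pr.conversion_rate(df, iterations=20, subset=100, seed=1,
                                 min_significant=15)
        assert res["rate"] == pytest.approx(100.0, rel=0.15)

    def test_no_hotspots_gives_null(self):
        rows = []
        p = 1
        for i in range(110):
            for _ in range(20):
                rows.append(mut("c", p, "C", "T", f"s{i}"))
                p += 1
        res = pr.conversion_rate(pd.DataFrame(rows), iterations=10, subset=100,
                                 seed=0, min_significant=8)
        assert res["rate"] is None

    def test_small_cohort_raises(self):
        df = pd.DataFrame([mut("c", 1, "C", "T", f"s{i}") for i in range(5)])
        with pytest.raises(ValueError):
            pr.conversion_rate(df, subset=100)


class TestSignatureFoldChange:
    def _vectors(self, shares, samples):
        rows = []
        for s in samples:
            for sh in shares:
                rows.append({"SAMPLE": s, **sh})
        return pd.DataFrame(rows)

    def test_identical_shares_fc_one(self):
        shares = [{"A": 0.6, "B": 0.4}] * 5
        ins = self._vectors(shares, [f"s{i}" for i in range(8)])
        outs = self._vectors(shares, [f"s{i}" for i in range(8)])
        res = pr.signature_fold_change(ins, outs)
        assert np.allclose(res["fold_change"], 1.0)
        assert not res["significant"].any()

    def test_constructed_twofold(self):
        # inside share of A exactly 2x its outside share in every sample
        ins = self._vectors([{"A": 0.8, "B": 0.2}], [f"s{i}" for i in range(10)])
        outs = self._vectors([{"A": 0.4, "B": 0.6}], [f"s{i}" for i in range(10)])
        res = pr.signature_fold_change(ins, outs)
        assert res.loc["A", "fold_change"] == pytest.approx(2.0)
        assert res.loc["B", "fold_change"] == pytest.approx(0.2 / 0.6)

    def test_single_sample_has_no_pvalue(self):
        ins = self._vectors([{"A": 0.8, "B": 0.2}], ["s0"])
        outs = self._vectors([{"A": 0.4, "B": 0.6}], ["s0"])
        res = pr.signature_fold_change(ins, outs)
        assert res.loc["A", "fold_change"] == pytest.approx(2.0)
        assert np.isnan(res.loc["A", "pvalue"])

    def test_bh_qvalues_monotone_in_rank(self):
        rng = np.random.default_rng(2)
        sig_names = [f"S{i}" for i in range(6)]
        samples = [f"s{i}" for i in range(12)]
        ins = pd.DataFrame(
            rng.dirichlet(np.ones(6), size=len(samples)), columns=sig_names
        )
        ins["SAMPLE"] = samples
        outs = pd.DataFrame(
            rng.dirichlet(np.ones(6), size=len(samples)), columns=sig_names
        )
        outs["SAMPLE"] = samples
        res = pr.signature_fold_change(ins, outs)
        sub = res.dropna(subset=["pvalue"]).sort_values("pvalue")
        assert sub["qvalue"].is_monotonic_increasing

    def test_shares_sum_to_one_before_fc(self):
        rng = np.random.default_rng(3)
        sig_names = ["A", "B", "C"]
        rows_in, rows_out = [], []
        for s in ("s0", "s1", "s2"):
            for _ in range(4):
                rows_in.append({"SAMPLE": s, **dict(zip(sig_names, rng.dirichlet([1, 1, 1])))})
                rows_out.append({"SAMPLE": s, **dict(zip(sig_names, rng.dirichlet([1, 1, 1])))})
        res = pr.signature_fold_change(pd.DataFrame(rows_in), pd.DataFrame(rows_out))
        assert res["fold_change"].notna().all()


class TestSubstitutionEnrichment:
    def test_identical_distributions(self):
        df = pd.DataFrame(
            [mut("c", i, "C", "T", "s") for i in range(10)]
            + [mut("c", i, "T", "G", "s") for i in range(10)]
        )
        res = pr.substitution_enrichment(df, df, scheme=6)
        present = res[res["freq_outside"] > 0]
        assert np.allclose(present["fold_change"], 1.0)

    def test_hand_arithmetic(self):
        inside = pd.DataFrame(
            [mut("c", i, "C", "T", "s") for i in range(5)]
            + [mut("c", i, "T", "G", "s") for i in range(5)]
        )
        outside = pd.DataFrame(
            [mut("c", i, "C", "T", "s") for i in range(5)]
            + [mut("c", i, "T", "G", "s") for i in range(15)]
        )
        res = pr.substitution_enrichment(inside, outside, scheme=6)
        assert res.loc["C>T", "fold_change"] == pytest.approx(0.5 / 0.25)

    def test_zero_outside_flagged_infinite(self):
        inside = pd.DataFrame([mut("c", 1, "C", "A", "s")])
        outside = pd.DataFrame([mut("c", 2, "C", "T", "s")])
        res = pr.substitution_enrichment(inside, outside, scheme=6)
        assert np.isinf(res.loc["C>A", "fold_change"])
        assert bool(res.loc["C>A", "zero_outside"])

    def test_empty_set_raises(self):
        df = pd.DataFrame([mut("c", 1, "C", "T", "s")])
        with pytest.raises(ValueError):
            pr.substitution_enrichment(df.iloc[:0], df)

    def test_96_channel_scheme(self):
        g = Genome({"c": "AACAAACAA"})
        inside = pd.DataFrame([mut("c", 3, "C", "T", "s")])
        outside = pd.DataFrame([mut("c", 7, "C", "T", "s")])
        res = pr.substitution_enrichment(inside, outside, genome=g, scheme=96)
        assert res.loc["A[C>T]A", "fold_change"] == pytest.approx(1.0)
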