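"""Profile handling, NNLS fitting, AIC search and attribution."""

import numpy as np
import pandas as pd
import pytest

from hotprop import signatures as sg
from hotprop.reference_model import CHANNELS, Genome, RegionSet, census
from hotprop.study import synthetic_profiles


class TestCatalog:
    def test_single_mutation_channel(self):
        g = Genome({"c": "AACAA"})
        df = pd.DataFrame(
            [dict(CHROMOSOME="c", POSITION=3, REF="C", ALT="T", SAMPLE="s1")]
        )
        cat, skipped = sg.build_catalog(df, g)
        assert skipped == 0
        assert cat.loc["A[C>T]A", "s1"] == 1 and cat["s1"].sum() == 1

    def test_purine_reference_collapses(self):
        # G>A on + strand context TGT collapses to A[C>T]A
        g = Genome({"c": "ATGTA"})
        df = pd.DataFrame(
            [dict(CHROMOSOME="c", POSITION=3, REF="G", ALT="A", SAMPLE="s1")]
        )
        cat, _ = sg.build_catalog(df, g)
        assert cat.loc["A[C>T]A", "s1"] == 1

    def test_column_sums_and_skips(self):
        g = Genome({"c": "AACANA"})
        df = pd.DataFrame(
            [
                dict(CHROMOSOME="c", POSITION=3, REF="C", ALT="G", SAMPLE="s1"),
                dict(CHROMOSOME="c", POSITION=5, REF="N", ALT="T", SAMPLE="s1"),
            ]
        )
        cat, skipped = sg.build_catalog(df, g)
        assert cat["s1"].sum() == 1 and skipped == 1


class TestNormalizeAndEntropy:
    def test_uniform_census_preserves_profile(self, flat_profile):
        from hotprop.reference_model import ContextCensus, TRIPLETS

        # equal counts for every triplet: normalization is a no-op
        idx = pd.MultiIndex.from_tuples(
            [(t, ".", ".") for t in TRIPLETS], names=["triplet", "bin", "meth"]
        )
        cen = ContextCensus(pd.Series(100, index=idx, dtype=np.int64))
        p = sg.normalize_profile(flat_profile, cen)
        assert np.allclose(p.to_numpy(), flat_profile.to_numpy())

    def test_hand_arithmetic(self):
        from hotprop.reference_model import ContextCensus

        prof = pd.Series(0.0, index=list(CHANNELS))
        prof["A[C>T]G"] = 0.5  # triplet ACG, census 2
        prof["A[T>C]T"] = 0.5  # triplet ATT, census 1
        idx = pd.MultiIndex.from_tuples(
            [("ACG", ".", "."), ("ATT", ".", ".")], names=["triplet", "bin", "meth"]
        )
        cen = ContextCensus(pd.Series([2, 1], index=idx, dtype=np.int64))
        p = sg.normalize_profile(prof, cen)
        assert p["A[C>T]G"] == pytest.approx(1 / 3)
        assert p["A[T>C]T"] == pytest.approx(2 / 3)

    def test_zero_census_for_active_channel_raises(self):
        from hotprop.reference_model import ContextCensus

        prof = pd.Series(0.0, index=list(CHANNELS))
        prof["A[C>T]G"] = 1.0
        idx = pd.MultiIndex.from_tuples(
            [("ATT", ".", ".")], names=["triplet", "bin", "meth"]
        )
        cen = ContextCensus(pd.Series([5], index=idx, dtype=np.int64))
        with pytest.raises(ValueError):
            sg.normalize_profile(prof, cen)

    def test_entropy_bounds_and_values(self, flat_profile):
        assert sg.profile_entropy(flat_profile) == pytest.approx(np.log(96))
        delta = np.zeros(96)
        delta[0] = 1.0
        assert sg.profile_entropy(delta) == 0.0
        half = np.zeros(96)
        half[:2] = 0.5
        assert sg.profile_entropy(half) == pytest.approx(np.log(2))

    def test_skewed_profile_has_lower_entropy(self, profiles):
        g_census_free = profiles  # raw profiles suffice for the ordering
        assert sg.profile_entropy(profiles["SIG_CPG"]) < sg.profile_entropy(
            profiles["SIG_FLAT"]
        )


class TestNNLS:
    def test_noiseless_recovery(self, profiles):
        rng = np.random.default_rng(0)
        E_true = pd.DataFrame(
            rng.uniform(10, 200, size=(3, 5)),
            index=profiles.columns,
            columns=[f"s{i}" for i in range(5)],
        )
        M = profiles @ E_true
        E_hat, resid = sg.fit_exposures_nnls(M, profiles)
        rel = np.abs(E_hat - E_true).to_numpy().max() / E_true.to_numpy().max()
        assert rel <= 1e-6
        assert (resid < 1e-8).all()

    def test_zero_catalog(self, profiles):
        M = pd.DataFrame(0.0, index=profiles.index, columns=["s0"])
        E, _ = sg.fit_exposures_nnls(M, profiles)
        assert (E.to_numpy() == 0).all()

    def test_optimality_against_perturbations(self, profiles):
        rng = np.random.default_rng(1)
        M = pd.DataFrame(
            rng.poisson(5, size=(96, 2)).astype(float),
            index=profiles.index, columns=["s0", "s1"],
        )
        E_hat, resid = sg.fit_exposures_nnls(M, profiles)
        S = profiles.to_numpy()
        base = ((S @ E_hat.to_numpy() - M.to_numpy()) ** 2).sum()
        for _ in range(100):
            pert = np.clip(
                E_hat.to_numpy() + rng.normal(0, 1, E_hat.shape), 0, None
            )
            assert ((S @ pert - M.to_numpy()) ** 2).sum() >= base - 1e-9

    def test_channel_mismatch_raises(self, profiles):
        M = pd.DataFrame(0.0, index=list(reversed(profiles.index)), columns=["s"])
        with pytest.raises(ValueError):
            sg.fit_exposures_nnls(M, profiles)


class TestCombinationSearch:
    def test_subset_count_formula(self):
        assert sg.count_signature_subsets(39, 4) == 92_170
        assert sg.count_signature_subsets(1, 1) == 1
        assert sg.count_signature_subsets(5, 2) == 15

    def test_recovers_generating_pair(self):
        rng = np.random.default_rng(7)
        # six distinct candidate profiles, two of them generate the catalog
        cand = pd.DataFrame(
            rng.dirichlet(np.full(96, 0.3), size=6).T,
            index=list(CHANNELS),
            columns=[f"P{i}" for i in range(6)],
        )
        E = pd.DataFrame(
            [[300.0, 250.0], [200.0, 350.0]], index=["P1", "P4"],
            columns=["s0", "s1"],
        )
        M = cand[["P1", "P4"]] @ E
        M = M + rng.normal(0, 0.05, M.shape).clip(-0.2, 0.2)
        res = sg.select_signature_combination(M.clip(lower=0), cand, kmax=3, top_t=10)
        assert set(res["best_subset"]) >= {"P1", "P4"}
        assert res["n_subsets"] == sg.count_signature_subsets(6, 3)
        assert res["top_frequency"].index[0] in {"P1", "P4"}

    def test_single_candidate(self):
        rng = np.random.default_rng(8)
        cand = pd.DataFrame(
            rng.dirichlet(np.ones(96), size=1).T, index=list(CHANNELS), columns=["A"]
        )
        M = cand * 100
        M.columns = ["s0"]
        res = sg.select_signature_combination(M, cand, kmax=1)
        assert res["best_subset"] == ("A",)

    def test_cap_enforced(self, profiles):
        M = pd.DataFrame(1.0, index=profiles.index, columns=["s"])
        with pytest.raises(ValueError):
            sg.select_signature_combination(M, profiles, kmax=3, max_subsets=2)

    def test_nested_rss_monotonicity(self, profiles):
        rng = np.random.default_rng(9)
        M = pd.DataFrame(
            rng.poisson(10, size=(96, 1)).astype(float),
            index=profiles.index, columns=["s"],
        )
        res = sg.select_signature_combination(M, profiles, kmax=3)
        r = res["ranking"].set_index("subset")["rss"]
        for sub in r.index:
            for bigger in r.index:
                if set(sub) < set(bigger):
                    assert r[bigger] <= r[sub] + 1e-9


class TestAttribution:
    def test_probability_vector_arithmetic(self, profiles):
        prof = pd.DataFrame(
            {"A": [0.1, 0.9] + [0] * 94, "B": [0.3, 0.7] + [0] * 94},
            index=list(CHANNELS),
        )
        expo = pd.Series({"A": 3.0, "B": 1.0})
        v = sg.mutation_probability_vector(CHANNELS[0], expo, prof)
        assert v["A"] == pytest.approx(0.5) and v["B"] == pytest.approx(0.5)
        assert v.sum() == pytest.approx(1.0)

    def test_single_active_signature_is_indicator(self, profiles):
        expo = pd.Series({"SIG_CPG": 10.0, "SIG_TT": 0.0, "SIG_FLAT": 0.0})
        v = sg.mutation_probability_vector("A[C>T]G", expo, profiles)
        assert v["SIG_CPG"] == 1.0

    def test_unattributable_returns_none(self, profiles):
        expo = pd.Series({"SIG_CPG": 1.0, "SIG_TT": 0.0, "SIG_FLAT": 0.0})
        # SIG_CPG has zero mass on T>A channels
        assert sg.mutation_probability_vector("A[T>A]A", expo, profiles) is None

    def test_max_likelihood_assignment(self):
        sig, hc = sg.assign_max_likelihood(pd.Series({"a": 0.6, "b": 0.4}))
        assert (sig, hc) == ("a", True)
        sig, hc = sg.assign_max_likelihood(pd.Series({"b": 0.5, "a": 0.5}))
        assert (sig, hc) == ("a", False)  # lexicographic tie-break, not high-conf
        sig, hc = sg.assign_max_likelihood(pd.Series({"a": 0.4, "b": 0.3, "c": 0.3}))
        assert (sig, hc) == ("a", False)

    def test_hotspot_assignment(self):
        vecs = pd.DataFrame([{"a": 0.7, "b": 0.3}, {"a": 0.4, "b": 0.6}])
        sig, mean, tie = sg.assign_hotspot_signature(vecs)
        assert sig == "a" and not tie
        assert mean["a"] == pytest.approx(0.55)
        vecs = pd.DataFrame([{"a": 1.0, "b": 0.0}, {"a": 0.0, "b": 1.0}])
        sig, _, tie = sg.assign_hotspot_signature(vecs)
        assert sig == "a" and tie

    def test_active_signature_thresholds(self):
        expo = pd.DataFrame(
            {
                f"s{i}": {"X": 5.0, "Y": 95.0} if i == 0 else {"X": 1.0, "Y": 99.0}
                for i in range(20)
            }
        )
        sample_active, cohort_active = sg.active_signatures(expo)
        assert bool(sample_active.loc["X", "s0"]) is True  # exactly 5% counts
        assert bool(sample_active.loc["X", "s1"]) is False  # 4.9% does not
        # active in 1 of 20 samples == 5% -> cohort-active
        assert cohort_active == ["X", "Y"]

    def test_probability_matrix_matches_scalar(self, profiles):
        expo = pd.DataFrame(
            {"s0": {"SIG_CPG": 5.0, "SIG_TT": 2.0, "SIG_FLAT": 3.0}}
        )
        channels = pd.Series(["A[C>T]G", "A[T>G]T"])
        samples = pd.Series(["s0", "s0"])
        P = sg.probability_matrix(channels, expo, profiles, samples)
        for i, ch in enumerate(channels):
            v = sg.mutation_probability_vector(ch, expo["s0"], profiles)
            assert np.allclose(P.iloc[i].to_numpy(), v.to_numpy())


class TestProfileIO:
    def test_roundtrip(self, profiles, tmp_path):
        path = tmp_path / "profiles.tsv"
        sg.write_profiles(profiles, path)
        back = sg.read_profiles(path)
        pd.testing.assert_frame_equal(back, profiles)

    def test_missing_channels_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"Type": ["A[C>A]A"], "X": [1.0]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError):
            sg.read_profiles(path)
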