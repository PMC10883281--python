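"""Canonical synthetic study: conditions, profiles and experiment drivers.

This module pins the study conditions under which the package's claims are
evaluated — cohort geometry of 100 samples x 300 subsampled mutations per
sample (the fixed-activity standard of the propensity metric), a CpG depletion
of 0.2 emulating the mammalian CpG deficit, and a set of synthetic signature
profiles spanning the entropy range of interest:

* ``SIG_CPG``  — concentrated on the four N[C>T]G channels (5-methylcytosine
  deamination style); its target contexts are depleted in the genome.
* ``SIG_TT``   — concentrated on the four N[T>G]T channels (SBS17-like);
  target contexts are abundant.
* ``SIG_FLAT`` — near-uniform over all 96 channels.

The experiment drivers below are what the analysis scripts, the test suite and
the acceptance script all call, so every reported number is recomputed from
scratch through the same code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import expected_model as em
from . import propensity as pr
from . import synthetic_data as sd
from .reference_model import (
    CHANNELS,
    TRIPLETS,
    ContextCensus,
    Genome,
    RegionSet,
    census,
    make_bins,
    select_mappable_bins,
)

# --------------------------------------------------------------------------
# printed corpus constants: the headline bookkeeping of the 7507-tumour study,
# used as *inputs* for pure-arithmetic ratios (not desk-reproducible otherwise)
CORPUS = {
    "snv_hotspots": 1_361_631,
    "total_hotspots_specific": 1_562_004,
    "total_hotspots_pancancer": 3_106_161,
    "mappable_genome_bp": 2_439_219_900,
    "mappable_megabases_bp": 2_012_091_302,
    "n_mappable_megabases": 2196,
}


def synthetic_profiles() -> pd.DataFrame:
    """The three synthetic signature profiles of the study."""
    idx = list(CHANNELS)
    prof = pd.DataFrame(0.0, index=idx, columns=["SIG_CPG", "SIG_TT", "SIG_FLAT"])
    for five in "ACGT":
        prof.loc[f"{five}[C>T]G", "SIG_CPG"] = 0.25
        prof.loc[f"{five}[T>G]T", "SIG_TT"] = 0.25
    prof["SIG_FLAT"] = 1.0 / 96
    prof.index.name = "Type"
    return prof


def study_config(seed: int, genome_mb: int = 20, **overrides) -> sd.SyntheticConfig:
    """The default study conditions on a single synthetic contig."""
    params = dict(
        contig_lengths={"chr1": genome_mb * 1_000_000},
        cpg_depletion=0.2,
        cohort_size=100,
        mutations_per_sample=450,  # pool per sample; propensity subsamples 300
        mappable_coverage=0.9,
        blacklist_coverage=0.0,
        variant_site_rate=0.0,
        driver_coverage=0.0,
        seed=seed,
    )
    params.update(overrides)
    return sd.SyntheticConfig(**params)


def _toy_census(spec: list[tuple[str, str, str, int]]) -> ContextCensus:
    """Build a ContextCensus directly from (triplet, bin, meth, N) rows."""
    idx = pd.MultiIndex.from_tuples(
        [(t, b, m) for t, b, m, _ in spec], names=["triplet", "bin", "meth"]
    )
    return ContextCensus(pd.Series([n for *_, n in spec], index=idx, dtype=np.int64))


def oracle_battery(seed: int, R: int = 2000) -> pd.DataFrame:
    """Closed form vs Monte-Carlo on a battery of small configurations.

    Configurations span uneven profiles, chunk-rate heterogeneity and
    methylation folds rho in {1, 2, 5}; all are kept in the regime where the
    per-sample binomial approximation is accurate (n small relative to the
    class sizes).  Returns one row per configuration with the analytic value,
    the Monte-Carlo mean and standard error over R cohorts, and the z-score.
    """
    rng = np.random.default_rng(seed)
    flat = pd.Series(1.0 / 96, index=list(CHANNELS))
    two_ch = pd.Series(0.0, index=list(CHANNELS))
    two_ch["A[C>T]G"] = 0.7
    two_ch["A[T>G]T"] = 0.3
    uneven = pd.Series(0.0, index=list(CHANNELS))
    uneven["A[C>T]G"] = 0.55
    uneven["C[C>T]G"] = 0.25
    uneven["T[T>C]T"] = 0.15
    uneven["G[C>A]A"] = 0.05
    single = pd.Series(0.0, index=list(CHANNELS))
    single["A[C>T]G"] = 1.0

    def gw(census_spec, profile, S, n, rho=None):
        cen = _toy_census(census_spec)
        wm = em.position_weight_map(cen, profile, methylation_fold=rho)
        return wm, S, n

    def chunked(census_spec, profile, rates, S, n, rho=None):
        cen = _toy_census(census_spec)
        wm = em.position_weight_map(
            cen, profile, rates=pd.Series(rates), methylation_fold=rho
        )
        return wm, S, n

    all_trips = [(t, ".", ".", 80) for t in TRIPLETS]
    cpg_meth = [
        ("ACG", ".", "meth", 1500), ("ACG", ".", "unmeth", 2500),
        ("ATT", ".", ".", 4000),
    ]
    cpg_meth_bins = [
        ("ACG", "b0", "meth", 800), ("ACG", "b0", "unmeth", 1200),
        ("ATT", "b0", ".", 2000),
        ("ACG", "b1", "meth", 700), ("ACG", "b1", "unmeth", 1300),
        ("ATT", "b1", ".", 2000),
    ]
    configs = [
        ("flat_genomewide", gw(all_trips, flat, 12, 6)),
        ("two_channel_genomewide",
         gw([("ACG", ".", ".", 2500), ("ATT", ".", ".", 3500)], two_ch, 10, 5)),
        ("uneven_genomewide",
         gw([("ACG", ".", ".", 2000), ("CCG", ".", ".", 1200),
             ("TTT", ".", ".", 5000), ("GCA", ".", ".", 3000),
             ("AAA", ".", ".", 1000)], uneven, 15, 6)),
        ("single_channel_small", gw([("ACG", ".", ".", 1000)], single, 10, 5)),
        ("chunks_uniform",
         chunked([("ACG", "b0", ".", 1500), ("ATT", "b0", ".", 1500),
                  ("ACG", "b1", ".", 1500), ("ATT", "b1", ".", 1500)],
                 two_ch, {"b0": 0.5, "b1": 0.5}, 12, 5)),
        ("chunks_skewed",
         chunked([("ACG", "b0", ".", 1500), ("ATT", "b0", ".", 1500),
                  ("ACG", "b1", ".", 1500), ("ATT", "b1", ".", 1500)],
                 two_ch, {"b0": 0.8, "b1": 0.2}, 12, 5)),
        ("chunks_composition_shift",
         chunked([("ACG", "b0", ".", 2500), ("ATT", "b0", ".", 500),
                  ("ACG", "b1", ".", 500), ("ATT", "b1", ".", 2500)],
                 two_ch, {"b0": 0.6, "b1": 0.4}, 10, 6)),
        ("meth_rho1", gw(cpg_meth, two_ch, 12, 6, rho=1.0)),
        ("meth_rho2", gw(cpg_meth, two_ch, 12, 6, rho=2.0)),
        ("meth_rho5", gw(cpg_meth, two_ch, 12, 6, rho=5.0)),
        ("meth_rho2_chunks",
         chunked(cpg_meth_bins, two_ch, {"b0": 0.7, "b1": 0.3}, 10, 6, rho=2.0)),
        ("larger_cohort",
         gw([("ACG", ".", ".", 3000), ("ATT", ".", ".", 5000)], two_ch, 30, 8)),
    ]
    rows = []
    for name, (wm, S, n) in configs:
        analytic = em.expected_hotspots(wm, S=S, n=n).total
        mc_mean, mc_se = em.monte_carlo_expected(
            wm, S=S, n=n, R=R, seed=rng.integers(2**31)
        )
        z = (analytic - mc_mean) / mc_se if mc_se > 0 else 0.0
        rows.append(dict(config=name, S=S, n=n, analytic=analytic,
                         mc_mean=mc_mean, mc_se=mc_se, z=z))
    return pd.DataFrame(rows)


def build_study(seed: int, genome_mb: int = 20):
    """Genome, masks, mappable-bin scope and census for the standard study."""
    cfg = study_config(seed, genome_mb=genome_mb)
    genome, masks = sd.generate_genome(cfg)
    bins = make_bins(genome, cfg.bin_width)
    kept = select_mappable_bins(bins, masks["mappable"])
    scope = RegionSet(
        [(b.contig, b.start, b.end) for b in kept]
    ).intersect(masks["mappable"])
    cen = census(genome, scope)
    return cfg, genome, masks, kept, scope, cen


def propensity_experiment(
    seed: int,
    genome_mb: int = 20,
    n_samples: int = 100,
    m: int = 300,
    iterations: int = 1000,
    mc_R: int = 200,
) -> dict:
    """Observed vs expected hotspot propensity for a skewed and a flat profile.

    Generates single-signature cohorts under identical conditions for the
    CpG-concentrated profile and the near-uniform profile, measures observed
    propensity (median hotspots over fixed-activity subsamples), computes the
    closed-form expectation and the Monte-Carlo count distribution of the
    matching model, and reports explained fractions.
    """
    cfg, genome, masks, kept, scope, cen = build_study(seed, genome_mb)
    profiles = synthetic_profiles()
    out: dict = {"seed": seed, "genome_mb": genome_mb}
    for off, sig in enumerate(("SIG_CPG", "SIG_FLAT")):
        muts, _ = sd.simulate_cohort(
            genome, profiles, {sig: 1.0}, cfg, seed=seed + 101 + off, scope=scope,
        )
        spec = pr.SubsampleSpec(
            n_samples=n_samples, mutations_per_sample=m,
            iterations=iterations, seed=seed + 7,
        )
        res = pr.observed_propensity(muts, spec)
        wm = em.position_weight_map(cen, profiles[sig])
        expected = em.expected_hotspots(wm, S=n_samples, n=m)
        mc_mean, mc_se, mc_counts = em.monte_carlo_expected(
            wm, S=n_samples, n=m, R=mc_R, seed=seed + 11, return_counts=True
        )
        out[sig] = {
            "observed_median": res.median,
            "observed_iqr": res.iqr,
            "expected_closed_form": expected.total,
            "mc_mean": mc_mean,
            "mc_se": mc_se,
            "mc_band_95": (
                float(np.quantile(mc_counts, 0.025)),
                float(np.quantile(mc_counts, 0.975)),
            ),
            "explained_fraction_pct": em.explained_fraction(
                res.median, expected.total
            ) if res.median > 0 else None,
        }
    out["propensity_ratio"] = (
        out["SIG_CPG"]["observed_median"] / max(out["SIG_FLAT"]["observed_median"], 1.0)
    )
    return out


def overdispersion_recovery(seed: int, n_bins: int = 2000, mu: float = 20.0) -> dict:
    """Recover NB overdispersion alpha in {0, 0.5, 1} from simulated counts."""
    rng = np.random.default_rng(seed)
    out = {}
    for alpha in (0.0, 0.5, 1.0):
        if alpha == 0.0:
            counts = rng.poisson(mu, size=n_bins)
        else:
            # NB2: size r = 1/alpha, p = r / (r + mu)
            r = 1.0 / alpha
            counts = rng.negative_binomial(r, r / (r + mu), size=n_bins)
        alpha_hat, se = em.fit_overdispersion(counts)
        out[alpha] = {"alpha_hat": alpha_hat, "se": se}
    return out


def methylation_fold_recovery(
    seed: int, rho_true: float = 2.0, genome_mb: int = 2
) -> dict:
    """Recover the methylated-CpG mutability fold from a simulated cohort."""
    cfg = study_config(
        seed, genome_mb=genome_mb, cpg_depletion=0.5,
        cohort_size=30, mutations_per_sample=200, meth_fold=rho_true,
        mappable_coverage=1.0,
    )
    genome, _ = sd.generate_genome(cfg)
    meth = sd.generate_methylation(genome, cfg)
    profiles = synthetic_profiles()
    muts, _ = sd.simulate_cohort(
        genome, profiles, {"SIG_CPG": 1.0}, cfg, methylation=meth
    )
    cells = em.cpg_mutation_counts(meth, muts, genome)
    rho_hat, corrected = em.infer_methylation_foldchange(
        cells["mutated_meth"], cells["unmutated_meth"],
        cells["mutated_unmeth"], cells["unmutated_unmeth"],
    )
    return {"rho_true": rho_true, "rho_hat": rho_hat, "corrected": corrected,
            "cells": cells}
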