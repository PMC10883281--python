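"""Mutational-signature handling: profiles, catalogs, fitting and attribution.

A single-base-substitution (SBS) signature is a probability distribution over
the 96 pyrimidine-collapsed trinucleotide substitution channels.  Given a set of
reference profiles S (96 x k) and a cohort catalog M (96 x n samples), exposures
are fitted per sample by non-negative least squares,

    E_hat = argmin_{E >= 0} |S E - M|_F^2 ,

and each mutation is then attributed probabilistically: the posterior weight of
signature s for a mutation in channel c is E_s f_s(c) / sum_t E_t f_t(c).

Profiles can be genome-normalized (divided channel-wise by the genomic abundance
of the reference triplet and renormalized) so that their Shannon entropy
H = -sum p_k log p_k measures the unevenness of per-context mutability
irrespective of genome composition: the lower H, the more concentrated the
process is on few contexts.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, log

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import entropy as _scipy_entropy

from .reference_model import (
    CHANNELS,
    ContextCensus,
    Genome,
    parse_channel,
    pyrimidine_context,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def read_profiles(path) -> pd.DataFrame:
    """Read a COSMIC-style profile TSV (column ``Type`` with channel labels like
    ``A[C>A]A``, one column per signature) into a 96 x k DataFrame."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "Type"
    missing = set(CHANNELS) - set(df.index)
    if missing:
        raise ValueError(f"profile file missing {len(missing)} channels")
    df = df.loc[list(CHANNELS)].astype(float)
    sums = df.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > 1e-6].index.tolist()
    if bad:
        raise ValueError(f"profile columns do not sum to 1: {bad}")
    return df


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.reindex(list(CHANNELS)).rename_axis("Type").to_csv(path, sep="\t")


def mutation_channel(genome: Genome, contig: str, pos1: int, ref: str, alt: str) -> str | None:
    """The 96-channel label of an SNV, or ``None`` if the context is unresolvable.

    Purine-reference mutations are collapsed to the opposite strand (both the
    context and the alternate are reverse-complemented).
    """
    trip = pyrimidine_context(genome, contig, pos1)
    if trip is None:
        return None
    if ref in "AG":
        alt = _COMP[alt]
    return f"{trip[0]}[{trip[1]}>{alt}]{trip[2]}"


def build_catalog(mutations: pd.DataFrame, genome: Genome) -> tuple[pd.DataFrame, int]:
    """96-channel mutation catalog, one column per sample.

    ``mutations`` needs columns CHROMOSOME, POSITION, REF, ALT, SAMPLE and must
    contain SNVs only.  Returns (catalog, number of skipped mutations with
    unresolvable context).
    """
    samples = sorted(mutations["SAMPLE"].unique())
    counts = pd.DataFrame(0, index=list(CHANNELS), columns=samples, dtype=np.int64)
    skipped = 0
    for row in mutations.itertuples(index=False):
        ch = mutation_channel(genome, row.CHROMOSOME, int(row.POSITION), row.REF, row.ALT)
        if ch is None:
            skipped += 1
            continue
        counts.loc[ch, row.SAMPLE] += 1
    return counts, skipped


def normalize_profile(profile: pd.Series, census: ContextCensus) -> pd.Series:
    """Genome-normalize a 96-channel profile.

    Each channel frequency is divided by the genomic abundance of its reference
    triplet, and the result renormalized to sum to 1.  A zero census count for a
    channel with positive frequency is an error.
    """
    totals = census.triplet_totals()
    weights = pd.Series(0.0, index=list(CHANNELS))
    for ch in CHANNELS:
        f = float(profile.get(ch, 0.0))
        if f == 0.0:
            continue
        trip, _ = parse_channel(ch)
        n = int(totals.get(trip, 0))
        if n == 0:
            raise ValueError(f"channel {ch} active but triplet {trip} absent from census")
        weights[ch] = f / n
    total = weights.sum()
    if total == 0:
        raise ValueError("profile is identically zero")
    return weights / total


def profile_entropy(p: pd.Series | np.ndarray) -> float:
    """Shannon entropy (natural log) of a normalized profile; 0*log 0 := 0."""
    arr = np.asarray(p, dtype=float)
    return float(_scipy_entropy(arr))


def fit_exposures_nnls(
    M: pd.DataFrame, S: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Column-wise non-negative least squares fit of exposures.

    Returns (exposures: signatures x samples, residual norms per sample).
    """
    if list(M.index) != list(S.index):
        raise ValueError("catalog and profile channels are not aligned")
    A = S.to_numpy(dtype=float)
    E = np.zeros((S.shape[1], M.shape[1]))
    resid = np.zeros(M.shape[1])
    for j, col in enumerate(M.columns):
        E[:, j], resid[j] = nnls(A, M[col].to_numpy(dtype=float))
    return (
        pd.DataFrame(E, index=S.columns, columns=M.columns),
        pd.Series(resid, index=M.columns, name="residual"),
    )


def count_signature_subsets(n_candidates: int, kmax: int = 4) -> int:
    """Number of non-empty signature subsets of size up to ``kmax``."""
    return sum(comb(n_candidates, k) for k in range(1, kmax + 1))


def aic_least_squares(rss: float, n_obs: int, n_params: int) -> float:
    """Gaussian least-squares AIC: n_obs * ln(RSS / n_obs) + 2 * n_params."""
    rss = max(rss, 1e-300)
    return n_obs * log(rss / n_obs) + 2 * n_params


def select_signature_combination(
    M: pd.DataFrame,
    candidates: pd.DataFrame,
    kmax: int = 4,
    top_t: int = 100,
    max_subsets: int = 500_000,
) -> dict:
    """Exhaustive AIC search over signature subsets of size 1..kmax.

    Every subset is fitted by NNLS; subsets are ranked by AIC (parameter count =
    free exposures = |subset| * n_samples).  Returns a dict with the best subset,
    the full ranking, and the per-signature frequency among the ``top_t`` best
    solutions ("most frequent in the top solutions" consensus).
    """
    names = list(candidates.columns)
    n_total = count_signature_subsets(len(names), kmax)
    if n_total > max_subsets:
        raise ValueError(
            f"{n_total} subsets exceed the cap ({max_subsets}); prune the "
            "candidate list or raise max_subsets"
        )
    n_obs = M.shape[0] * M.shape[1]
    rows = []
    for k in range(1, kmax + 1):
        for subset in combinations(names, k):
            _, resid = fit_exposures_nnls(M, candidates[list(subset)])
            rss = float((resid**2).sum())
            rows.append((subset, k, rss, aic_least_squares(rss, n_obs, k * M.shape[1])))
    ranking = pd.DataFrame(rows, columns=["subset", "k", "rss", "aic"])
    ranking = ranking.sort_values("aic", kind="mergesort").reset_index(drop=True)
    top = ranking.head(top_t)
    freq: dict[str, int] = {name: 0 for name in names}
    for subset in top["subset"]:
        for s in subset:
            freq[s] += 1
    return {
        "best_subset": tuple(ranking.loc[0, "subset"]),
        "ranking": ranking,
        "top_frequency": pd.Series(freq).sort_values(ascending=False),
        "n_subsets": len(ranking),
    }


def mutation_probability_vector(
    channel: str, exposures: pd.Series, profiles: pd.DataFrame
) -> pd.Series | None:
    """Posterior probability of each signature having generated a mutation.

    P(s) = E_s f_s(channel) / sum_t E_t f_t(channel); ``None`` when the
    denominator is zero (mutation unattributable under the fitted exposures).
    """
    w = exposures.reindex(profiles.columns).to_numpy(dtype=float) * profiles.loc[
        channel
    ].to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        return None
    return pd.Series(w / total, index=profiles.columns)


def probability_matrix(
    channels: pd.Series, exposures: pd.DataFrame, profiles: pd.DataFrame, samples: pd.Series
) -> pd.DataFrame:
    """Vectorised per-mutation probability vectors.

    ``channels``/``samples`` are parallel per-mutation Series; ``exposures`` is
    signatures x samples.  Rows with an all-zero denominator come back as NaN.
    """
    F = profiles.loc[list(CHANNELS)].to_numpy(dtype=float)  # 96 x k
    ch_idx = pd.Index(CHANNELS).get_indexer(channels)
    E = exposures.reindex(columns=samples.unique(), fill_value=0.0)
    s_idx = E.columns.get_indexer(samples)
    W = F[ch_idx, :] * E.to_numpy(dtype=float).T[s_idx, :]
    totals = W.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(totals > 0, W / totals, np.nan)
    return pd.DataFrame(P, columns=exposures.index, index=channels.index)


def assign_max_likelihood(
    vector: pd.Series, threshold: float = 0.5
) -> tuple[str, bool]:
    """Maximum-likelihood signature call with a high-confidence flag.

    Ties break lexicographically; high confidence requires the maximum to be
    strictly greater than ``threshold``.
    """
    if len(vector) == 0:
        raise ValueError("empty probability vector")
    vmax = vector.max()
    winner = sorted(vector.index[vector == vmax])[0]
    return winner, bool(vmax > threshold)


def assign_hotspot_signature(vectors: pd.DataFrame) -> tuple[str, pd.Series, bool]:
    """Signature of a hotspot: argmax of the mean member probability vector.

    Returns (signature, mean vector, tie flag); ties break lexicographically.
    """
    if len(vectors) == 0:
        raise ValueError("hotspot has no member probability vectors")
    mean = vectors.mean(axis=0)
    vmax = mean.max()
    winners = sorted(mean.index[mean == vmax])
    return winners[0], mean, len(winners) > 1


def active_signatures(
    exposures: pd.DataFrame, sample_fraction: float = 0.05, exposure_share: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Sample- and cohort-level activity calls.

    A signature is active in a sample when its exposure share is at least
    ``exposure_share`` of the sample's fitted mutations, and active in the
    cohort when sample-active in at least ``sample_fraction`` of samples.
    """
    totals = exposures.sum(axis=0)
    shares = exposures.div(totals.where(totals > 0, np.nan), axis=1).fillna(0.0)
    sample_active = shares >= exposure_share
    frac = sample_active.mean(axis=1)
    cohort_active = sorted(frac.index[frac >= sample_fraction])
    return sample_active, cohort_active
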