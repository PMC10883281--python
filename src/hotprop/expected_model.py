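"""Closed-form expected hotspot counts under an idealised cohort model.

The model assumes (i) every sample in a cohort of size S contributes the same
number n of mutations and (ii) positions mutate independently.  Given a
per-position, per-alternate single-mutation probability q (the weight map), the
probability that one sample hits a given (position, alternate) at least once in
its n draws is pi = 1 - (1 - q)^n, and the probability that no alternate-
specific hotspot forms there is

    P(no hotspot) = (1 - pi)^S + S * pi * (1 - pi)^(S-1)

(at most one of the S samples hit it).  Collapsing to one hotspot per position,
a position's hotspot probability is one minus the product of the no-hotspot
terms over its three alternates (cross-alternate independence approximation),
and by positional independence the regional expectation is the sum over
positions — computed class-wise (per channel / bin / methylation stratum) since
all positions of a class share q.

Three resolutions of the weight map are supported:

* genome-wide:  q(c,a) = f(c->a) / N_c   (trinucleotide profile + composition)
* per-chunk:    q(c,a,k) = r_k * f_k(c->a) / N_{c,k}  with f renormalized
                within each chunk over the contexts it actually contains
* methylation-aware: NpCpG channels split by CpG methylation state with a
                mutability fold rho:  q_meth = f * rho / (rho*N_m + N_u),
                q_unmeth = f / (rho*N_m + N_u)

In every mode the map sums to 1 over all (position, alternate) pairs.  A
class-based Monte-Carlo simulator provides an independent check of the closed
form (it draws whole cohorts and counts hotspots combinatorially, without the
binomial or cross-alternate approximations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .reference_model import (
    CHANNELS,
    CPG_TRIPLETS,
    ContextCensus,
    Genome,
    GenomicBin,
    channel_label,
    parse_channel,
)

_ALTS = {"C": ("A", "G", "T"), "T": ("A", "C", "G")}


def chunk_relative_rates(counts: pd.Series) -> pd.Series:
    """Relative mutation rate per chunk from attributed mutation counts.

    r_k = count_k / total; zero-count chunks keep rate 0 (no pseudocount).
    """
    total = counts.sum()
    if total <= 0:
        raise ValueError("no attributed mutations: chunk rates undefined")
    return counts / total


def mutation_bin_counts(mutations: pd.DataFrame, bins: list[GenomicBin]) -> pd.Series:
    """Count mutations per bin (mutations outside every bin are dropped)."""
    by_contig: dict[str, list[GenomicBin]] = {}
    for b in bins:
        by_contig.setdefault(b.contig, []).append(b)
    counts = pd.Series(0, index=[b.bin_id for b in bins], dtype=np.int64)
    for contig, sub in mutations.groupby("CHROMOSOME"):
        blist = sorted(by_contig.get(contig, []), key=lambda b: b.start)
        if not blist:
            continue
        starts = np.array([b.start for b in blist])
        ends = np.array([b.end for b in blist])
        pos0 = sub["POSITION"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        for i in idx[inside]:
            counts[blist[i].bin_id] += 1
    return counts


def position_weight_map(
    census: ContextCensus,
    profile: pd.Series,
    rates: pd.Series | None = None,
    methylation_fold: float | None = None,
) -> pd.DataFrame:
    """Per-class single-mutation probabilities q.

    Returns a DataFrame with one row per (triplet, alt, bin, meth) class:
    columns triplet, alt, bin, meth, N (positions in the class) and q (the
    probability that a single drawn mutation is a given position+alternate of
    the class).  Sums to 1: sum over rows of N * q == 1.

    ``rates`` maps bin id -> r_k for the per-chunk mode (census must then be
    bin-stratified); ``methylation_fold`` is rho for the methylation-aware mode
    (census must then be methylation-split).
    """
    f = profile.reindex(list(CHANNELS), fill_value=0.0).astype(float)
    if not np.isclose(f.sum(), 1.0, atol=1e-6):
        raise ValueError("profile must sum to 1")

    counts = census.counts
    rows: list[dict] = []
    bin_levels = counts.index.get_level_values("bin").unique()
    if rates is not None:
        missing = set(bin_levels) - set(rates.index) - {"."}
        if missing:
            raise ValueError(f"bins without a rate: {sorted(missing)[:5]}")
        if "." in bin_levels and len(bin_levels) > 1:
            raise ValueError("census mixes binned and unbinned classes")
        if not np.isclose(rates.sum(), 1.0, atol=1e-6):
            raise ValueError("chunk rates must sum to 1")
        bins_iter = [b for b in bin_levels if b != "."]
    else:
        if list(bin_levels) != ["."]:
            # rates not supplied: pool the census genome-wide
            counts = counts.groupby(level=[0, 2]).sum()
            counts.index = pd.MultiIndex.from_tuples(
                [(t, ".", m) for t, m in counts.index], names=["triplet", "bin", "meth"]
            )
        bins_iter = ["."]

    for bin_id in bins_iter:
        sub = counts.xs(bin_id, level="bin")
        n_by_class = sub.groupby(level=[0, 1]).sum()  # (triplet, meth) -> N
        trip_totals = sub.groupby(level=0).sum()
        r_k = float(rates[bin_id]) if rates is not None else 1.0

        # renormalize f within the chunk over contexts that exist in it
        active_mass = 0.0
        for ch in CHANNELS:
            trip, _ = parse_channel(ch)
            if trip_totals.get(trip, 0) > 0:
                active_mass += f[ch]
        if active_mass == 0.0:
            if r_k > 0:
                raise ValueError(
                    f"chunk {bin_id!r} has rate {r_k} but no context of the profile"
                )
            continue

        for ch in CHANNELS:
            fk = f[ch] / active_mass
            trip, alt = parse_channel(ch)
            n_total = float(trip_totals.get(trip, 0))
            if n_total == 0:
                if f[ch] > 0 and rates is None:
                    raise ValueError(
                        f"context {trip} required by the profile is absent"
                    )
                continue
            if methylation_fold is not None and trip in CPG_TRIPLETS:
                n_m = float(n_by_class.get((trip, "meth"), 0.0))
                n_u = float(n_by_class.get((trip, "unmeth"), 0.0))
                if not np.isclose(n_m + n_u, n_total):
                    raise ValueError(
                        f"NpCpG triplet {trip} in bin {bin_id!r} is not fully "
                        "methylation-classified"
                    )
                denom = methylation_fold * n_m + n_u
                if denom > 0:
                    rows.append(
                        dict(triplet=trip, alt=alt, bin=bin_id, meth="meth",
                             N=int(n_m), q=r_k * fk * methylation_fold / denom)
                    )
                    rows.append(
                        dict(triplet=trip, alt=alt, bin=bin_id, meth="unmeth",
                             N=int(n_u), q=r_k * fk / denom)
                    )
            else:
                rows.append(
                    dict(triplet=trip, alt=alt, bin=bin_id, meth=".",
                         N=int(n_total), q=r_k * fk / n_total)
                )

    wm = pd.DataFrame(rows, columns=["triplet", "alt", "bin", "meth", "N", "q"])
    total = float((wm["N"] * wm["q"]).sum())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"weight map sums to {total}, not 1")
    return wm


@dataclass
class ExpectationResult:
    """Expected hotspot count with a per-class breakdown."""

    total: float
    breakdown: pd.DataFrame  # one row per (triplet, bin, meth) class with N, h


def expected_hotspots(weight_map: pd.DataFrame, S: int, n: int) -> ExpectationResult:
    """Closed-form expected number of hotspots (one per position).

    For each position class, pi_a = 1 - (1-q_a)^n per alternate, the no-hotspot
    probability per alternate is (1-pi)^S + S pi (1-pi)^(S-1), and the position
    hotspot probability is 1 minus the product over alternates.  The expectation
    is sum over classes of N * h.  S < 2 legally yields 0.
    """
    if S < 2:
        empty = pd.DataFrame(columns=["triplet", "bin", "meth", "N", "h"])
        return ExpectationResult(total=0.0, breakdown=empty)
    rows = []
    for (trip, bin_id, meth), sub in weight_map.groupby(
        ["triplet", "bin", "meth"], sort=True
    ):
        q = sub["q"].to_numpy(dtype=float)
        N = int(sub["N"].iloc[0])
        if N == 0:
            continue
        with np.errstate(divide="ignore"):  # q == 1 legitimately gives pi == 1
            pi = -np.expm1(n * np.log1p(-q))
            no_hs = (
                np.exp(S * np.log1p(-pi)) + S * pi * np.exp((S - 1) * np.log1p(-pi))
            )
        h = float(-np.expm1(np.sum(np.log(np.clip(no_hs, 1e-300, 1.0)))))
        rows.append(dict(triplet=trip, bin=bin_id, meth=meth, N=N, h=h))
    breakdown = pd.DataFrame(rows, columns=["triplet", "bin", "meth", "N", "h"])
    total = float((breakdown["N"] * breakdown["h"]).sum()) if len(breakdown) else 0.0
    return ExpectationResult(total=total, breakdown=breakdown)


def _draw_cohort_events(
    cum_w: np.ndarray,
    row_N: np.ndarray,
    S: int,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw S samples x n events without replacement within each sample.

    Events are (row, position-within-class); rows carry the class/alternate
    identity.  Sequential rejection of within-sample duplicates reproduces exact
    successive (weighted, without-replacement) sampling.
    """
    maxN = int(row_N.max()) + 1
    rows_out = np.empty(S * n, dtype=np.int64)
    pos_out = np.empty(S * n, dtype=np.int64)
    sample_out = np.repeat(np.arange(S), n)

    # fast path: draw all events at once; samples with no internal duplicate
    # are done, the rest are completed by sequential rejection
    r0 = np.searchsorted(cum_w, rng.random(S * n), side="right")
    p0 = (rng.random(S * n) * row_N[r0]).astype(np.int64)
    codes0 = (r0 * maxN + p0).reshape(S, n)
    rows_out[:] = r0
    pos_out[:] = p0
    if n > 1:
        sorted_codes = np.sort(codes0, axis=1)
        has_dup = (sorted_codes[:, 1:] == sorted_codes[:, :-1]).any(axis=1)
    else:
        has_dup = np.zeros(S, dtype=bool)

    for s in np.nonzero(has_dup)[0]:
        chosen: dict[int, None] = {}
        filled = 0
        # keep the first occurrences from the initial draw
        for j in range(n):
            c = int(codes0[s, j])
            if c not in chosen:
                chosen[c] = None
                rows_out[s * n + filled] = codes0[s, j] // maxN
                pos_out[s * n + filled] = codes0[s, j] % maxN
                filled += 1
        guard = 0
        while filled < n:
            guard += 1
            if guard > 10_000:
                raise RuntimeError("event sampling failed to converge")
            m = max((n - filled) * 2, 16)
            r = np.searchsorted(cum_w, rng.random(m), side="right")
            p = (rng.random(m) * row_N[r]).astype(np.int64)
            for rr, pp in zip(r, p):
                c = int(rr) * maxN + int(pp)
                if c not in chosen:
                    chosen[c] = None
                    rows_out[s * n + filled] = rr
                    pos_out[s * n + filled] = pp
                    filled += 1
                    if filled == n:
                        break
    return rows_out, pos_out, sample_out


def monte_carlo_expected(
    weight_map: pd.DataFrame,
    S: int,
    n: int,
    R: int,
    seed: int | np.random.Generator,
    return_counts: bool = False,
):
    """Monte-Carlo estimate of the expected hotspot count (one per position).

    Simulates R cohorts of S samples with n events each, drawn class-wise from
    the weight map (positions of a class are exchangeable), events within a
    sample distinct; counts positions where some alternate was hit by >= 2
    distinct samples.  Returns (mean, standard error) or, with
    ``return_counts``, (mean, se, per-cohort counts).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wm = weight_map[weight_map["q"] > 0].reset_index(drop=True)
    if len(wm) == 0:
        raise ValueError("weight map has no positive-probability classes")
    class_keys = wm[["triplet", "bin", "meth"]].apply(tuple, axis=1)
    class_idx = pd.Categorical(class_keys).codes.astype(np.int64)
    row_N = wm["N"].to_numpy(dtype=np.int64)
    w = wm["N"].to_numpy(dtype=float) * wm["q"].to_numpy(dtype=float)
    cum_w = np.cumsum(w / w.sum())
    cum_w[-1] = 1.0
    n_positions = int(
        wm.drop_duplicates(["triplet", "bin", "meth"])["N"].sum()
    )
    if n > n_positions:
        raise ValueError(f"n={n} exceeds the {n_positions} available positions")

    maxN = int(row_N.max()) + 1
    counts = np.zeros(R, dtype=np.int64)
    for rep in range(R):
        if S < 1:
            break
        rows, pos, _ = _draw_cohort_events(cum_w, row_N, S, n, rng)
        # alternate-specific recurrence: same (row, pos) in >= 2 samples
        # (within-sample events are distinct, so multiplicity == sample count)
        event_code = rows * maxN + pos
        uniq, mult = np.unique(event_code, return_counts=True)
        hot = uniq[mult >= 2]
        # collapse to one hotspot per position
        hot_rows = hot // maxN
        hot_pos = hot % maxN
        pos_code = class_idx[hot_rows] * maxN + hot_pos
        counts[rep] = len(np.unique(pos_code))
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(R)) if R > 1 else float("nan")
    if return_counts:
        return mean, se, counts
    return mean, se


def cpg_mutation_counts(
    methylation: pd.DataFrame, mutations: pd.DataFrame, genome: Genome
) -> dict[str, int]:
    """2x2 counts of CpG sites by methylation class and mutated status.

    A CpG site (keyed by the 1-based + strand C) is mutated when any SNV falls
    on its C or its G.  Returns keys mutated_meth, unmutated_meth,
    mutated_unmeth, unmutated_unmeth.
    """
    if len(methylation) == 0:
        raise ValueError("no CpG sites")
    mutated_sites: set[tuple[str, int]] = set()
    for row in mutations.itertuples(index=False):
        contig, pos1 = row.CHROMOSOME, int(row.POSITION)
        if contig not in genome:
            continue
        seq = genome[contig]
        base = seq[pos1 - 1] if 1 <= pos1 <= len(seq) else "N"
        if base == "C" and seq[pos1 : pos1 + 1] == "G":
            mutated_sites.add((contig, pos1))
        elif base == "G" and seq[pos1 - 2 : pos1 - 1] == "C":
            mutated_sites.add((contig, pos1 - 1))
    out = dict(mutated_meth=0, unmutated_meth=0, mutated_unmeth=0, unmutated_unmeth=0)
    for row in methylation.itertuples(index=False):
        meth = float(row.FRACTION) > 0.5
        mutated = (str(row.CONTIG), int(row.POS)) in mutated_sites
        key = ("mutated_" if mutated else "unmutated_") + ("meth" if meth else "unmeth")
        out[key] += 1
    return out


def infer_methylation_foldchange(
    mutated_meth: int, unmutated_meth: int, mutated_unmeth: int, unmutated_unmeth: int
) -> tuple[float, bool]:
    """Methylated/unmethylated per-site mutability fold as an odds ratio.

    rho = (mutated_meth/unmutated_meth) / (mutated_unmeth/unmutated_unmeth),
    with the Haldane-Anscombe 0.5 correction (flagged) when any cell is zero.
    """
    cells = [mutated_meth, unmutated_meth, mutated_unmeth, unmutated_unmeth]
    if mutated_meth + unmutated_meth == 0 or mutated_unmeth + unmutated_unmeth == 0:
        raise ValueError("a methylation class has no CpG sites")
    corrected = any(c == 0 for c in cells)
    if corrected:
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    return float((a / b) / (c / d)), corrected


def explained_fraction(observed: float, expected: float) -> float:
    """Expected / observed as a percentage; > 100 is allowed (and meaningful)."""
    if observed == 0:
        raise ValueError("observed count is zero: explained fraction undefined")
    return 100.0 * expected / observed


def fit_overdispersion(counts) -> tuple[float, float]:
    """Negative-binomial overdispersion of binned counts (v = mu + alpha*mu^2).

    Intercept-only NB2 maximum likelihood; returns (alpha, standard error).
    alpha near zero means the counts are Poisson-consistent.
    """
    arr = np.asarray(counts)
    if len(arr) < 10:
        raise ValueError("need at least 10 bins")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    arr = arr.astype(float)
    exog = np.ones((len(arr), 1))
    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings(record=True):
        # degenerate (Poisson-consistent) inputs push alpha to its boundary;
        # the resulting chatter (incl. warnings statsmodels forces past
        # filters) is expected and swallowed
        _warnings.simplefilter("ignore")
        model = NegativeBinomial(arr, exog, loglike_method="nb2")
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            res = model.fit(disp=0, method="nm", maxiter=2000)
        alpha = float(res.params[-1])
        se = float(res.bse[-1])
    return max(alpha, 0.0), se
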