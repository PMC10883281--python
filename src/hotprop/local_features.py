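"""Sub-10-Kbp feature analyses around hotspots.

Covers three local readouts: (i) enrichment of hotspot mutations at feature
cores (CTCF-binding-site-like intervals) relative to their flanks, tested
against a composition-aware randomization null; (ii) odds ratios of mutation /
hotspot occurrence at methylated versus unmethylated CpG sites; and (iii)
decile summaries of signature activity against a per-bin covariate signal.

The feature windows align each kept feature on a fixed frame: a window of
length L (2000 bp) whose central L_feature (600 bp) is the core and whose two
flanks are (L - L_feature)/2 = 700 bp each.  The null redistributes the
observed number of inside-hotspot mutations across window positions with
probability proportional to the total mutability of each position's
trinucleotide under the signature profile, so any enrichment purely driven by
sequence composition is absorbed into the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import gaussian_kde

from .reference_model import (
    CHANNELS,
    TRIPLETS,
    Genome,
    RegionSet,
    _contig_context_codes,
    parse_channel,
)
from .expected_model import cpg_mutation_counts


@dataclass
class FeatureWindow:
    """A fixed-length window centred on a feature midpoint."""

    contig: str
    start: int  # window start, 0-based
    end: int
    core_start: int
    core_end: int
    feature_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


def build_feature_windows(
    features: RegionSet,
    genome: Genome,
    mappable: RegionSet,
    window_length: int = 2000,
    core_length: int = 600,
    feature_length_range: tuple[int, int] = (200, 600),
    min_mappable_overlap: float = 0.9,
) -> list[FeatureWindow]:
    """Windows for features passing the length and mappability filters.

    Features with length within ``feature_length_range`` and mappable overlap
    >= ``min_mappable_overlap`` get a ``window_length`` window centred on the
    feature midpoint (floor rounding); windows extending past a contig end are
    dropped.
    """
    lo, hi = feature_length_range
    half = window_length // 2
    core_half = core_length // 2
    out = []
    for i, (contig, s, e) in enumerate(features.intervals()):
        length = e - s
        if not lo <= length <= hi:
            continue
        if mappable.overlap_length(contig, s, e) / length < min_mappable_overlap:
            continue
        mid = (s + e) // 2
        w_start, w_end = mid - half, mid + half
        if w_start < 0 or contig not in genome or w_end > genome.length(contig):
            continue
        out.append(
            FeatureWindow(
                contig=contig,
                start=w_start,
                end=w_end,
                core_start=mid - core_half,
                core_end=mid + core_half,
                feature_id=f"feat{i}:{contig}:{s}-{e}",
            )
        )
    return out


def _window_offsets(
    windows: list[FeatureWindow], mutations: pd.DataFrame
) -> np.ndarray:
    """Aligned 0-based window offsets for every mutation inside a window."""
    by_contig: dict[str, list[FeatureWindow]] = {}
    for w in windows:
        by_contig.setdefault(w.contig, []).append(w)
    for lst in by_contig.values():
        lst.sort(key=lambda w: w.start)
    offsets = []
    for contig, sub in mutations.groupby("CHROMOSOME"):
        wins = by_contig.get(contig, [])
        if not wins:
            continue
        starts = np.array([w.start for w in wins])
        ends = np.array([w.end for w in wins])
        pos0 = sub["POSITION"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        offsets.append(pos0[inside] - starts[idx[inside]])
    if not offsets:
        return np.array([], dtype=np.int64)
    return np.concatenate(offsets)


def _core_flank_fc(
    counts: np.ndarray, core_slice: slice, window_length: int
) -> float:
    core = counts[core_slice].sum()
    flank = counts.sum() - core
    core_bp = core_slice.stop - core_slice.start
    flank_bp = window_length - core_bp
    if flank == 0:
        return np.inf
    return (core / core_bp) / (flank / flank_bp)


def pileup_enrichment(
    windows: list[FeatureWindow],
    inside_mutations: pd.DataFrame,
    outside_mutations: pd.DataFrame,
    genome: Genome,
    profile: pd.Series,
    n_rand: int = 1000,
    seed: int = 0,
    smooth_window: int = 101,
    smooth_order: int = 3,
) -> dict:
    """Core-vs-flank enrichment of inside-hotspot mutations with a
    composition-aware randomization null.

    Mutations are piled onto aligned window coordinates; the fold change is
    (core count / core bp) / (flank count / flank bp).  The null redistributes
    the observed inside count over all window positions with probability
    proportional to the summed channel probability of each position's
    trinucleotide; the p-value is the upper-tail mass of the observed fold
    change under a Gaussian KDE of the null fold changes, floored at 1/n_rand.
    Normalized piled profiles smoothed with a Savitzky-Golay filter are
    returned for display only.
    """
    if not windows:
        raise ValueError("no feature windows")
    rng = np.random.default_rng(seed)
    L = windows[0].length
    core_rel = slice(
        windows[0].core_start - windows[0].start, windows[0].core_end - windows[0].start
    )

    obs_off = _window_offsets(windows, inside_mutations)
    if len(obs_off) == 0:
        raise ValueError("no inside-hotspot mutation overlaps the windows")
    obs_counts = np.bincount(obs_off, minlength=L)
    obs_fc = _core_flank_fc(obs_counts, core_rel, L)
    out_off = _window_offsets(windows, outside_mutations)
    out_counts = np.bincount(out_off, minlength=L) if len(out_off) else np.zeros(L)

    # per-triplet total mutability under the profile
    trip_weight = np.zeros(32)
    for ch in CHANNELS:
        trip, _ = parse_channel(ch)
        trip_weight[TRIPLETS.index(trip)] += float(profile.get(ch, 0.0))

    # composition weight of every (window, offset) slot
    slot_weights = np.zeros((len(windows), L))
    codes_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for wi, w in enumerate(windows):
        if w.contig not in codes_cache:
            codes_cache[w.contig] = _contig_context_codes(genome[w.contig])
        trip_codes, valid = codes_cache[w.contig]
        sl = slice(w.start, w.end)
        wts = np.where(valid[sl], trip_weight[trip_codes[sl]], 0.0)
        slot_weights[wi] = wts
    flat = slot_weights.ravel()
    total_w = flat.sum()
    if total_w <= 0:
        raise ValueError("profile has no mutable context within the windows")
    p_flat = flat / total_w

    n_obs = len(obs_off)
    null_fcs = np.empty(n_rand)
    for it in range(n_rand):
        draws = rng.multinomial(n_obs, p_flat)
        counts = draws.reshape(len(windows), L).sum(axis=0)
        null_fcs[it] = _core_flank_fc(counts, core_rel, L)
    finite_null = null_fcs[np.isfinite(null_fcs)]

    flagged = not np.isfinite(obs_fc)
    if flagged:
        pval = 1.0 / n_rand
    else:
        kde = gaussian_kde(finite_null)
        pval = float(kde.integrate_box_1d(obs_fc, np.inf))
        pval = max(pval, 1.0 / n_rand)

    def _smooth(counts):
        total = counts.sum()
        norm = counts / total if total > 0 else counts
        if len(norm) >= smooth_window:
            return savgol_filter(norm, smooth_window, smooth_order)
        return norm

    return {
        "fold_change": float(obs_fc),
        "pvalue": float(pval),
        "null_fold_changes": null_fcs,
        "n_inside": int(n_obs),
        "flagged_infinite": flagged,
        "profile_inside": _smooth(obs_counts.astype(float)),
        "profile_outside": _smooth(out_counts.astype(float)),
        "counts_inside": obs_counts,
    }


def odds_ratio_2x2(a: float, b: float, c: float, d: float) -> dict:
    """OR = (a/b)/(c/d) with a Wald 95% CI; Haldane 0.5 correction on zeros."""
    corrected = any(x == 0 for x in (a, b, c, d))
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return {
        "odds_ratio": float(or_),
        "ci_low": float(or_ * np.exp(-1.96 * se)),
        "ci_high": float(or_ * np.exp(1.96 * se)),
        "corrected": corrected,
    }


def methylation_odds_ratio(
    methylation: pd.DataFrame, events: pd.DataFrame, genome: Genome
) -> dict:
    """Odds ratio of per-site event occurrence at methylated vs unmethylated CpGs.

    ``events`` is any table with CHROMOSOME/POSITION columns (mutations or
    hotspots); a CpG site counts as hit when an event falls on its C or G.
    Returns per-class site counts and percentages plus the OR and its 95% CI.
    """
    cells = cpg_mutation_counts(methylation, events, genome)
    n_meth = cells["mutated_meth"] + cells["unmutated_meth"]
    n_unmeth = cells["mutated_unmeth"] + cells["unmutated_unmeth"]
    if n_meth == 0 or n_unmeth == 0:
        raise ValueError("a methylation class has no CpG sites")
    stats = odds_ratio_2x2(
        cells["mutated_meth"],
        cells["unmutated_meth"],
        cells["mutated_unmeth"],
        cells["unmutated_unmeth"],
    )
    stats.update(
        cells,
        pct_meth_hit=100.0 * cells["mutated_meth"] / n_meth,
        pct_unmeth_hit=100.0 * cells["mutated_unmeth"] / n_unmeth,
    )
    return stats


def covariate_deciles(
    signal: pd.Series,
    activity_inside: pd.Series,
    activity_outside: pd.Series,
) -> pd.DataFrame:
    """Signature activity inside/outside hotspots by covariate-signal decile.

    Bins are ranked by signal and split into 10 equal-count groups; per group
    the normalized activities are summed.  Totals are conserved across deciles.
    """
    if len(signal) < 10:
        raise ValueError("need at least 10 bins for deciles")
    if signal.nunique() == 1:
        warnings.warn("constant covariate signal: deciles are degenerate", stacklevel=2)
    common = signal.index
    ai = activity_inside.reindex(common, fill_value=0.0)
    ao = activity_outside.reindex(common, fill_value=0.0)
    rank = signal.rank(method="first")
    decile = pd.qcut(rank, 10, labels=False)
    rows = []
    for d in range(10):
        mask = decile == d
        rows.append(
            dict(
                decile=d + 1,
                n_bins=int(mask.sum()),
                signal_mean=float(signal[mask].mean()),
                inside=float(ai[mask].sum()),
                outside=float(ao[mask].sum()),
            )
        )
    return pd.DataFrame(rows).set_index("decile")
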