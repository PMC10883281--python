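"""Observed hotspot propensity and inside/outside-hotspot enrichment statistics.

Hotspot propensity is the number of hotspots a mutational process forms under
fixed activity — a fixed number of samples each contributing a fixed number of
mutations — estimated by repeated subsampling from the pool of high-confidence
mutations attributed to the process.  Because activity is held constant, the
readout isolates the intrinsic single-base mutation-rate variability of the
process from cohort size and burden.

Conversion rates (mutations needed on average to form one hotspot) come from
the inverse slope of per-sample hotspot membership regressed on mutation
burden across random cohort subsets.  The enrichment statistics compare
signature activity (or raw substitution channels) between the mutations inside
and outside hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reference_model import Genome, RegionSet
from .signatures import mutation_channel

_ALT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SubsampleSpec:
    """Geometry of the propensity subsampling experiment."""

    n_samples: int = 100
    mutations_per_sample: int = 300
    iterations: int = 1000
    grouping: str = "by_sample"  # or "pooled"
    scope: RegionSet | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.mutations_per_sample, self.iterations) < 1:
            raise ValueError("n_samples, mutations_per_sample, iterations must be >= 1")
        if self.grouping not in ("by_sample", "pooled"):
            raise ValueError(f"unknown grouping {self.grouping!r}")


@dataclass
class PropensityResult:
    """Distribution of hotspot counts across subsampling iterations."""

    counts: np.ndarray
    median: float
    iqr: tuple[float, float]
    spec: SubsampleSpec | None = None


def eligible_pairs(
    hotspot_counts: dict,
    highconf_sample_counts: dict,
    min_hotspots: int = 450,
    min_mutations_per_sample: int = 300,
    min_samples: int = 101,
) -> list:
    """Signature/cohort pairs with enough hotspots and qualifying samples.

    Eligible when the pair has >= ``min_hotspots`` attributed hotspots AND at
    least ``min_samples`` samples each contributing strictly more than
    ``min_mutations_per_sample`` high-confidence mutations.
    """
    out = []
    for key, n_hs in hotspot_counts.items():
        counts = highconf_sample_counts.get(key)
        if counts is None:
            continue
        qualifying = int((pd.Series(counts) > min_mutations_per_sample).sum())
        if n_hs >= min_hotspots and qualifying >= min_samples:
            out.append(key)
    return out


def _encode_events(mutations: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(position id, event id) per mutation; event = position + alternate."""
    pos_id = pd.factorize(
        mutations["CHROMOSOME"].astype(str) + ":" + mutations["POSITION"].astype(str)
    )[0].astype(np.int64)
    alt = mutations["ALT"].map(_ALT_CODE).to_numpy(dtype=np.int64)
    return pos_id, pos_id * 4 + alt


def count_position_hotspots(event_codes: np.ndarray, min_hits: int = 2) -> int:
    """Hotspots among drawn events, collapsed to one per position.

    An event (position + alternate) hit ``min_hits`` or more times marks its
    position; the count is the number of marked positions.
    """
    uniq, mult = np.unique(event_codes, return_counts=True)
    hot = uniq[mult >= min_hits]
    return len(np.unique(hot // 4))


def observed_propensity(
    mutations: pd.DataFrame, spec: SubsampleSpec
) -> PropensityResult:
    """Hotspot propensity by repeated fixed-activity subsampling.

    ``by_sample``: each iteration draws ``n_samples`` qualifying samples
    (those with at least ``mutations_per_sample`` eligible mutations) without
    replacement, then ``mutations_per_sample`` mutations per chosen sample
    without replacement; hotspots are positions where >= 2 distinct samples
    drew the same alternate, counted once per position.  ``pooled``: draws
    n_samples * mutations_per_sample mutations from the merged pool and counts
    positions with >= 2 sampled mutations of equal alternate.
    """
    rng = np.random.default_rng(spec.seed)
    df = mutations
    if spec.scope is not None:
        keep = np.zeros(len(df), dtype=bool)
        for contig, sub in df.groupby("CHROMOSOME"):
            keep[sub.index] = spec.scope.contains_many(
                contig, sub["POSITION"].to_numpy() - 1
            )
        df = df[keep]
    df = df.reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no mutations in scope")
    _, events = _encode_events(df)

    m = spec.mutations_per_sample
    counts = np.zeros(spec.iterations, dtype=np.int64)

    if spec.grouping == "pooled":
        total = spec.n_samples * m
        if total > len(df):
            raise ValueError(
                f"pooled draw of {total} exceeds the {len(df)} available mutations"
            )
        for it in range(spec.iterations):
            take = rng.choice(len(df), size=total, replace=False)
            counts[it] = count_position_hotspots(events[take])
    else:
        sample_groups = {
            s: sub.index.to_numpy() for s, sub in df.groupby("SAMPLE")
        }
        qualifying = [s for s, idx in sample_groups.items() if len(idx) >= m]
        if len(qualifying) < spec.n_samples:
            raise ValueError(
                f"only {len(qualifying)} samples have >= {m} mutations; "
                f"{spec.n_samples} required"
            )
        qualifying = sorted(qualifying)
        # within a sample events are deduplicated before drawing
        sample_events = {}
        for s in qualifying:
            ev = np.unique(events[sample_groups[s]])
            sample_events[s] = ev
            if len(ev) < m:
                raise ValueError(f"sample {s} has fewer than {m} distinct events")
        for it in range(spec.iterations):
            picked = rng.choice(len(qualifying), size=spec.n_samples, replace=False)
            drawn = [
                sample_events[qualifying[p]][
                    rng.choice(len(sample_events[qualifying[p]]), size=m, replace=False)
                ]
                for p in picked
            ]
            # distinct samples drawing the same event == event multiplicity,
            # since each sample's drawn events are distinct
            counts[it] = count_position_hotspots(np.concatenate(drawn))

    q25, median, q75 = np.quantile(counts, [0.25, 0.5, 0.75])
    return PropensityResult(
        counts=counts, median=float(median), iqr=(float(q25), float(q75)), spec=spec
    )


def conversion_rate(
    mutations: pd.DataFrame,
    iterations: int = 1000,
    subset: int = 100,
    seed: int = 0,
    significance: float = 0.05,
    min_significant: int = 750,
    invert_per_replicate: bool = False,
) -> dict:
    """Mutations per hotspot from the hotspot-vs-burden regression.

    Each iteration draws ``subset`` samples, pools their SNVs, finds
    alternate-specific hotspots, and regresses each sample's hotspot
    membership count on its mutation burden (OLS, t-test on the slope).  When
    at least ``min_significant`` iterations give p < ``significance``, the
    conversion rate is the inverse of the median significant slope (or, with
    ``invert_per_replicate``, the median of the inverse slopes).  Otherwise
    ``rate`` is None and diagnostics are returned.
    """
    samples = sorted(mutations["SAMPLE"].unique())
    if len(samples) <= subset:
        raise ValueError(f"cohort of {len(samples)} samples needs > {subset}")
    rng = np.random.default_rng(seed)
    df = mutations.reset_index(drop=True)
    _, events = _encode_events(df)
    sample_idx = {s: sub.index.to_numpy() for s, sub in df.groupby("SAMPLE")}

    slopes, discarded = [], 0
    for _ in range(iterations):
        chosen = [samples[i] for i in rng.choice(len(samples), size=subset, replace=False)]
        idx = np.concatenate([sample_idx[s] for s in chosen])
        ev = events[idx]
        uniq, mult = np.unique(ev, return_counts=True)
        hot_events = set(uniq[mult >= 2].tolist())
        burden = np.array([len(sample_idx[s]) for s in chosen], dtype=float)
        response = np.array(
            [
                sum(1 for e in np.unique(events[sample_idx[s]]) if e in hot_events)
                for s in chosen
            ],
            dtype=float,
        )
        if np.var(burden) == 0:
            discarded += 1
            continue
        if np.all(response == response[0]):
            # exact flat response: slope 0, never significant
            continue
        res = stats.linregress(burden, response)
        pval = res.pvalue if np.isfinite(res.pvalue) else 0.0
        if pval < significance and res.slope != 0:
            slopes.append(res.slope)

    result = {
        "n_significant": len(slopes),
        "n_discarded": discarded,
        "iterations": iterations,
        "rate": None,
    }
    if len(slopes) >= min_significant:
        if invert_per_replicate:
            result["rate"] = float(np.median([1.0 / s for s in slopes]))
        else:
            result["rate"] = float(1.0 / np.median(slopes))
    return result


def signature_fold_change(
    inside_vectors: pd.DataFrame,
    outside_vectors: pd.DataFrame,
    sample_col: str = "SAMPLE",
    active: pd.DataFrame | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-signature inside/outside-hotspot activity fold change.

    ``inside_vectors`` / ``outside_vectors`` hold one row per mutation: a
    SAMPLE column plus one probability column per signature.  Per sample, the
    vectors of each set are summed and normalized to shares; the fold change of
    a signature is inside share / outside share, summarised as the median over
    samples where the signature is active (all samples when ``active`` is
    None).  Sample-paired shares are compared with a two-sided signed-rank
    test, BH-adjusted across signatures at ``alpha``.
    """
    signatures = [c for c in inside_vectors.columns if c != sample_col]
    ins = inside_vectors.groupby(sample_col)[signatures].sum()
    outs = outside_vectors.groupby(sample_col)[signatures].sum()
    common = ins.index.intersection(outs.index)
    if len(common) == 0:
        raise ValueError("no sample has mutations both inside and outside hotspots")
    ins = ins.loc[common].div(ins.loc[common].sum(axis=1), axis=0)
    outs = outs.loc[common].div(outs.loc[common].sum(axis=1), axis=0)

    rows = []
    for sig in signatures:
        if active is not None and sig in active.index:
            use = [s for s in common if bool(active.loc[sig].get(s, False))]
        else:
            use = list(common)
        pairs = [
            (ins.loc[s, sig], outs.loc[s, sig])
            for s in use
            if outs.loc[s, sig] > 0
        ]
        excluded = len(use) - len(pairs)
        fc = float(np.median([i / o for i, o in pairs])) if pairs else np.nan
        if len(pairs) >= 2 and any(i != o for i, o in pairs):
            try:
                p = float(
                    stats.wilcoxon(
                        [i for i, _ in pairs], [o for _, o in pairs]
                    ).pvalue
                )
            except ValueError:
                p = np.nan
        else:
            p = np.nan
        rows.append(
            dict(signature=sig, fold_change=fc, n_samples=len(pairs),
                 n_excluded=excluded, pvalue=p)
        )
    out = pd.DataFrame(rows).set_index("signature")
    tested = out["pvalue"].notna()
    out["qvalue"] = np.nan
    out["significant"] = False
    if tested.any():
        rej, q, _, _ = multipletests(
            out.loc[tested, "pvalue"], alpha=alpha, method="fdr_bh"
        )
        out.loc[tested, "qvalue"] = q
        out.loc[tested, "significant"] = rej
    return out


_SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_PYR_COLLAPSE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _six_class(ref: str, alt: str) -> str:
    if ref in "AG":
        ref, alt = _PYR_COLLAPSE[ref], _PYR_COLLAPSE[alt]
    return f"{ref}>{alt}"


def substitution_enrichment(
    inside: pd.DataFrame,
    outside: pd.DataFrame,
    genome: Genome | None = None,
    scheme: int = 6,
) -> pd.DataFrame:
    """Per-channel fold change of substitution frequencies inside vs outside
    hotspots (6-class or 96-channel).

    Channels absent outside but present inside get fold change +inf, flagged.
    """
    if len(inside) == 0 or len(outside) == 0:
        raise ValueError("inside and outside sets must both be non-empty")
    if scheme == 6:
        f_in = pd.Series(
            [_six_class(r, a) for r, a in zip(inside["REF"], inside["ALT"])]
        ).value_counts(normalize=True)
        f_out = pd.Series(
            [_six_class(r, a) for r, a in zip(outside["REF"], outside["ALT"])]
        ).value_counts(normalize=True)
        channels = list(_SIX_CLASSES)
    elif scheme == 96:
        if genome is None:
            raise ValueError("96-channel scheme needs the genome for contexts")

        def chans(df):
            out = [
                mutation_channel(genome, r.CHROMOSOME, int(r.POSITION), r.REF, r.ALT)
                for r in df.itertuples(index=False)
            ]
            return pd.Series([c for c in out if c is not None]).value_counts(
                normalize=True
            )

        f_in, f_out = chans(inside), chans(outside)
        from .reference_model import CHANNELS as channels  # noqa: N811
        channels = list(channels)
    else:
        raise ValueError("scheme must be 6 or 96")

    rows = []
    for ch in channels:
        fi = float(f_in.get(ch, 0.0))
        fo = float(f_out.get(ch, 0.0))
        if fo == 0.0:
            fc = np.inf if fi > 0 else np.nan
        else:
            fc = fi / fo
        rows.append(dict(channel=ch, freq_inside=fi, freq_outside=fo,
                         fold_change=fc, zero_outside=fo == 0.0 and fi > 0))
    return pd.DataFrame(rows).set_index("channel")
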