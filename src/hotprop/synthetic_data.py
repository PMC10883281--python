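"""Synthetic genomes, methylomes, feature tracks and mutation cohorts.

The generators emulate the statistical structure the downstream analyses
assume: i.i.d. base composition with a controllable CpG depletion (the human
genome carries roughly one fifth of the CpG dinucleotides expected under
independence, a footprint of 5-methylcytosine deamination), bimodal CpG
methylation with a per-site mutability fold, bin-level mutation-rate
heterogeneity with a Dirichlet-controlled concentration, signature-driven
trinucleotide channel preferences, and optional enriched feature intervals,
hypermutators and duplicate samples.

Mutations are drawn per sample without replacement (a sample never carries the
same event twice) and independently across samples, matching the cohort model
under which hotspot expectations are computed.  Every generator is fully
deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .reference_model import (
    CHANNELS,
    CPG_TRIPLETS,
    TRIPLETS,
    Genome,
    GenomicBin,
    RegionSet,
    _contig_context_codes,
    _encode,
    channel_label,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    The defaults mirror the cohort geometry used for hotspot-propensity
    subsampling (100 samples x 300 mutations/sample) and a CpG depletion of 0.2
    (the approximate genome-wide deficit of CpG dinucleotides relative to the
    independence expectation in mammals).
    """

    contig_lengths: dict = field(default_factory=lambda: {"chr1": 2_000_000})
    base_composition: tuple = (0.25, 0.25, 0.25, 0.25)  # A, C, G, T
    cpg_depletion: float = 0.2
    bin_width: int = 1_000_000
    chunk_rate_concentration: float | None = None  # Dirichlet alpha; None = uniform
    cohort_size: int = 100
    mutations_per_sample: int = 300
    hypermutator_fraction: float = 0.0
    hypermutator_burden: int = 20_000
    duplicate_fraction: float = 0.0
    duplicate_shared_fraction: float = 0.5
    meth_weight: float = 0.7  # pi_m: fraction of CpGs in the methylated mode
    meth_beta_high: tuple = (12.0, 3.0)
    meth_beta_low: tuple = (3.0, 12.0)
    meth_fold: float = 1.0  # rho_true: methylated-CpG mutability multiplier
    feature_count: int = 0
    feature_length_range: tuple = (200, 600)
    feature_multiplier: float = 1.0
    mappable_coverage: float = 0.9
    blacklist_coverage: float = 0.02
    variant_site_rate: float = 0.001  # per-bp rate of population-variant positions
    driver_coverage: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.base_composition), 1.0):
            raise ValueError("base composition must sum to 1")
        if self.cpg_depletion < 0 or self.meth_fold <= 0:
            raise ValueError("cpg_depletion must be >= 0 and meth_fold > 0")
        for p in (
            self.hypermutator_fraction,
            self.duplicate_fraction,
            self.meth_weight,
            self.mappable_coverage,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(l <= 0 for l in self.contig_lengths.values()):
            raise ValueError("contig lengths must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "contig_lengths" in raw:
            raw["contig_lengths"] = {str(k): int(v) for k, v in raw["contig_lengths"].items()}
        for key in ("base_composition", "meth_beta_high", "meth_beta_low",
                    "feature_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _random_mask(
    rng: np.random.Generator, length: int, coverage: float, chunk: int
) -> list[tuple[int, int]]:
    """Random disjoint intervals: include each consecutive chunk w.p. coverage."""
    if length < chunk:
        raise ValueError(f"contig of length {length} too short for {chunk}-bp mask chunks")
    out = []
    for start in range(0, length, chunk):
        if rng.random() < coverage:
            out.append((start, min(start + chunk, length)))
    return out


def generate_genome(
    config: SyntheticConfig, seed: int | np.random.Generator | None = None
) -> tuple[Genome, dict[str, RegionSet]]:
    """Draw a genome plus mappable / blacklist / variant / driver masks.

    Bases are i.i.d. from the configured composition; CpG dinucleotides are then
    thinned so their frequency is ``cpg_depletion`` times the independence
    expectation: each G following a C is kept with that probability and
    otherwise resampled from {A, T} (which cannot create a new CpG, so a single
    pass hits the analytic target exactly in expectation).
    """
    rng = _as_rng(seed, config.seed)
    comp = np.asarray(config.base_composition, dtype=float)
    contigs: dict[str, str] = {}
    masks: dict[str, list[tuple[str, int, int]]] = {
        "mappable": [], "blacklist": [], "variants": [], "drivers": []
    }
    at = np.array([comp[0], comp[3]])
    at = at / at.sum() if at.sum() > 0 else np.array([0.5, 0.5])
    for name, length in config.contig_lengths.items():
        codes = rng.choice(4, size=length, p=comp)
        if config.cpg_depletion != 1.0:
            cg = np.nonzero((codes[:-1] == 1) & (codes[1:] == 2))[0]
            drop = cg[rng.random(len(cg)) >= config.cpg_depletion]
            codes[drop + 1] = np.where(rng.random(len(drop)) < at[0], 0, 3)
        contigs[name] = "".join(_BASES[c] for c in codes)
        masks["mappable"].extend(
            (name, s, e)
            for s, e in _random_mask(rng, length, config.mappable_coverage, 10_000)
        )
        if config.blacklist_coverage > 0:
            masks["blacklist"].extend(
                (name, s, e)
                for s, e in _random_mask(rng, length, config.blacklist_coverage, 500)
            )
        n_var = rng.binomial(length, config.variant_site_rate)
        var_pos = np.unique(rng.integers(0, length, size=n_var))
        masks["variants"].extend((name, int(p), int(p) + 1) for p in var_pos)
        if config.driver_coverage > 0:
            masks["drivers"].extend(
                (name, s, e)
                for s, e in _random_mask(rng, length, config.driver_coverage, 2_000)
            )
    genome = Genome(contigs)
    return genome, {k: RegionSet(v) for k, v in masks.items()}


def cpg_sites(genome: Genome) -> list[tuple[str, int]]:
    """All CpG sites as (contig, 1-based + strand C position)."""
    out = []
    for name, seq in genome.contigs.items():
        codes = _encode(seq)
        cs = np.nonzero((codes[:-1] == 1) & (codes[1:] == 2))[0]
        out.extend((name, int(p) + 1) for p in cs)
    return out


def generate_methylation(
    genome: Genome,
    config: SyntheticConfig,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fractional methylation per CpG from a two-component Beta mixture.

    Each CpG site draws from the high mode with probability ``meth_weight``
    (pi_m) and from the low mode otherwise; one row per site, columns CONTIG,
    POS (1-based C), FRACTION.
    """
    rng = _as_rng(seed, config.seed + 1)
    sites = cpg_sites(genome)
    if not sites:
        raise ValueError("genome contains no CpG site")
    n = len(sites)
    hi = rng.random(n) < config.meth_weight
    a_hi, b_hi = config.meth_beta_high
    a_lo, b_lo = config.meth_beta_low
    frac = np.where(hi, rng.beta(a_hi, b_hi, n), rng.beta(a_lo, b_lo, n))
    return pd.DataFrame(
        {
            "CONTIG": [c for c, _ in sites],
            "POS": [p for _, p in sites],
            "FRACTION": frac,
        }
    )


def generate_features(
    genome: Genome,
    config: SyntheticConfig,
    seed: int | np.random.Generator | None = None,
) -> RegionSet:
    """Non-overlapping feature intervals with lengths uniform in the configured
    range (CTCF-peak-like, default 200-600 bp)."""
    rng = _as_rng(seed, config.seed + 2)
    lo, hi = config.feature_length_range
    intervals: list[tuple[str, int, int]] = []
    names = list(genome.contigs)
    total_len = sum(genome.length(c) for c in names)
    if total_len < config.feature_count * hi * 2:
        raise ValueError("genome too short for the requested feature count")
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    guard = 0
    while len(intervals) < config.feature_count:
        guard += 1
        if guard > config.feature_count * 100 + 100:
            raise RuntimeError("could not place non-overlapping features")
        contig = names[rng.integers(len(names))]
        length = int(rng.integers(lo, hi + 1))
        if genome.length(contig) <= length:
            continue
        start = int(rng.integers(0, genome.length(contig) - length))
        end = start + length
        if any(s < end and start < e for s, e in occupied[contig]):
            continue
        occupied[contig].append((start, end))
        intervals.append((contig, start, end))
    return RegionSet(intervals)


def _as_rng(seed, fallback: int) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(fallback if seed is None else seed)


class EventSpace:
    """The discrete space of drawable (position, alternate) events.

    Positions with resolvable context inside the scoped region are grouped into
    strata sharing (triplet, bin, methylation state, feature membership); all
    positions of a stratum are exchangeable, so events are drawn stratum-first
    and then uniformly within the stratum.  Per-signature event masses follow

        mass(stratum, alt) ∝ N_s / N_{c,k} * r_k * f(c->a) * rho^[meth] * m^[feat]

    renormalized to 1 (N_{c,k}: positions of context c in chunk k).
    """

    def __init__(
        self,
        genome: Genome,
        scope: RegionSet | None = None,
        bins: list[GenomicBin] | None = None,
        methylation: pd.DataFrame | None = None,
        features: RegionSet | None = None,
    ):
        self.genome = genome
        contig_names = list(genome.contigs)
        pos_list, trip_list, bin_list, meth_list, feat_list, contig_idx_list = (
            [], [], [], [], [], []
        )
        meth_lookup: dict[str, set[int]] = {}
        if methylation is not None:
            for contig, sub in methylation.groupby("CONTIG"):
                meth_lookup[str(contig)] = set(
                    int(p)
                    for p, f in zip(sub["POS"], sub["FRACTION"])
                    if float(f) > 0.5
                )
        bins_by_contig: dict[str, list[GenomicBin]] = {}
        if bins is not None:
            for b in bins:
                bins_by_contig.setdefault(b.contig, []).append(b)
            for lst in bins_by_contig.values():
                lst.sort(key=lambda b: b.start)
        self._bin_ids: list[str] = ["."] if bins is None else [b.bin_id for b in bins]

        for ci, contig in enumerate(contig_names):
            seq = genome[contig]
            trip_codes, valid = _contig_context_codes(seq)
            pos = np.nonzero(valid)[0]
            if scope is not None:
                pos = pos[scope.contains_many(contig, pos)]
            if len(pos) == 0:
                continue
            tc = trip_codes[pos].astype(np.int64)

            if bins is not None:
                blist = bins_by_contig.get(contig, [])
                if not blist:
                    continue
                bstarts = np.array([b.start for b in blist])
                bends = np.array([b.end for b in blist])
                bi_local = np.searchsorted(bstarts, pos, side="right") - 1
                inside = (bi_local >= 0) & (pos < bends[np.clip(bi_local, 0, None)])
                pos, tc, bi_local = pos[inside], tc[inside], bi_local[inside]
                id_map = np.array(
                    [self._bin_ids.index(b.bin_id) for b in blist], dtype=np.int64
                )
                bi = id_map[bi_local]
            else:
                bi = np.zeros(len(pos), dtype=np.int64)

            is_cpg = np.array([TRIPLETS[t] in CPG_TRIPLETS for t in range(32)])
            if methylation is not None:
                codes = _encode(seq)
                centre_is_c = codes[pos] == 1
                c_pos1 = np.where(centre_is_c, pos + 1, pos)
                mset = meth_lookup.get(contig, set())
                mcode = np.where(
                    is_cpg[tc],
                    np.where([int(p) in mset for p in c_pos1], 1, 2),
                    0,
                )
            else:
                mcode = np.zeros(len(pos), dtype=np.int64)

            if features is not None:
                fcode = features.contains_many(contig, pos).astype(np.int64)
            else:
                fcode = np.zeros(len(pos), dtype=np.int64)

            pos_list.append(pos)
            trip_list.append(tc)
            bin_list.append(bi)
            meth_list.append(mcode)
            feat_list.append(fcode)
            contig_idx_list.append(np.full(len(pos), ci, dtype=np.int64))

        if not pos_list:
            raise ValueError("no scorable positions in scope")
        pos_all = np.concatenate(pos_list)
        trip_all = np.concatenate(trip_list)
        bin_all = np.concatenate(bin_list)
        meth_all = np.concatenate(meth_list)
        feat_all = np.concatenate(feat_list)
        ci_all = np.concatenate(contig_idx_list)

        nb = len(self._bin_ids)
        composite = (((trip_all * nb + bin_all) * 3 + meth_all) * 2 + feat_all)
        order = np.argsort(composite, kind="mergesort")
        self.positions = pos_all[order]
        self.contig_idx = ci_all[order]
        self.contig_names = contig_names
        comp_sorted = composite[order]
        uniq, starts = np.unique(comp_sorted, return_index=True)
        self.stratum_start = starts
        self.stratum_end = np.append(starts[1:], len(comp_sorted))
        self.stratum_N = self.stratum_end - self.stratum_start
        self.stratum_trip = (uniq // (nb * 6)).astype(np.int64)
        self.stratum_bin = ((uniq // 6) % nb).astype(np.int64)
        self.stratum_meth = ((uniq // 2) % 3).astype(np.int64)
        self.stratum_feat = (uniq % 2).astype(np.int64)
        # N_{c,k}: positions of each (triplet, bin)
        ck = self.stratum_trip * nb + self.stratum_bin
        self._N_ck = np.zeros(32 * nb, dtype=np.int64)
        np.add.at(self._N_ck, ck, self.stratum_N)
        self._ck = ck

    @property
    def n_positions(self) -> int:
        return int(self.stratum_N.sum())

    def event_masses(
        self,
        profile: pd.Series,
        rates: pd.Series | None = None,
        meth_fold: float = 1.0,
        feature_multiplier: float = 1.0,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Normalized per-(stratum, alt) event masses for one signature.

        Returns (row stratum index, row alt code 0..3 excluding the ref, mass).
        """
        f = profile.reindex(list(CHANNELS), fill_value=0.0).to_numpy(dtype=float)
        f_by_trip_alt = np.zeros((32, 4))
        for i, ch in enumerate(CHANNELS):
            trip = ch[0] + ch[2] + ch[6]
            alt = ch[4]
            f_by_trip_alt[TRIPLETS.index(trip), _BASES.index(alt)] = f[i]
        nb = len(self._bin_ids)
        if rates is not None:
            r = np.array([float(rates.get(b, 0.0)) for b in self._bin_ids])
        else:
            r = np.ones(nb) / 1.0 if nb == 1 else np.ones(nb)
            if nb > 1:
                raise ValueError("binned event space requires chunk rates")
        base = (
            self.stratum_N.astype(float)
            / np.maximum(self._N_ck[self._ck], 1)
            * r[self.stratum_bin]
            * np.where(self.stratum_meth == 1, meth_fold, 1.0)
            * np.where(self.stratum_feat == 1, feature_multiplier, 1.0)
        )
        rows_s, rows_a, rows_m = [], [], []
        for a in range(4):
            mass = base * f_by_trip_alt[self.stratum_trip, a]
            keep = mass > 0
            rows_s.append(np.nonzero(keep)[0])
            rows_a.append(np.full(keep.sum(), a, dtype=np.int64))
            rows_m.append(mass[keep])
        s = np.concatenate(rows_s)
        a = np.concatenate(rows_a)
        m = np.concatenate(rows_m)
        total = m.sum()
        if total <= 0:
            raise ValueError("signature has no drawable event (all masses zero)")
        return s, a, m / total

    def decode(self, stratum: np.ndarray, offset: np.ndarray, alt_code: np.ndarray):
        """Map (stratum, within-stratum offset, pyrimidine alt) to mutation rows."""
        idx = self.stratum_start[stratum] + offset
        pos0 = self.positions[idx]
        ci = self.contig_idx[idx]
        rows = []
        for p0, c, a in zip(pos0, ci, alt_code):
            contig = self.contig_names[c]
            ref = self.genome[contig][p0]
            alt = _BASES[a]
            if ref in "AG":  # pyrimidine channel is on the opposite strand
                alt = _COMP[alt]
            rows.append((contig, int(p0) + 1, ref, alt))
        return rows


def simulate_cohort(
    genome: Genome,
    profiles: pd.DataFrame,
    exposures: pd.Series | dict,
    config: SyntheticConfig,
    seed: int | np.random.Generator | None = None,
    scope: RegionSet | None = None,
    bins: list[GenomicBin] | None = None,
    rates: pd.Series | None = None,
    methylation: pd.DataFrame | None = None,
    features: RegionSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of samples with signature-driven mutations.

    Each sample draws its events without replacement, with per-event weights
    proportional to the channel mass of its generating signature (chunk rates,
    methylation fold and feature multiplier included, renormalized).  Returns
    (mutation table, truth table); the truth table records the generating
    signature of every event.
    """
    rng = _as_rng(seed, config.seed + 3)
    exposures = pd.Series(exposures, dtype=float)
    exposures = exposures / exposures.sum()
    space = EventSpace(genome, scope=scope, bins=bins,
                       methylation=methylation, features=features)

    sig_rows = {}
    for sig in exposures.index:
        s, a, m = space.event_masses(
            profiles[sig],
            rates=rates,
            meth_fold=config.meth_fold if methylation is not None else 1.0,
            feature_multiplier=config.feature_multiplier,
        )
        sig_rows[sig] = (s, a, np.cumsum(m))

    S = config.cohort_size
    n_hyper = int(round(config.hypermutator_fraction * S))
    n_dup = int(round(config.duplicate_fraction * S))
    burdens = [config.mutations_per_sample] * S
    for i in range(n_hyper):
        burdens[i] = config.hypermutator_burden

    if max(burdens) > space.n_positions * 3:
        raise ValueError(
            f"per-sample burden {max(burdens)} exceeds the "
            f"{space.n_positions * 3} available events"
        )

    mut_rows, truth_rows = [], []
    sample_events: dict[str, set] = {}
    for i in range(S):
        sample = f"S{i:04d}"
        n = burdens[i]
        per_sig = rng.multinomial(n, exposures.to_numpy())
        chosen: set[tuple[int, int, int]] = set()
        drawn: list[tuple[int, int, int, str]] = []
        for sig, k in zip(exposures.index, per_sig):
            s_idx, a_idx, cum = sig_rows[sig]
            filled = 0
            guard = 0
            while filled < k:
                guard += 1
                if guard > 10_000:
                    raise RuntimeError("cohort sampling failed to converge")
                m = max((k - filled) * 2, 16)
                r = np.searchsorted(cum, rng.random(m), side="right")
                r = np.minimum(r, len(cum) - 1)
                strat = s_idx[r]
                off = (rng.random(m) * space.stratum_N[strat]).astype(np.int64)
                for st, of, al in zip(strat, off, a_idx[r]):
                    key = (int(st), int(of), int(al))
                    if key not in chosen:
                        chosen.add(key)
                        drawn.append((int(st), int(of), int(al), sig))
                        filled += 1
                        if filled == k:
                            break
        strat = np.array([d[0] for d in drawn])
        off = np.array([d[1] for d in drawn])
        alts = np.array([d[2] for d in drawn])
        decoded = space.decode(strat, off, alts)
        sample_events[sample] = set(decoded)
        for (contig, pos1, ref, alt), (_, _, _, sig) in zip(decoded, drawn):
            mut_rows.append((contig, pos1, ref, alt, sample))
            truth_rows.append((contig, pos1, ref, alt, sample, sig))

    # duplicate samples: copy a shared fraction of an existing sample
    base_names = [f"S{i:04d}" for i in range(S)]
    for j in range(n_dup):
        src = base_names[j % S]
        sample = f"D{j:04d}"
        src_events = sorted(sample_events[src])
        k_shared = int(round(config.duplicate_shared_fraction * len(src_events)))
        pick = rng.choice(len(src_events), size=k_shared, replace=False)
        for idx in pick:
            contig, pos1, ref, alt = src_events[idx]
            mut_rows.append((contig, pos1, ref, alt, sample))
            truth_rows.append((contig, pos1, ref, alt, sample, "copied"))

    mutations = pd.DataFrame(
        mut_rows, columns=["CHROMOSOME", "POSITION", "REF", "ALT", "SAMPLE"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["CHROMOSOME", "POSITION", "REF", "ALT", "SAMPLE", "SIGNATURE"],
    )
    return mutations, truth


def write_truth_sidecar(truth: pd.DataFrame, config: SyntheticConfig, path) -> None:
    payload = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "signature_counts": truth["SIGNATURE"].value_counts().to_dict(),
        "n_events": int(len(truth)),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
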