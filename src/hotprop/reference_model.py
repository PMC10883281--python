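"""Reference sequence handling, trinucleotide accounting and the genomic bin system.

Single-base substitutions are conventionally collapsed to the strand carrying a
pyrimidine (C or T) at the mutated base, which reduces the 64 trinucleotides to
32 pyrimidine-centred ones and the 192 possible context/alternate combinations
to 96 channels.  This module owns that accounting: context lookup, the census of
scorable positions (optionally stratified by genomic bin and by CpG methylation
state), and the construction/selection/partitioning of the fixed-width bins used
to model regional mutation-rate heterogeneity.

Coordinates follow the two conventions of the input formats: mutations are
1-based (variant-table convention), regions and bins are 0-based half-open
(BED convention).  Conversion happens only at these interfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: the 32 pyrimidine-centred trinucleotides, lexicographic
TRIPLETS: tuple[str, ...] = tuple(
    five + centre + three
    for centre in "CT"
    for five in "ACGT"
    for three in "ACGT"
)

#: the 96 substitution channels in COSMIC order ("A[C>A]A", ...)
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref in "CT"
    for alt in "ACGT"
    if alt != ref
    for five in "ACGT"
    for three in "ACGT"
)

#: NpCpG triplets: the classes whose census may be methylation-split
CPG_TRIPLETS: frozenset[str] = frozenset(t for t in TRIPLETS if t[1:] == "CG")

# byte -> base code; A=0 C=1 G=2 T=3, anything else 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def parse_channel(channel: str) -> tuple[str, str]:
    """Split ``"A[C>T]G"`` into (triplet ``"ACG"``, alternate ``"T"``)."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, alt


def channel_label(triplet: str, alt: str) -> str:
    return f"{triplet[0]}[{triplet[1]}>{alt}]{triplet[2]}"


@dataclass
class Genome:
    """An in-memory reference genome: ordered map of contig name -> sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.contigs) != len(set(self.contigs)):
            raise ValueError("duplicate contig names")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        contigs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        if not contigs:
            raise ValueError(f"no sequences in {path}")
        return cls(contigs)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")


class RegionSet:
    """A set of genomic intervals (0-based half-open), stored sorted and merged.

    The canonical form keeps, per contig, two parallel arrays of starts and ends
    with no overlaps and no zero-length intervals, which makes membership tests
    and overlap arithmetic simple binary searches.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if start >= end:
                raise ValueError(f"empty interval {contig}:{start}-{end}")
            per_contig.setdefault(contig, []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for contig, ivs in per_contig.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[contig] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[contig] = np.array([m[1] for m in merged], dtype=np.int64)

    @property
    def contigs(self) -> list[str]:
        return list(self._starts)

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for contig in self._starts:
            out.extend(
                (contig, int(s), int(e))
                for s, e in zip(self._starts[contig], self._ends[contig])
            )
        return out

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def total_length(self) -> int:
        return int(
            sum(
                (self._ends[c] - self._starts[c]).sum()
                for c in self._starts
            )
        )

    def contains(self, contig: str, pos0: int) -> bool:
        return bool(self.contains_many(contig, np.asarray([pos0]))[0])

    def contains_many(self, contig: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorised membership test for 0-based positions on one contig."""
        starts = self._starts.get(contig)
        if starts is None or len(starts) == 0:
            return np.zeros(len(pos0), dtype=bool)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        safe = np.clip(idx, 0, None)
        return ok & (pos0 < self._ends[contig][safe])

    def overlap_length(self, contig: str, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by this set."""
        starts = self._starts.get(contig)
        if starts is None or len(starts) == 0:
            return 0
        ends = self._ends[contig]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0
        s = np.clip(starts[lo:hi], start, end)
        e = np.clip(ends[lo:hi], start, end)
        return int((e - s).sum())

    def intersect(self, other: "RegionSet") -> "RegionSet":
        out = []
        for contig in self._starts:
            if contig not in other._starts:
                continue
            a_s, a_e = self._starts[contig], self._ends[contig]
            b_s, b_e = other._starts[contig], other._ends[contig]
            i = j = 0
            while i < len(a_s) and j < len(b_s):
                s = max(a_s[i], b_s[j])
                e = min(a_e[i], b_e[j])
                if s < e:
                    out.append((contig, int(s), int(e)))
                if a_e[i] < b_e[j]:
                    i += 1
                else:
                    j += 1
        return RegionSet(out)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                rows.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(rows)

    def to_bed(self, path, names: Iterable[str] | None = None) -> None:
        ivs = self.intervals()
        names = list(names) if names is not None else [""] * len(ivs)
        with open(path, "w") as fh:
            for (contig, s, e), name in zip(ivs, names):
                if name:
                    fh.write(f"{contig}\t{s}\t{e}\t{name}\n")
                else:
                    fh.write(f"{contig}\t{s}\t{e}\n")


@dataclass
class GenomicBin:
    """One fixed-width chunk of a contig (0-based half-open)."""

    contig: str
    start: int
    end: int
    width: int  # the width class; end - start may be smaller for trailing bins
    mappable_fraction: float | None = None
    short: bool = False
    parent_id: str | None = None

    @property
    def bin_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


def pyrimidine_context(genome: Genome, contig: str, pos1: int) -> str | None:
    """Pyrimidine-collapsed trinucleotide centred on a 1-based position.

    Returns ``None`` when the 3-bp window leaves the contig or contains a base
    outside {A,C,G,T}; raises for an unknown contig or an out-of-bounds position.
    """
    if contig not in genome:
        raise KeyError(f"unknown contig {contig!r}")
    seq = genome[contig]
    if not 1 <= pos1 <= len(seq):
        raise IndexError(f"position {pos1} outside contig {contig!r}")
    if pos1 == 1 or pos1 == len(seq):
        return None
    trip = seq[pos1 - 2 : pos1 + 1].upper()
    if any(b not in "ACGT" for b in trip):
        return None
    if trip[1] in "AG":
        trip = reverse_complement(trip)
    return trip


@dataclass
class ContextCensus:
    """Counts of pyrimidine-collapsed trinucleotides over scored positions.

    ``counts`` is indexed by (triplet, bin, meth); ``bin`` is ``"."`` when the
    census is not stratified by bins and ``meth`` is ``"."`` for classes that are
    not methylation-split (only NpCpG triplets ever are, into ``"meth"`` /
    ``"unmeth"``).  ``skipped`` tallies positions whose context was unresolvable.
    """

    counts: pd.Series
    skipped: int = 0

    def total(self) -> int:
        return int(self.counts.sum())

    def triplet_totals(self) -> pd.Series:
        """Counts aggregated to the 32 triplets (all bins / meth states merged)."""
        totals = self.counts.groupby(level=0).sum()
        return totals.reindex(TRIPLETS, fill_value=0).astype(int)

    def get(self, triplet: str, bin_id: str = ".", meth: str = ".") -> int:
        try:
            return int(self.counts.loc[(triplet, bin_id, meth)])
        except KeyError:
            return 0


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _contig_context_codes(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position collapsed triplet code (0..31) and validity mask.

    Position i (0-based) is scored from seq[i-1:i+2]; terminal positions and
    windows containing non-ACGT bases are invalid.  The code indexes TRIPLETS.
    """
    codes = _encode(seq)
    n = len(codes)
    valid = np.zeros(n, dtype=bool)
    trip = np.zeros(n, dtype=np.int16)
    if n < 3:
        return trip, valid
    left, centre, right = codes[:-2], codes[1:-1], codes[2:]
    ok = (left != 4) & (centre != 4) & (right != 4)
    # pyrimidine collapse: A(0)/G(2) centres are reverse-complemented
    purine = (centre == 0) | (centre == 2)
    l = np.where(purine, 3 - right, left)
    c = np.where(purine, 3 - centre, centre)
    r = np.where(purine, 3 - left, right)
    # map centre C(1)->0, T(3)->1 into the TRIPLETS layout: idx = ct*16 + l*4 + r
    ct = (c == 3).astype(np.int16)
    trip[1:-1] = ct * 16 + l.astype(np.int16) * 4 + r.astype(np.int16)
    valid[1:-1] = ok
    return trip, valid


def census(
    genome: Genome,
    regions: RegionSet,
    bins: list[GenomicBin] | None = None,
    methylation: pd.DataFrame | None = None,
) -> ContextCensus:
    """Census of pyrimidine-collapsed triplets over all positions in ``regions``.

    When ``bins`` is given, counts are stratified by bin id (positions outside
    every bin are dropped).  When ``methylation`` is given (columns CONTIG, POS,
    FRACTION; POS the 1-based C of a CpG on the + strand), NpCpG positions are
    split into ``meth`` / ``unmeth`` using the >0.5 classification rule; CpG
    positions missing from the table count as unmethylated.
    """
    meth_lookup: dict[str, dict[int, bool]] = {}
    if methylation is not None:
        for contig, sub in methylation.groupby("CONTIG"):
            meth_lookup[str(contig)] = dict(
                zip(sub["POS"].astype(int), sub["FRACTION"].astype(float) > 0.5)
            )

    keys: dict[tuple[str, str, str], int] = {}
    skipped = 0
    bins_by_contig: dict[str, list[GenomicBin]] = {}
    if bins is not None:
        for b in bins:
            bins_by_contig.setdefault(b.contig, []).append(b)
        for lst in bins_by_contig.values():
            lst.sort(key=lambda b: b.start)

    for contig, seq in genome.contigs.items():
        starts = regions._starts.get(contig)
        if starts is None or len(starts) == 0:
            continue
        trip_codes, valid = _contig_context_codes(seq)
        # 0-based positions covered by the region set
        pos_chunks = [
            np.arange(s, e, dtype=np.int64)
            for s, e in zip(starts, regions._ends[contig])
        ]
        pos = np.concatenate(pos_chunks)
        pos = pos[(pos >= 0) & (pos < len(seq))]
        ok = valid[pos]
        skipped += int((~ok).sum())
        pos = pos[ok]
        tcodes = trip_codes[pos]

        if bins is not None:
            blist = bins_by_contig.get(contig, [])
            if not blist:
                continue
            bstarts = np.array([b.start for b in blist])
            bends = np.array([b.end for b in blist])
            bidx = np.searchsorted(bstarts, pos, side="right") - 1
            inside = (bidx >= 0) & (pos < bends[np.clip(bidx, 0, None)])
            pos, tcodes, bidx = pos[inside], tcodes[inside], bidx[inside]
            bin_ids = np.array([b.bin_id for b in blist])
        else:
            bidx = None
            bin_ids = None

        # meth code: 0 = unsplit, 1 = meth, 2 = unmeth
        if methylation is not None:
            contig_meth = meth_lookup.get(contig, {})
            seq_codes = _encode(seq)
            is_cpg = np.array([TRIPLETS[t] in CPG_TRIPLETS for t in range(32)])
            cpg_mask = is_cpg[tcodes]
            # 1-based C position of the CpG: the position itself if the + strand
            # base is C, else (centre G) the preceding base
            centre_is_c = seq_codes[pos] == 1
            c_pos1 = np.where(centre_is_c, pos + 1, pos)
            mcode = np.zeros(len(pos), dtype=np.int64)
            cpg_idx = np.nonzero(cpg_mask)[0]
            mcode[cpg_idx] = [
                1 if contig_meth.get(int(p), False) else 2 for p in c_pos1[cpg_idx]
            ]
        else:
            mcode = np.zeros(len(pos), dtype=np.int64)

        nb = len(bin_ids) if bidx is not None else 1
        b_arr = bidx if bidx is not None else np.zeros(len(pos), dtype=np.int64)
        composite = (tcodes.astype(np.int64) * nb + b_arr) * 3 + mcode
        uniq, cnt = np.unique(composite, return_counts=True)
        meth_names = (".", "meth", "unmeth")
        for code, c in zip(uniq, cnt):
            m = meth_names[code % 3]
            rest = code // 3
            b = bin_ids[rest % nb] if bidx is not None else "."
            trip = TRIPLETS[rest // nb]
            keys[(trip, b, m)] = keys.get((trip, b, m), 0) + int(c)

    if keys:
        idx = pd.MultiIndex.from_tuples(keys, names=["triplet", "bin", "meth"])
        counts = pd.Series(list(keys.values()), index=idx, dtype=np.int64).sort_index()
    else:
        idx = pd.MultiIndex.from_arrays([[], [], []], names=["triplet", "bin", "meth"])
        counts = pd.Series([], index=idx, dtype=np.int64)
    return ContextCensus(counts=counts, skipped=skipped)


def make_bins(genome: Genome, width: int) -> list[GenomicBin]:
    """Tile every contig with consecutive non-overlapping chunks of ``width`` bp.

    A shorter trailing chunk is emitted and flagged ``short``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    out = []
    for contig, seq in genome.contigs.items():
        for start in range(0, len(seq), width):
            end = min(start + width, len(seq))
            out.append(
                GenomicBin(contig, start, end, width, short=(end - start < width))
            )
    return out


def select_mappable_bins(
    bins: list[GenomicBin],
    mappable: RegionSet,
    contig_class: Mapping[str, str] | None = None,
) -> list[GenomicBin]:
    """Keep full-width autosomal bins whose mappable overlap exceeds the first
    quartile of the fractional-overlap distribution (linear-interpolation Q1,
    strict inequality).

    ``contig_class`` maps contig name -> class; contigs whose class is not
    ``"autosome"`` are excluded.  Without metadata all contigs are candidates.
    """
    candidates = []
    for b in bins:
        if b.short:
            continue
        if contig_class is not None and contig_class.get(b.contig) != "autosome":
            continue
        frac = mappable.overlap_length(b.contig, b.start, b.end) / len(b)
        candidates.append(replace(b, mappable_fraction=frac))
    if len(candidates) < 4:
        raise ValueError(
            f"need at least 4 candidate bins to define a quartile, got {len(candidates)}"
        )
    fracs = np.array([b.mappable_fraction for b in candidates])
    q1 = float(np.quantile(fracs, 0.25))
    kept = [b for b in candidates if b.mappable_fraction > q1]
    if not kept:
        warnings.warn(
            "no bins strictly above the first quartile of mappable overlap "
            f"(Q1 = {q1:.3f}); selection is empty",
            stacklevel=2,
        )
    return kept


def partition_bins(bins: list[GenomicBin], target_width: int) -> list[GenomicBin]:
    """Split each parent bin into consecutive chunks of ``target_width`` bp.

    The target must divide the parent width exactly; children inherit the parent
    bin id.
    """
    out = []
    for parent in bins:
        if len(parent) % target_width != 0:
            raise ValueError(
                f"target width {target_width} does not divide bin "
                f"{parent.bin_id} of length {len(parent)}"
            )
        for start in range(parent.start, parent.end, target_width):
            out.append(
                GenomicBin(
                    parent.contig,
                    start,
                    start + target_width,
                    target_width,
                    mappable_fraction=parent.mappable_fraction,
                    parent_id=parent.bin_id,
                )
            )
    return out


def write_bins_bed(bins: list[GenomicBin], path) -> None:
    """Write bins as BED4; the name column carries the parent-bin id."""
    with open(path, "w") as fh:
        for b in bins:
            fh.write(f"{b.contig}\t{b.start}\t{b.end}\t{b.parent_id or b.bin_id}\n")
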