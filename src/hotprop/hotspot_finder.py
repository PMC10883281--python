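"""Mutation filtering, cohort QC and hotspot identification.

A hotspot is a single genomic position recurrently mutated across distinct
samples: in alternate-specific mode two or more mutations with the same
alternate allele (e.g. two C>T transitions at the same base), in position mode
two or more mutations regardless of alternate.  Hotspot calling operates on
mutation tables that have passed a fixed sequence of quality filters designed to
remove artefacts (reference mismatches, ambiguous context), germline
contamination (population-variant positions), mapping problems (non-mappable and
blacklisted territory) and positively selected sites (driver regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference_model import Genome, RegionSet

MUTATION_COLUMNS = ["CHROMOSOME", "POSITION", "REF", "ALT", "SAMPLE"]

#: filter reason codes, in application order
FILTER_ORDER = [
    "unknown_contig",
    "ref_equals_alt",
    "ref_mismatch",
    "n_in_context",
    "complex_indel",
    "not_mappable",
    "blacklist_region",
    "population_variant",
    "driver_region",
]


def read_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHROMOSOME": str, "SAMPLE": str})
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns {sorted(missing)}")
    df["POSITION"] = df["POSITION"].astype(np.int64)
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def classify_mutation_type(ref: str, alt: str) -> str:
    """SNV / MNV / INS / DEL / COMPLEX classification from allele strings.

    Insertions and deletions must share the anchor base (VCF-style left
    anchoring); a mixed-length change that does not is a complex indel (e.g.
    GTG > GAAA).
    """
    for allele in (ref, alt):
        if not allele or any(b not in "ACGT" for b in allele):
            raise ValueError(f"invalid allele {allele!r}")
    if len(ref) == len(alt) == 1:
        if ref == alt:
            return "SNV"  # caller filters ref==alt; keep classification total
        return "SNV"
    if len(ref) == len(alt):
        return "MNV"
    if len(ref) < len(alt) and alt.startswith(ref):
        return "INS"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "DEL"
    return "COMPLEX"


def filter_mutations(
    mutations: pd.DataFrame,
    genome: Genome,
    mappable: RegionSet | None = None,
    blacklist: RegionSet | None = None,
    population_variants: RegionSet | None = None,
    driver_regions: RegionSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the QC filter cascade; the first failing rule is the recorded reason.

    Returns (kept, removed) where ``removed`` carries a REASON column.  ``kept``
    gains a MUT_TYPE column.
    """
    df = mutations.copy().reset_index(drop=True)
    reason = pd.Series("", index=df.index, dtype=object)

    known = df["CHROMOSOME"].isin(list(genome.contigs))
    reason[~known] = "unknown_contig"

    same = (reason == "") & (df["REF"] == df["ALT"])
    reason[same] = "ref_equals_alt"

    mut_type = df.apply(
        lambda r: classify_mutation_type(r["REF"], r["ALT"]), axis=1
    )

    for i in df.index[reason == ""]:
        contig = df.at[i, "CHROMOSOME"]
        pos1 = int(df.at[i, "POSITION"])
        ref = df.at[i, "REF"]
        seq = genome[contig]
        if not 1 <= pos1 <= len(seq):
            reason[i] = "ref_mismatch"
            continue
        genome_ref = seq[pos1 - 1 : pos1 - 1 + len(ref)]
        if mut_type[i] in ("SNV", "MNV", "DEL", "COMPLEX") and genome_ref != ref:
            reason[i] = "ref_mismatch"
            continue
        if mut_type[i] == "INS" and seq[pos1 - 1 : pos1] != ref[0]:
            reason[i] = "ref_mismatch"
            continue
        # +-2 bp context window (covers both the trinucleotide and the
        # pentanucleotide context of the start position)
        lo = max(0, pos1 - 3)
        hi = min(len(seq), pos1 + 2)
        if any(b not in "ACGT" for b in seq[lo:hi]):
            reason[i] = "n_in_context"

    cx = (reason == "") & (mut_type == "COMPLEX")
    reason[cx] = "complex_indel"

    region_filters = [
        ("not_mappable", mappable, False),  # keep only inside
        ("blacklist_region", blacklist, True),  # remove inside
        ("population_variant", population_variants, True),
        ("driver_region", driver_regions, True),
    ]
    for code, regions, remove_inside in region_filters:
        if regions is None:
            continue
        open_idx = df.index[reason == ""]
        for contig, sub in df.loc[open_idx].groupby("CHROMOSOME"):
            inside = regions.contains_many(
                contig, sub["POSITION"].to_numpy() - 1
            )
            bad = inside if remove_inside else ~inside
            reason[sub.index[bad]] = code

    kept = df[reason == ""].copy()
    kept["MUT_TYPE"] = mut_type[reason == ""]
    removed = df[reason != ""].copy()
    removed["REASON"] = reason[reason != ""]
    return kept.reset_index(drop=True), removed.reset_index(drop=True)


@dataclass
class CohortQC:
    """Per-sample counts plus duplicate / hypermutator flags and filter tallies."""

    sample_counts: pd.Series
    duplicate_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    hypermutators: list[str] = field(default_factory=list)
    filter_tallies: dict[str, int] = field(default_factory=dict)


def detect_duplicates(
    mutations: pd.DataFrame, threshold: float = 0.10
) -> list[tuple[str, str, float]]:
    """Flag sample pairs sharing a suspicious fraction of identical mutations.

    Sharing between two samples = |identical mutations| / (n1 + n2); pairs with
    sharing strictly above ``threshold`` are flagged (reported, not removed).
    """
    samples = sorted(mutations["SAMPLE"].unique())
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    keysets = {
        s: set(
            zip(sub["CHROMOSOME"], sub["POSITION"], sub["REF"], sub["ALT"])
        )
        for s, sub in mutations.groupby("SAMPLE")
    }
    flagged = []
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            shared = len(keysets[a] & keysets[b])
            denom = len(keysets[a]) + len(keysets[b])
            sharing = shared / denom if denom else 0.0
            if sharing > threshold:
                flagged.append((a, b, sharing))
    return flagged


def detect_hypermutators(
    sample_counts: pd.Series, absolute_minimum: int = 10_000
) -> list[str]:
    """Samples exceeding both an absolute burden and the Tukey upper fence.

    A sample is a hypermutator when its count is above ``absolute_minimum`` AND
    above P75 + 1.5*IQR of the cohort's per-sample counts.
    """
    if len(sample_counts) < 4:
        raise ValueError("need at least 4 samples for quartiles")
    q1, q3 = np.quantile(sample_counts.to_numpy(dtype=float), [0.25, 0.75])
    fence = q3 + 1.5 * (q3 - q1)
    return sorted(
        sample_counts.index[
            (sample_counts > absolute_minimum) & (sample_counts > fence)
        ]
    )


def find_hotspots(mutations: pd.DataFrame, mode: str = "alternate_specific") -> pd.DataFrame:
    """Identify recurrently mutated positions.

    Groups mutations by (contig, position, ref, alt) in ``alternate_specific``
    mode or (contig, position) in ``position`` mode, always separately per
    mutation type; each sample counts once per group; groups hit by >= 2 distinct
    samples become hotspots.  Output columns: CHROMOSOME, POSITION, REF, ALT,
    MUT_TYPE, N_SAMPLES, SAMPLES; deterministically sorted.
    """
    if mode not in ("alternate_specific", "position"):
        raise ValueError(f"unknown mode {mode!r}")
    df = mutations.copy()
    if "MUT_TYPE" not in df.columns:
        df["MUT_TYPE"] = [
            classify_mutation_type(r, a) for r, a in zip(df["REF"], df["ALT"])
        ]
    rows = []
    if mode == "alternate_specific":
        group_cols = ["MUT_TYPE", "CHROMOSOME", "POSITION", "REF", "ALT"]
    else:
        group_cols = ["MUT_TYPE", "CHROMOSOME", "POSITION"]
    for key, sub in df.groupby(group_cols, sort=False):
        samples = sorted(set(sub["SAMPLE"]))
        if len(samples) < 2:
            continue
        if mode == "alternate_specific":
            mtype, contig, pos, ref, alt = key
        else:
            mtype, contig, pos = key
            ref, alt = sub["REF"].iloc[0], "*"
        rows.append(
            {
                "CHROMOSOME": contig,
                "POSITION": int(pos),
                "REF": ref,
                "ALT": alt,
                "MUT_TYPE": mtype,
                "N_SAMPLES": len(samples),
                "SAMPLES": ";".join(samples),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["CHROMOSOME", "POSITION", "REF", "ALT", "MUT_TYPE", "N_SAMPLES", "SAMPLES"],
    )
    return out.sort_values(
        ["CHROMOSOME", "POSITION", "ALT", "MUT_TYPE"], kind="mergesort"
    ).reset_index(drop=True)


def cohort_qc(
    mutations: pd.DataFrame, removed: pd.DataFrame | None = None
) -> CohortQC:
    counts = mutations.groupby("SAMPLE").size().sort_index()
    tallies = (
        removed["REASON"].value_counts().to_dict() if removed is not None else {}
    )
    qc = CohortQC(sample_counts=counts, filter_tallies=tallies)
    if len(counts) >= 2:
        qc.duplicate_pairs = detect_duplicates(mutations)
    if len(counts) >= 4:
        qc.hypermutators = detect_hypermutators(counts)
    return qc
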