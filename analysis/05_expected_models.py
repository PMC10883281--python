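"""Expected-hotspot models of increasing resolution and explained fractions.

For each cohort, computes the closed-form expected hotspot count at 100
samples x 300 mutations under (i) the genome-wide trinucleotide model, (ii)
per-chunk models at 1 Mbp down to 100 Kbp using chunk rates estimated from the
cohort's own attributed mutations, and (iii) for the CpG signature a
methylation-aware model with an empirically inferred fold, then compares each
against the observed propensity medians of 04_propensity.py.  Also fits the
negative-binomial overdispersion of per-megabase mutation counts.
"""

from pathlib import Path

import pandas as pd

from hotprop import expected_model as em
from hotprop import hotspot_finder as hf
from hotprop import study
from hotprop.reference_model import (
    Genome,
    RegionSet,
    census,
    make_bins,
    partition_bins,
    select_mappable_bins,
)

SEED = 7
DATA = Path("results/data")
OUT = Path("results")
S, N = 100, 300


def main() -> None:
    genome = Genome.from_fasta(DATA / "genome.fa")
    mappable = RegionSet.from_bed(DATA / "mappable.bed")
    profiles = study.synthetic_profiles()
    bins_1mb = make_bins(genome, 1_000_000)
    kept = select_mappable_bins(bins_1mb, mappable)
    scope = RegionSet([(b.contig, b.start, b.end) for b in kept]).intersect(mappable)
    meth = pd.read_csv(DATA / "methylation.tsv", sep="\t")
    observed = pd.read_csv(OUT / "propensity.tsv", sep="\t").set_index("signature")

    rows = []
    for sig in profiles.columns:
        muts = hf.read_mutations(DATA / f"mutations_{sig}_filtered.tsv")
        obs_median = float(observed.loc[sig, "median_hotspots"])
        # overdispersion at 100 Kbp (few megabase bins exist on this genome)
        bins_100kb = partition_bins(kept, 100_000)
        counts_100kb = em.mutation_bin_counts(muts, bins_100kb)
        alpha, alpha_se = em.fit_overdispersion(counts_100kb.to_numpy())

        # genome-wide model
        cen = census(genome, scope)
        wm = em.position_weight_map(cen, profiles[sig])
        exp_gw = em.expected_hotspots(wm, S=S, n=N).total
        rows.append(dict(signature=sig, model="genomewide", expected=exp_gw,
                         observed_median=obs_median,
                         explained_pct=em.explained_fraction(obs_median, exp_gw),
                         overdispersion_100kb=alpha))

        # per-chunk models at decreasing bin size
        for width in (1_000_000, 500_000, 250_000, 100_000):
            sub_bins = kept if width == 1_000_000 else partition_bins(kept, width)
            cen_b = census(genome, scope, bins=sub_bins)
            rates = em.chunk_relative_rates(em.mutation_bin_counts(muts, sub_bins))
            wm_b = em.position_weight_map(cen_b, profiles[sig], rates=rates)
            exp_b = em.expected_hotspots(wm_b, S=S, n=N).total
            rows.append(dict(signature=sig, model=f"chunks_{width // 1000}kb",
                             expected=exp_b, observed_median=obs_median,
                             explained_pct=em.explained_fraction(obs_median, exp_b),
                             overdispersion_100kb=alpha))

        # methylation-aware model for the CpG-targeting signature
        if sig == "SIG_CPG":
            cells = em.cpg_mutation_counts(meth, muts, genome)
            rho, _ = em.infer_methylation_foldchange(
                cells["mutated_meth"], cells["unmutated_meth"],
                cells["mutated_unmeth"], cells["unmutated_unmeth"],
            )
            cen_m = census(genome, scope, methylation=meth)
            wm_m = em.position_weight_map(cen_m, profiles[sig],
                                          methylation_fold=rho)
            exp_m = em.expected_hotspots(wm_m, S=S, n=N).total
            rows.append(dict(signature=sig, model="methylation_aware",
                             expected=exp_m, observed_median=obs_median,
                             explained_pct=em.explained_fraction(obs_median, exp_m),
                             overdispersion_100kb=alpha))
            print(f"{sig}: inferred methylation fold rho = {rho:.2f}")

    table = pd.DataFrame(rows)
    table.to_csv(OUT / "expected_models.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
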