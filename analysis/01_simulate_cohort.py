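"""Generate the synthetic study: genome, masks, methylome, bins and cohorts.

Builds an 8-Mbp CpG-depleted genome with mappability masks, selects the
mappable megabase bins, draws a bimodal CpG methylome, and simulates three
single-signature cohorts (CpG-concentrated, TT-concentrated, near-uniform)
of 100 samples x 450 mutations each.  Writes the mutation tables and a study
summary under results/data/.
"""

import json
from dataclasses import replace
from pathlib import Path

import pandas as pd

from hotprop import study
from hotprop import synthetic_data as sd
from hotprop.reference_model import RegionSet, census, make_bins, select_mappable_bins

SEED = 7
GENOME_MB = 8
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = study.study_config(
        SEED, genome_mb=GENOME_MB,
        blacklist_coverage=0.01, variant_site_rate=0.0005, driver_coverage=0.01,
    )
    genome, masks = sd.generate_genome(cfg)
    bins = make_bins(genome, cfg.bin_width)
    kept = select_mappable_bins(bins, masks["mappable"])
    scope = RegionSet([(b.contig, b.start, b.end) for b in kept]).intersect(
        masks["mappable"]
    )
    meth = sd.generate_methylation(genome, cfg)
    meth.to_csv(OUT / "methylation.tsv", sep="\t", index=False)
    genome.to_fasta(OUT / "genome.fa")
    for name, rs in masks.items():
        rs.to_bed(OUT / f"{name}.bed")

    profiles = study.synthetic_profiles()
    summary = {
        "seed": SEED,
        "genome_bp": sum(cfg.contig_lengths.values()),
        "mappable_bp": masks["mappable"].total_length(),
        "bins_total": len(bins),
        "bins_kept": len(kept),
        "scope_bp": scope.total_length(),
        "n_cpg_sites": len(meth),
        "cohorts": {},
    }
    for off, sig in enumerate(profiles.columns):
        # the CpG cohort carries a true 2x methylated-CpG mutability fold;
        # the others mutate independently of methylation
        if sig == "SIG_CPG":
            cfg_sig = replace(cfg, meth_fold=2.0)
            muts, truth = sd.simulate_cohort(
                genome, profiles, {sig: 1.0}, cfg_sig, seed=SEED + 50 + off,
                scope=scope, methylation=meth,
            )
        else:
            muts, truth = sd.simulate_cohort(
                genome, profiles, {sig: 1.0}, cfg, seed=SEED + 50 + off, scope=scope
            )
        muts.to_csv(OUT / f"mutations_{sig}.tsv", sep="\t", index=False)
        sd.write_truth_sidecar(truth, cfg, OUT / f"truth_{sig}.json")
        summary["cohorts"][sig] = {
            "samples": int(muts["SAMPLE"].nunique()),
            "mutations": int(len(muts)),
        }
        print(f"{sig}: {len(muts)} mutations across "
              f"{muts['SAMPLE'].nunique()} samples")
    with open(OUT / "study_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"kept {len(kept)}/{len(bins)} megabase bins; "
          f"scope {scope.total_length():,} bp; {len(meth):,} CpG sites")


if __name__ == "__main__":
    main()
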