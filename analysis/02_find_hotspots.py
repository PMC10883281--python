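"""Filter the simulated cohorts and call alternate-specific hotspots.

Reads the mutation tables written by 01_simulate_cohort.py, applies the QC
filter cascade against the masks, runs cohort QC (duplicates, hypermutators)
and writes per-cohort hotspot tables plus a filter tally under results/.
"""

from pathlib import Path

import pandas as pd

from hotprop import hotspot_finder as hf
from hotprop import study
from hotprop.reference_model import Genome, RegionSet

SEED = 7
DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    genome = Genome.from_fasta(DATA / "genome.fa")
    masks = {name: RegionSet.from_bed(DATA / f"{name}.bed")
             for name in ("mappable", "blacklist", "variants", "drivers")}
    rows = []
    for sig in study.synthetic_profiles().columns:
        muts = hf.read_mutations(DATA / f"mutations_{sig}.tsv")
        kept, removed = hf.filter_mutations(
            muts, genome,
            mappable=masks["mappable"],
            blacklist=masks["blacklist"],
            population_variants=masks["variants"],
            driver_regions=masks["drivers"],
        )
        qc = hf.cohort_qc(kept, removed)
        hs = hf.find_hotspots(kept)
        hs.to_csv(OUT / f"hotspots_{sig}.tsv", sep="\t", index=False)
        kept.to_csv(DATA / f"mutations_{sig}_filtered.tsv", sep="\t", index=False)
        rows.append(
            dict(signature=sig, input=len(muts), kept=len(kept),
                 removed=len(removed), hotspots=len(hs),
                 duplicates=len(qc.duplicate_pairs),
                 hypermutators=len(qc.hypermutators),
                 **{f"removed_{k}": v for k, v in qc.filter_tallies.items()})
        )
        print(f"{sig}: kept {len(kept)}/{len(muts)} mutations, "
              f"{len(hs)} alternate-specific hotspots")
    pd.DataFrame(rows).to_csv(OUT / "hotspot_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
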