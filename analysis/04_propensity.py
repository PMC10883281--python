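"""Observed hotspot propensity, conversion rates and inside/outside enrichment.

Subsamples each cohort at fixed activity (100 samples x 300 mutations, 1000
iterations) to measure hotspot propensity per signature, computes the
mutations-per-hotspot conversion rate, and contrasts substitution channels of
mutations inside vs outside hotspots.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hotprop import hotspot_finder as hf
from hotprop import propensity as pr
from hotprop import study

SEED = 7
DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    rows = []
    for sig in study.synthetic_profiles().columns:
        muts = hf.read_mutations(DATA / f"mutations_{sig}_filtered.tsv")
        spec = pr.SubsampleSpec(
            n_samples=100, mutations_per_sample=300, iterations=1000, seed=SEED
        )
        res = pr.observed_propensity(muts, spec)
        # conversion-rate regression needs burden variance: thin each sample to
        # a random burden before pooling
        rng = np.random.default_rng(SEED)
        thinned = []
        for _, sub in muts.groupby("SAMPLE"):
            keep = rng.choice(len(sub), size=rng.integers(200, len(sub) + 1),
                              replace=False)
            thinned.append(sub.iloc[keep])
        conv = pr.conversion_rate(
            pd.concat(thinned, ignore_index=True), iterations=200, subset=80,
            seed=SEED, min_significant=150,
        )
        rows.append(
            dict(signature=sig, median_hotspots=res.median,
                 iqr_low=res.iqr[0], iqr_high=res.iqr[1],
                 conversion_rate=conv["rate"],
                 significant_models=conv["n_significant"])
        )
        print(f"{sig}: median {res.median:.1f} hotspots per 30,000 subsampled "
              f"mutations (IQR {res.iqr[0]:.0f}-{res.iqr[1]:.0f}); "
              f"conversion rate {conv['rate']}")

        hs = pd.read_csv(OUT / f"hotspots_{sig}.tsv", sep="\t")
        hot_keys = set(zip(hs["CHROMOSOME"], hs["POSITION"], hs["ALT"]))
        inside_mask = [
            (c, p, a) in hot_keys
            for c, p, a in zip(muts["CHROMOSOME"], muts["POSITION"], muts["ALT"])
        ]
        inside = muts[np.array(inside_mask)]
        outside = muts[~np.array(inside_mask)]
        if len(inside) and len(outside):
            enr = pr.substitution_enrichment(inside, outside, scheme=6)
            enr.to_csv(OUT / f"substitution_enrichment_{sig}.tsv", sep="\t")
    pd.DataFrame(rows).to_csv(OUT / "propensity.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
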