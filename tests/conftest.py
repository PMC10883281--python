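import numpy as np
import pandas as pd
import pytest

from hotprop import synthetic_data as sd
from hotprop.reference_model import CHANNELS, Genome, RegionSet
from hotprop.study import synthetic_profiles


@pytest.fixture(scope="session")
def profiles() -> pd.DataFrame:
    return synthetic_profiles()


@pytest.fixture(scope="session")
def small_config() -> sd.SyntheticConfig:
    return sd.SyntheticConfig(
        contig_lengths={"chr1": 300_000, "chr2": 200_000},
        cohort_size=10,
        mutations_per_sample=60,
        blacklist_coverage=0.0,
        variant_site_rate=0.0,
        driver_coverage=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config, profiles):
    """A small synthetic genome with masks and a single-signature cohort."""
    genome, masks = sd.generate_genome(small_config)
    muts, truth = sd.simulate_cohort(
        genome, profiles, {"SIG_CPG": 1.0}, small_config, scope=masks["mappable"]
    )
    return dict(genome=genome, masks=masks, mutations=muts, truth=truth,
                config=small_config)


@pytest.fixture()
def flat_profile() -> pd.Series:
    return pd.Series(1.0 / 96, index=list(CHANNELS))


@pytest.fixture()
def toy_genome() -> Genome:
    #          123456789012345678
    return Genome({"chrA": "ACGTACGTACGTACGTAC", "chrB": "TTTTTTTTTT"})


@pytest.fixture()
def whole(toy_genome) -> RegionSet:
    return RegionSet([(c, 0, toy_genome.length(c)) for c in toy_genome.contigs])
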