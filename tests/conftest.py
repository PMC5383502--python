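import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from troph import (
    BenthosSample,
    PreyTaxon,
    StomachRecord,
    Taxonomy,
    load_site_summary_fixture,
)


@pytest.fixture(scope="session")
def reisa():
    """The packaged 11-site survey summary."""
    return load_site_summary_fixture()


@pytest.fixture()
def taxonomy():
    return Taxonomy(
        [
            PreyTaxon("Baetis", "Ephemeroptera", False),
            PreyTaxon("Ephemerella", "Ephemeroptera", False),
            PreyTaxon("Capnia", "Plecoptera", False),
            PreyTaxon("Apatania", "Trichoptera", False),
            PreyTaxon("Chironomidae", "Diptera", False),
            PreyTaxon("Simuliidae", "Diptera", False),
            PreyTaxon("Lymnaea", "Mollusca", False),
            PreyTaxon("Elmis", "Coleoptera", False),
            PreyTaxon("Hydracarina", "others", False),
            PreyTaxon("terrestrial_insect", "surface", True),
            PreyTaxon("spider", "surface", True),
        ]
    )


def make_fish(fish_id, prey, species="salmon", site="S01", length=80.0):
    return StomachRecord(
        fish_id=fish_id,
        site=site,
        species=species,
        fork_length_mm=length,
        total_fullness_pct=sum(prey.values()),
        prey_points=dict(prey),
    )


@pytest.fixture()
def make_stomach():
    return make_fish


@pytest.fixture()
def kick_samples():
    """Three replicates pooling to 600 individuals over 6.75 m^2."""
    rng = np.random.default_rng(7)
    taxa = [f"t{i}" for i in range(8)]
    samples = []
    remaining = 600
    for rep in (1, 2, 3):
        n = 200
        counts = rng.multinomial(n, np.full(8, 1 / 8))
        samples.append(
            BenthosSample(
                site="S01",
                replicate=rep,
                counts=dict(zip(taxa, map(int, counts))),
                area_m2=2.25,
            )
        )
        remaining -= n
    return samples
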