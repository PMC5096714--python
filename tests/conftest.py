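import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

from proteonet.synthetic import SimulationConfig, generate_all, generate_proteomes


def small_sim_config(seed: int = 11) -> SimulationConfig:
    """Scaled-down study design for fast end-to-end tests."""
    return SimulationConfig(
        seed=seed,
        n_proteins_a=90,
        n_proteins_b=100,
        overlap_fraction=60 / 90,
        planted_folds=((10 / 60, 4.0), (12 / 60, -4.0)),
        ppi_extra_interactors=40,
        hub_spokes=15,
        clique_size=6,
        n_terms=20,
        n_planted_enriched=3,
        term_size_range=(8, 20),
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A written-to-disk small synthetic dataset plus its truth manifest."""
    outdir = tmp_path_factory.mktemp("simdata")
    truth = generate_all(small_sim_config(), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def study_scale_proteomes():
    """Proteome pair at the published study scale (735/789, 496 shared)."""
    return generate_proteomes(SimulationConfig(seed=5))
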