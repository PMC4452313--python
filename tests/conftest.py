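import pytest
from hypothesis import HealthCheck, settings

from seclocus import SimulationConfig, generate_pangenome, generate_similarity_table

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """A reduced pangenome: fast to generate, same planted structure."""
    return SimulationConfig(
        n_genomes=12,
        genes_per_genome=60,
        n_families=60,
        n_trait_families=8,
        locus_genomes=5,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_pangenome(small_config):
    return generate_pangenome(small_config)


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory, small_pangenome):
    bundle, truth = small_pangenome
    outdir = tmp_path_factory.mktemp("bundle")
    bundle.write(outdir)
    (outdir / "ground_truth.json").write_text(truth.to_json())
    return outdir


@pytest.fixture(scope="session")
def small_similarity(small_pangenome, small_config):
    _bundle, truth = small_pangenome
    return generate_similarity_table(truth, small_config)
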