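import pytest

from targetatlas import RunConfig, WorldConfig, generate_world, run_pipeline
from targetatlas.vocab import read_mrconso, read_semantic_types

#: Study conditions for the exactly-recoverable world: no trait ambiguity.
EXACT_WORLD = WorldConfig(
    seed=20260923, n_traits=200, n_concepts=150, n_compounds=40, ambiguity_rate=0.0
)

#: Same scale with the default one-to-many ambiguity planted.
AMBIGUOUS_WORLD = WorldConfig(
    seed=97, n_traits=200, n_concepts=150, n_compounds=40, ambiguity_rate=0.5
)


@pytest.fixture(scope="session")
def exact_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("exact_world")
    paths, ledger = generate_world(EXACT_WORLD, outdir)
    return outdir, ledger


@pytest.fixture(scope="session")
def ambiguous_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("ambiguous_world")
    paths, ledger = generate_world(AMBIGUOUS_WORLD, outdir)
    return outdir, ledger


@pytest.fixture(scope="session")
def exact_run(exact_bundle):
    """Full pipeline result on the unambiguous world."""
    outdir, ledger = exact_bundle
    config = RunConfig.from_yaml(outdir / "run_config.yaml")
    return run_pipeline(config), ledger


@pytest.fixture(scope="session")
def world_store(exact_bundle):
    """Concept store + semantic-type table loaded from the exact world."""
    outdir, _ledger = exact_bundle
    store = read_mrconso(outdir / "MRCONSO.RRF")
    types = read_semantic_types(outdir / "MRSTY.RRF")
    store.attach_semantic_types(types)
    return store, types


MRCONSO_3ROWS = "\n".join(
    [
        "C0000001|||||||||||MSH||D000001|Crohn Disease||||",
        "C0000001|||||||||||SNOMEDCT_US||S1|Regional Enteritis||||",
        "C0000002|||||||||||MSH||D000002|Hypertension||||",
    ]
) + "\n"


@pytest.fixture()
def tiny_mrconso(tmp_path):
    path = tmp_path / "MRCONSO.RRF"
    path.write_text(MRCONSO_3ROWS)
    return path
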