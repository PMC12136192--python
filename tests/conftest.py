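import numpy as np
import pytest

from convergene import pipeline, synthdata
from convergene.msea import EnrichmentConfig


def small_config(**overrides) -> synthdata.SyntheticConfig:
    """A miniature study: fast to generate, still exercises every stage."""
    base = dict(
        n_markers=600, n_genes=300, n_blocks=30, block_size=4,
        n_tissues=2, n_modules_per_tissue=15, module_size_range=(12, 24),
        n_planted_modules=2, network_nodes=150, edges_per_node=2,
        n_planted_hubs=1, hub_neighbors=20, hub_disease_fraction=0.8,
        rare_level_sizes={"S": 2, "1": 4, "2": 6, "3": 8},
        rare_hub_overlap=0.3, n_pathways=20, pathway_size_range=(8, 20),
        seed=11,
    )
    base.update(overrides)
    return synthdata.SyntheticConfig(**base)


@pytest.fixture(scope="session")
def mini_config():
    return small_config()


@pytest.fixture(scope="session")
def mini_bundle(tmp_path_factory, mini_config):
    out = tmp_path_factory.mktemp("bundle")
    truth = synthdata.generate_study(mini_config, out)
    return out, truth


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory, mini_bundle):
    """Full pipeline over the miniature bundle, shared across tests."""
    bundle_dir, truth = mini_bundle
    out = tmp_path_factory.mktemp("results")
    results = pipeline.run_pipeline(
        bundle_dir, out, seed=11,
        msea_config=EnrichmentConfig(n_permutations=200, seed=11))
    results["truth"] = truth
    results["bundle_dir"] = bundle_dir
    results["out_dir"] = out
    return results


@pytest.fixture
def rng():
    return np.random.default_rng(0)
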