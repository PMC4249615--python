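import networkx as nx
import numpy as np
import pytest

from hifnet import GeneratorConfig, generate_cohorts, run_pipeline
from hifnet.consensus import Subnetwork
import pandas as pd


def make_small_config(**overrides) -> GeneratorConfig:
    """Desk-scale-but-fast generator config used by unit tests."""
    params = dict(
        n_seed_anchors=20,
        members_per_anchor=3,
        n_background_genes=60,
        n_dead_genes=60,
        apl_up_size=10,
        apl_up_anchors=2,
        apl_down_size=20,
        apl_down_anchors=2,
        n_regulator_mirnas=2,
        targets_per_regulator=8,
        n_decoy_mirnas=6,
        samples_a={"M0": 8, "M1": 12, "M2": 12, "M3": 12, "M4": 12, "M5": 12},
        samples_b={"M0": 8, "M1": 12, "M2": 10, "M3": 12, "M4": 12, "M5": 10},
        seed=0,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


@pytest.fixture(scope="session")
def small_config():
    return make_small_config()


@pytest.fixture(scope="session")
def small_cohorts(small_config):
    return generate_cohorts(small_config)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default-scale synthetic cohorts (shared across tests)."""
    cfg = GeneratorConfig(seed=0)
    em_a, em_b, annotation, seeds, truth = generate_cohorts(cfg)
    result = run_pipeline(em_a, em_b, annotation, seeds, rng_seed=101)
    return cfg, annotation, seeds, truth, result


def subnetwork_from_truth(truth, annotation) -> Subnetwork:
    """Build the ideal subnetwork directly from the planted truth (no inference)."""
    graph = nx.Graph()
    directions = {g: ("up" if s > 0 else "down") for g, s in truth.subtype_shifts.items()}
    apl = truth.apl_genes
    for member, anchor in truth.member_of.items():
        if member not in apl:
            continue
        for pu in annotation.probes_of(anchor):
            for pv in annotation.probes_of(member):
                graph.add_edge(pu, pv, mi=1.0)
    for node in graph.nodes:
        gene = annotation.gene_of(node)
        graph.nodes[node].update(
            gene=gene,
            direction=directions[gene],
            dir_a=directions[gene],
            dir_b=directions[gene],
            is_seed=gene in truth.modules["seed"],
            component=0,
        )
    comps = pd.DataFrame(
        [{"component": 0, "n_probes": graph.number_of_nodes(),
          "n_genes": len({annotation.gene_of(n) for n in graph.nodes})}]
    )
    return Subnetwork(graph=graph, components=comps)


@pytest.fixture(scope="session")
def truth_subnetwork(small_cohorts):
    _, _, annotation, _, truth = small_cohorts
    return subnetwork_from_truth(truth, annotation)


def gaussian_pair(rho: float, n: int, rng: np.random.Generator):
    cov = np.array([[1.0, rho], [rho, 1.0]])
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return xy[:, 0], xy[:, 1]
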