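import numpy as np
import pandas as pd
import pytest

from netconverge import FunctionalLinkageNetwork, make_paperlike_bundle


def make_network(edges, extra_genes=()):
    return FunctionalLinkageNetwork.from_edges(edges, extra_genes=extra_genes)


@pytest.fixture
def path_abc():
    """Path graph A - B - C with unit weights."""
    return make_network([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def star():
    """Star with center S and leaves L1..L4, unit weights."""
    return make_network([("S", f"L{i}", 1.0) for i in range(1, 5)])


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic study-set (seed 17), shared across tests."""
    return make_paperlike_bundle(seed=17)


def bundle_config(bundle, paths, out_dir, **overrides):
    """PipelineConfig wiring a written bundle's files end-to-end."""
    from netconverge import PipelineConfig
    kwargs = dict(
        network=paths["network"], seeds_a=paths["seeds_a"],
        seeds_b=paths["seeds_b"], out_dir=out_dir,
        expression_studies=[
            {"label": label, "expression": str(paths[f"expr_{label}"]),
             "annotation": str(paths[f"groups_{label}"]), "control_group": "HC"}
            for label in bundle.studies],
        qpcr_cohorts=[
            {"label": name, "path": str(paths[f"qpcr_{name}"]),
             "calibrator_group": "HC", "case_group": "PD"}
            for name in bundle.qpcr],
        seed=bundle.seed,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


def random_weighted_network(rng, n_max=50, allow_isolated=True):
    """Random weighted graph for oracle comparisons; may contain isolated
    (dangling) nodes."""
    n = int(rng.integers(2, n_max + 1))
    genes = [f"n{i:03d}" for i in range(n)]
    p = float(rng.uniform(0.08, 0.5))
    net = FunctionalLinkageNetwork()
    if allow_isolated:
        for g in genes:
            net.add_gene(g)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < p
    weights = rng.uniform(0.1, 2.0, size=len(iu))
    for i, j, w in zip(iu[keep], ju[keep], weights[keep]):
        net.add_edge(genes[i], genes[j], float(w))
    if net.n_edges == 0:
        net.add_edge(genes[0], genes[1], 1.0)
    k = int(rng.integers(1, max(2, n // 3)))
    seeds = sorted(rng.choice(genes, size=k, replace=False))
    return net, seeds
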