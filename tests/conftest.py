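import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from empath import (
    FixtureSpec,
    GeneRule,
    IntegratedNetwork,
    WeightedNetwork,
    WeightingConfig,
    generate,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TOY_MODEL_TSV = """id\tequation\tlower\tupper\trule
R1\tA[c] -> B[c]\t0\t10\tg1
R2\tB[c] -> C[c]\t0\t10\tg2 or g3
R3\tD[c] -> E[c]\t-10\t10\tg4 and (g5 or g6)
R4\tC[c] -> F[c]\t0\t10\t
"""


@pytest.fixture
def toy_model_path(tmp_path):
    p = tmp_path / "model.tsv"
    p.write_text(TOY_MODEL_TSV)
    return p


@pytest.fixture
def toy_model(toy_model_path):
    from empath import read_model

    return read_model(toy_model_path, "tabular")


def make_weighted_line(weights: dict[str, float],
                       edges: list[tuple[str, str]] | None = None) -> WeightedNetwork:
    """Hand-built weighted network: reaction nodes with given w_tot."""
    import pandas as pd

    net = IntegratedNetwork()
    names = list(weights)
    for i, n in enumerate(names):
        net.add_reaction_node(n, GeneRule.leaf(f"g{i}"))
    if edges is None:
        edges = list(zip(names, names[1:]))
    for u, v in edges:
        net.add_metabolic_edge(u, v, {"m"})
    w = pd.Series(weights, dtype=float)
    zero = pd.Series(0.0, index=w.index)
    return WeightedNetwork(network=net, w_trans=w.copy(), w_flux=zero, w_tot=w.copy(),
                           config=WeightingConfig(a=0.0))


@pytest.fixture(scope="session")
def small_bundle():
    """Default-sized planted synthetic study, shared across tests."""
    return generate(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def benchmark_spec():
    """The ~200-node planted benchmark configuration."""
    def _make(seed: int, planted: bool = True) -> FixtureSpec:
        return FixtureSpec(
            seed=seed, n_reactions=170, n_metabolites=180, n_cofactors=4,
            n_proteins=30, n_ppi=120,
            planted_path_length=8 if planted else None,
        )

    return _make


def random_weighted_graph(seed: int, n_max: int = 25) -> WeightedNetwork:
    """Random connected-ish weighted network for search oracles."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, n_max + 1))
    p = 0.25
    net = IntegratedNetwork()
    names = [f"v{i}" for i in range(n)]
    for i, name in enumerate(names):
        net.add_reaction_node(name, GeneRule.leaf(f"g{i}"))
    for i in range(1, n):  # spanning tree keeps it connected
        j = int(rng.integers(i))
        net.add_metabolic_edge(names[i], names[j], {"m"})
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p and not net.graph.has_edge(names[i], names[j]):
                net.add_metabolic_edge(names[i], names[j], {"m"})
    w = pd.Series(rng.standard_normal(n), index=names)
    zero = pd.Series(0.0, index=w.index)
    return WeightedNetwork(network=net, w_trans=w.copy(), w_flux=zero, w_tot=w,
                           config=WeightingConfig(a=0.0))
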