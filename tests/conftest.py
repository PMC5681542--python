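import pathlib

import numpy as np
import pandas as pd
import pytest

import cephbn as cb

ROOT = pathlib.Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def fixture_cohort() -> cb.Cohort:
    """The frozen 143-patient synthetic study cohort shipped with the repo."""
    return cb.read_cohort(ROOT / "data" / "synthetic_cohort.csv")


@pytest.fixture(scope="session")
def rate_table(fixture_cohort) -> cb.RateTable:
    return cb.compute_differences(fixture_cohort)


def chain_net(beta: float = 2.0, sigma: float = 1.0) -> cb.FittedNetwork:
    """A -> B with B = 2 + beta*A + eps; A ~ N(0, 1)."""
    return cb.build_network(("A", "B"), [
        cb.LocalModel("A", (), 0.0, (), 1.0),
        cb.LocalModel("B", ("A",), 2.0, (beta,), sigma),
    ])


def mediator_net() -> cb.FittedNetwork:
    """Treatment -> dANB -> Growth: the prognosis depends on treatment only
    through the sagittal-imbalance mediator (a ground truth for intervention
    semantics; deliberately not constrained to the learning tiers)."""
    return cb.build_network(("Treatment", "dANB", "Growth"), [
        cb.LocalModel("Treatment", (), 0.5, (), 0.5),
        cb.LocalModel("dANB", ("Treatment",), 0.5, (-1.5,), 0.8),
        cb.LocalModel("Growth", ("dANB",), 0.2, (-0.5,), 0.4),
    ])


def simulate_linear(arcs, n, seed, beta_range=(1.0, 3.0), sigma=1.0,
                    nodes=("A", "B", "C", "D")) -> pd.DataFrame:
    """Sample a dataset from a linear-Gaussian DAG given as arc list.

    Used as a test-local generator independent of the package's simulator.
    """
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for c in nodes:
        pa = [p for p, ch in arcs if ch == c]
        x = rng.normal(0.0, sigma, n)
        for p in pa:
            x = x + rng.uniform(*beta_range) * rng.choice([-1.0, 1.0]) * data[p]
        data[c] = x
    return pd.DataFrame(data)


def random_4node_dataset(seed: int, n: int = 500) -> pd.DataFrame:
    """Random 4-node linear-Gaussian truth (each forward arc with prob 0.5)."""
    rng = np.random.default_rng(seed)
    nodes = ("A", "B", "C", "D")
    arcs = [(p, c) for i, p in enumerate(nodes) for c in nodes[i + 1:]
            if rng.random() < 0.5]
    return simulate_linear(arcs, n, seed + 1000, nodes=nodes)
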