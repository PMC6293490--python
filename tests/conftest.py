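import numpy as np
import pandas as pd
import pytest

from gasnet.candidates import CandidateSet
from gasnet.datatypes import ExpressionMatrix, PhenotypeLabels
from gasnet.simulate import (
    PlantedModule,
    SimulationConfig,
    plan_roles,
    simulate_dataset,
)


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """4 genes x 6 samples with one clean case/control split in gA."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0, 3.0],
            "s2": [2.0, 5.0, 2.0, 3.0],
            "s3": [1.5, 5.0, 2.0, 3.0],
            "s4": [8.0, 5.0, 2.0, 3.0],
            "s5": [9.0, 5.0, 2.0, 3.0],
            "s6": [8.5, 5.0, 2.0, 3.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def tiny_labels() -> PhenotypeLabels:
    return PhenotypeLabels(
        pd.Series(
            ["ctl", "ctl", "ctl", "tum", "tum", "tum"],
            index=["s1", "s2", "s3", "s4", "s5", "s6"],
        ),
        comparison=("ctl", "tum"),
    )


@pytest.fixture(scope="session")
def bench_dataset():
    """The standard synthetic benchmark (default configuration)."""
    return simulate_dataset(SimulationConfig(rng_seed=42))


@pytest.fixture(scope="session")
def bench_module(bench_dataset):
    roles = plan_roles(bench_dataset.config)
    return roles.modules[0]


def make_mini_instance(rep: int, max_candidates: int = 15):
    """A planted-module instance small enough to enumerate exhaustively."""
    from gasnet.benchmarks import make_enumerable_instance

    return make_enumerable_instance(3000 + rep, max_candidates)


def bh_oracle(p_values: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg: sort, scale by m/rank, then take the
    running minimum from the largest p downward."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def mi_oracle(joint_counts: np.ndarray) -> float:
    """Direct plug-in MI (bits) from a joint contingency table."""
    total = joint_counts.sum()
    mi = 0.0
    row = joint_counts.sum(axis=1)
    col = joint_counts.sum(axis=0)
    for i in range(joint_counts.shape[0]):
        for j in range(joint_counts.shape[1]):
            nij = joint_counts[i, j]
            if nij > 0:
                pij = nij / total
                mi += pij * np.log2(pij * total * total / (row[i] * col[j]))
    return mi


def precision_recall(members, truth_members):
    members, truth_members = set(members), set(truth_members)
    tp = len(members & truth_members)
    return tp / len(members), tp / len(truth_members)
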