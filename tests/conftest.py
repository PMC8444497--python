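import numpy as np
import pandas as pd
import pytest

from veinlaw import (
    SyntheticTruth,
    make_variant,
    simulate_dataset,
    solve_table,
)


def make_measurements(rows):
    """Canonical-schema frame from (d0, d1, d2) triples."""
    n = len(rows)
    frame = pd.DataFrame(rows, columns=["d0", "d1", "d2"])
    frame.insert(0, "specimen_id", [f"S{i:03d}" for i in range(n)])
    frame.insert(1, "taxon_superfamily", "Tineoidea")
    frame.insert(2, "taxon_family", None)
    frame.insert(3, "order_label", "Lepidoptera")
    frame.insert(4, "wing_length", 10.0)
    frame.insert(5, "fork_index", 1)
    frame["angle_children"] = 12.0
    frame["angle_parent_child1"] = 8.0
    frame["angle_parent_child2"] = 14.0
    return frame


@pytest.fixture
def ten_row_table():
    """Hand-built solved table covering every geometric case."""
    murray = 2.0 ** (-1.0 / 3.0) * 100.0
    triples = [
        (100.0, murray, murray),   # standard, k = 3
        (100.0, 80.0, 80.0),       # standard
        (100.0, 90.0, 50.0),       # standard
        (100.0, 110.0, 110.0),     # both_wider
        (100.0, 120.0, 105.0),     # both_wider
        (100.0, 105.0, 99.9),      # mixed (extreme argmin)
        (100.0, 110.0, 60.0),      # mixed
        (100.0, 100.0000001, 99.99999999),  # mixed, |k*| ~ 2e9 -> uncomputable
        (100.0, 100.0, 50.0),      # degenerate
        (100.0, 70.0, 70.0),       # standard
    ]
    return solve_table(make_measurements(triples))


@pytest.fixture(scope="session")
def benchmark_truth():
    """The synthetic study conditions: n=2000 forks, threshold at 50 um."""
    return SyntheticTruth(n_bifurcations=2000, seed=1)


@pytest.fixture(scope="session")
def benchmark_v1(benchmark_truth):
    """Solved V1 table of the benchmark dataset (shared across tests)."""
    records, _ = simulate_dataset(benchmark_truth)
    return make_variant(solve_table(records), "V1")
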