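"""Shared fixtures: tiny pedigrees and a small synthetic dataset."""

import warnings

import numpy as np
import pytest

from pinegs import Pedigree, SimulationConfig, simulate_dataset, sort_pedigree
from pinegs.simulate import SeriesConfig


@pytest.fixture
def trio_ped():
    return sort_pedigree(Pedigree([("P", "S", "D"), ("S", "0", "0"), ("D", "0", "0")]))


@pytest.fixture
def fullsib_ped():
    """Two founders, two full sibs, one progeny of the sibs (F = 0.25)."""
    return sort_pedigree(
        Pedigree(
            [
                ("S", "0", "0"),
                ("D", "0", "0"),
                ("C1", "S", "D"),
                ("C2", "S", "D"),
                ("X", "C1", "C2"),
            ]
        )
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One small clean dataset shared by read-only tests (two series, two/three sites)."""
    cfg = SimulationConfig(
        series=(
            SeriesConfig("S1", 16, 60, "single_pair", ("A", "B")),
            SeriesConfig("S2", 12, 60, "factorial", ("B", "C")),
        ),
        n_unrelated=20,
        n_markers=400,
        pedigree_error_rate=0.0,
        genotype_error_rate=0.0,
        missing_rate=0.0,
        seed=91,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(cfg)


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """Random acyclic pedigree of <= n individuals (founders plus offspring)."""
    n_founders = max(2, int(rng.integers(2, max(3, n // 2))))
    records = [(f"I{k}", "0", "0") for k in range(n_founders)]
    for k in range(n_founders, n):
        mode = rng.random()
        if mode < 0.15:  # founder
            records.append((f"I{k}", "0", "0"))
            continue
        parents = rng.integers(0, k, size=2)
        if mode < 0.30:  # one parent known
            records.append((f"I{k}", f"I{parents[0]}", "0"))
        else:
            records.append((f"I{k}", f"I{parents[0]}", f"I{parents[1]}"))
    return sort_pedigree(Pedigree(records))


def kinship_oracle(ped: Pedigree):
    """Independent recursive coancestry oracle: f(i,j) with memoisation.

    Uses the classical recursion on the (sorted) pedigree: f(i,i) =
    0.5 (1 + f(s,d)); for j before i, f(i,j) = 0.5 (f(s,j) + f(d,j));
    unknown parents contribute 0. Returns the matrix 2f (additive
    relationship) as a plain dict of dicts.
    """
    order = {ind: k for k, ind in enumerate(ped.ids)}
    parents = ped.parents
    cache: dict[tuple[str, str], float] = {}

    def f(i, j):
        if i == "0" or j == "0":
            return 0.0
        if order[i] < order[j]:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        s, d = parents[i]
        if i == j:
            val = 0.5 * (1.0 + f(s, d))
        else:
            val = 0.5 * (f(s, j) + f(d, j))
        cache[key] = val
        return val

    ids = ped.ids
    return {i: {j: 2.0 * f(i, j) for j in ids} for i in ids}
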