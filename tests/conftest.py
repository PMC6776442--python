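"""Shared fixtures: small designed barcode sets and synthetic screens.

Everything is generated programmatically; no data files are shipped.
"""

import numpy as np
import pytest

from pesca.barcodes import assign_barcodes, design_barcodes
from pesca.simulate import ScreenTruth, simulate_screen


@pytest.fixture(scope="session")
def small_bset():
    """60 distance-3 10-mers for matching tests."""
    return design_barcodes(length=10, min_dist=3, n_required=60, seed=11)


@pytest.fixture(scope="session")
def full_bset():
    """A full 861-barcode library (287 GREs x 3)."""
    return design_barcodes(length=10, min_dist=3, n_required=861, seed=1)


@pytest.fixture(scope="session")
def full_gre_map(full_bset):
    truth = ScreenTruth()
    return assign_barcodes(truth.gre_ids(), full_bset, per_gre=3, seed=1)


@pytest.fixture(scope="session")
def small_screen():
    """600-cell screen over 20 GREs with one 8-fold target-enriched hit."""
    truth = ScreenTruth(
        n_gres=20,
        true_fold={"GRE003": 8.0},
        seed=5,
    )
    return simulate_screen(truth, 600, seed=5)


def brute_force_edit_distance(a: str, b: str) -> int:
    """Exponential-recursion edit distance with memoization (test oracle)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(d(i - 1, j) + 1, d(i, j - 1) + 1, d(i - 1, j - 1) + cost)

    return d(len(a), len(b))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
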