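"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import phasikit as pk

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


# ---------------------------------------------------------------------------
# oracles (independent of the implementation paths they check)

def enum_max_pairs(seq: str, lo: int = 0, hi: int | None = None, min_loop: int = 3) -> int:
    """Maximum base pairs by exhaustive enumeration of non-crossing structures.

    Recursion on the first position: leave it unpaired, or pair it with
    every admissible partner and recurse on the two resulting segments.
    Exponential; intended for sequences of length <= 12.
    """
    if hi is None:
        hi = len(seq)
    if hi - lo < min_loop + 2:
        return 0
    best = enum_max_pairs(seq, lo + 1, hi, min_loop)
    for j in range(lo + min_loop + 1, hi):
        if (seq[lo], seq[j]) in _PAIRS:
            best = max(
                best,
                1 + enum_max_pairs(seq, lo + 1, j, min_loop) + enum_max_pairs(seq, j + 1, hi, min_loop),
            )
    return best


def hypergeom_tail_enum(N: int, m: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating every n-subset of N positions (m marked)."""
    total = 0
    hits = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in subset if x < m) >= k:
            hits += 1
    return hits / total if total else 1.0


def hypergeom_occupancy_table(N: int, m: int) -> np.ndarray:
    """T[n, j] = number of subsets of {0..N-1} with size n and j marked.

    Enumerates all 2^N subsets with vectorized popcounts; the marked set is
    {0..m-1}. An exhaustive-occupancy oracle usable up to N = 20.
    """
    x = np.arange(1 << N, dtype=np.uint32)
    nbits = np.bitwise_count(x).astype(np.int64)
    j = np.bitwise_count(x & np.uint32((1 << m) - 1)).astype(np.int64)
    T = np.bincount(nbits * (m + 1) + j, minlength=(N + 1) * (m + 1))
    return T.reshape(N + 1, m + 1)


# ---------------------------------------------------------------------------
# fixtures: one default simulated study shared across test modules

@pytest.fixture(scope="session")
def default_dataset() -> pk.SimulatedDataset:
    return pk.simulate_dataset(pk.SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_alignments(default_dataset):
    return pk.align_dataset(default_dataset)


@pytest.fixture(scope="session")
def peak_alignments(default_alignments):
    return default_alignments["MDS_V"]


@pytest.fixture(scope="session")
def default_loci(default_dataset, peak_alignments):
    params = pk.PhasingParams()
    windows = pk.scan_phas(peak_alignments, default_dataset.genome, params)
    return pk.merge_windows_to_loci(windows, peak_alignments, params)


def overlaps(locus, truth) -> bool:
    return locus.start < truth.end and locus.end > truth.start
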