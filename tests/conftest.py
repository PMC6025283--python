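"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by exhaustive enumeration
(all simple paths, all spanning trees, per-record rescans) so the tests
check the implementation against definitions, not against itself.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np
import pytest

from meshnet.synthetic import default_spec, generate, hub_fixture_spec


# ---------------------------------------------------------------------------
# Corpora

@pytest.fixture(scope="session")
def planted():
    """Noise-free two-cluster synthetic corpus with its ground truth."""
    return generate(default_spec(seed=11))


@pytest.fixture(scope="session")
def hub_planted():
    """Fixture corpus whose query term indexes every final-period record."""
    return generate(hub_fixture_spec(seed=11))


# ---------------------------------------------------------------------------
# Worked-example inputs (annual counts of a published case study)

@pytest.fixture(scope="session")
def worked_annual_counts():
    from meshnet.worked_example import ANNUAL_COUNTS

    return dict(ANNUAL_COUNTS)


# ---------------------------------------------------------------------------
# Brute-force oracles for Pathfinder pruning


def minimax_brute(d: np.ndarray) -> np.ndarray:
    """All-pairs minimax distances by enumerating every simple path."""
    n = d.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            others = [k for k in range(n) if k not in (i, j)]
            best = np.inf
            for r in range(len(others) + 1):
                for mid in itertools.permutations(others, r):
                    path = (i, *mid, j)
                    cost = max(d[a, b] for a, b in zip(path, path[1:]))
                    best = min(best, cost)
            dist[i, j] = best
    return dist


def pathfinder_brute(d: np.ndarray) -> set[tuple[int, int]]:
    """Edges surviving the minimax criterion, straight from the definition."""
    dist = minimax_brute(d)
    n = d.shape[0]
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.isfinite(d[i, j]) and d[i, j] <= dist[i, j] + 1e-9
    }


def _is_spanning_tree(n: int, edges: tuple[tuple[int, int], ...]) -> bool:
    if len(edges) != n - 1:
        return False
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra == rb:
            return False
        parent[ra] = rb
    return True


def mst_union_brute(d: np.ndarray) -> set[tuple[int, int]]:
    """Union of ALL minimum spanning trees, by enumerating every spanning
    tree of the finite-edge graph.  Connected inputs only."""
    n = d.shape[0]
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if np.isfinite(d[i, j])
    ]
    best_weight = np.inf
    union: set[tuple[int, int]] = set()
    for subset in itertools.combinations(edges, n - 1):
        if not _is_spanning_tree(n, subset):
            continue
        weight = sum(d[a, b] for a, b in subset)
        if weight < best_weight - 1e-9:
            best_weight = weight
            union = set(subset)
        elif abs(weight - best_weight) <= 1e-9:
            union |= set(subset)
    return union


# ---------------------------------------------------------------------------
# Independent per-record recounts


def recount_by_period(corpus, periods) -> dict[str, list[int]]:
    """Document-frequency recount, independently of TermCountTable."""
    out: dict[str, list[int]] = defaultdict(lambda: [0] * len(periods))
    for record in corpus:
        for idx, period in enumerate(periods):
            if period.start_year <= record.year <= period.end_year:
                for descriptor in {h.descriptor for h in record.headings}:
                    out[descriptor][idx] += 1
    return dict(out)


def pair_cooccurrence_brute(corpus, terms) -> dict[tuple[str, str], int]:
    """Per-publication pair enumeration of term co-occurrence."""
    counts: dict[tuple[str, str], int] = defaultdict(int)
    term_set = set(terms)
    for record in corpus:
        present = sorted(record.descriptors & term_set)
        for a, b in itertools.combinations(present, 2):
            counts[(a, b)] += 1
    return dict(counts)
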