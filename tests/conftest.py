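"""Shared fixtures and random-graph generators for the test suite."""

from __future__ import annotations

import random

import pytest

from ersfviz import (
    OntologyGraph,
    compute_layout,
    extract_spanning_tree,
    make_g1,
    make_g2,
)


@pytest.fixture
def g1():
    return make_g1()


@pytest.fixture
def g2():
    return make_g2()


@pytest.fixture
def g1_tree(g1):
    return extract_spanning_tree(g1)


@pytest.fixture
def g2_tree(g2):
    return extract_spanning_tree(g2)


@pytest.fixture
def g2_layout(g2_tree):
    return compute_layout(g2_tree)


def random_tree_edges(n_nodes: int, rng: random.Random) -> list[tuple[str, str]]:
    """Random rooted tree: node i's parent is uniform among nodes < i."""
    edges = []
    for i in range(1, n_nodes):
        parent = rng.randrange(i)
        edges.append((f"n{parent}", f"n{i}"))
    return edges


def random_dag(n_nodes: int, n_extra: int, rng: random.Random) -> OntologyGraph:
    """Random single-root DAG: a random tree plus extra forward edges.

    Extra edges run from a lower-numbered to a higher-numbered node (so the
    graph stays acyclic) and avoid duplicating existing edges; the achieved
    number of extra edges may be below ``n_extra`` on small graphs.
    """
    edges = random_tree_edges(n_nodes, rng)
    present = set(edges)
    attempts = 0
    added = 0
    while added < n_extra and attempts < 50 * n_extra:
        attempts += 1
        a, b = rng.randrange(n_nodes - 1), rng.randrange(1, n_nodes)
        if a >= b:
            continue
        edge = (f"n{a}", f"n{b}")
        if edge in present:
            continue
        present.add(edge)
        edges.append(edge)
        added += 1
    return OntologyGraph(edges=edges)


def brute_force_multi_parent_count(g: OntologyGraph) -> int:
    """Oracle: count nodes with at least two distinct parents."""
    return sum(1 for n in g.nodes if len(set(g.parents_of(n))) >= 2)
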