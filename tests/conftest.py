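"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: the motif
oracle re-interprets the consensus grammar with its own parser and a naive
per-window check; the contact oracle is a pure-Python all-pairs distance scan.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pytest

from sh3prm import GeneratorConfig, default_registry
from sh3prm.contacts import ComplexStructure

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def generator_config():
    return GeneratorConfig(seed=20240120)


# ---------------------------------------------------------------------------
# naive motif oracle (independent grammar interpretation)
# ---------------------------------------------------------------------------

def oracle_parse(spec: str) -> list[set[str]]:
    """Independent parse of a normalized consensus spec (letters, X, [..])."""
    out: list[set[str]] = []
    i = 0
    while i < len(spec):
        if spec[i] == "[":
            j = spec.index("]", i)
            out.append(set(spec[i + 1 : j]))
            i = j + 1
        elif spec[i] == "X":
            out.append(set(STANDARD_AA))
            i += 1
        else:
            out.append({spec[i]})
            i += 1
    return out


def oracle_scan(seq: str, spec: str) -> list[tuple[int, int]]:
    """All (start, end) 1-based matches of spec in seq, by naive windowing."""
    elements = oracle_parse(spec)
    L = len(elements)
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if all(c in allowed for c, allowed in zip(window, elements)):
            hits.append((i + 1, i + L))
    return hits


# ---------------------------------------------------------------------------
# brute-force contact oracle
# ---------------------------------------------------------------------------

def oracle_contacts(struct: ComplexStructure, cutoff: float, heavy_only: bool = True):
    """All-pairs pure-Python contact extraction: residue numbers within cutoff."""
    dom = struct.chains[struct.domain_chain]
    pep = struct.chains[struct.peptide_chain]
    pep_atoms = [
        a.coord for r in pep for a in r.atoms
        if not (heavy_only and a.element in ("H", "D"))
    ]
    out = []
    for res in dom:
        best = math.inf
        for a in res.atoms:
            if heavy_only and a.element in ("H", "D"):
                continue
            for b in pep_atoms:
                best = min(best, math.dist(a.coord, b))
        if best <= cutoff:
            out.append((res.number, best))
    return out


# ---------------------------------------------------------------------------
# random additive trees (oracle for neighbor joining)
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves: int, rng: random.Random):
    """A random unrooted binary tree with positive branch lengths.

    Returns (edges, leaves): edges as {(u, v): length} over integer node ids,
    leaf ids 0..n_leaves-1 carrying names "L0".."L{n-1}".
    """
    nodes = list(range(n_leaves))
    edges: dict[tuple[int, int], float] = {}
    next_id = n_leaves

    def link(u, v):
        edges[(u, v)] = rng.uniform(0.5, 3.0)

    active = nodes[:]
    while len(active) > 3:
        a, b = rng.sample(active, 2)
        parent = next_id
        next_id += 1
        link(parent, a)
        link(parent, b)
        active = [x for x in active if x not in (a, b)] + [parent]
    hub = next_id
    for x in active:
        link(hub, x)
    return edges, [f"L{i}" for i in range(n_leaves)]


def tree_metric(edges: dict[tuple[int, int], float], n_leaves: int) -> np.ndarray:
    """Leaf-to-leaf path lengths computed by BFS over the edge dict."""
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    n = len(adj)
    dm = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            dm[src, dst] = dist[dst]
    return (dm + dm.T) / 2.0  # exact up to float addition order
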