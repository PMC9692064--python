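"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive every statistic from first
principles (explicit dominance walks, pairwise span interleaving, direct
child counts) without touching the package's internals, so they can arbitrate
the fast implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from icmdlm import DepTree, tree_from_heads


# ---------------------------------------------------------------------------
# schematic six-word structures: one dependency spanning four interveners,
# with the intervening material either all terminal (a) or a chain of heads (b)
# ---------------------------------------------------------------------------

@pytest.fixture
def schematic_flat() -> DepTree:
    """Head at 1, dependent at 6; positions 2..5 are leaf dependents of 1."""
    return tree_from_heads([0, 1, 1, 1, 1, 1], sentence_id="flat")


@pytest.fixture
def schematic_chain() -> DepTree:
    """Head at 1, dependent at 6; positions 2..5 form the chain 2<-3<-4<-5,
    with 5 attached to 6."""
    return tree_from_heads([0, 3, 4, 5, 6, 1], sentence_id="chain")


@pytest.fixture
def four_word_crossing() -> DepTree:
    """heads: h(2)=4, h(3)=1, h(4)=1, root 1 — edge 4->2 crosses."""
    return tree_from_heads([0, 4, 1, 1], sentence_id="crossing4")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_dominated(heads, h: int, i: int) -> bool:
    """True iff h (reflexively, transitively) dominates i, by ancestor walk."""
    j = i
    while j != 0:
        if j == h:
            return True
        j = heads[j - 1]
    return False


def oracle_edge_ic(heads, h: int, d: int) -> int:
    """Count interveners with >= 1 dependent, by scanning all child relations."""
    lo, hi = min(h, d), max(h, d)
    count = 0
    for i in range(lo + 1, hi):
        if any(hd == i for hd in heads):
            count += 1
    return count


def oracle_nonprojective_edges(heads) -> int:
    count = 0
    for d, h in enumerate(heads, start=1):
        if h == 0:
            continue
        lo, hi = min(h, d), max(h, d)
        if any(not oracle_dominated(heads, h, i) for i in range(lo + 1, hi)):
            count += 1
    return count


def oracle_crossing_pairs(heads) -> int:
    # the artificial root attachment (position 0 -> root word) is an edge here
    edges = [(min(h, d), max(h, d)) for d, h in enumerate(heads, start=1)]
    count = 0
    for a in range(len(edges)):
        for b in range(a + 1, len(edges)):
            (la, ra), (lb, rb) = edges[a], edges[b]
            if la < lb < ra < rb or lb < la < rb < ra:
                count += 1
    return count


def random_heads(n: int, rng: np.random.Generator) -> list[int]:
    """A uniform rooted labeled tree as a head vector, built independently of
    the package's sampler (random parent among already-placed nodes after a
    random relabeling — not uniform over trees, but valid and varied)."""
    labels = [int(x) + 1 for x in rng.permutation(n)]
    heads = [0] * n
    for k in range(1, n):
        parent = labels[int(rng.integers(0, k))]
        heads[labels[k] - 1] = parent
    return heads


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
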