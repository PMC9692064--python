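"""Per-dependency and per-sentence complexity measures.

Two measures sit at the centre of the package:

* **Dependency length (DL)** of an edge head->dependent: the number of words
  linearly intervening between the two (adjacent words have DL 0).
* **Intervener complexity (IC)** of an edge: the number of intervening words
  that are themselves syntactic heads, i.e. have at least one dependent
  anywhere in the sentence.  Intervening terminal dependents (leaves) do not
  count, so IC <= DL always.

Head status is a global leaf/non-leaf distinction: a word with a dependent
outside the edge's span still counts as an intervening head.

Crossing dependencies come in two formalizations, both provided: the
edge-level count (an edge h->d is non-projective iff some word between h and
d is not dominated by h) and the pairwise count of edges whose spans
interleave strictly.  The edge-level count is the default used for baseline
matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .treebank_io import DepTree

CROSSING_METHODS = ("nonprojective_edges", "crossing_pairs")


@dataclass(frozen=True)
class EdgeMetrics:
    head_pos: int
    dep_pos: int
    dl: int
    ic: int
    nonprojective: bool


@dataclass(frozen=True)
class SentenceMetrics:
    sentence_id: str
    language: str
    n_words: int
    mean_dl: float
    mean_ic: float
    crossing_count: int
    max_arity: int
    mean_arity: float
    depth: int


# ---------------------------------------------------------------------------
# fast head-vector kernels (used in the rejection-sampling hot loop)
# ---------------------------------------------------------------------------

def _arities(heads: Sequence[int]) -> list[int]:
    n = len(heads)
    ar = [0] * (n + 1)
    for h in heads:
        ar[h] += 1
    return ar[1:]  # arity of word i at index i-1 (root's arity dropped)


def _ancestor_sets(heads: Sequence[int]) -> list[set[int]]:
    """For each word (1-based), the set {word} ∪ its ancestors (excluding 0)."""
    n = len(heads)
    anc: list[set[int]] = [set() for _ in range(n + 1)]
    for i in range(1, n + 1):
        j = i
        chain = set()
        while j != 0:
            chain.add(j)
            j = heads[j - 1]
        anc[i] = chain
    return anc


def _edge_ic(heads: Sequence[int], arity: Sequence[int], h: int, d: int) -> int:
    lo, hi = (h, d) if h < d else (d, h)
    return sum(1 for i in range(lo + 1, hi) if arity[i - 1] > 0)


def _nonprojective(anc: list[set[int]], h: int, d: int) -> bool:
    lo, hi = (h, d) if h < d else (d, h)
    for i in range(lo + 1, hi):
        if h not in anc[i]:
            return True
    return False


def crossing_count_heads(heads: Sequence[int]) -> int:
    """Edge-level crossing count straight from a head vector (0 = root)."""
    anc = _ancestor_sets(heads)
    count = 0
    for d in range(1, len(heads) + 1):
        h = heads[d - 1]
        if h == 0:
            continue
        if _nonprojective(anc, h, d):
            count += 1
    return count


def dl_multiset_heads(heads: Sequence[int]) -> tuple[int, ...]:
    """Sorted per-edge DL values of a head vector."""
    return tuple(
        sorted(
            abs(h - d) - 1
            for d, h in enumerate(heads, start=1)
            if h != 0
        )
    )


def ic_multiset_heads(heads: Sequence[int]) -> tuple[int, ...]:
    """Sorted per-edge IC values of a head vector."""
    arity = _arities(heads)
    return tuple(
        sorted(
            _edge_ic(heads, arity, h, d)
            for d, h in enumerate(heads, start=1)
            if h != 0
        )
    )


# ---------------------------------------------------------------------------
# public per-tree operations
# ---------------------------------------------------------------------------

def _check_edge(tree: DepTree, head_pos: int, dep_pos: int) -> None:
    n = tree.n_words
    if not (1 <= dep_pos <= n) or tree.heads[dep_pos - 1] != head_pos:
        raise ValueError(f"edge {head_pos}->{dep_pos} not in tree {tree.sentence_id!r}")


def edge_dl(tree: DepTree, head_pos: int, dep_pos: int, positional: bool = False) -> int:
    """Dependency length: count of words strictly between head and dependent.

    ``positional=True`` returns the position difference |h - d| instead
    (the other convention in the minimization literature, larger by one);
    every analysis in this package uses the intervening-word count.
    """
    _check_edge(tree, head_pos, dep_pos)
    gap = abs(head_pos - dep_pos)
    return gap if positional else gap - 1


def edge_ic(tree: DepTree, head_pos: int, dep_pos: int) -> int:
    """Intervener complexity: intervening words that have >= 1 dependent."""
    _check_edge(tree, head_pos, dep_pos)
    return _edge_ic(tree.heads, _arities(tree.heads), head_pos, dep_pos)


def node_arity(tree: DepTree, pos: int) -> int:
    """Number of dependents of the word at ``pos``."""
    if not (1 <= pos <= tree.n_words):
        raise ValueError(f"position {pos} not in tree")
    return sum(1 for h in tree.heads if h == pos)


def nonprojective_edge(tree: DepTree, head_pos: int, dep_pos: int) -> bool:
    """True iff some intervening word is not (transitively) dominated by the head."""
    _check_edge(tree, head_pos, dep_pos)
    return _nonprojective(_ancestor_sets(tree.heads), head_pos, dep_pos)


def crossing_count(tree: DepTree, method: str = "nonprojective_edges") -> int:
    """Count crossing dependencies.

    ``nonprojective_edges`` (default) counts edges violating projectivity;
    ``crossing_pairs`` counts unordered edge pairs with strictly interleaving
    spans, where the artificial root attachment participates as an edge from
    position 0 (so an edge covering the root word is crossed, matching the
    dominance view).  Both are zero exactly on projective trees.
    """
    if method == "nonprojective_edges":
        return crossing_count_heads(tree.heads)
    if method == "crossing_pairs":
        edges = [
            (min(h, d), max(h, d))
            for d, h in enumerate(tree.heads, start=1)
        ]
        count = 0
        for a in range(len(edges)):
            la, ra = edges[a]
            for b in range(a + 1, len(edges)):
                lb, rb = edges[b]
                if la < lb < ra < rb or lb < la < rb < ra:
                    count += 1
        return count
    raise ValueError(f"unknown crossing method {method!r}; use one of {CROSSING_METHODS}")


def tree_depth(tree: DepTree) -> int:
    """Longest root-to-leaf path in words (the root word has depth 1)."""
    heads = tree.heads
    depth = 0
    for i in range(1, tree.n_words + 1):
        d = 0
        j = i
        while j != 0:
            d += 1
            j = heads[j - 1]
        depth = max(depth, d)
    return depth


def edge_metrics(tree: DepTree) -> list[EdgeMetrics]:
    """Metrics for every word-word dependency (the root attachment is excluded)."""
    heads = tree.heads
    arity = _arities(heads)
    anc = _ancestor_sets(heads)
    out = []
    for d, h in enumerate(heads, start=1):
        if h == 0:
            continue
        out.append(
            EdgeMetrics(
                head_pos=h,
                dep_pos=d,
                dl=abs(h - d) - 1,
                ic=_edge_ic(heads, arity, h, d),
                nonprojective=_nonprojective(anc, h, d),
            )
        )
    return out


def sentence_summary(tree: DepTree) -> SentenceMetrics:
    """Per-sentence aggregates: mean DL/IC over the n-1 word-word edges, etc."""
    if tree.n_words < 2:
        raise ValueError(f"tree {tree.sentence_id!r} has no dependencies")
    edges = edge_metrics(tree)
    arity = _arities(tree.heads)
    n_edges = len(edges)
    return SentenceMetrics(
        sentence_id=tree.sentence_id,
        language=tree.language,
        n_words=tree.n_words,
        mean_dl=sum(e.dl for e in edges) / n_edges,
        mean_ic=sum(e.ic for e in edges) / n_edges,
        crossing_count=sum(e.nonprojective for e in edges),
        max_arity=max(arity),
        mean_arity=sum(arity) / len(arity),
        depth=tree_depth(tree),
    )


def corpus_summary(corpus: Iterable[DepTree]) -> pd.DataFrame:
    """One :class:`SentenceMetrics` row per tree, as a DataFrame."""
    rows = [sentence_summary(t).__dict__ for t in corpus]
    return pd.DataFrame(
        rows,
        columns=[
            "sentence_id",
            "language",
            "n_words",
            "mean_dl",
            "mean_ic",
            "crossing_count",
            "max_arity",
            "mean_arity",
            "depth",
        ],
    )


def corpus_edges(corpus: Iterable[DepTree]) -> pd.DataFrame:
    """One row per word-word dependency across the corpus."""
    rows = []
    for t in corpus:
        for e in edge_metrics(t):
            rows.append(
                {
                    "sentence_id": t.sentence_id,
                    "language": t.language,
                    "n_words": t.n_words,
                    "head_pos": e.head_pos,
                    "dep_pos": e.dep_pos,
                    "dl": e.dl,
                    "ic": e.ic,
                    "nonprojective": e.nonprojective,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sentence_id",
            "language",
            "n_words",
            "head_pos",
            "dep_pos",
            "dl",
            "ic",
            "nonprojective",
        ],
    )
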