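"""Synthetic dependency treebanks with controllable statistical structure.

These corpora emulate the gross shape of the short-sentence slice of a
natural-language treebank — 3..11-word sentences with a short-skewed length
distribution, language-like arity (a truncated-geometric number of dependents
per head), and predominantly projective orders with occasional crossings —
while letting tests plant word-order pressures of known direction:

* ``uniform_random``: a uniform random projective linearization (no ordering
  pressure; the null control),
* ``dlm_greedy``: dependents placed alternately left/right of their head in
  increasing order of subtree size — the classic dependency-length-minimizing
  heuristic,
* ``icm_biased``: leaf dependents hug their head while head-bearing subtrees
  are pushed outward, so the words intervening a dependency are predominantly
  terminal (low intervener complexity).

No natural-language lexicon or morphology is attempted: forms are synthetic
tokens and UPOS marks only the leaf/non-leaf distinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .metrics import crossing_count_heads
from .treebank_io import DepTree, tree_from_heads

ORDERING_POLICIES = ("uniform_random", "dlm_greedy", "icm_biased")


def default_length_distribution(
    min_len: int = 3, max_len: int = 11, decay: float = 0.82
) -> dict[int, float]:
    """Short-skewed sentence-length distribution on min_len..max_len.

    Geometric decay per added word; ``decay=0.82`` makes 3-word sentences
    roughly five times as frequent as 11-word ones, echoing the short-sentence
    slice of natural corpora.
    """
    weights = {n: decay ** (n - min_len) for n in range(min_len, max_len + 1)}
    z = sum(weights.values())
    return {n: w / z for n, w in weights.items()}


def truncated_geometric_arity(mean: float = 1.1, max_arity: int = 5) -> dict[int, float]:
    """Distribution over dependents-per-head 0..max_arity, geometric with the
    given (untruncated) mean; mean around 1 mimics natural arity profiles."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    q = mean / (1.0 + mean)
    weights = {k: (1 - q) * q**k for k in range(max_arity + 1)}
    z = sum(weights.values())
    return {k: w / z for k, w in weights.items()}


@dataclass(frozen=True)
class SynthCorpusSpec:
    """Parameters of one synthetic multi-language corpus."""

    n_languages: int = 5
    sentences_per_language: int = 200
    length_distribution: Mapping[int, float] = field(
        default_factory=default_length_distribution
    )
    arity_distribution: Mapping[int, float] = field(
        default_factory=truncated_geometric_arity
    )
    ordering_policy: str = "uniform_random"
    crossing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ordering_policy not in ORDERING_POLICIES:
            raise ValueError(f"unknown ordering policy {self.ordering_policy!r}")
        if not 0.0 <= self.crossing_rate <= 1.0:
            raise ValueError("crossing_rate must be in [0, 1]")
        for dist, name in (
            (self.length_distribution, "length_distribution"),
            (self.arity_distribution, "arity_distribution"),
        ):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")


@dataclass
class TreeShape:
    """An unordered rooted tree: children lists over node ids 0..n-1, root 0."""

    children: list[list[int]]

    @property
    def n(self) -> int:
        return len(self.children)

    def subtree_sizes(self) -> list[int]:
        sizes = [1] * self.n
        order: list[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        for v in reversed(order):
            for c in self.children[v]:
                sizes[v] += sizes[c]
        return sizes


def _draw(dist: Mapping[int, float], rng: np.random.Generator) -> int:
    ks = sorted(dist)
    ps = np.array([dist[k] for k in ks])
    return int(rng.choice(ks, p=ps / ps.sum()))


def gen_tree_shape(
    n: int, arity_distribution: Mapping[int, float], rng: np.random.Generator
) -> TreeShape:
    """Grow a rooted tree to exactly n nodes by iterated dependent attachment.

    Nodes are expanded breadth-first, each drawing its dependent count from
    the arity distribution; the final draw is truncated so the tree lands on
    exactly n nodes.  If every frontier node draws zero before n is reached,
    a uniformly chosen existing node is re-entered with a forced minimum of
    one dependent (the distribution conditioned on >= 1).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if arity_distribution.get(0, 0.0) >= 1.0 - 1e-12:
        raise ValueError("arity distribution cannot be concentrated at 0")
    children: list[list[int]] = [[]]
    queue = [0]
    size = 1
    while size < n:
        if queue:
            v = queue.pop(0)
            k = _draw(arity_distribution, rng)
        else:
            v = int(rng.integers(0, size))
            k = 0
            while k == 0:
                k = _draw(arity_distribution, rng)
        k = min(k, n - size)
        for _ in range(k):
            children.append([])
            children[v].append(size)
            queue.append(size)
            size += 1
    return TreeShape(children=children)


def _linearize_blocks(
    shape: TreeShape,
    rng: np.random.Generator,
    order_children,
) -> list[int]:
    """Shared projective linearizer: each node's block is itself plus its
    children's blocks, placed per ``order_children``'s (child, side) plan."""
    sizes = shape.subtree_sizes()

    def lin(v: int) -> list[int]:
        seq = [v]
        for c, side in order_children(v, sizes):
            block = lin(c)
            seq = block + seq if side == 0 else seq + block
        return seq

    return lin(0)


def _shape_to_tree(
    shape: TreeShape, order: Sequence[int], sentence_id: str, language: str
) -> DepTree:
    """Assign linear positions per ``order`` (node ids left-to-right)."""
    n = shape.n
    pos = {node: i + 1 for i, node in enumerate(order)}
    parent = [0] * n  # node id -> parent node id, root sentinel handled below
    has_parent = [False] * n
    for v, kids in enumerate(shape.children):
        for c in kids:
            parent[c] = v
            has_parent[c] = True
    heads = [0] * n
    leaf = [len(shape.children[v]) == 0 for v in range(n)]
    for v in range(n):
        heads[pos[v] - 1] = pos[parent[v]] if has_parent[v] else 0
    upos = [""] * n
    forms = [""] * n
    for v in range(n):
        p = pos[v]
        upos[p - 1] = "NOUN" if leaf[v] else "VERB"
        forms[p - 1] = f"w{p}"
    return tree_from_heads(
        heads, forms=forms, upos=upos, sentence_id=sentence_id, language=language
    )


def uniform_projective_linearize(
    shape: TreeShape,
    rng: np.random.Generator,
    sentence_id: str = "",
    language: str = "",
) -> DepTree:
    """Uniform random projective order: each head and its child blocks are
    arranged in a uniformly random sequence, recursively."""

    def lin(v: int) -> list[int]:
        items: list[list[int]] = [[v]] + [lin(c) for c in shape.children[v]]
        idx = rng.permutation(len(items))
        seq: list[int] = []
        for i in idx:
            seq.extend(items[int(i)])
        return seq

    return _shape_to_tree(shape, lin(0), sentence_id, language)


def dlm_greedy_linearize(
    shape: TreeShape,
    rng: np.random.Generator,
    sentence_id: str = "",
    language: str = "",
) -> DepTree:
    """Dependency-length-minimizing heuristic: dependents placed alternately
    left/right of the head in increasing order of subtree size (RNG breaks
    ties and chooses the starting side)."""

    def order_children(v: int, sizes: list[int]):
        kids = list(shape.children[v])
        rng.shuffle(kids)  # tie-break before the stable sort
        kids.sort(key=lambda c: sizes[c])
        side = int(rng.integers(0, 2))
        plan = []
        for c in kids:
            plan.append((c, side))
            side ^= 1
        return plan

    order = _linearize_blocks(shape, rng, order_children)
    return _shape_to_tree(shape, order, sentence_id, language)


def icm_biased_linearize(
    shape: TreeShape,
    rng: np.random.Generator,
    sentence_id: str = "",
    language: str = "",
) -> DepTree:
    """Low-intervener-complexity order: leaf dependents hug the head (placed
    first, alternating sides); head-bearing subtrees go outside them, largest
    outermost, so interveners are predominantly terminal dependents."""

    def order_children(v: int, sizes: list[int]):
        kids = list(shape.children[v])
        rng.shuffle(kids)
        # leaves first (nearest the head), then subtrees by increasing size
        kids.sort(key=lambda c: (len(shape.children[c]) > 0, sizes[c]))
        side = int(rng.integers(0, 2))
        plan = []
        for c in kids:
            plan.append((c, side))
            side ^= 1
        return plan

    order = _linearize_blocks(shape, rng, order_children)
    return _shape_to_tree(shape, order, sentence_id, language)


_LINEARIZERS = {
    "uniform_random": uniform_projective_linearize,
    "dlm_greedy": dlm_greedy_linearize,
    "icm_biased": icm_biased_linearize,
}


def _inject_crossing(tree: DepTree, rng: np.random.Generator) -> DepTree | None:
    """Try adjacent transpositions until one creates >= 1 crossing.

    Some orders (e.g. a perfectly linearized chain) admit no crossing-creating
    adjacent swap; after n^2 failed proposals the tree is left unchanged and
    None is returned.
    """
    n = tree.n_words
    heads = list(tree.heads)
    for _ in range(n * n):
        k = int(rng.integers(1, n))  # swap positions k, k+1
        perm = list(range(1, n + 1))
        perm[k - 1], perm[k] = perm[k], perm[k - 1]
        new_heads = [0] * n
        for old, h in enumerate(heads, start=1):
            new_heads[perm[old - 1] - 1] = perm[h - 1] if h != 0 else 0
        if crossing_count_heads(new_heads) >= 1:
            from .baseline_gen import _apply_perm_tree

            return _apply_perm_tree(tree, perm)
    return None


def gen_corpus(spec: SynthCorpusSpec) -> list[DepTree]:
    """Generate the corpus: deterministic given ``spec.seed``, one RNG stream
    per language, sentence ids ``<language>-<index>``."""
    linearize = _LINEARIZERS[spec.ordering_policy]
    corpus: list[DepTree] = []
    for j in range(spec.n_languages):
        language = f"synth{j:02d}"
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, j)))
        for i in range(spec.sentences_per_language):
            n = _draw(spec.length_distribution, rng)
            shape = gen_tree_shape(n, spec.arity_distribution, rng)
            tree = linearize(
                shape, rng, sentence_id=f"{language}-{i}", language=language
            )
            if spec.crossing_rate > 0 and rng.random() < spec.crossing_rate:
                crossed = _inject_crossing(tree, rng)
                if crossed is not None:
                    tree = crossed
            corpus.append(tree)
    return corpus
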