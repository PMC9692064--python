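"""Constrained random baselines for dependency trees.

Six baseline families, each matched to its reference tree in sentence length
and crossing count, generated by uniform sampling plus rejection:

==============================  =========  ===========  ===========  ========
kind                            length     DL multiset  IC multiset  topology
==============================  =========  ===========  ===========  ========
random_structures               yes        --           --           --
rla                             yes        --           --           yes
dl_matched_random_structures    yes        yes          --           --
dl_matched_rla                  yes        yes          --           yes
ic_matched_random_structures    yes        --           yes          --
ic_matched_rla                  yes        --           yes          yes
==============================  =========  ===========  ===========  ========

``*_random_structures`` kinds draw uniformly over rooted labeled trees on the
sentence's positions (uniform Prüfer sequence + uniform root, giving each of
the n^(n-1) rooted trees equal mass).  ``*_rla`` kinds draw uniform random
linear arrangements: the word order is permuted while the dependency
relations among the words are preserved, so arity multiset, depth and tree
shape carry over by construction.

"Matching the sequence of dependency lengths / intervener complexities" is
implemented as multiset equality of the per-edge values: random-structure
candidates have no positional edge correspondence with the reference, so an
order-sensitive reading would be ill-defined there, and the same reading is
applied to both families for consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .treebank_io import DepTree, Word, tree_from_heads

BASELINE_KINDS = (
    "random_structures",
    "rla",
    "dl_matched_random_structures",
    "dl_matched_rla",
    "ic_matched_random_structures",
    "ic_matched_rla",
)


@dataclass(frozen=True)
class BaselineSpec:
    """Which baseline to generate and with what budget.

    max_attempts is the rejection-sampling budget per reference tree; when it
    is exhausted the tree is reported as a failure (a typed outcome, not an
    exception) and excluded pairwise from downstream model input.
    """

    kind: str
    max_attempts: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        if self.max_attempts <= 0:
            raise ValueError("max_attempts must be positive")


@dataclass
class BaselineResult:
    tree: DepTree | None
    attempts: int
    kind: str

    @property
    def success(self) -> bool:
        return self.tree is not None


@dataclass
class BaselineReport:
    """Bookkeeping for one corpus-level generation run."""

    kind: str
    seed: int
    attempts: list[int] = field(default_factory=list)
    outcomes: list[bool] = field(default_factory=list)
    lengths: list[int] = field(default_factory=list)

    @property
    def successes(self) -> int:
        return sum(self.outcomes)

    @property
    def failures(self) -> int:
        return len(self.outcomes) - self.successes

    def acceptance_by_length(self) -> pd.DataFrame:
        """Per sentence length: trees attempted, successes, mean attempts."""
        df = pd.DataFrame(
            {"n_words": self.lengths, "success": self.outcomes, "attempts": self.attempts}
        )
        out = (
            df.groupby("n_words")
            .agg(
                trees=("success", "size"),
                successes=("success", "sum"),
                mean_attempts=("attempts", "mean"),
            )
            .reset_index()
        )
        out["acceptance_rate"] = out["successes"] / out["trees"]
        return out


# ---------------------------------------------------------------------------
# uniform samplers
# ---------------------------------------------------------------------------

def prufer_decode(seq: Sequence[int], n: int) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence over labels 1..n into the edges of its tree.

    Standard decode: repeatedly join the smallest-degree-one label not
    remaining in the sequence to the sequence head.  Bijective between
    sequences of length n-2 and labeled trees on n nodes.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    seq = [int(s) for s in seq]
    if len(seq) != n - 2:
        raise ValueError(f"sequence length must be n-2 = {n - 2}")
    if any(s < 1 or s > n for s in seq):
        raise ValueError("sequence entries must be in 1..n")
    deg = [1] * (n + 1)
    for s in seq:
        deg[s] += 1
    import heapq

    leaves = [i for i in range(1, n + 1) if deg[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for s in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, s))
        deg[s] -= 1
        if deg[s] == 1:
            heapq.heappush(leaves, s)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((u, v))
    return edges


def _orient(edges: list[tuple[int, int]], root: int, n: int) -> list[int]:
    """Head vector (1-based word -> head, 0 at root) from undirected edges."""
    adj: list[list[int]] = [[] for _ in range(n + 1)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    heads = [0] * n
    stack = [root]
    seen = [False] * (n + 1)
    seen[root] = True
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if not seen[w]:
                seen[w] = True
                heads[w - 1] = v
                stack.append(w)
    return heads


def _sample_structure_heads(n: int, rng: np.random.Generator) -> list[int]:
    if n == 2:
        edges = [(1, 2)]
    else:
        seq = rng.integers(1, n + 1, size=n - 2)
        edges = prufer_decode(seq, n)
    root = int(rng.integers(1, n + 1))
    return _orient(edges, root, n)


def sample_random_structure(
    n: int, rng: np.random.Generator, sentence_id: str = "", language: str = ""
) -> DepTree:
    """Uniform draw over the n^(n-1) rooted labeled trees on positions 1..n."""
    heads = _sample_structure_heads(n, rng)
    return tree_from_heads(
        heads, upos=["X"] * n, sentence_id=sentence_id, language=language
    )


def _permute_heads(heads: Sequence[int], perm: Sequence[int]) -> list[int]:
    """perm[i] is the new position of the word at old position i+1."""
    out = [0] * len(heads)
    for old, h in enumerate(heads, start=1):
        out[perm[old - 1] - 1] = perm[h - 1] if h != 0 else 0
    return out


def sample_rla(tree: DepTree, rng: np.random.Generator) -> DepTree:
    """Uniform random linear arrangement: permute word order, keep the relations."""
    n = tree.n_words
    perm = [int(p) + 1 for p in rng.permutation(n)]
    new_heads = _permute_heads(tree.heads, perm)
    new_words: list[Word | None] = [None] * n
    for w in tree.words:
        p = perm[w.position - 1]
        new_words[p - 1] = Word(
            position=p,
            form=w.form,
            upos=w.upos,
            head=new_heads[p - 1],
            lemma=w.lemma,
            xpos=w.xpos,
            feats=w.feats,
            deprel=w.deprel,
            deps=w.deps,
            misc=w.misc,
        )
    return DepTree(
        words=tuple(new_words),  # type: ignore[arg-type]
        sentence_id=tree.sentence_id,
        language=tree.language,
        meta=dict(tree.meta),
    )


# ---------------------------------------------------------------------------
# rejection sampling under matched statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Targets:
    n: int
    crossings: int
    dl: tuple[int, ...] | None
    ic: tuple[int, ...] | None


def _targets_for(reference: DepTree, kind: str) -> _Targets:
    heads = reference.heads
    return _Targets(
        n=reference.n_words,
        crossings=metrics.crossing_count_heads(heads),
        dl=metrics.dl_multiset_heads(heads) if kind.startswith("dl_matched") else None,
        ic=metrics.ic_multiset_heads(heads) if kind.startswith("ic_matched") else None,
    )


def _heads_match(heads: Sequence[int], tgt: _Targets) -> bool:
    if metrics.crossing_count_heads(heads) != tgt.crossings:
        return False
    if tgt.dl is not None and metrics.dl_multiset_heads(heads) != tgt.dl:
        return False
    if tgt.ic is not None and metrics.ic_multiset_heads(heads) != tgt.ic:
        return False
    return True


def matches_constraints(candidate: DepTree, reference: DepTree, kind: str) -> bool:
    """True iff the candidate satisfies the kind's matching constraints."""
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind {kind!r}")
    if candidate.n_words != reference.n_words:
        raise ValueError("candidate and reference differ in n_words")
    return _heads_match(candidate.heads, _targets_for(reference, kind))


def generate_baseline(
    tree: DepTree, spec: BaselineSpec, rng: np.random.Generator
) -> BaselineResult:
    """Rejection-sample one baseline tree for ``tree`` under ``spec``.

    Draws from the uniform proposal (random rooted structures or RLAs of the
    reference, by kind) until the matching constraints hold or the attempt
    budget is exhausted.  Accepted draws are therefore uniform over the exact
    constraint-satisfying set.
    """
    tgt = _targets_for(tree, spec.kind)
    n = tree.n_words
    use_rla = spec.kind.endswith("rla") and spec.kind != "random_structures"
    ref_heads = tree.heads
    for attempt in range(1, spec.max_attempts + 1):
        if use_rla:
            perm = [int(p) + 1 for p in rng.permutation(n)]
            heads = _permute_heads(ref_heads, perm)
        else:
            heads = _sample_structure_heads(n, rng)
        if _heads_match(heads, tgt):
            if use_rla:
                # rebuild with word identities under the accepted permutation
                out = _apply_perm_tree(tree, perm)
            else:
                out = tree_from_heads(
                    heads,
                    upos=["X"] * n,
                    sentence_id=tree.sentence_id,
                    language=tree.language,
                )
            meta = dict(out.meta)
            meta.update(
                baseline_kind=spec.kind, seed=str(spec.seed), attempts=str(attempt)
            )
            out = DepTree(
                words=out.words,
                sentence_id=out.sentence_id,
                language=out.language,
                meta=meta,
            )
            return BaselineResult(tree=out, attempts=attempt, kind=spec.kind)
    return BaselineResult(tree=None, attempts=spec.max_attempts, kind=spec.kind)


def _apply_perm_tree(tree: DepTree, perm: Sequence[int]) -> DepTree:
    n = tree.n_words
    new_heads = _permute_heads(tree.heads, perm)
    new_words: list[Word | None] = [None] * n
    for w in tree.words:
        p = perm[w.position - 1]
        new_words[p - 1] = Word(
            position=p,
            form=w.form,
            upos=w.upos,
            head=new_heads[p - 1],
            lemma=w.lemma,
            xpos=w.xpos,
            feats=w.feats,
            deprel=w.deprel,
            deps=w.deps,
            misc=w.misc,
        )
    return DepTree(
        words=tuple(new_words),  # type: ignore[arg-type]
        sentence_id=tree.sentence_id,
        language=tree.language,
        meta=dict(tree.meta),
    )


def _tree_rng(seed: int, index: int) -> np.random.Generator:
    """Per-tree stream derived from (global seed, corpus index): reproducible
    and independent of execution order."""
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def generate_baseline_corpus(
    corpus: Iterable[DepTree], spec: BaselineSpec
) -> tuple[list[BaselineResult], BaselineReport]:
    """One baseline tree per reference tree, budget permitting.

    Returns results aligned with the input corpus (failures carry
    ``tree=None``) plus a :class:`BaselineReport` with per-length acceptance
    statistics.
    """
    results: list[BaselineResult] = []
    report = BaselineReport(kind=spec.kind, seed=spec.seed)
    for index, tree in enumerate(corpus):
        rng = _tree_rng(spec.seed, index)
        res = generate_baseline(tree, spec, rng)
        results.append(res)
        report.attempts.append(res.attempts)
        report.outcomes.append(res.success)
        report.lengths.append(tree.n_words)
    return results, report
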