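"""Prüfer decoding, uniform samplers, and constraint-matched rejection."""

from collections import Counter
from itertools import product

import numpy as np
import pytest

from icmdlm import (
    BASELINE_KINDS,
    BaselineSpec,
    generate_baseline,
    generate_baseline_corpus,
    matches_constraints,
    prufer_decode,
    sample_random_structure,
    sample_rla,
    tree_from_heads,
    validate_tree,
    write_conllu,
)
from icmdlm.metrics import (
    crossing_count_heads,
    dl_multiset_heads,
    ic_multiset_heads,
)
from conftest import random_heads


def canon(edges):
    return frozenset(frozenset(e) for e in edges)


class TestPruferDecode:
    def test_n2_single_edge(self):
        assert canon(prufer_decode([], 2)) == canon([(1, 2)])

    def test_star_from_constant_sequence(self):
        edges = prufer_decode([2, 2], 4)
        assert canon(edges) == canon([(1, 2), (3, 2), (4, 2)])

    def test_bijection_n4(self):
        trees = {canon(prufer_decode(seq, 4)) for seq in product(range(1, 5), repeat=2)}
        assert len(trees) == 16  # Cayley: 4^2 distinct labeled trees

    def test_out_of_range_entry(self):
        with pytest.raises(ValueError, match="1..n"):
            prufer_decode([0, 3], 4)
        with pytest.raises(ValueError, match="length"):
            prufer_decode([1], 4)

    def test_matches_networkx_oracle(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(100):
            n = int(rng.integers(3, 10))
            seq = [int(s) for s in rng.integers(1, n + 1, size=n - 2)]
            ours = canon(prufer_decode(seq, n))
            theirs = canon(
                (u + 1, v + 1)
                for u, v in nx.from_prufer_sequence([s - 1 for s in seq]).edges
            )
            assert ours == theirs


class TestUniformSamplers:
    def test_random_structure_is_valid_rooted_tree(self, rng):
        for n in (2, 5, 9):
            t = sample_random_structure(n, rng)
            assert t.n_words == n
            assert validate_tree(t) == []

    def test_random_structure_deterministic(self):
        a = sample_random_structure(7, np.random.default_rng(42))
        b = sample_random_structure(7, np.random.default_rng(42))
        assert a.heads == b.heads

    def test_n2_both_rootings_appear(self, rng):
        seen = Counter(sample_random_structure(2, rng).heads for _ in range(400))
        assert set(seen) == {(0, 1), (2, 0)}
        assert min(seen.values()) > 100  # ~1/2 each

    def test_rla_preserves_topology(self, rng):
        for _ in range(50):
            t = tree_from_heads(random_heads(int(rng.integers(3, 10)), rng))
            out = sample_rla(t, rng)
            assert validate_tree(out) == []
            assert sorted(Counter(h for h in out.heads if h).values()) == sorted(
                Counter(h for h in t.heads if h).values()
            )  # arity multiset
            from icmdlm import tree_depth

            assert tree_depth(out) == tree_depth(t)

    def test_rla_moves_words_with_positions(self, rng):
        t = tree_from_heads([2, 0, 2], forms=["a", "b", "c"])
        out = sample_rla(t, rng)
        # the word with form "b" is still the root wherever it landed
        root_word = next(w for w in out.words if w.head == 0)
        assert root_word.form == "b"

    def test_rla_n2_both_orders(self, rng):
        t = tree_from_heads([0, 1], forms=["x", "y"])
        seen = Counter(sample_rla(t, rng).forms for _ in range(400))
        assert set(seen) == {("x", "y"), ("y", "x")}
        assert min(seen.values()) > 100


class TestMatchesConstraints:
    def test_identity_matches_every_kind(self, rng):
        t = tree_from_heads(random_heads(6, rng))
        for kind in BASELINE_KINDS:
            assert matches_constraints(t, t, kind)

    def test_crossing_mismatch_rejected(self, four_word_crossing):
        projective = tree_from_heads([2, 3, 4, 0])
        assert not matches_constraints(projective, four_word_crossing, "random_structures")

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="n_words"):
            matches_constraints(tree_from_heads([0, 1]), tree_from_heads([0, 1, 1]), "rla")

    def test_agrees_with_brute_force_small_n(self, rng):
        """Acceptance decisions re-derived from scratch statistics for n <= 6."""
        for _ in range(200):
            n = int(rng.integers(3, 7))
            cand = tree_from_heads(random_heads(n, rng))
            ref = tree_from_heads(random_heads(n, rng))
            cross_ok = crossing_count_heads(cand.heads) == crossing_count_heads(ref.heads)
            dl_ok = dl_multiset_heads(cand.heads) == dl_multiset_heads(ref.heads)
            ic_ok = ic_multiset_heads(cand.heads) == ic_multiset_heads(ref.heads)
            assert matches_constraints(cand, ref, "random_structures") == cross_ok
            assert matches_constraints(cand, ref, "dl_matched_rla") == (cross_ok and dl_ok)
            assert matches_constraints(cand, ref, "ic_matched_random_structures") == (
                cross_ok and ic_ok
            )


class TestGenerateBaseline:
    def test_rla_postcondition_crossings(self, rng):
        star = tree_from_heads([2, 0, 2])  # n=3 star rooted at 2, 0 crossings
        spec = BaselineSpec(kind="rla", max_attempts=1000, seed=1)
        for _ in range(20):
            res = generate_baseline(star, spec, rng)
            assert res.success
            assert crossing_count_heads(res.tree.heads) == 0

    def test_dl_matched_rla_exact_multiset(self, rng):
        spec = BaselineSpec(kind="dl_matched_rla", max_attempts=20000, seed=2)
        for _ in range(10):
            ref = tree_from_heads(random_heads(6, rng))
            res = generate_baseline(ref, spec, rng)
            if res.success:
                assert dl_multiset_heads(res.tree.heads) == dl_multiset_heads(ref.heads)

    def test_ic_matched_structures_exact_multiset(self, rng):
        spec = BaselineSpec(kind="ic_matched_random_structures", max_attempts=20000, seed=2)
        ref = tree_from_heads(random_heads(5, rng))
        res = generate_baseline(ref, spec, rng)
        assert res.success
        assert ic_multiset_heads(res.tree.heads) == ic_multiset_heads(ref.heads)
        assert crossing_count_heads(res.tree.heads) == crossing_count_heads(ref.heads)

    def test_metadata_carried(self, rng):
        ref = tree_from_heads([2, 0, 2])
        res = generate_baseline(ref, BaselineSpec(kind="rla", seed=17), rng)
        assert res.tree.meta["baseline_kind"] == "rla"
        assert res.tree.meta["seed"] == "17"
        assert int(res.tree.meta["attempts"]) == res.attempts

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            BaselineSpec(kind="rla", max_attempts=0)
        with pytest.raises(ValueError):
            BaselineSpec(kind="nonsense")


class TestCorpusGeneration:
    def _corpus(self, rng, k=30):
        return [
            tree_from_heads(random_heads(int(rng.integers(3, 8)), rng), sentence_id=f"s{i}")
            for i in range(k)
        ]

    def test_report_accounting(self, rng):
        corpus = self._corpus(rng)
        spec = BaselineSpec(kind="dl_matched_random_structures", max_attempts=1, seed=3)
        results, report = generate_baseline_corpus(corpus, spec)
        assert report.successes + report.failures == len(corpus)
        assert len(results) == len(corpus)
        assert report.failures > 0  # 1 attempt cannot satisfy a hard constraint often

    def test_projective_targets_always_reachable(self, rng):
        corpus = [tree_from_heads([2, 0, 2], sentence_id=f"s{i}") for i in range(10)]
        _, report = generate_baseline_corpus(
            corpus, BaselineSpec(kind="random_structures", max_attempts=5000, seed=4)
        )
        assert report.failures == 0

    def test_deterministic_given_seed(self, rng):
        corpus = self._corpus(rng, k=15)
        spec = BaselineSpec(kind="rla", max_attempts=5000, seed=11)
        res1, _ = generate_baseline_corpus(corpus, spec)
        res2, _ = generate_baseline_corpus(corpus, spec)
        doc1 = write_conllu([r.tree for r in res1 if r.tree])
        doc2 = write_conllu([r.tree for r in res2 if r.tree])
        assert doc1 == doc2

    def test_empty_corpus(self):
        results, report = generate_baseline_corpus([], BaselineSpec(kind="rla"))
        assert results == [] and report.successes == 0

    def test_monotone_difficulty(self, rng):
        """More constraints never make acceptance easier (on the same corpus)."""
        corpus = self._corpus(rng, k=25)
        _, plain = generate_baseline_corpus(
            corpus, BaselineSpec(kind="rla", max_attempts=30000, seed=5)
        )
        _, matched = generate_baseline_corpus(
            corpus, BaselineSpec(kind="ic_matched_rla", max_attempts=30000, seed=5)
        )
        assert np.mean(matched.attempts) >= np.mean(plain.attempts)

    def test_acceptance_by_length_table(self, rng):
        corpus = self._corpus(rng, k=20)
        _, report = generate_baseline_corpus(
            corpus, BaselineSpec(kind="rla", max_attempts=30000, seed=6)
        )
        table = report.acceptance_by_length()
        assert table["trees"].sum() == 20
        assert set(table.columns) >= {"n_words", "successes", "mean_attempts", "acceptance_rate"}
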