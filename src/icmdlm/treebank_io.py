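"""Reading, validating, filtering and writing CoNLL-U dependency treebanks.

Only the ID, FORM, UPOS and HEAD columns are interpreted; the remaining
CoNLL-U columns are carried opaquely so that parse -> write round-trips.
The artificial root is position 0 and is not a word: every tree has exactly
one word whose head is 0, and all complexity metrics downstream are computed
over word-word dependencies only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: UPOS tag treated as punctuation by :func:`filter_corpus`.
PUNCT_TAG = "PUNCT"


class ConlluParseError(ValueError):
    """Raised for a malformed or invalid sentence; carries the sentence id."""

    def __init__(self, message: str, sentence_id: str = ""):
        self.sentence_id = sentence_id
        super().__init__(
            f"sentence {sentence_id!r}: {message}" if sentence_id else message
        )


@dataclass(frozen=True)
class Word:
    """One word line of a sentence.

    ``position`` is 1-based; ``head`` is the position of the governing word,
    with 0 denoting attachment to the artificial root.
    """

    position: int
    form: str
    upos: str
    head: int
    lemma: str = "_"
    xpos: str = "_"
    feats: str = "_"
    deprel: str = "_"
    deps: str = "_"
    misc: str = "_"


@dataclass(frozen=True)
class DepTree:
    """A single sentence's rooted dependency tree over linearly ordered words."""

    words: tuple[Word, ...]
    sentence_id: str = ""
    language: str = ""
    meta: Mapping[str, str] = field(default_factory=dict)

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def heads(self) -> tuple[int, ...]:
        """Head position for each word, in linear order (0 = root)."""
        return tuple(w.head for w in self.words)

    @property
    def forms(self) -> tuple[str, ...]:
        return tuple(w.form for w in self.words)

    def __repr__(self) -> str:  # compact: trees appear in logs a lot
        return (
            f"DepTree(id={self.sentence_id!r}, lang={self.language!r}, "
            f"n={self.n_words}, heads={self.heads})"
        )


@dataclass(frozen=True)
class CorpusFilter:
    """Length and punctuation filter applied before any analysis.

    Defaults keep 3..11-word sentences (strictly below 12 words) and count
    every CoNLL-U word line, punctuation included.
    """

    min_len: int = 3
    max_len: int = 11
    exclude_punct: bool = False

    def __post_init__(self) -> None:
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")


def tree_from_heads(
    heads: Sequence[int],
    forms: Sequence[str] | None = None,
    upos: Sequence[str] | None = None,
    sentence_id: str = "",
    language: str = "",
    meta: Mapping[str, str] | None = None,
) -> DepTree:
    """Build a :class:`DepTree` from a head vector (``heads[i]`` governs word i+1)."""
    n = len(heads)
    if forms is None:
        forms = [f"w{i + 1}" for i in range(n)]
    if upos is None:
        upos = ["_"] * n
    words = tuple(
        Word(position=i + 1, form=forms[i], upos=upos[i], head=int(heads[i]))
        for i in range(n)
    )
    return DepTree(
        words=words,
        sentence_id=sentence_id,
        language=language,
        meta=dict(meta) if meta else {},
    )


def validate_tree(tree: DepTree) -> list[str]:
    """Check the tree invariants; returns a list of violations (empty iff valid)."""
    report: list[str] = []
    n = tree.n_words
    if n == 0:
        return ["empty tree"]
    positions = [w.position for w in tree.words]
    if positions != list(range(1, n + 1)):
        report.append("positions not consecutive 1..n")
    roots = [w.position for w in tree.words if w.head == 0]
    if len(roots) == 0:
        report.append("no root")
    elif len(roots) > 1:
        report.append("multiple roots")
    for w in tree.words:
        if w.head == w.position:
            report.append(f"word {w.position} is its own head")
        elif w.head != 0 and not (1 <= w.head <= n):
            report.append(f"head out of range for word {w.position}")
    if report:
        return report
    # single root, heads in range: connectivity to root <=> acyclicity
    heads = tree.heads
    for start in range(1, n + 1):
        seen = set()
        j = start
        while j != 0:
            if j in seen:
                report.append("cyclic")
                return report
            seen.add(j)
            j = heads[j - 1]
    return report


def _finish_sentence(
    word_lines: list[list[str]], comments: dict[str, str], index: int
) -> DepTree:
    sid = comments.get("sent_id", f"s{index}")
    words = []
    for cols in word_lines:
        try:
            pos = int(cols[0])
            head = int(cols[6])
        except ValueError as exc:
            raise ConlluParseError(f"non-integer ID/HEAD: {exc}", sid) from None
        words.append(
            Word(
                position=pos,
                form=cols[1],
                upos=cols[3],
                head=head,
                lemma=cols[2],
                xpos=cols[4],
                feats=cols[5],
                deprel=cols[7],
                deps=cols[8],
                misc=cols[9],
            )
        )
    meta = {k: v for k, v in comments.items() if k not in ("sent_id", "language")}
    tree = DepTree(
        words=tuple(words),
        sentence_id=sid,
        language=comments.get("language", ""),
        meta=meta,
    )
    problems = validate_tree(tree)
    if problems:
        raise ConlluParseError("; ".join(problems), sid)
    return tree


def parse_conllu(
    text: str, *, language: str = "", on_error: str = "raise"
) -> list[DepTree]:
    """Parse a CoNLL-U document into a list of validated :class:`DepTree`.

    Multiword-token range lines (ID ``a-b``) and empty-node lines (ID ``a.b``)
    are skipped. ``# sent_id`` comments are retained; other ``# key = value``
    comments land in ``DepTree.meta``.

    Parameters
    ----------
    language:
        Label attached to every parsed tree (overrides any ``# language``
        comment) — treebank files do not themselves name their language.
    on_error:
        ``"raise"`` aborts on the first bad sentence; ``"skip"`` logs it and
        continues.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    trees: list[DepTree] = []
    word_lines: list[list[str]] = []
    comments: dict[str, str] = {}
    index = 0

    def flush() -> None:
        nonlocal index, word_lines, comments
        if not word_lines and not comments:
            return
        index += 1
        try:
            tree = _finish_sentence(word_lines, comments, index)
            if language:
                tree = replace(tree, language=language)
            trees.append(tree)
        except ConlluParseError as exc:
            if on_error == "raise":
                raise
            logger.warning("skipping sentence: %s", exc)
        word_lines = []
        comments = {}

    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                comments[key.strip()] = value.strip()
            else:
                comments[body] = ""
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            sid = comments.get("sent_id", f"s{index + 1}")
            err = ConlluParseError(f"expected 10 columns, got {len(cols)}", sid)
            if on_error == "raise":
                raise err
            logger.warning("skipping sentence: %s", err)
            # poison the sentence: consume remaining lines until blank
            word_lines = []
            comments = {"__bad__": ""}
            continue
        if "__bad__" in comments:
            continue
        if "-" in cols[0] or "." in cols[0]:
            continue  # multiword-token range or empty node
        word_lines.append(cols)
    # tolerate missing trailing blank line
    if "__bad__" in comments:
        word_lines, comments = [], {}
    flush()
    return trees


def write_conllu(
    corpus: Iterable[DepTree],
    annotations: Sequence[Mapping[str, object]] | None = None,
) -> str:
    """Serialize trees to a CoNLL-U document.

    ``annotations`` optionally supplies extra ``# key = value`` comments per
    tree (aligned by index), e.g. baseline kind, RNG seed, attempts used.
    """
    corpus = list(corpus)
    if annotations is not None and len(annotations) != len(corpus):
        raise ValueError("annotations must align with corpus")
    chunks: list[str] = []
    for i, tree in enumerate(corpus):
        lines = [f"# sent_id = {tree.sentence_id}"]
        if tree.language:
            lines.append(f"# language = {tree.language}")
        for k, v in tree.meta.items():
            lines.append(f"# {k} = {v}")
        if annotations is not None:
            for k, v in annotations[i].items():
                lines.append(f"# {k} = {v}")
        for w in tree.words:
            lines.append(
                "\t".join(
                    [
                        str(w.position),
                        w.form,
                        w.lemma,
                        w.upos,
                        w.xpos,
                        w.feats,
                        str(w.head),
                        w.deprel,
                        w.deps,
                        w.misc,
                    ]
                )
            )
        chunks.append("\n".join(lines))
    if not chunks:
        return ""
    return "\n\n".join(chunks) + "\n"


def _strip_punctuation(tree: DepTree) -> DepTree | None:
    """Remove PUNCT words and re-index; None if a PUNCT word heads a non-PUNCT word."""
    punct = {w.position for w in tree.words if w.upos == PUNCT_TAG}
    if not punct:
        return tree
    kept = [w for w in tree.words if w.position not in punct]
    if not kept:
        return None
    for w in kept:
        if w.head in punct:
            return None
    remap = {w.position: i + 1 for i, w in enumerate(kept)}
    words = tuple(
        replace(w, position=remap[w.position], head=remap.get(w.head, 0))
        for w in kept
    )
    return DepTree(
        words=words,
        sentence_id=tree.sentence_id,
        language=tree.language,
        meta=tree.meta,
    )


def filter_corpus(corpus: Iterable[DepTree], filt: CorpusFilter) -> list[DepTree]:
    """Apply the length (and optionally punctuation) filter to a corpus.

    With ``exclude_punct``, punctuation words are removed *before* the length
    test; a tree in which a punctuation token heads a non-punctuation word is
    dropped (with a log entry) rather than guessing a reattachment.
    """
    out: list[DepTree] = []
    for tree in corpus:
        if filt.exclude_punct:
            stripped = _strip_punctuation(tree)
            if stripped is None:
                logger.info(
                    "dropping %s: punctuation token heads a non-punctuation word",
                    tree.sentence_id,
                )
                continue
            tree = stripped
        if filt.min_len <= tree.n_words <= filt.max_len:
            out.append(tree)
    return out
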