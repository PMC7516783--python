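"""Bag-of-words corpora: construction, validation and plain-text IO.

A corpus is a sparse document-word count matrix plus an ordered vocabulary.
Documents and words are 0-indexed in memory; the on-disk triplet format uses
1-based indices (header line ``D N NNZ``, then ``doc word count`` lines).
Labels are stored as per-document sets of class ids in ``1..C`` and written
as 1-based ``doc class`` pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Corpus",
    "LabelSet",
    "CorpusError",
    "build_corpus",
    "read_corpus",
    "write_corpus",
    "read_labels",
    "write_labels",
]


class CorpusError(ValueError):
    """Raised for malformed corpus data or files."""


@dataclass
class Corpus:
    """Document-word counts with vocabulary.

    Attributes
    ----------
    vocab:
        Ordered list of N unique, non-empty word strings.
    counts:
        ``(D, N)`` sparse nonnegative integer matrix; entry ``(d, n)`` is the
        number of occurrences of word ``n`` in document ``d``.
    """

    vocab: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts, dtype=np.int64)
        self.counts.eliminate_zeros()
        problems = self.validate()
        if problems:
            raise CorpusError("; ".join(problems))

    @property
    def num_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def num_words(self) -> int:
        return self.counts.shape[1]

    @property
    def doc_lengths(self) -> np.ndarray:
        """Total token count Ld per document (row sums of ``counts``)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def total_tokens(self) -> int:
        return int(self.counts.sum())

    def dense(self) -> np.ndarray:
        """Counts as a dense ``(D, N)`` float array."""
        return np.asarray(self.counts.todense(), dtype=float)

    def validate(self) -> list[str]:
        """Check every corpus invariant; return a list of violations."""
        problems: list[str] = []
        if len(self.vocab) != self.counts.shape[1]:
            problems.append(
                f"vocab length {len(self.vocab)} != count columns {self.counts.shape[1]}"
            )
        if len(set(self.vocab)) != len(self.vocab):
            problems.append("vocabulary entries are not unique")
        if any((not isinstance(w, str)) or w == "" for w in self.vocab):
            problems.append("vocabulary contains empty or non-string entries")
        if self.counts.nnz and self.counts.data.min() < 0:
            problems.append("negative counts present")
        lengths = self.doc_lengths
        if self.counts.shape[0] == 0:
            problems.append("corpus has no documents")
        elif lengths.min() < 1:
            empty = np.flatnonzero(lengths < 1)
            problems.append(f"documents with zero tokens: {empty.tolist()}")
        col = np.asarray(self.counts.sum(axis=0)).ravel()
        if self.counts.shape[1] == 0:
            problems.append("corpus has no vocabulary")
        elif col.min() < 1:
            missing = np.flatnonzero(col < 1)
            problems.append(f"vocabulary words occurring nowhere: {missing.tolist()}")
        return problems


@dataclass
class LabelSet:
    """Per-document class labels (single- or multi-label).

    ``labels[d]`` is a non-empty frozenset of class ids drawn from ``1..C``.
    """

    labels: list[frozenset[int]]
    num_classes: int

    def __post_init__(self) -> None:
        self.labels = [frozenset(s) for s in self.labels]
        for d, s in enumerate(self.labels):
            if not s:
                raise CorpusError(f"document {d} has an empty label set")
            bad = [c for c in s if not (1 <= c <= self.num_classes)]
            if bad:
                raise CorpusError(
                    f"document {d} references class ids {bad} outside 1..{self.num_classes}"
                )

    @property
    def num_docs(self) -> int:
        return len(self.labels)

    def sizes(self) -> np.ndarray:
        """|Cd| per document."""
        return np.array([len(s) for s in self.labels])


def build_corpus(tokenized_docs: Sequence[Sequence[str]]) -> Corpus:
    """Build a corpus from already-tokenized documents.

    The vocabulary is the sorted set of distinct tokens; empty documents are
    dropped with a warning. Raises :class:`CorpusError` if every document is
    empty.
    """
    kept = [list(doc) for doc in tokenized_docs if len(doc) > 0]
    n_dropped = len(tokenized_docs) - len(kept)
    if n_dropped:
        logger.warning("dropping %d empty document(s)", n_dropped)
    if not kept:
        raise CorpusError("all documents are empty")
    vocab = sorted({tok for doc in kept for tok in doc})
    index = {w: n for n, w in enumerate(vocab)}
    rows, cols, data = [], [], []
    for d, doc in enumerate(kept):
        counts: dict[int, int] = {}
        for tok in doc:
            counts[index[tok]] = counts.get(index[tok], 0) + 1
        for n, c in sorted(counts.items()):
            rows.append(d)
            cols.append(n)
            data.append(c)
    counts_mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(kept), len(vocab)), dtype=np.int64
    )
    return Corpus(vocab=vocab, counts=counts_mat)


def write_corpus(corpus: Corpus, count_file: str | Path, vocab_file: str | Path) -> None:
    """Write a corpus as a 1-based sparse triplet file plus a vocabulary file."""
    coo = corpus.counts.tocoo()
    with open(count_file, "w") as fh:
        fh.write(f"{corpus.num_docs} {corpus.num_words} {coo.nnz}\n")
        order = np.lexsort((coo.col, coo.row))
        for d, n, c in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{d + 1} {n + 1} {c}\n")
    with open(vocab_file, "w") as fh:
        for w in corpus.vocab:
            fh.write(w + "\n")


def read_corpus(count_file: str | Path, vocab_file: str | Path) -> Corpus:
    """Read a corpus written by :func:`write_corpus`.

    Malformed lines are reported with their 1-based line numbers.
    """
    with open(vocab_file) as fh:
        vocab = [line.rstrip("\n") for line in fh if line.strip() != ""]
    with open(count_file) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise CorpusError(f"{count_file}: empty count file")
    header = lines[0].split()
    if len(header) != 3:
        raise CorpusError(f"{count_file}:1: header must be 'D N NNZ'")
    try:
        D, N, nnz = (int(x) for x in header)
    except ValueError as exc:
        raise CorpusError(f"{count_file}:1: non-integer header: {exc}") from None
    body = [ln for ln in lines[1:] if ln.strip() != ""]
    if len(body) != nnz:
        raise CorpusError(
            f"{count_file}: header declares {nnz} triplets but found {len(body)}"
        )
    if len(vocab) != N:
        raise CorpusError(
            f"{vocab_file}: vocab length {len(vocab)} != declared N={N}"
        )
    rows = np.empty(nnz, dtype=np.int64)
    cols = np.empty(nnz, dtype=np.int64)
    data = np.empty(nnz, dtype=np.int64)
    for i, line in enumerate(body):
        lineno = i + 2
        parts = line.split()
        if len(parts) != 3:
            raise CorpusError(f"{count_file}:{lineno}: expected 'doc word count'")
        try:
            d, n, c = (int(x) for x in parts)
        except ValueError:
            raise CorpusError(f"{count_file}:{lineno}: non-integer field") from None
        if not (1 <= d <= D):
            raise CorpusError(f"{count_file}:{lineno}: document index {d} outside 1..{D}")
        if not (1 <= n <= N):
            raise CorpusError(f"{count_file}:{lineno}: word index {n} outside 1..{N}")
        if c < 0:
            raise CorpusError(f"{count_file}:{lineno}: negative count {c}")
        rows[i], cols[i], data[i] = d - 1, n - 1, c
    counts = sp.csr_matrix((data, (rows, cols)), shape=(D, N), dtype=np.int64)
    return Corpus(vocab=vocab, counts=counts)


def write_labels(labels: LabelSet, path: str | Path) -> None:
    """Write labels as 1-based ``doc class`` pairs, one per line."""
    with open(path, "w") as fh:
        for d, s in enumerate(labels.labels):
            for c in sorted(s):
                fh.write(f"{d + 1} {c}\n")


def read_labels(path: str | Path, num_docs: int, num_classes: int | None = None) -> LabelSet:
    """Read a 1-based ``doc class`` label file."""
    per_doc: list[set[int]] = [set() for _ in range(num_docs)]
    max_c = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.strip() == "":
                continue
            parts = line.split()
            if len(parts) != 2:
                raise CorpusError(f"{path}:{i + 1}: expected 'doc class'")
            try:
                d, c = int(parts[0]), int(parts[1])
            except ValueError:
                raise CorpusError(f"{path}:{i + 1}: non-integer field") from None
            if not (1 <= d <= num_docs):
                raise CorpusError(f"{path}:{i + 1}: document index {d} outside 1..{num_docs}")
            if c < 1:
                raise CorpusError(f"{path}:{i + 1}: class id {c} must be >= 1")
            per_doc[d - 1].add(c)
            max_c = max(max_c, c)
    C = num_classes if num_classes is not None else max_c
    return LabelSet(labels=[frozenset(s) for s in per_doc], num_classes=C)
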