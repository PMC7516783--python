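"""The parsimonious topic model: structure (switches), parameters, likelihood.

A model of order M over a corpus of D documents and N words consists of

* topic switches ``v`` (M x D): topic j participates in document d iff
  ``v[j, d] == 1``; every document keeps at least one active topic,
* word switches ``u`` (M x N): word n has a topic-specific probability
  ``beta[j, n]`` under topic j iff ``u[j, n] == 1``, otherwise it is emitted
  from the shared (universal) distribution ``beta0``,
* document-topic proportions ``alpha`` (M x D), a pmf over the active topics
  of each document,
* per-topic emission rows that mix topic-specific and shared probabilities:
  word n under topic j has probability ``beta[j, n]`` if the switch is open
  and ``beta0[n]`` otherwise; each such row sums to one.

``alpha`` entries are stored as exactly 0 wherever ``v`` is 0, and ``beta``
entries as exactly 0 wherever ``u`` is 0, so stale values can never leak
through switch flips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import Corpus

__all__ = [
    "ModelStructure",
    "ModelParams",
    "PTMModel",
    "ModelError",
    "word_prob",
    "log_likelihood",
    "validate",
    "save_model",
    "load_model",
]

_TOL = 1e-9

MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    """Raised for invalid model states or impossible likelihood evaluations."""


@dataclass
class ModelStructure:
    """Discrete model structure: order M plus topic and word switches."""

    v: np.ndarray  # (M, D) binary
    u: np.ndarray  # (M, N) binary

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.int8)
        self.u = np.asarray(self.u, dtype=np.int8)

    @property
    def M(self) -> int:
        return self.v.shape[0]

    @property
    def num_docs(self) -> int:
        return self.v.shape[1]

    @property
    def num_words(self) -> int:
        return self.u.shape[1]

    @property
    def Md(self) -> np.ndarray:
        """Number of active topics per document."""
        return self.v.sum(axis=0, dtype=np.int64)

    @property
    def Nj(self) -> np.ndarray:
        """Number of topic-specific words per topic."""
        return self.u.sum(axis=1, dtype=np.int64)

    def effective_sample_sizes(self, doc_lengths: np.ndarray) -> np.ndarray:
        """L̄j = Σd Ld·vjd, the token mass of documents where topic j is active."""
        return self.v.astype(np.int64) @ np.asarray(doc_lengths, dtype=np.int64)


@dataclass
class ModelParams:
    """Continuous parameters: proportions, topic-specific and shared pmfs."""

    alpha: np.ndarray  # (M, D)
    beta: np.ndarray  # (M, N); meaningful only where u == 1
    beta0: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.beta0 = np.asarray(self.beta0, dtype=float)


@dataclass
class PTMModel:
    structure: ModelStructure
    params: ModelParams

    @property
    def M(self) -> int:
        return self.structure.M

    def word_prob_matrix(self) -> np.ndarray:
        """(M, N) emission matrix: beta where the switch is open, beta0 otherwise."""
        s = self.structure
        return np.where(s.u == 1, self.params.beta, self.params.beta0[None, :])

    def copy(self) -> "PTMModel":
        return PTMModel(
            ModelStructure(self.structure.v.copy(), self.structure.u.copy()),
            ModelParams(
                self.params.alpha.copy(),
                self.params.beta.copy(),
                self.params.beta0.copy(),
            ),
        )


def word_prob(model: PTMModel, j: int, n: int) -> float:
    """Emission probability of word ``n`` under topic ``j``."""
    if not (0 <= j < model.structure.M):
        raise IndexError(f"topic index {j} out of range")
    if not (0 <= n < model.structure.num_words):
        raise IndexError(f"word index {n} out of range")
    if model.structure.u[j, n] == 1:
        return float(model.params.beta[j, n])
    return float(model.params.beta0[n])


def log_likelihood(model: PTMModel, corpus: Corpus) -> float:
    """Incomplete-data log-likelihood of the corpus under the model.

    Computes ``Σd Σn counts(d,n)·log Σj αjd·vjd·p(n|j)``. The inner mixture
    sum runs over at most M terms and is taken in linear space; a mixture
    probability of exactly 0 for an observed word is a hard error.
    """
    A = model.params.alpha * model.structure.v  # (M, D)
    WP = model.word_prob_matrix()  # (M, N)
    coo = corpus.counts.tocoo()
    mix = np.einsum("kd,kn->dn", A, WP)[coo.row, coo.col]
    bad = mix <= 0.0
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ModelError(
            "zero mixture probability for observed word: "
            f"document {int(coo.row[i])}, word {int(coo.col[i])}"
        )
    return float(np.sum(coo.data * np.log(mix)))


def validate(model: PTMModel, corpus: Corpus | None = None) -> list[str]:
    """Check all model invariants to tolerance 1e-9; return violations."""
    s, p = model.structure, model.params
    out: list[str] = []
    M, D = s.v.shape
    _, N = s.u.shape
    if p.alpha.shape != (M, D):
        out.append(f"alpha shape {p.alpha.shape} != {(M, D)}")
        return out
    if p.beta.shape != (M, N):
        out.append(f"beta shape {p.beta.shape} != {(M, N)}")
        return out
    if p.beta0.shape != (N,):
        out.append(f"beta0 shape {p.beta0.shape} != {(N,)}")
        return out
    if corpus is not None and (corpus.num_docs != D or corpus.num_words != N):
        out.append(
            f"corpus dims ({corpus.num_docs}, {corpus.num_words}) != model dims ({D}, {N})"
        )
    if not np.isin(s.v, (0, 1)).all():
        out.append("v contains non-binary entries")
    if not np.isin(s.u, (0, 1)).all():
        out.append("u contains non-binary entries")
    Md = s.Md
    for d in np.flatnonzero(Md < 1):
        out.append(f"document {d}: no active topic (Md = 0)")
    if (p.alpha < 0).any() or (p.beta < 0).any() or (p.beta0 < 0).any():
        out.append("negative probability parameters")
    # alpha is a pmf over each document's active topics, zero elsewhere
    col = (p.alpha * s.v).sum(axis=0)
    for d in np.flatnonzero((np.abs(col - 1.0) > _TOL) & (Md >= 1)):
        out.append(f"document {d}: active alpha sums to {col[d]:.12g}, not 1")
    if np.any(np.abs(p.alpha * (1 - s.v)) > _TOL):
        out.append("alpha nonzero where v = 0")
    # each topic's emission row is a pmf
    row = np.where(s.u == 1, p.beta, p.beta0[None, :]).sum(axis=1)
    for j in np.flatnonzero(np.abs(row - 1.0) > _TOL):
        out.append(f"topic {j}: emission row sums to {row[j]:.12g}, not 1")
    if np.any(np.abs(p.beta * (1 - s.u)) > _TOL):
        out.append("beta nonzero where u = 0")
    if abs(p.beta0.sum() - 1.0) > _TOL:
        out.append(f"beta0 sums to {p.beta0.sum():.12g}, not 1")
    if corpus is not None:
        lbar = s.effective_sample_sizes(corpus.doc_lengths)
        for j in np.flatnonzero((lbar == 0) & (s.Nj > 0)):
            out.append(f"topic {j}: open word switches but zero effective sample size")
    return out


def save_model(model: PTMModel, path: str | Path) -> None:
    """Serialize a model to a JSON file (switches and sparse entries only)."""
    s, p = model.structure, model.params
    v_idx = [np.flatnonzero(s.v[j]).tolist() for j in range(s.M)]
    u_idx = [np.flatnonzero(s.u[j]).tolist() for j in range(s.M)]
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "M": s.M,
        "D": s.num_docs,
        "N": s.num_words,
        "v_active_docs": v_idx,
        "u_open_words": u_idx,
        "alpha_active": [p.alpha[j, v_idx[j]].tolist() for j in range(s.M)],
        "beta_open": [p.beta[j, u_idx[j]].tolist() for j in range(s.M)],
        "beta0": p.beta0.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> PTMModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelError(f"unsupported model format version {payload.get('format_version')}")
    M, D, N = payload["M"], payload["D"], payload["N"]
    v = np.zeros((M, D), dtype=np.int8)
    u = np.zeros((M, N), dtype=np.int8)
    alpha = np.zeros((M, D))
    beta = np.zeros((M, N))
    for j in range(M):
        vd = np.asarray(payload["v_active_docs"][j], dtype=int)
        un = np.asarray(payload["u_open_words"][j], dtype=int)
        v[j, vd] = 1
        u[j, un] = 1
        alpha[j, vd] = payload["alpha_active"][j]
        beta[j, un] = payload["beta_open"][j]
    beta0 = np.asarray(payload["beta0"], dtype=float)
    return PTMModel(ModelStructure(v, u), ModelParams(alpha, beta, beta0))
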