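"""Customized BIC for the parsimonious topic model, and the naive BIC.

The objective is a description length: a structure prior for which topics are
present in each document, Laplace-approximation parameter costs with
per-parameter effective sample sizes, a word-switch coding cost, and the
negative data log-likelihood.  The word-switch cost distinguishes three
configurations of a word's switch column across the M topics:

* F1 (all closed) - the word is wholly uninformative; it costs only the
  shared parameter's ``(1/2)·log(ΣL̄j/2π)``,
* F2 (all open) - one topic-specific parameter per topic,
  ``(1/2)·Σj log(L̄j/2π)``,
* F3 (mixed) - the shared cost plus ``M·log 2`` to encode which switches are
  open plus ``(1/2)·log(L̄j/2π)`` per open switch.

The cheap F1 coding is what rewards declaring words wholly uninformative.
``word_cost_scheme="flat_mixed"`` prices every column with the F3 formula
(no all-closed or all-open discount) and exists as an ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .corpus import Corpus
from .model import ModelError, PTMModel, log_likelihood

__all__ = [
    "BICBreakdown",
    "word_switch_cost",
    "word_cost_total",
    "bic",
    "naive_bic",
    "log_binomial",
]

TWO_PI = 2.0 * np.pi
_LOG2 = np.log(2.0)


def log_binomial(M: int, k: np.ndarray | int) -> np.ndarray | float:
    """log C(M, k) via log-gamma."""
    k = np.asarray(k, dtype=float)
    out = gammaln(M + 1.0) - gammaln(k + 1.0) - gammaln(M - k + 1.0)
    return out if out.ndim else float(out)


@dataclass
class BICBreakdown:
    """Additive decomposition of the customized BIC."""

    order_cost: float  # D·log M
    topic_config_cost: float  # Σd log(#topic-switch configurations)
    alpha_cost: float  # (1/2)·Σd (Md−1)·log(Ld/2π)
    word_cost: float  # Σn word_switch_cost(u·n, L̄)
    neg_loglik: float  # −log p(data | H, Θ) or −E[Lc]

    @property
    def total(self) -> float:
        return (
            self.order_cost
            + self.topic_config_cost
            + self.alpha_cost
            + self.word_cost
            + self.neg_loglik
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "order_cost": self.order_cost,
            "topic_config_cost": self.topic_config_cost,
            "alpha_cost": self.alpha_cost,
            "word_cost": self.word_cost,
            "neg_loglik": self.neg_loglik,
            "total": self.total,
        }


def word_switch_cost(un: np.ndarray, lbar: np.ndarray, scheme: str = "modified") -> float:
    """Description-length cost of one word's switch column.

    Parameters
    ----------
    un:
        Length-M binary switch column for the word.
    lbar:
        Length-M effective sample sizes L̄j.
    scheme:
        ``"modified"`` for the three-case coding, ``"flat_mixed"`` to price
        every column with the mixed-case (F3) formula.
    """
    un = np.asarray(un)
    lbar = np.asarray(lbar, dtype=float)
    M = un.shape[0]
    if np.any((un == 1) & (lbar <= 0)):
        j = int(np.flatnonzero((un == 1) & (lbar <= 0))[0])
        raise ModelError(
            f"topic {j} has an open word switch but zero effective sample size"
        )
    total = float(lbar.sum())
    log_shared = 0.5 * np.log(total / TWO_PI)
    open_term = 0.5 * float(np.sum(np.where(un == 1, np.log(np.where(lbar > 0, lbar, 1.0) / TWO_PI), 0.0)))
    s = int(un.sum())
    if scheme == "flat_mixed":
        return log_shared + M * _LOG2 + open_term
    if scheme != "modified":
        raise ValueError(f"unknown word cost scheme {scheme!r}")
    if s == 0:  # F1: wholly uninformative
        return log_shared
    if s == M:  # F2: topic-specific everywhere
        return open_term
    return log_shared + M * _LOG2 + open_term  # F3: mixed


def word_cost_total(u: np.ndarray, lbar: np.ndarray, scheme: str = "modified") -> float:
    """Vectorized Σn word_switch_cost(u[:, n], lbar)."""
    u = np.asarray(u)
    lbar = np.asarray(lbar, dtype=float)
    M, N = u.shape
    if np.any((u == 1) & (lbar[:, None] <= 0)):
        j = int(np.flatnonzero(((u == 1) & (lbar[:, None] <= 0)).any(axis=1))[0])
        raise ModelError(
            f"topic {j} has open word switches but zero effective sample size"
        )
    log_shared = 0.5 * np.log(lbar.sum() / TWO_PI)
    l_safe = np.where(lbar > 0, np.log(np.where(lbar > 0, lbar, 1.0) / TWO_PI), 0.0)
    open_l = 0.5 * (u * l_safe[:, None]).sum(axis=0)  # per word
    sums = u.sum(axis=0)
    if scheme == "flat_mixed":
        return float(np.sum(log_shared + M * _LOG2 + open_l))
    f1 = sums == 0
    f2 = sums == M
    f3 = ~(f1 | f2)
    return float(
        f1.sum() * log_shared
        + open_l[f2].sum()
        + np.sum(log_shared + M * _LOG2 + open_l[f3])
    )


def bic(
    model: PTMModel,
    corpus: Corpus,
    neg_loglik_override: float | None = None,
    topic_config_prior: str = "binomial",
    word_cost_scheme: str = "modified",
) -> BICBreakdown:
    """Customized BIC of the model on the corpus.

    ``neg_loglik_override`` substitutes the expected complete-data negative
    log-likelihood for the exact one (used by the GEM machinery).
    ``topic_config_prior`` selects the per-document topic-subset coding:
    ``"binomial"`` charges ``log C(M, Md)``, ``"power"`` charges
    ``Md·log M``.
    """
    s = model.structure
    M, D = s.M, s.num_docs
    Ld = corpus.doc_lengths.astype(float)
    Md = s.Md
    lbar = s.effective_sample_sizes(corpus.doc_lengths).astype(float)
    order_cost = D * np.log(M)
    if topic_config_prior == "binomial":
        config_cost = float(np.sum(log_binomial(M, Md)))
    elif topic_config_prior == "power":
        config_cost = float(np.sum(Md * np.log(M)))
    else:
        raise ValueError(f"unknown topic_config_prior {topic_config_prior!r}")
    alpha_cost = 0.5 * float(np.sum((Md - 1) * np.log(Ld / TWO_PI)))
    wc = word_cost_total(s.u, lbar, scheme=word_cost_scheme)
    if neg_loglik_override is None:
        nll = -log_likelihood(model, corpus)
    else:
        nll = float(neg_loglik_override)
    return BICBreakdown(
        order_cost=float(order_cost),
        topic_config_cost=config_cost,
        alpha_cost=alpha_cost,
        word_cost=wc,
        neg_loglik=nll,
    )


def naive_bic(model: PTMModel, corpus: Corpus) -> float:
    """Classical ``K·log D − 2·log L̂`` with a flat per-parameter cost.

    Free parameters: ``Σd (Md−1)`` proportions, ``Σj Nj`` topic-specific word
    probabilities, and ``N−1`` shared probabilities.
    """
    s = model.structure
    K = int(np.sum(s.Md - 1)) + int(s.Nj.sum()) + (s.num_words - 1)
    return K * np.log(corpus.num_docs) - 2.0 * log_likelihood(model, corpus)
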