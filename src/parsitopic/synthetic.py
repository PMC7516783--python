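"""Synthetic corpora with planted switch structure, and recovery metrics.

The generator follows the model's own two-stage generative process: sample
the structure (which topics are active per document, which words are
topic-specific per topic, with a designated pool of noise words forced
all-closed), sample the parameters subject to the pmf constraints, then draw
each document's tokens by first picking a topic from the document's
proportions and then a word from that topic's emission row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from .corpus import Corpus
from .model import ModelParams, ModelStructure, PTMModel

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "match_topics",
    "recovery_metrics",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the recovery benchmark.

    Defaults are the desk-scale recovery configuration: 200 documents over a
    300-word vocabulary, 4 planted topics, document lengths uniform in
    [80, 120], each topic active in half the documents, 15% of eligible
    words topic-specific per topic, and half the vocabulary designated pure
    noise (all-closed under every topic).
    """

    D: int = 200
    N: int = 300
    M_true: int = 4
    doc_length_min: int = 80
    doc_length_max: int = 120
    p_topic_active: float = 0.5
    p_word_specific: float = 0.15
    frac_noise_words: float = 0.5
    alpha_concentration: float = 0.8
    beta_concentration: float = 25.0
    beta0_concentration: float = 1.0
    ratio_up: float = 12.0
    ratio_down: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.D, self.N, self.M_true) < 1:
            raise ValueError("D, N and M_true must all be >= 1")
        for p in (self.p_topic_active, self.p_word_specific, self.frac_noise_words):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if not (1 <= self.doc_length_min <= self.doc_length_max):
            raise ValueError("need 1 <= doc_length_min <= doc_length_max")
        if min(self.alpha_concentration, self.beta_concentration, self.beta0_concentration) <= 0:
            raise ValueError("concentrations must be > 0")
        if not (0 < self.ratio_down < 1 < self.ratio_up):
            raise ValueError("need ratio_down < 1 < ratio_up")


@dataclass
class GroundTruth:
    """Planted structure and parameters, plus the noise-word designation."""

    v: np.ndarray
    u: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    beta0: np.ndarray
    noise_words: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def as_model(self) -> PTMModel:
        return PTMModel(
            ModelStructure(self.v.copy(), self.u.copy()),
            ModelParams(self.alpha.copy(), self.beta.copy(), self.beta0.copy()),
        )


def generate(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Sample a corpus and its planted ground truth; deterministic in the seed.

    Any vocabulary word left unseen by the finite sample receives one extra
    token in a randomly chosen document so the corpus invariant (every word
    occurs somewhere) always holds; at the default scale this essentially
    never fires.
    """
    rng = np.random.default_rng(config.seed)
    D, N, M = config.D, config.N, config.M_true

    beta0 = rng.dirichlet(np.full(N, config.beta0_concentration))
    # Guard against zero shared probabilities (possible for tiny concentrations).
    beta0 = np.maximum(beta0, 1e-12)
    beta0 /= beta0.sum()

    # The noise pool (words all-closed under every topic) is the rare half of
    # the vocabulary: topic-specific candidates are drawn from frequent words,
    # where per-word evidence exists at desk scale.
    n_noise = int(round(config.frac_noise_words * N))
    noise_words = np.argsort(beta0, kind="stable")[:n_noise]
    eligible = np.setdiff1d(np.arange(N), noise_words)

    u = np.zeros((M, N), dtype=np.int8)
    if eligible.size:
        u[:, eligible] = (rng.random((M, eligible.size)) < config.p_word_specific).astype(np.int8)

    # Topic-specific emissions are planted with log-odds separated from the
    # shared model: each specific word is either enriched (ratio_up) or
    # depleted (ratio_down) relative to beta0, with the up-probability chosen
    # so the expected mass matches the pmf-constraint target; the Dirichlet
    # concentration controls the spread around that separated base pattern.
    p_up = (1.0 - config.ratio_down) / (config.ratio_up - config.ratio_down)
    beta = np.zeros((M, N))
    for j in range(M):
        open_idx = np.flatnonzero(u[j])
        if open_idx.size == 0:
            continue
        open_mass = float(beta0[open_idx].sum())  # pmf constraint fixes the scale
        if open_mass <= 0:
            raise ValueError(f"topic {j}: no probability mass left for specific words")
        up = rng.random(open_idx.size) < p_up
        target = beta0[open_idx] * np.where(up, config.ratio_up, config.ratio_down)
        target /= target.sum()
        draw = rng.dirichlet(np.maximum(
            config.beta_concentration * open_idx.size * target, 1e-3
        ))
        beta[j, open_idx] = draw * open_mass

    v = np.zeros((M, D), dtype=np.int8)
    for d in range(D):
        while True:
            row = (rng.random(M) < config.p_topic_active).astype(np.int8)
            if row.sum() >= 1:
                v[:, d] = row
                break

    alpha = np.zeros((M, D))
    for d in range(D):
        active = np.flatnonzero(v[:, d])
        alpha[active, d] = rng.dirichlet(np.full(active.size, config.alpha_concentration))

    WP = np.where(u == 1, beta, beta0[None, :])  # (M, N)
    lengths = rng.integers(config.doc_length_min, config.doc_length_max + 1, size=D)
    counts = np.zeros((D, N), dtype=np.int64)
    for d in range(D):
        topic_counts = rng.multinomial(lengths[d], alpha[:, d])
        for j in np.flatnonzero(topic_counts):
            counts[d] += rng.multinomial(topic_counts[j], WP[j])

    unseen = np.flatnonzero(counts.sum(axis=0) == 0)
    for n in unseen:
        counts[int(rng.integers(D)), n] += 1

    vocab = [f"w{n:04d}" for n in range(N)]
    corpus = Corpus(vocab=vocab, counts=sp.csr_matrix(counts))
    truth = GroundTruth(
        v=v, u=u, alpha=alpha, beta=beta, beta0=beta0, noise_words=np.sort(noise_words)
    )
    return corpus, truth


def _emission_rows(model: PTMModel) -> np.ndarray:
    return model.word_prob_matrix()


def match_topics(truth: GroundTruth | PTMModel, fitted: PTMModel) -> tuple[np.ndarray, np.ndarray]:
    """Optimal assignment of fitted topics to true topics.

    Minimizes the total variation distance between topic word distributions
    (optimal rectangular assignment).  Returns ``(mapping, distances)``:
    ``mapping[k] = (true_topic, fitted_topic)`` pairs and their TV distances.
    """
    true_model = truth.as_model() if isinstance(truth, GroundTruth) else truth
    P = _emission_rows(true_model)  # (Mt, N)
    Q = _emission_rows(fitted)  # (Mf, N)
    cost = 0.5 * np.abs(P[:, None, :] - Q[None, :, :]).sum(axis=2)  # TV distances
    rows, cols = linear_sum_assignment(cost)
    mapping = np.stack([rows, cols], axis=1)
    return mapping, cost[rows, cols]


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 1.0
    recall = tp / (tp + fn) if tp + fn > 0 else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def recovery_metrics(
    truth: GroundTruth,
    fitted: PTMModel,
    mapping: np.ndarray,
) -> dict:
    """Structure- and parameter-recovery report after topic matching.

    Reports pooled and per-topic word-switch precision/recall/F1, all-closed
    word detection (a word is detected uninformative iff its fitted column is
    entirely closed), topic-switch F1, and mean L1 errors of the matched
    emission rows and of the proportions.
    """
    true_model = truth.as_model()
    P = _emission_rows(true_model)
    Q = _emission_rows(fitted)
    tp = fp = fn = 0.0
    per_topic = []
    l1_beta = []
    v_tp = v_fp = v_fn = 0.0
    l1_alpha = []
    for t, f in mapping:
        ut, uf = truth.u[t], fitted.structure.u[f]
        t_tp = float(np.sum((ut == 1) & (uf == 1)))
        t_fp = float(np.sum((ut == 0) & (uf == 1)))
        t_fn = float(np.sum((ut == 1) & (uf == 0)))
        tp, fp, fn = tp + t_tp, fp + t_fp, fn + t_fn
        per_topic.append(_prf(t_tp, t_fp, t_fn))
        l1_beta.append(float(np.abs(P[t] - Q[f]).sum()))
        vt, vf = truth.v[t], fitted.structure.v[f]
        v_tp += float(np.sum((vt == 1) & (vf == 1)))
        v_fp += float(np.sum((vt == 0) & (vf == 1)))
        v_fn += float(np.sum((vt == 1) & (vf == 0)))
        l1_alpha.append(float(np.abs(truth.alpha[t] - fitted.params.alpha[f]).mean()))
    u_precision, u_recall, u_f1 = _prf(tp, fp, fn)
    _, _, v_f1 = _prf(v_tp, v_fp, v_fn)

    true_closed = truth.u.sum(axis=0) == 0
    fit_closed = fitted.structure.u.sum(axis=0) == 0
    c_tp = float(np.sum(true_closed & fit_closed))
    c_fp = float(np.sum(~true_closed & fit_closed))
    c_fn = float(np.sum(true_closed & ~fit_closed))
    closed_precision, closed_recall, closed_f1 = _prf(c_tp, c_fp, c_fn)

    return {
        "u_precision": u_precision,
        "u_recall": u_recall,
        "u_f1": u_f1,
        "u_per_topic": per_topic,
        "v_f1": v_f1,
        "all_closed_precision": closed_precision,
        "all_closed_recall": closed_recall,
        "all_closed_f1": closed_f1,
        "beta_l1_mean": float(np.mean(l1_beta)) if l1_beta else 0.0,
        "alpha_l1_mean": float(np.mean(l1_alpha)) if l1_alpha else 0.0,
    }
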