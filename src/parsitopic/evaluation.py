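"""Evaluation measures: document-completion held-out likelihood, label
purity, and multi-label precision/recall AUC.

The held-out protocol splits each test document's tokens into an observed
and a held-out sub-bag, infers topic proportions on the observed half with
the trained model's structure frozen (word switches, beta, beta0 fixed; all
topics allowed for the test document), then scores the held-out half under
the inferred mixture.

Note on precision/recall: the multi-label measures are computed, by default,
with precision = (correctly discovered labels) / (total ground-truth labels)
and recall = (correctly discovered labels) / (total labels assigned by the
classifier).  These are swapped relative to the usual convention; pass
``conventional_pr=True`` for the standard definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .corpus import Corpus, LabelSet
from .model import ModelError, PTMModel

logger = logging.getLogger(__name__)

__all__ = [
    "HeldoutSplit",
    "make_heldout_split",
    "infer_test_proportions",
    "heldout_loglik",
    "topic_class_profiles",
    "multilabel_pr_auc",
    "single_label_purity",
]


@dataclass
class HeldoutSplit:
    """Observed / held-out sub-bags of a test corpus."""

    observed: sp.csr_matrix  # (Dtest, N)
    heldout: sp.csr_matrix  # (Dtest, N)
    split_fraction: float
    seed: int


def make_heldout_split(corpus: Corpus, split_fraction: float = 0.5, seed: int = 0) -> HeldoutSplit:
    """Random per-document token split.

    ``round(split_fraction * Ld)`` tokens go to the observed half, clamped so
    that both halves are non-empty whenever ``Ld >= 2``.  Documents with a
    single token put it in the observed half (empty held-out half).
    """
    if not (0.0 < split_fraction < 1.0):
        raise ValueError("split_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    csr = corpus.counts
    D, N = csr.shape
    obs = sp.lil_matrix((D, N), dtype=np.int64)
    for d in range(D):
        lo, hi = csr.indptr[d], csr.indptr[d + 1]
        idx, cnt = csr.indices[lo:hi], csr.data[lo:hi]
        tokens = np.repeat(idx, cnt)
        Ld = tokens.size
        k = int(round(split_fraction * Ld))
        if Ld >= 2:
            k = min(max(k, 1), Ld - 1)
        else:
            k = Ld
        chosen = rng.permutation(Ld)[:k]
        picked = np.bincount(tokens[chosen], minlength=N)
        for n in np.flatnonzero(picked):
            obs[d, n] = picked[n]
    obs = obs.tocsr()
    held = csr - obs
    return HeldoutSplit(
        observed=obs, heldout=held.tocsr(), split_fraction=split_fraction, seed=seed
    )


def infer_test_proportions(
    model: PTMModel,
    observed_counts: sp.spmatrix | np.ndarray,
    rel_tol: float = 1e-6,
    max_iters: int = 200,
) -> np.ndarray:
    """Topic proportions for test documents from their observed sub-bags.

    The trained structure is frozen (u, beta, beta0 fixed) and every topic is
    allowed in each test document; only the proportions are estimated, by
    alternating the posterior E-step with the proportion update until the
    proportions stabilize.  Documents with an empty observed half are skipped
    with a warning and returned with uniform proportions.

    Returns an ``(M, Dtest)`` array of proportions.
    """
    X = np.asarray(
        observed_counts.todense() if sp.issparse(observed_counts) else observed_counts,
        dtype=float,
    )
    Dt, N = X.shape
    M = model.M
    WP = model.word_prob_matrix()  # (M, N)
    Ld = X.sum(axis=1)
    empty = Ld <= 0
    if empty.any():
        logger.warning("skipping %d test document(s) with empty observed half", int(empty.sum()))
    alpha = np.full((M, Dt), 1.0 / M)
    mask = X > 0
    for _ in range(max_iters):
        numer = alpha.T[:, None, :] * WP.T[None, :, :]  # (Dt, N, M)
        mix = numer.sum(axis=2)
        if np.any(mask & (mix <= 0)):
            d, n = np.argwhere(mask & (mix <= 0))[0]
            raise ModelError(f"observed word has zero probability: document {d}, word {n}")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = numer / np.where(mix > 0, mix, 1.0)[:, :, None]
        r[~mask] = 0.0
        m = np.einsum("dn,dnj->jd", X, r)
        new_alpha = np.where(empty[None, :], 1.0 / M, m / np.where(Ld > 0, Ld, 1.0)[None, :])
        if np.max(np.abs(new_alpha - alpha)) <= rel_tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    return alpha


def heldout_loglik(
    model: PTMModel,
    split: HeldoutSplit,
    alpha: np.ndarray | None = None,
) -> float:
    """Σ over held-out tokens of log Σj αjd·[ujn·βjn + (1−ujn)·β0n]."""
    if alpha is None:
        alpha = infer_test_proportions(model, split.observed)
    WP = model.word_prob_matrix()
    coo = split.heldout.tocoo()
    mix = np.einsum("jd,jn->dn", alpha, WP)[coo.row, coo.col]
    if np.any(mix <= 0):
        i = int(np.flatnonzero(mix <= 0)[0])
        raise ModelError(
            f"held-out token has zero mixture probability: document {int(coo.row[i])}, "
            f"word {int(coo.col[i])}"
        )
    return float(np.sum(coo.data * np.log(mix)))


def topic_class_profiles(
    model: PTMModel,
    labels: LabelSet,
    alpha: np.ndarray | None = None,
) -> np.ndarray:
    """Per-topic class pmf by proportion-weighted label frequency counting.

    ``p[j, c-1] ∝ Σd 1[c ∈ Cd]·|Cd|·αjd·vjd``; rows are normalized.  A topic
    with zero total weight gets a uniform profile with a warning.
    """
    if alpha is None:
        alpha = model.params.alpha
    weights = alpha * model.structure.v  # (M, D)
    M = model.M
    C = labels.num_classes
    sizes = labels.sizes().astype(float)
    member = np.zeros((labels.num_docs, C))
    for d, s in enumerate(labels.labels):
        for c in s:
            member[d, c - 1] = 1.0
    num = weights @ (member * sizes[:, None])  # (M, C)
    totals = num.sum(axis=1)
    profiles = np.empty((M, C))
    for j in range(M):
        if totals[j] <= 0:
            logger.warning("topic %d has zero label weight; using uniform profile", j)
            profiles[j] = 1.0 / C
        else:
            profiles[j] = num[j] / totals[j]
    return profiles


def multilabel_pr_auc(
    model: PTMModel,
    labels: LabelSet,
    thresholds: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    profiles: np.ndarray | None = None,
    conventional_pr: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Area under the threshold-swept precision/recall curve for multi-label
    document classification.

    Each document is scored ``score(c) = Σj αjd·pj(c)`` and assigned the
    labels whose score exceeds the threshold T; T sweeps the given grid
    (default 101 evenly spaced values in [0, 1]).  See the module docstring
    for the precision/recall definitions; an empty prediction set contributes
    a ratio of 0/0 for the assigned-label denominator, counted as 1.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if alpha is None:
        alpha = model.params.alpha
    if profiles is None:
        profiles = topic_class_profiles(model, labels, alpha=alpha)
    scores = alpha.T @ profiles  # (D, C)
    C = labels.num_classes
    member = np.zeros((labels.num_docs, C), dtype=bool)
    for d, s in enumerate(labels.labels):
        for c in s:
            member[d, c - 1] = True
    total_true = float(member.sum())
    rows = []
    for T in thresholds:
        pred = scores > T
        correct = float((pred & member).sum())
        assigned = float(pred.sum())
        over_truth = correct / total_true
        over_assigned = correct / assigned if assigned > 0 else 1.0
        if conventional_pr:
            precision, recall = over_assigned, over_truth
        else:
            precision, recall = over_truth, over_assigned
        rows.append((float(T), precision, recall))
    curve = pd.DataFrame(rows, columns=["threshold", "precision", "recall"])
    pts = curve.sort_values(["recall", "precision"]).drop_duplicates()
    rec = pts["recall"].to_numpy()
    prec = pts["precision"].to_numpy()
    if rec.size and rec[0] > 0.0:  # anchor so a one-point curve has area
        rec = np.concatenate([[0.0], rec])
        prec = np.concatenate([[prec[0]], prec])
    auc = float(np.trapezoid(prec, rec))
    return min(max(auc, 0.0), 1.0), curve


def single_label_purity(
    model: PTMModel,
    labels: LabelSet,
    alpha: np.ndarray | None = None,
) -> float:
    """Clustering purity with dominant-topic hard assignment.

    Each document is assigned to ``argmax_j αjd·vjd``; each topic is mapped
    to the most frequent true class among its documents; purity is the
    fraction of documents whose topic's class matches their own.
    """
    if alpha is None:
        alpha = model.params.alpha
    weights = alpha * model.structure.v
    assignment = np.argmax(weights, axis=0)  # (D,)
    doc_class = np.array([min(s) for s in labels.labels])  # single-label expected
    correct = 0
    for j in range(model.M):
        docs = np.flatnonzero(assignment == j)
        if docs.size == 0:
            continue
        classes, counts = np.unique(doc_class[docs], return_counts=True)
        majority = classes[np.argmax(counts)]
        correct += int(np.sum(doc_class[docs] == majority))
    return correct / labels.num_docs
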