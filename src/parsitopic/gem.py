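"""Generalized EM for the parsimonious topic model at fixed order M.

One outer iteration is:

1. E-step: posterior responsibilities of each topic for every observed
   (document, word) pair.
2. Parameter M-step: closed-form updates of the proportions ``alpha`` and
   the topic-specific probabilities ``beta`` (the shared ``beta0`` is
   estimated once from global frequencies and frozen).
3. Word-switch sweep: for each word, the whole switch column across topics
   is re-chosen to minimize the expected-complete-data BIC (exhaustively
   over feasible configurations when 2^M is small, greedily otherwise).
4. Topic-switch sweep: each ``v[j, d]`` is tentatively flipped; a close
   renormalizes the document's responsibilities and proportions over the
   remaining active topics, an open gives the new topic the pseudo
   proportion 1/Md before renormalization.  Flips are kept only on strict
   objective decrease.

Discrete moves are scored, and the trace is recorded, on the variational
(free-energy) form of the expected BIC:

    F = penalties − E[Lc] − H(r),

where ``E[Lc]`` is the expected complete-data log-likelihood and ``H(r)``
the token-weighted entropy of the topic attributions.  For moves that keep
the responsibilities fixed (parameter updates, word-switch changes) the
entropy is a constant and F ranks candidates exactly like the plain
expected BIC; for topic-switch closes, which restrict and renormalize a
document's responsibilities, the entropy term is what makes the comparison
consistent — without it a close would be credited with the attribution
entropy of the document (≈ Ld·log 2 for two equally likely topics) even
when the data likelihood is unchanged.  Right after each E-step F equals
the true BIC, every phase of an outer iteration can only lower F, and the
E-step itself minimizes F over r, so the recorded sequence is non-
increasing across phases *and* across iterations.

Cold starts are initialized by a shrinkage-regularized EM warmup (see
``_initial_model``) so that the topics have differentiated before the
structure search starts pruning switches; the all-closed state is a fixed
point of the iteration, so structure search from undifferentiated topics
would collapse immediately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bic import TWO_PI, BICBreakdown, bic, log_binomial, word_cost_total
from .corpus import Corpus
from .model import ModelError, ModelParams, ModelStructure, PTMModel

logger = logging.getLogger(__name__)

__all__ = [
    "Responsibilities",
    "FitConfig",
    "FitTrace",
    "e_step",
    "expected_complete_loglik",
    "expected_complete_bic",
    "attribution_entropy",
    "free_energy_bic",
    "update_alpha",
    "update_beta",
    "init_beta0",
    "update_word_switches_for_word",
    "update_topic_switches",
    "fit",
]

_LOG2 = np.log(2.0)
_FLIP_TOL = 1e-10  # strict-decrease threshold for accepting a switch change


@dataclass
class Responsibilities:
    """Posterior topic-of-origin probabilities.

    ``r[d, n, j]`` is the probability that topic j generated word n in
    document d; rows sum to one over j wherever ``counts(d, n) > 0`` and are
    identically zero elsewhere (all tokens of the same word in a document
    share one posterior).
    """

    r: np.ndarray  # (D, N, M)


@dataclass
class FitConfig:
    """Knobs for the GEM fit. All randomness flows from ``seed``."""

    max_outer_iters: int = 60
    max_switch_sweeps: int = 20
    burn_in_iters: int = 0
    burn_in_shrinkage: float = 0.05
    rel_tol: float = 1e-6
    seed: int = 0
    init_scheme: str = "nmf"
    init_noise: float = 0.5
    init_blend: float = 0.7
    topic_config_prior: str = "binomial"
    word_cost_scheme: str = "modified"

    def __post_init__(self) -> None:
        if self.max_outer_iters < 1 or self.max_switch_sweeps < 1:
            raise ValueError("iteration caps must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")
        if self.burn_in_iters < 0:
            raise ValueError("burn_in_iters must be >= 0")


@dataclass
class FitTrace:
    """Per-outer-iteration expected-BIC values and switch-change counts."""

    bic_after_e: list[float] = field(default_factory=list)
    bic_after_m: list[float] = field(default_factory=list)
    bic_after_u: list[float] = field(default_factory=list)
    bic_after_v: list[float] = field(default_factory=list)
    true_bic: list[float] = field(default_factory=list)
    u_changes: list[int] = field(default_factory=list)
    v_changes: list[int] = field(default_factory=list)
    converged: bool = False
    message: str = ""

    @property
    def n_iters(self) -> int:
        return len(self.bic_after_e)

    def phase_sequence(self) -> list[float]:
        """Expected-BIC values in phase order, grouped by iteration."""
        out: list[float] = []
        for i in range(self.n_iters):
            out.extend(
                [self.bic_after_e[i], self.bic_after_m[i], self.bic_after_u[i], self.bic_after_v[i]]
            )
        return out


def init_beta0(corpus: Corpus) -> np.ndarray:
    """Shared word pmf from global frequency counts; never updated afterwards."""
    col = np.asarray(corpus.counts.sum(axis=0), dtype=float).ravel()
    return col / col.sum()


def e_step(model: PTMModel, corpus: Corpus) -> Responsibilities:
    """Posterior responsibilities under the current model."""
    A = model.params.alpha * model.structure.v  # (M, D)
    WP = model.word_prob_matrix()  # (M, N)
    X = corpus.dense()
    mask = X > 0
    numer = A.T[:, None, :] * WP.T[None, :, :]  # (D, N, M)
    mix = numer.sum(axis=2)
    bad = mask & (mix <= 0.0)
    if bad.any():
        d, n = np.argwhere(bad)[0]
        raise ModelError(
            f"zero posterior denominator for observed word: document {d}, word {n}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = numer / np.where(mix > 0, mix, 1.0)[:, :, None]
    r[~mask] = 0.0
    return Responsibilities(r=r)


def expected_complete_loglik(model: PTMModel, corpus: Corpus, resp: Responsibilities) -> float:
    """E[Lc] = Σd Σn counts·Σj r·(log αjd + ujn·log βjn + (1−ujn)·log β0n).

    Terms with zero responsibility contribute zero; positive responsibility
    paired with a zero probability parameter is an error.
    """
    X = corpus.dense()
    A = model.params.alpha * model.structure.v
    WP = model.word_prob_matrix()
    m = np.einsum("dn,dnj->jd", X, resp.r)  # responsibility mass per (topic, doc)
    S = np.einsum("dn,dnj->jn", X, resp.r)  # responsibility-weighted counts
    if np.any((m > 0) & (A <= 0)):
        j, d = np.argwhere((m > 0) & (A <= 0))[0]
        raise ModelError(f"positive responsibility with zero proportion: topic {j}, document {d}")
    if np.any((S > 0) & (WP <= 0)):
        j, n = np.argwhere((S > 0) & (WP <= 0))[0]
        raise ModelError(f"positive responsibility with zero word probability: topic {j}, word {n}")
    la = np.where(A > 0, np.log(np.where(A > 0, A, 1.0)), 0.0)
    lw = np.where(WP > 0, np.log(np.where(WP > 0, WP, 1.0)), 0.0)
    return float(np.sum(m * la) + np.sum(S * lw))


def expected_complete_bic(
    model: PTMModel,
    corpus: Corpus,
    resp: Responsibilities,
    topic_config_prior: str = "binomial",
    word_cost_scheme: str = "modified",
) -> BICBreakdown:
    """BIC with the expected complete-data log-likelihood in place of the exact one."""
    elc = expected_complete_loglik(model, corpus, resp)
    return bic(
        model,
        corpus,
        neg_loglik_override=-elc,
        topic_config_prior=topic_config_prior,
        word_cost_scheme=word_cost_scheme,
    )


def attribution_entropy(corpus: Corpus, resp: Responsibilities) -> float:
    """Token-weighted entropy of the topic attributions: −Σ counts·Σj r·log r."""
    r = resp.r
    with np.errstate(divide="ignore", invalid="ignore"):
        rlogr = np.where(r > 0, r * np.log(np.where(r > 0, r, 1.0)), 0.0)
    return float(-np.einsum("dn,dnj->", corpus.dense(), rlogr))


def free_energy_bic(
    model: PTMModel,
    corpus: Corpus,
    resp: Responsibilities,
    topic_config_prior: str = "binomial",
    word_cost_scheme: str = "modified",
) -> float:
    """Variational BIC bound: penalties − E[Lc] − H(r).

    Equals the true BIC when ``resp`` is the exact posterior under the
    model, and upper-bounds it otherwise; this is the quantity the GEM
    descends and the trace records.
    """
    elc = expected_complete_loglik(model, corpus, resp)
    ent = attribution_entropy(corpus, resp)
    return bic(
        model,
        corpus,
        neg_loglik_override=-(elc + ent),
        topic_config_prior=topic_config_prior,
        word_cost_scheme=word_cost_scheme,
    ).total


def update_alpha(resp: Responsibilities, structure: ModelStructure, corpus: Corpus) -> np.ndarray:
    """Closed-form proportion update: responsibility mass normalized per document."""
    X = corpus.dense()
    m = np.einsum("dn,dnj->jd", X, resp.r) * structure.v
    denom = m.sum(axis=0)
    if np.any(denom <= 0):
        d = int(np.flatnonzero(denom <= 0)[0])
        raise ModelError(f"document {d} has zero total responsibility mass")
    return m / denom


def update_beta(
    resp: Responsibilities,
    structure: ModelStructure,
    corpus: Corpus,
    beta0: np.ndarray,
) -> np.ndarray:
    """Closed-form topic-specific word probabilities.

    For each topic the open words share the probability mass left over by the
    shared model on its closed words (``1 − Σ closed β0``), in proportion to
    their responsibility-weighted counts.
    """
    X = corpus.dense()
    S = np.einsum("dn,dnj->jn", X, resp.r)
    M, N = structure.u.shape
    beta = np.zeros((M, N))
    for j in range(M):
        open_mask = structure.u[j] == 1
        if not open_mask.any():
            continue
        open_b0 = float(beta0[open_mask].sum())
        if open_b0 <= 0:
            raise ModelError(
                f"topic {j}: shared mass of closed words is >= 1; no mass left for open words"
            )
        mass = float(S[j, open_mask].sum())
        if mass <= 0:
            raise ModelError(
                f"topic {j}: open word switches but zero responsibility mass on open words"
            )
        mu = mass / open_b0
        beta[j, open_mask] = S[j, open_mask] / mu
    return beta


# ---------------------------------------------------------------------------
# Word-switch (u) search


class _WordSwitchSearch:
    """Joint per-word switch-column search over topics.

    Maintains per-topic aggregates of the emission part of the expected
    complete-data log-likelihood so that re-normalizing a topic's beta row
    after a switch change can be scored in O(1):

        E_j = Σ_open S·log S + A_j·log(openB0_j / A_j) + Σ_closed S·log β0,

    where ``S`` are responsibility-weighted counts, ``A_j`` their sum over
    the topic's open words, and ``openB0_j`` the shared-model mass of the
    open words (the Lagrangian normalization makes β = S·openB0/A).
    """

    def __init__(
        self,
        structure: ModelStructure,
        S: np.ndarray,
        beta0: np.ndarray,
        lbar: np.ndarray,
        scheme: str = "modified",
        exhaustive_limit: int = 6,
    ) -> None:
        self.u = structure.u
        self.S = S
        self.beta0 = beta0
        self.lbar = np.asarray(lbar, dtype=float)
        self.scheme = scheme
        self.exhaustive_limit = exhaustive_limit
        self.M, self.N = self.u.shape
        with np.errstate(divide="ignore", invalid="ignore"):
            self.SlogS = np.where(S > 0, S * np.log(np.where(S > 0, S, 1.0)), 0.0)
        self.Slogb0 = S * np.log(beta0)[None, :]
        open_mask = self.u == 1
        self.openB0 = (open_mask * beta0[None, :]).sum(axis=1)
        self.A = (open_mask * S).sum(axis=1)
        self.G = (open_mask * self.SlogS).sum(axis=1)
        self.B = ((~open_mask) * self.Slogb0).sum(axis=1)
        self.cnt = open_mask.sum(axis=1)
        self.log_shared = 0.5 * np.log(self.lbar.sum() / TWO_PI)
        self.lhalf = 0.5 * np.where(
            self.lbar > 0, np.log(np.where(self.lbar > 0, self.lbar, 1.0) / TWO_PI), 0.0
        )
        self.changed_topics: set[int] = set()

    @staticmethod
    def _emission(cnt: np.ndarray, A: np.ndarray, openB0: np.ndarray,
                  G: np.ndarray, B: np.ndarray) -> np.ndarray:
        out = B.copy()
        has_open = cnt > 0
        ok = has_open & (A > 0)
        out[ok] = G[ok] + A[ok] * np.log(openB0[ok] / A[ok]) + B[ok]
        deg = has_open & (A <= 0)  # degenerate incumbent: all open words massless
        out[deg] = G[deg] + B[deg]
        return out

    def _wsc(self, n_open_total: np.ndarray, open_l: np.ndarray) -> np.ndarray:
        """Vectorized word-switch cost for candidate columns."""
        if self.scheme == "flat_mixed":
            return self.log_shared + self.M * _LOG2 + open_l
        out = np.full(n_open_total.shape, self.log_shared + self.M * _LOG2) + open_l
        out[n_open_total == 0] = self.log_shared
        out[n_open_total == self.M] = open_l[n_open_total == self.M]
        return out

    def column_score_parts(self, n: int):
        """Per-topic emission values for closed/open states of word n's switch."""
        cur = self.u[:, n].astype(bool)
        Sn = self.S[:, n]
        b0n = self.beta0[n]
        exB0 = self.openB0 - np.where(cur, b0n, 0.0)
        exA = self.A - np.where(cur, Sn, 0.0)
        exG = self.G - np.where(cur, self.SlogS[:, n], 0.0)
        exB = self.B - np.where(~cur, self.Slogb0[:, n], 0.0)
        excnt = self.cnt - cur.astype(int)
        E0 = self._emission(excnt, exA, exB0, exG, exB + self.Slogb0[:, n])
        E1 = self._emission(excnt + 1, exA + Sn, exB0 + b0n, exG + self.SlogS[:, n], exB)
        return cur, Sn, E0, E1, exA, excnt

    def best_column(self, n: int) -> tuple[np.ndarray, float]:
        """Minimum-expected-BIC switch column for word n and its score delta.

        The incumbent column is always a scored candidate, so the returned
        delta is <= 0.  A candidate may not open a switch on a topic with
        zero effective sample size or zero responsibility mass for the word,
        and may not leave a topic whose other open words are all massless.
        """
        cur, Sn, E0, E1, exA, excnt = self.column_score_parts(n)
        feas_open = (self.lbar >= 1) & (Sn > 0)
        # Closing word n under topic j must not strand massless open words.
        close_ok = ~((excnt > 0) & (exA <= 0))
        dE = E1 - E0

        def score(col: np.ndarray) -> float:
            open_l = float((col * self.lhalf).sum())  # (1/2)·Σ_open log(L̄j/2π)
            return float(
                self._wsc(np.array([col.sum()]), np.array([open_l]))[0]
                - (col * dE).sum()
            )

        base_cur = score(cur.astype(int))
        fidx = np.flatnonzero(feas_open)
        f = len(fidx)
        best_col = cur.astype(int)
        best_score = base_cur
        if f > 0 and f <= self.exhaustive_limit:
            patterns = np.arange(2 ** f)[:, None] >> np.arange(f)[None, :] & 1  # (2^f, f)
            cols = np.zeros((2 ** f, self.M), dtype=int)
            cols[:, fidx] = patterns
            open_l = (cols * self.lhalf[None, :]).sum(axis=1)
            totals = cols.sum(axis=1)
            scores = self._wsc(totals, open_l) - cols @ dE
            # enforce close feasibility: columns closing an infeasible-to-close switch
            closing_bad = ((cur.astype(int) - cols) == 1) & ~close_ok[None, :]
            scores[closing_bad.any(axis=1)] = np.inf
            k = int(np.argmin(scores))
            if scores[k] < best_score:
                best_score = float(scores[k])
                best_col = cols[k]
        elif f > 0:
            # Greedy per-topic improvement from the (feasibility-corrected) incumbent.
            col = (cur & feas_open).astype(int)
            if np.any(cur & ~feas_open & ~close_ok):
                col = cur.astype(int)  # cannot legally correct; stay put
            cur_score = score(col)
            for _ in range(self.M):
                improved = False
                for j in fidx:
                    cand = col.copy()
                    cand[j] = 1 - cand[j]
                    if cand[j] == 0 and not close_ok[j]:
                        continue
                    s = score(cand)
                    if s < cur_score - _FLIP_TOL:
                        col, cur_score = cand, s
                        improved = True
                if not improved:
                    break
            if cur_score < best_score:
                best_score, best_col = cur_score, col
        return best_col, best_score - base_cur

    def install(self, n: int, col: np.ndarray) -> None:
        cur = self.u[:, n].astype(bool)
        new = col.astype(bool)
        changed = np.flatnonzero(cur != new)
        if changed.size == 0:
            return
        Sn = self.S[:, n]
        b0n = self.beta0[n]
        for j in changed:
            if new[j]:
                self.openB0[j] += b0n
                self.A[j] += Sn[j]
                self.G[j] += self.SlogS[j, n]
                self.B[j] -= self.Slogb0[j, n]
                self.cnt[j] += 1
            else:
                self.openB0[j] -= b0n
                self.A[j] -= Sn[j]
                self.G[j] -= self.SlogS[j, n]
                self.B[j] += self.Slogb0[j, n]
                self.cnt[j] -= 1
            self.changed_topics.add(int(j))
        self.u[:, n] = col.astype(np.int8)

    def rebuild_beta(self, beta: np.ndarray, topics=None) -> None:
        """Re-normalize beta rows of the given (or all changed) topics."""
        topics = self.changed_topics if topics is None else topics
        for j in topics:
            open_mask = self.u[j] == 1
            beta[j, :] = 0.0
            if not open_mask.any():
                continue
            if self.A[j] <= 0:
                raise ModelError(f"topic {j}: open switches with zero responsibility mass")
            beta[j, open_mask] = self.S[j, open_mask] * (self.openB0[j] / self.A[j])

    def _column_cost(self, n: int) -> float:
        col = self.u[:, n].astype(int)
        open_l = float((col * self.lhalf).sum())
        return float(self._wsc(np.array([col.sum()]), np.array([open_l]))[0])

    def pair_open(self, j: int, n_candidates: int = 15) -> float:
        """Try to open the best PAIR of words for a topic with no open words.

        A single open switch carries zero likelihood gain: the pmf constraint
        forces its beta to equal beta0 when it is the topic's only open word.
        The search over one column at a time therefore cannot leave the
        all-closed state; mass must be re-allocated between at least two
        words (one enriched, one depleted).  Returns the accepted (negative)
        delta, or 0.0 if no pair improves the objective.
        """
        if self.cnt[j] != 0 or self.lbar[j] < 1:
            return 0.0
        Sj = self.S[j]
        Tj = float(Sj.sum())
        if Tj <= 0:
            return 0.0
        expected = self.beta0 * Tj  # attribution under the shared model
        with np.errstate(divide="ignore"):
            t = np.where((Sj > 0) & (expected > 0), Sj / np.where(expected > 0, expected, 1.0), np.nan)
        valid = np.isfinite(t)
        if valid.sum() < 2:
            return 0.0
        order = np.argsort(np.where(valid, np.abs(np.log(np.where(valid, t, 1.0))), -np.inf))
        cand = order[-min(2 * n_candidates, int(valid.sum())):]
        best = (0.0, None)
        for ia, a in enumerate(cand):
            for b in cand[ia + 1:]:
                Sa, Sb = Sj[a], Sj[b]
                if Sa <= 0 or Sb <= 0:
                    continue
                mass = self.beta0[a] + self.beta0[b]
                scale = mass / (Sa + Sb)
                dE = (
                    Sa * np.log(Sa * scale / self.beta0[a])
                    + Sb * np.log(Sb * scale / self.beta0[b])
                )
                old_cost = self._column_cost(int(a)) + self._column_cost(int(b))
                ca = self.u[:, a].astype(int).copy()
                cb = self.u[:, b].astype(int).copy()
                self.u[j, a] = 1
                self.u[j, b] = 1
                new_cost = self._column_cost(int(a)) + self._column_cost(int(b))
                self.u[:, a] = ca
                self.u[:, b] = cb
                delta = (new_cost - old_cost) - dE
                if delta < best[0]:
                    best = (delta, (int(a), int(b)))
        if best[1] is None or best[0] >= -_FLIP_TOL:
            return 0.0
        a, b = best[1]
        for n in (a, b):
            col = self.u[:, n].astype(int)
            col[j] = 1
            self.install(n, col)
        return best[0]

    def sweep(self, word_order: np.ndarray, max_sweeps: int) -> tuple[float, int]:
        total_delta = 0.0
        total_changed = 0
        for _ in range(max_sweeps):
            changed_this = 0
            for n in word_order:
                col, delta = self.best_column(int(n))
                if delta < -_FLIP_TOL:
                    self.install(int(n), col)
                    total_delta += delta
                    changed_this += 1
            # rescue topics stuck in the all-closed minimum
            for j in range(self.M):
                if self.cnt[j] == 0:
                    delta = self.pair_open(j)
                    if delta < 0:
                        total_delta += delta
                        changed_this += 1
            total_changed += changed_this
            if changed_this == 0:
                break
        return total_delta, total_changed


def _resp_weighted_counts(corpus: Corpus, resp: Responsibilities) -> np.ndarray:
    return np.einsum("dn,dnj->jn", corpus.dense(), resp.r)


def update_word_switches_for_word(
    model: PTMModel,
    corpus: Corpus,
    resp: Responsibilities,
    n: int,
    word_cost_scheme: str = "modified",
    exhaustive_limit: int = 6,
) -> float:
    """Jointly re-choose word n's switch column; install the best candidate.

    Candidates are all-closed, all-open, and mixed configurations; with
    ``2^M <= 2**exhaustive_limit`` the search is exhaustive over feasible
    configurations.  Affected beta rows are re-normalized before scoring.
    Returns the (non-positive) expected-BIC change.
    """
    S = _resp_weighted_counts(corpus, resp)
    lbar = model.structure.effective_sample_sizes(corpus.doc_lengths)
    search = _WordSwitchSearch(
        model.structure, S, model.params.beta0, lbar,
        scheme=word_cost_scheme, exhaustive_limit=exhaustive_limit,
    )
    col, delta = search.best_column(n)
    if delta < -_FLIP_TOL:
        search.install(n, col)
        search.rebuild_beta(model.params.beta)
        return delta
    return 0.0


# ---------------------------------------------------------------------------
# Topic-switch (v) search


def update_topic_switches(
    model: PTMModel,
    corpus: Corpus,
    resp: Responsibilities,
    max_sweeps: int = 20,
    topic_config_prior: str = "binomial",
    word_cost_scheme: str = "modified",
) -> tuple[float, int]:
    """Sweep all topic switches ``v[j, d]``; accept strict objective drops.

    Candidates are scored on the free-energy BIC (see module docstring).
    Closing a topic in a document renormalizes that document's
    responsibilities and proportions over the remaining active topics (beta
    stays fixed until the next parameter M-step); opening gives the topic
    the pseudo-proportion ``1/Md_new`` before renormalization.  Modifies the
    model and ``resp`` in place and returns (total delta, accepted flips).
    """
    s, p = model.structure, model.params
    M, D = s.v.shape
    N = s.num_words
    X = corpus.dense()
    Ld = corpus.doc_lengths.astype(float)
    r = resp.r
    WP = model.word_prob_matrix()
    LW = np.where(WP > 0, np.log(np.where(WP > 0, WP, 1.0)), 0.0)
    m = np.einsum("dn,dnj->jd", X, r)
    lbar = s.effective_sample_sizes(corpus.doc_lengths).astype(float)
    Md = s.Md.astype(int)
    Nj = s.Nj.astype(float)
    sums = s.u.sum(axis=0)
    if word_cost_scheme == "flat_mixed":
        n_shared, n_mixed = float(N), float(N)
    else:
        n_shared = float(np.sum(sums == 0) + np.sum((sums > 0) & (sums < M)))
        n_mixed = float(np.sum((sums > 0) & (sums < M)))

    def wc_total(lbar_vec: np.ndarray) -> float:
        log_shared = 0.5 * np.log(lbar_vec.sum() / TWO_PI)
        l_safe = np.where(lbar_vec > 0, np.log(np.where(lbar_vec > 0, lbar_vec, 1.0) / TWO_PI), 0.0)
        return float(n_shared * log_shared + n_mixed * M * _LOG2 + 0.5 * np.sum(l_safe * Nj))

    def cfg_cost(md: int) -> float:
        if topic_config_prior == "power":
            return md * np.log(M)
        return float(log_binomial(M, md))

    doc_nz = [None] * D
    csr = corpus.counts
    for d in range(D):
        lo, hi = csr.indptr[d], csr.indptr[d + 1]
        doc_nz[d] = (csr.indices[lo:hi], csr.data[lo:hi].astype(float))

    wc_cur = wc_total(lbar)
    total_delta = 0.0
    flips = 0
    for _ in range(max_sweeps):
        accepted = 0
        for d in range(D):
            idx, cnt = doc_nz[d]
            for j in range(M):
                if s.v[j, d] == 1:
                    if Md[d] < 2:
                        continue
                    new_lbar_j = lbar[j] - Ld[d]
                    if new_lbar_j <= 0 and Nj[j] > 0:
                        continue  # would strand topic-specific words with no sample
                    rj = r[d, idx, j]
                    if np.any(rj >= 1.0 - 1e-12):
                        continue  # some word's posterior sits entirely on topic j
                    rmat = r[d, idx, :]
                    lw = LW[:, idx].T  # (k, M)
                    new_r = rmat.copy()
                    new_r[:, j] = 0.0
                    new_r /= (1.0 - rj)[:, None]
                    d_em = float(cnt @ ((new_r - rmat) * lw).sum(axis=1))
                    with np.errstate(divide="ignore", invalid="ignore"):
                        h_cur = -np.where(rmat > 0, rmat * np.log(np.where(rmat > 0, rmat, 1.0)), 0.0).sum(axis=1)
                        h_new = -np.where(new_r > 0, new_r * np.log(np.where(new_r > 0, new_r, 1.0)), 0.0).sum(axis=1)
                    d_H = float(cnt @ (h_new - h_cur))
                    a = p.alpha[:, d]
                    if a[j] >= 1.0 - 1e-12:
                        new_a = np.zeros(M)
                        rest = np.flatnonzero((s.v[:, d] == 1) & (np.arange(M) != j))
                        new_a[rest] = 1.0 / rest.size
                    else:
                        new_a = a / (1.0 - a[j])
                        new_a[j] = 0.0
                    m_new = cnt @ new_r
                    if np.any((m_new > 0) & (new_a <= 0)):
                        continue
                    m_cur = m[:, d]
                    T_new = float(np.sum(np.where(m_new > 0, m_new * np.log(np.where(new_a > 0, new_a, 1.0)), 0.0)))
                    T_cur = float(np.sum(np.where(m_cur > 0, m_cur * np.log(np.where(a > 0, a, 1.0)), 0.0)))
                    lbar_cand = lbar.copy()
                    lbar_cand[j] = new_lbar_j
                    wc_new = wc_total(lbar_cand)
                    delta = (
                        -0.5 * np.log(Ld[d] / TWO_PI)
                        + cfg_cost(Md[d] - 1) - cfg_cost(Md[d])
                        + wc_new - wc_cur
                        - (d_em + (T_new - T_cur) + d_H)
                    )
                    if delta < -_FLIP_TOL:
                        s.v[j, d] = 0
                        p.alpha[:, d] = new_a
                        r[d, idx, :] = new_r
                        m[:, d] = m_new
                        lbar[j] = new_lbar_j
                        Md[d] -= 1
                        wc_cur = wc_new
                        total_delta += delta
                        accepted += 1
                else:
                    md_new = Md[d] + 1
                    a = p.alpha[:, d]
                    scale = 1.0 / (1.0 + 1.0 / md_new)
                    new_a = a * scale
                    new_a[j] = (1.0 / md_new) * scale
                    m_cur = m[:, d]
                    T_delta = float(m_cur.sum()) * np.log(scale)
                    lbar_cand = lbar.copy()
                    lbar_cand[j] = lbar[j] + Ld[d]
                    wc_new = wc_total(lbar_cand)
                    delta = (
                        0.5 * np.log(Ld[d] / TWO_PI)
                        + cfg_cost(md_new) - cfg_cost(Md[d])
                        + wc_new - wc_cur
                        - T_delta
                    )
                    if delta < -_FLIP_TOL:
                        s.v[j, d] = 1
                        p.alpha[:, d] = new_a
                        lbar[j] += Ld[d]
                        Md[d] = md_new
                        wc_cur = wc_new
                        total_delta += delta
                        accepted += 1
        flips += accepted
        if accepted == 0:
            break
    return total_delta, flips


# ---------------------------------------------------------------------------
# Full fit


def _initial_model(corpus: Corpus, M: int, config: FitConfig) -> PTMModel:
    """Richest-structure start: all switches open, topics seeded by a
    continuous admixture decomposition, optionally refined by a
    shrinkage-regularized EM warmup.

    The default ``"nmf"`` scheme runs a KL-divergence NMF (the maximum-
    likelihood admixture decomposition of the count matrix) with NNDSVD
    seeding and blends the resulting topics toward the shared distribution
    (weight ``init_blend`` on the NMF topic).  The blend damps the NMF's
    overfit word-level deviations below the switch-opening threshold while
    keeping genuine topic anchors above it, so the first switch sweeps open
    only well-supported words.  ``"perturbed_global"`` starts all topics at
    noise-perturbed global frequencies; with ``burn_in_iters > 0`` it is
    followed by an EM warmup whose beta update is shrunk toward beta0
    (pseudo-counts ``burn_in_shrinkage·L̄j·β0``), which lets systematically
    covarying words differentiate the topics before structure search
    starts.  The warmup is part of initialization: the GEM proper (and its
    descent guarantees) starts from the returned model.
    """
    D, N = corpus.num_docs, corpus.num_words
    rng = np.random.default_rng(config.seed)
    beta0 = init_beta0(corpus)
    v = np.ones((M, D), dtype=np.int8)
    u = np.ones((M, N), dtype=np.int8)
    alpha = np.full((M, D), 1.0 / M)
    if config.init_scheme == "nmf":
        from sklearn.decomposition import NMF

        X = corpus.dense()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nmf = NMF(
                n_components=M,
                beta_loss="kullback-leibler",
                solver="mu",
                init="nndsvda" if M > 1 else "random",
                max_iter=300,
                tol=1e-6,
                random_state=config.seed % (2**32),
            )
            W = nmf.fit_transform(X)
        H = nmf.components_
        beta = H / np.maximum(H.sum(axis=1, keepdims=True), 1e-300)
        beta = config.init_blend * beta + (1.0 - config.init_blend) * beta0[None, :]
        alpha_w = (W / np.maximum(W.sum(axis=1, keepdims=True), 1e-12)).T
        alpha = np.maximum(alpha_w, 1e-6)
        alpha /= alpha.sum(axis=0, keepdims=True)
    elif config.init_scheme == "perturbed_global":
        noise = np.exp(config.init_noise * rng.standard_normal((M, N)))
        beta = beta0[None, :] * noise
    elif config.init_scheme == "doc_seeded":
        # anchor each topic on a randomly drawn document, smoothed toward the
        # global frequencies so every word keeps positive probability
        seeds = rng.choice(D, size=M, replace=M > D)
        X = corpus.dense()
        rows = X[seeds] / X[seeds].sum(axis=1, keepdims=True)
        beta = rows + config.init_noise * beta0[None, :]
    elif config.init_scheme == "uniform":
        beta = np.tile(beta0, (M, 1))
    else:
        raise ValueError(f"unknown init_scheme {config.init_scheme!r}")
    beta = np.maximum(beta, 1e-300)
    beta /= beta.sum(axis=1, keepdims=True)
    model = PTMModel(ModelStructure(v, u), ModelParams(alpha, beta, beta0))
    if config.burn_in_iters > 0:
        X = corpus.dense()
        kappa = config.burn_in_shrinkage
        lbar = model.structure.effective_sample_sizes(corpus.doc_lengths).astype(float)
        for _ in range(config.burn_in_iters):
            resp = e_step(model, corpus)
            model.params.alpha = update_alpha(resp, model.structure, corpus)
            S = np.einsum("dn,dnj->jn", X, resp.r)
            B = S + kappa * lbar[:, None] * beta0[None, :]
            model.params.beta = B / B.sum(axis=1, keepdims=True)
    return model


def fit(
    corpus: Corpus,
    M: int,
    config: FitConfig | None = None,
    init_model: PTMModel | None = None,
) -> tuple[PTMModel, FitTrace]:
    """Fit the model at fixed order M by generalized EM.

    Alternates E-step, closed-form parameter updates, word-switch sweeps and
    topic-switch sweeps until the relative change of the end-of-iteration
    expected BIC falls below ``config.rel_tol`` or the iteration cap is hit.
    ``init_model`` warm-starts the search (used by order selection).
    """
    if M < 1:
        raise ValueError("model order M must be >= 1")
    config = config or FitConfig()
    if init_model is not None:
        model = init_model.copy()
        if model.M != M:
            raise ValueError(f"init_model has order {model.M}, expected {M}")
    else:
        model = _initial_model(corpus, M, config)
    beta0 = model.params.beta0
    # High-evidence words are decided first in the switch sweeps.
    totals = np.asarray(corpus.counts.sum(axis=0)).ravel()
    word_order = np.argsort(-totals, kind="stable")
    opts = dict(
        topic_config_prior=config.topic_config_prior,
        word_cost_scheme=config.word_cost_scheme,
    )
    trace = FitTrace()
    prev = None
    for it in range(config.max_outer_iters):
        resp = e_step(model, corpus)
        S = _resp_weighted_counts(corpus, resp)
        # Degeneracy guard: a topic that no longer explains any token cannot
        # carry topic-specific words; close its switches so it reverts to the
        # shared model (the topic-switch sweep then prunes it for free).
        open_mass = (S * (model.structure.u == 1)).sum(axis=1)
        dead = (open_mass <= 0) & (model.structure.Nj > 0)
        if dead.any():
            logger.debug("closing word switches of %d starved topic(s)", int(dead.sum()))
            model.structure.u[dead, :] = 0
            model.params.beta[dead, :] = 0.0
        trace.bic_after_e.append(free_energy_bic(model, corpus, resp, **opts))
        model.params.alpha = update_alpha(resp, model.structure, corpus)
        model.params.beta = update_beta(resp, model.structure, corpus, beta0)
        trace.bic_after_m.append(free_energy_bic(model, corpus, resp, **opts))
        lbar = model.structure.effective_sample_sizes(corpus.doc_lengths)
        search = _WordSwitchSearch(
            model.structure, S, beta0, lbar, scheme=config.word_cost_scheme
        )
        _, n_u = search.sweep(word_order, config.max_switch_sweeps)
        search.rebuild_beta(model.params.beta)
        trace.bic_after_u.append(free_energy_bic(model, corpus, resp, **opts))
        trace.u_changes.append(n_u)
        _, n_v = update_topic_switches(
            model, corpus, resp,
            max_sweeps=config.max_switch_sweeps,
            topic_config_prior=config.topic_config_prior,
            word_cost_scheme=config.word_cost_scheme,
        )
        trace.bic_after_v.append(free_energy_bic(model, corpus, resp, **opts))
        trace.v_changes.append(n_v)
        trace.true_bic.append(bic(model, corpus, **opts).total)
        cur = trace.bic_after_v[-1]
        if prev is not None and abs(cur - prev) <= config.rel_tol * abs(prev):
            trace.converged = True
            break
        prev = cur
    if not trace.converged:
        trace.message = (
            f"not converged after {trace.n_iters} outer iterations "
            f"(rel_tol={config.rel_tol})"
        )
        logger.warning(trace.message)
    return model, trace
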