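"""Top-down model-order selection by BIC.

Fit at a user-supplied upper bound ``Mmax``, then repeatedly remove the
``delta`` topics with the smallest mass (expected token count attributed to
the topic), warm-start a new GEM fit at the reduced order, and finally keep
the order whose fitted model attains the smallest BIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bic import bic
from .corpus import Corpus
from .gem import FitConfig, FitTrace, fit
from .model import ModelParams, ModelStructure, PTMModel

__all__ = ["OrderSweepResult", "topic_mass", "prune", "select_order"]


@dataclass
class OrderSweepResult:
    """One row per candidate order, plus the BIC-selected model."""

    orders: list[int] = field(default_factory=list)
    bic_values: list[float] = field(default_factory=list)
    all_closed_fractions: list[float] = field(default_factory=list)
    models: list[PTMModel] = field(default_factory=list)
    traces: list[FitTrace] = field(default_factory=list)

    @property
    def selected_index(self) -> int:
        return int(np.argmin(self.bic_values))

    @property
    def selected_order(self) -> int:
        return self.orders[self.selected_index]

    @property
    def selected_model(self) -> PTMModel:
        return self.models[self.selected_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "order": self.orders,
                "bic": self.bic_values,
                "all_closed_fraction": self.all_closed_fractions,
                "selected": [i == self.selected_index for i in range(len(self.orders))],
            }
        )


def topic_mass(model: PTMModel, corpus: Corpus) -> np.ndarray:
    """Expected token count attributed to each topic: Σd Ld·αjd·vjd."""
    Ld = corpus.doc_lengths.astype(float)
    return ((model.params.alpha * model.structure.v) * Ld[None, :]).sum(axis=1)


def all_closed_fraction(model: PTMModel) -> float:
    """Fraction of vocabulary words whose switch column is all closed."""
    return float(np.mean(model.structure.u.sum(axis=0) == 0))


def prune(model: PTMModel, corpus: Corpus, k: int) -> PTMModel:
    """Remove the k lowest-mass topics (ties broken by lower index).

    Each document's proportions are renormalized over its remaining active
    topics; a document left with no active topic gets its highest-mass
    remaining topic opened with proportion 1.
    """
    M = model.M
    if k >= M:
        raise ValueError(f"cannot prune {k} topics from a model of order {M}")
    if k == 0:
        return model.copy()
    mass = topic_mass(model, corpus)
    drop = np.argsort(mass, kind="stable")[:k]
    keep = np.setdiff1d(np.arange(M), drop)
    keep_mass = mass[keep]
    v = model.structure.v[keep].copy()
    u = model.structure.u[keep].copy()
    alpha = model.params.alpha[keep].copy()
    beta = model.params.beta[keep].copy()
    beta0 = model.params.beta0
    # Close zero-probability open switches (words with no responsibility mass
    # under the topic); they block the posterior for documents that lose
    # their other topics in the prune.  The remaining open words absorb the
    # freed shared mass so the per-topic pmf constraint still holds.
    for j in range(len(keep)):
        dead = (u[j] == 1) & (beta[j] <= 0)
        if dead.any():
            u[j, dead] = 0
            live = u[j] == 1
            if live.any():
                target = beta0[live].sum()
                cur = beta[j, live].sum()
                if cur > 0:
                    beta[j, live] *= target / cur
                else:
                    u[j, live] = 0
    col = (alpha * v).sum(axis=0)
    for d in range(v.shape[1]):
        if v[:, d].sum() == 0:
            j = int(np.argmax(keep_mass))
            v[j, d] = 1
            alpha[:, d] = 0.0
            alpha[j, d] = 1.0
        elif col[d] <= 0:
            active = np.flatnonzero(v[:, d])
            alpha[:, d] = 0.0
            alpha[active, d] = 1.0 / active.size
        else:
            alpha[:, d] = np.where(v[:, d] == 1, alpha[:, d] / col[d], 0.0)
    return PTMModel(
        ModelStructure(v, u),
        ModelParams(alpha, beta, model.params.beta0.copy()),
    )


def select_order(
    corpus: Corpus,
    Mmax: int,
    Mmin: int = 1,
    delta: int = 1,
    config: FitConfig | None = None,
) -> OrderSweepResult:
    """Fit from Mmax down to Mmin in steps of ``delta``; keep the min-BIC order.

    At every order two fits are run — one warm-started from the pruned
    previous model (the top-down continuation) and one cold-started from the
    configured initialization — and the lower-BIC fit is retained.  Pruned
    warm starts alone accumulate path dependence from the Mmax fit; the
    independent per-order fit recovers from a poor start higher up the
    sweep.  A final step larger than the remaining range clamps to Mmin.
    """
    if not (1 <= Mmin <= Mmax):
        raise ValueError(f"need 1 <= Mmin <= Mmax, got Mmin={Mmin}, Mmax={Mmax}")
    if delta < 1:
        raise ValueError("delta must be >= 1")
    config = config or FitConfig()
    result = OrderSweepResult()
    current: PTMModel | None = None
    M = Mmax
    while True:
        candidates = []
        cold_model, cold_trace = fit(corpus, M, config)
        candidates.append((cold_model, cold_trace))
        if current is not None:
            warm_model, warm_trace = fit(corpus, M, config, init_model=current)
            candidates.append((warm_model, warm_trace))
        scored = [
            (
                bic(
                    m,
                    corpus,
                    topic_config_prior=config.topic_config_prior,
                    word_cost_scheme=config.word_cost_scheme,
                ).total,
                i,
            )
            for i, (m, _) in enumerate(candidates)
        ]
        best_bic, best_i = min(scored)
        model, trace = candidates[best_i]
        result.orders.append(M)
        result.bic_values.append(best_bic)
        result.all_closed_fractions.append(all_closed_fraction(model))
        result.models.append(model)
        result.traces.append(trace)
        if M <= Mmin:
            break
        next_M = max(M - delta, Mmin)
        current = prune(model, corpus, M - next_M)
        M = next_M
    return result
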