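"""Generalized EM: E-step, parameter updates, switch search, full fits."""

import itertools

import numpy as np
import pytest

import parsitopic as pt
from parsitopic.gem import (
    _WordSwitchSearch,
    _resp_weighted_counts,
    attribution_entropy,
    e_step,
    expected_complete_bic,
    expected_complete_loglik,
    free_energy_bic,
    init_beta0,
    update_alpha,
    update_beta,
    update_topic_switches,
    update_word_switches_for_word,
)
from parsitopic.model import ModelError, ModelParams, ModelStructure, PTMModel

from conftest import random_small_corpus, random_valid_model, shared_unigram_model


# ---------------------------------------------------------------------------
# E-step


def test_e_step_single_topic_is_one(tiny_corpus, unigram_tiny):
    r = e_step(unigram_tiny, tiny_corpus).r
    mask = tiny_corpus.dense() > 0
    np.testing.assert_allclose(r[mask], 1.0)


def test_e_step_posterior_hand_value():
    # alpha=(0.6,0.4); word specific under topic 0 with beta=0.2, shared 0.1
    corpus = pt.build_corpus([["a", "b"]])  # word "a" is index 0
    v = np.ones((2, 1), dtype=np.int8)
    u = np.array([[1, 0], [0, 0]], dtype=np.int8)
    beta0 = np.array([0.1, 0.9])
    beta = np.array([[0.2, 0.0], [0.0, 0.0]])
    alpha = np.array([[0.6], [0.4]])
    m = PTMModel(ModelStructure(v, u), ModelParams(alpha, beta, beta0))
    r = e_step(m, corpus).r
    np.testing.assert_allclose(r[0, 0], [0.75, 0.25])  # 0.12 / (0.12 + 0.04)


def test_e_step_symmetric_topics_give_uniform_posterior(two_doc_corpus):
    M, D, N = 2, 2, 3
    v = np.ones((M, D), dtype=np.int8)
    u = np.zeros((M, N), dtype=np.int8)
    beta0 = init_beta0(two_doc_corpus)
    m = PTMModel(
        ModelStructure(v, u),
        ModelParams(np.full((M, D), 0.5), np.zeros((M, N)), beta0),
    )
    r = e_step(m, two_doc_corpus).r
    mask = two_doc_corpus.dense() > 0
    np.testing.assert_allclose(r[mask], 0.5)


def test_e_step_rows_normalized_and_zero_off_support():
    rng = np.random.default_rng(2)
    corpus = random_small_corpus(rng, D=4, N=6)
    m = random_valid_model(3, 4, 6, rng)
    r = e_step(m, corpus).r
    X = corpus.dense()
    sums = r.sum(axis=2)
    np.testing.assert_allclose(sums[X > 0], 1.0, atol=1e-12)
    assert np.all(r[X == 0] == 0)
    # responsibilities vanish where the topic switch is closed
    for d in range(4):
        inactive = np.flatnonzero(m.structure.v[:, d] == 0)
        assert np.all(r[d, :, inactive] == 0)


# ---------------------------------------------------------------------------
# Expected complete-data quantities


def scalar_expected_loglik(model, corpus, resp):
    """Independent direct-summation oracle for E[Lc]."""
    X = corpus.dense()
    out = 0.0
    for d in range(corpus.num_docs):
        for n in range(corpus.num_words):
            if X[d, n] == 0:
                continue
            for j in range(model.M):
                rr = resp.r[d, n, j]
                if rr == 0:
                    continue
                wp = (
                    model.params.beta[j, n]
                    if model.structure.u[j, n] == 1
                    else model.params.beta0[n]
                )
                out += X[d, n] * rr * (np.log(model.params.alpha[j, d]) + np.log(wp))
    return out


def test_expected_complete_loglik_matches_scalar_oracle():
    rng = np.random.default_rng(4)
    corpus = random_small_corpus(rng, D=2, N=3, lmin=4, lmax=8)
    m = random_valid_model(2, 2, 3, rng, p_open=0.4)
    resp = e_step(m, corpus)
    assert expected_complete_loglik(m, corpus, resp) == pytest.approx(
        scalar_expected_loglik(m, corpus, resp), rel=1e-12
    )


def test_expected_bic_single_topic_equals_plain_bic(tiny_corpus, unigram_tiny):
    resp = e_step(unigram_tiny, tiny_corpus)
    eb = expected_complete_bic(unigram_tiny, tiny_corpus, resp)
    b = pt.bic(unigram_tiny, tiny_corpus)
    assert eb.total == pytest.approx(b.total, abs=1e-9)


def test_expected_bic_upper_bounds_true_bic():
    # Jensen: the expected complete-data likelihood never exceeds the
    # incomplete-data likelihood, so expected BIC >= true BIC.
    rng = np.random.default_rng(6)
    for _ in range(10):
        corpus = random_small_corpus(rng, D=3, N=5)
        m = random_valid_model(2, 3, 5, rng)
        resp = e_step(m, corpus)
        eb = expected_complete_bic(m, corpus, resp).total
        b = pt.bic(m, corpus).total
        assert eb >= b - 1e-9


def test_free_energy_equals_true_bic_at_posterior():
    rng = np.random.default_rng(8)
    corpus = random_small_corpus(rng, D=4, N=6)
    m = random_valid_model(3, 4, 6, rng)
    resp = e_step(m, corpus)
    assert free_energy_bic(m, corpus, resp) == pytest.approx(
        pt.bic(m, corpus).total, rel=1e-10
    )


# ---------------------------------------------------------------------------
# Parameter updates


def test_update_alpha_examples():
    corpus = pt.build_corpus([["a", "a", "b"]])
    v = np.ones((2, 1), dtype=np.int8)
    s = ModelStructure(v, np.zeros((2, 2), dtype=np.int8))
    # r(a) = (1,0), r(b) = (0,1) -> alpha = (2/3, 1/3)
    r = np.zeros((1, 2, 2))
    r[0, 0] = [1.0, 0.0]
    r[0, 1] = [0.0, 1.0]
    alpha = update_alpha(pt.Responsibilities(r), s, corpus)
    np.testing.assert_allclose(alpha[:, 0], [2 / 3, 1 / 3])
    # uniform responsibilities -> uniform proportions
    r[:] = 0.5
    alpha = update_alpha(pt.Responsibilities(r), s, corpus)
    np.testing.assert_allclose(alpha[:, 0], [0.5, 0.5])


def test_update_beta_forced_open_mass():
    # one open word; the pmf constraint forces its probability to the
    # mass beta0 leaves free, independent of responsibilities
    corpus = pt.build_corpus([["a", "a", "b", "c"]])
    beta0 = np.array([0.3, 0.4, 0.3])  # closed words b,c carry 0.7
    u = np.array([[1, 0, 0]], dtype=np.int8)
    s = ModelStructure(np.ones((1, 1), dtype=np.int8), u)
    r = np.zeros((1, 3, 1))
    r[0, [0, 1, 2], 0] = 1.0
    beta = update_beta(pt.Responsibilities(r), s, corpus, beta0)
    assert beta[0, 0] == pytest.approx(0.3)  # = 1 - 0.7
    row = np.where(u[0] == 1, beta[0], beta0)
    assert row.sum() == pytest.approx(1.0)


def test_update_beta_all_open_is_weighted_frequency():
    rng = np.random.default_rng(10)
    corpus = random_small_corpus(rng, D=3, N=4)
    m = random_valid_model(2, 3, 4, rng)
    m.structure.u[:] = 1
    m.params.beta = np.tile(init_beta0(corpus), (2, 1))
    resp = e_step(m, corpus)
    beta = update_beta(resp, m.structure, corpus, m.params.beta0)
    S = _resp_weighted_counts(corpus, resp)
    np.testing.assert_allclose(beta, S / S.sum(axis=1, keepdims=True), atol=1e-12)


def test_update_beta_closed_topic_row_is_zero(two_doc_corpus):
    m = shared_unigram_model(two_doc_corpus)
    resp = e_step(m, two_doc_corpus)
    beta = update_beta(resp, m.structure, two_doc_corpus, m.params.beta0)
    assert np.all(beta == 0)


def test_init_beta0_frequencies():
    c = pt.build_corpus([["a", "a", "a", "b"]])
    np.testing.assert_allclose(init_beta0(c), [0.75, 0.25])
    c1 = pt.build_corpus([["x", "x"]])
    np.testing.assert_allclose(init_beta0(c1), [1.0])
    rng = np.random.default_rng(0)
    c2 = random_small_corpus(rng)
    assert init_beta0(c2).sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Word-switch search vs exhaustive oracle


def brute_best_column(model, corpus, resp, n):
    """Exhaustively score every feasible configuration of word n's switch
    column by rebuilding beta (Lagrangian normalization) and recomputing the
    expected complete-data BIC from scratch."""
    S = _resp_weighted_counts(corpus, resp)
    M = model.M
    lbar = model.structure.effective_sample_sizes(corpus.doc_lengths)
    best = (np.inf, None)
    for bits in itertools.product([0, 1], repeat=M):
        col = np.array(bits, dtype=np.int8)
        # no NEW opening without responsibility mass and a positive sample size
        # (a currently-open switch may be kept)
        if any(
            col[j] == 1
            and lbar[j] < 1
            or col[j] == 1
            and S[j, n] <= 0
            and model.structure.u[j, n] == 0
            for j in range(M)
        ):
            continue
        m2 = model.copy()
        m2.structure.u[:, n] = col
        ok = True
        beta = np.zeros_like(m2.params.beta)
        for j in range(M):
            open_mask = m2.structure.u[j] == 1
            if not open_mask.any():
                continue
            mass = S[j, open_mask].sum()
            if mass <= 0:
                ok = False
                break
            beta[j, open_mask] = S[j, open_mask] * (
                m2.params.beta0[open_mask].sum() / mass
            )
        if not ok:
            continue
        m2.params.beta = beta
        total = expected_complete_bic(m2, corpus, resp).total
        if total < best[0]:
            best = (total, col)
    return best


@pytest.mark.parametrize("seed", range(8))
def test_word_switch_update_matches_exhaustive_minimum(seed):
    rng = np.random.default_rng(seed)
    corpus = random_small_corpus(rng, D=4, N=6, lmin=5, lmax=12)
    m = random_valid_model(2, 4, 6, rng, p_open=0.5)
    resp = e_step(m, corpus)
    m.params.alpha = update_alpha(resp, m.structure, corpus)
    m.params.beta = update_beta(resp, m.structure, corpus, m.params.beta0)
    for n in range(corpus.num_words):
        expected_total, expected_col = brute_best_column(m, corpus, resp, n)
        update_word_switches_for_word(m, corpus, resp, n)
        got = expected_complete_bic(m, corpus, resp).total
        assert got == pytest.approx(expected_total, rel=1e-9), f"word {n}"
        # repeating the update is a no-op at the local optimum
        assert update_word_switches_for_word(m, corpus, resp, n) == 0.0


def test_word_without_evidence_stays_closed():
    # word "b" occurs only where topic 0 is inactive: no evidence can ever
    # justify a topic-specific parameter for (topic 0, "b")
    corpus = pt.build_corpus([["a", "a", "a"], ["b", "b", "b"]])
    v = np.array([[1, 0], [1, 1]], dtype=np.int8)
    u = np.zeros((2, 2), dtype=np.int8)
    beta0 = init_beta0(corpus)
    alpha = np.array([[0.5, 0.0], [0.5, 1.0]])
    m = PTMModel(ModelStructure(v, u), ModelParams(alpha, np.zeros((2, 2)), beta0))
    resp = e_step(m, corpus)
    S = _resp_weighted_counts(corpus, resp)
    assert S[0, 1] == 0
    update_word_switches_for_word(m, corpus, resp, 1)
    assert m.structure.u[0, 1] == 0


# ---------------------------------------------------------------------------
# Topic-switch search


def test_topic_switch_no_legal_flip_single_topic(tiny_corpus, unigram_tiny):
    resp = e_step(unigram_tiny, tiny_corpus)
    delta, flips = update_topic_switches(unigram_tiny, tiny_corpus, resp)
    assert flips == 0
    assert delta == 0.0


def test_closing_zero_mass_topic_is_accepted():
    # documents long enough that the saved proportion-coding cost
    # (1/2)·log(Ld/2π) outweighs the binomial subset-prior change
    corpus = pt.build_corpus([["a", "a", "b", "b", "a", "b"] * 4] * 2)
    M, D, N = 2, 2, 2
    v = np.ones((M, D), dtype=np.int8)
    u = np.zeros((M, N), dtype=np.int8)
    beta0 = init_beta0(corpus)
    alpha = np.array([[1.0, 1.0], [0.0, 0.0]])  # topic 1 active but massless
    m = PTMModel(ModelStructure(v, u), ModelParams(alpha, np.zeros((M, N)), beta0))
    resp = e_step(m, corpus)
    before = free_energy_bic(m, corpus, resp)
    delta, flips = update_topic_switches(m, corpus, resp)
    after = free_energy_bic(m, corpus, resp)
    assert flips >= 2  # the massless topic is closed in both documents
    assert np.all(m.structure.v[1] == 0)
    assert after < before
    assert after - before == pytest.approx(delta, abs=1e-6)


def test_topic_switch_delta_matches_from_scratch_recomputation():
    rng = np.random.default_rng(17)
    corpus = random_small_corpus(rng, D=5, N=6, lmin=6, lmax=12)
    m = random_valid_model(3, 5, 6, rng)
    resp = e_step(m, corpus)
    m.params.alpha = update_alpha(resp, m.structure, corpus)
    m.params.beta = update_beta(resp, m.structure, corpus, m.params.beta0)
    before = free_energy_bic(m, corpus, resp)
    delta, flips = update_topic_switches(m, corpus, resp)
    after = free_energy_bic(m, corpus, resp)
    assert after - before == pytest.approx(delta, abs=1e-8)
    assert delta <= 0.0
    # idempotent at the local optimum
    delta2, flips2 = update_topic_switches(m, corpus, resp)
    assert flips2 == 0 and delta2 == 0.0


# ---------------------------------------------------------------------------
# Full fit


def test_fit_single_topic_shared_unigram(tiny_corpus):
    model, trace = pt.fit(tiny_corpus, 1, pt.FitConfig(seed=0))
    assert model.M == 1
    assert pt.validate(model, tiny_corpus) == []
    # at M=1 the all-closed and all-open codings tie exactly and the fitted
    # emissions coincide with the global frequencies either way
    np.testing.assert_allclose(
        model.word_prob_matrix()[0], init_beta0(tiny_corpus), atol=1e-12
    )
    np.testing.assert_allclose(model.params.beta0, init_beta0(tiny_corpus))
    assert trace.converged


def test_fit_constraints_and_descent_small():
    rng = np.random.default_rng(23)
    corpus = random_small_corpus(rng, D=8, N=10, lmin=8, lmax=16)
    model, trace = pt.fit(corpus, 3, pt.FitConfig(seed=1))
    assert pt.validate(model, corpus) == []
    seq = trace.phase_sequence()
    for i in range(trace.n_iters):
        a, b, c, d = seq[4 * i : 4 * i + 4]
        assert b <= a + 1e-8 * abs(a)
        assert c <= b + 1e-8 * abs(b)
        assert d <= c + 1e-8 * abs(c)


def test_fit_seed_determinism():
    corpus, _ = pt.generate(pt.SyntheticConfig(D=30, N=40, M_true=2, doc_length_min=20, doc_length_max=30, seed=5))
    m1, t1 = pt.fit(corpus, 2, pt.FitConfig(seed=7))
    m2, t2 = pt.fit(corpus, 2, pt.FitConfig(seed=7))
    np.testing.assert_array_equal(m1.structure.u, m2.structure.u)
    np.testing.assert_array_equal(m1.structure.v, m2.structure.v)
    np.testing.assert_allclose(m1.params.alpha, m2.params.alpha)
    assert t1.bic_after_v == t2.bic_after_v
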