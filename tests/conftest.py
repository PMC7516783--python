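"""Shared fixtures: tiny hand corpora and session-scoped recovery fits."""

import numpy as np
import pytest

import parsitopic as pt


@pytest.fixture
def tiny_corpus():
    """Single document 'a a b'."""
    return pt.build_corpus([["a", "a", "b"]])


@pytest.fixture
def two_doc_corpus():
    return pt.build_corpus([["a", "b"], ["b", "c"]])


def shared_unigram_model(corpus):
    """M=1 model with every switch closed (pure shared model)."""
    D, N = corpus.num_docs, corpus.num_words
    v = np.ones((1, D), dtype=np.int8)
    u = np.zeros((1, N), dtype=np.int8)
    alpha = np.ones((1, D))
    beta = np.zeros((1, N))
    beta0 = pt.init_beta0(corpus)
    return pt.PTMModel(pt.ModelStructure(v, u), pt.ModelParams(alpha, beta, beta0))


@pytest.fixture
def unigram_tiny(tiny_corpus):
    return shared_unigram_model(tiny_corpus)


def random_valid_model(M, D, N, rng, p_open=0.5):
    """A random model satisfying every invariant (for property tests)."""
    v = np.zeros((M, D), dtype=np.int8)
    for d in range(D):
        active = rng.choice(M, size=rng.integers(1, M + 1), replace=False)
        v[active, d] = 1
    for j in range(M):  # every topic present somewhere (L̄j >= 1)
        if v[j].sum() == 0:
            v[j, rng.integers(D)] = 1
    u = (rng.random((M, N)) < p_open).astype(np.int8)
    beta0 = rng.dirichlet(np.ones(N))
    alpha = np.zeros((M, D))
    for d in range(D):
        active = np.flatnonzero(v[:, d])
        alpha[active, d] = rng.dirichlet(np.ones(active.size))
    beta = np.zeros((M, N))
    for j in range(M):
        open_idx = np.flatnonzero(u[j])
        if open_idx.size == 0:
            continue
        mass = beta0[open_idx].sum()
        beta[j, open_idx] = rng.dirichlet(np.ones(open_idx.size)) * mass
    return pt.PTMModel(pt.ModelStructure(v, u), pt.ModelParams(alpha, beta, beta0))


def random_small_corpus(rng, D=3, N=5, lmin=3, lmax=9):
    docs = []
    words = [f"w{i}" for i in range(N)]
    for d in range(D):
        L = rng.integers(lmin, lmax + 1)
        docs.append([words[i] for i in rng.integers(0, N, size=L)])
    for i in range(N):  # every vocabulary word occurs somewhere
        docs[i % D].append(words[i])
    return pt.build_corpus(docs)


# ---------------------------------------------------------------------------
# Session-scoped recovery fits shared by several acceptance checks.

N_RECOVERY_SEEDS = 20


@pytest.fixture(scope="session")
def recovery_fits():
    """Default-condition synthetic corpora fitted at the planted order."""
    out = []
    for seed in range(N_RECOVERY_SEEDS):
        corpus, truth = pt.generate(pt.SyntheticConfig(seed=seed))
        model, trace = pt.fit(corpus, 4, pt.FitConfig(seed=seed))
        out.append((corpus, truth, model, trace))
    return out
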