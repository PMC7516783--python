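# Methods

## Model

A corpus has D documents over an N-word vocabulary; `counts(d, n)` is the
number of occurrences of word n in document d and `L_d` the document's total
token count (all sums in the likelihood, the updates and the information
criterion are count-weighted — the model treats repeated tokens as repeated
draws). A model of order M consists of binary topic switches `v` (M×D, each
document keeps at least one active topic), binary word switches `u` (M×N),
document proportions `α` (a pmf over each document's active topics), topic
word probabilities `β` (meaningful only at open switches), and one shared
word pmf `β0`. Topic j emits word n with probability `β_jn` if `u_jn = 1`
and `β0_n` otherwise; each topic's emission row sums to one, which pins the
total probability of a topic's specific words to `1 − Σ_closed β0_n`. `β0`
is the global frequency estimate, computed once and frozen.

## Objective

The fit minimizes a Laplace-approximation description length:

```
BIC = D·log M  +  Σ_d log C(M, M_d)  +  (1/2) Σ_d (M_d − 1)·log(L_d / 2π)
    + Σ_n wordcost(u_·n)  −  log p(data | H, Θ)
```

where `M_d` is the number of active topics in document d and the per-word
switch-column cost distinguishes three cases, with `L̄_j = Σ_d L_d v_jd` the
effective sample size of topic j's word parameters:

* all closed: `(1/2)·log(Σ_j L̄_j / 2π)` — one shared parameter only; this
  is the cheap coding for wholly uninformative words,
* all open: `(1/2)·Σ_j log(L̄_j / 2π)`,
* mixed: `(1/2)·log(Σ_j L̄_j / 2π) + M·log 2 + (1/2)·Σ_open log(L̄_j / 2π)`,
  the `M·log 2` being the cost of saying which switches are open.

The per-document topic-subset prior is `log C(M, M_d)` by default (a
uniform prior over size-`M_d` subsets); `topic_config_prior="power"` gives
the `M_d·log M` alternative. An ablation (`word_cost_scheme="flat_mixed"`)
prices every column with the mixed-case formula; comparing the two isolates
the effect of the cheap all-closed coding (it raises the fitted all-closed
fraction by several points on the synthetic benchmark). A naive
`K·log D − 2·log L̂` BIC is provided for comparison only.

Note one consequence of the binomial subset prior: closing a topic in a
document *raises* `log C(M, M_d)` when `M_d > (M+1)/2`, so for very short
documents a zero-mass topic can survive; with realistic document lengths
the `(1/2)·log(L_d/2π)` saving dominates.

## Generalized EM

One outer iteration: E-step (posterior topic responsibilities per observed
document-word pair), closed-form updates of `α` and `β`, a word-switch
sweep, then a topic-switch sweep.

**Scoring of discrete moves.** Moves are scored on the variational free
energy `F = penalties − E[L_c] − H(r)`, where `E[L_c]` is the expected
complete-data log-likelihood under the current responsibilities `r` and
`H(r)` their token-weighted entropy. For moves that keep `r` fixed
(parameter updates and word-switch changes) this ranks candidates exactly
like the plain expected BIC. For topic-switch closes, which restrict and
renormalize a document's responsibilities, the entropy term is essential:
without it, a close is credited with the document's attribution entropy
(about `L_d·log 2` when two topics explain it equally well) even when the
marginal likelihood is unchanged, and the sweep destroys genuine topic
structure. `F` equals the true BIC immediately after each E-step,
upper-bounds it otherwise, and every phase — including the E-step itself —
can only decrease it, so the recorded per-phase sequence is non-increasing
within and across iterations. Switch changes are accepted only on strict
decrease (> 1e-10), which guarantees termination.

**Word-switch sweep.** Words are visited in descending corpus frequency;
for each word the whole switch column is re-chosen jointly: exhaustive
enumeration over feasible configurations when `2^M ≤ 64`, greedy per-topic
improvement otherwise. Opening a switch requires positive responsibility
mass for the word under the topic and `L̄_j ≥ 1`; the incumbent column is
always a candidate. Affected `β` rows are re-normalized (via the Lagrangian
closed form `β_jn = S_jn · openβ0_j / A_j`) before scoring, which the
implementation does in O(1) per candidate with per-topic aggregates.

**The all-closed trap and pair opening.** Opening a *single* word switch
for a topic has exactly zero likelihood gain: the pmf constraint forces the
lone open word's probability to equal `β0_n`. The all-closed state is
therefore an absorbing local minimum of any one-column-at-a-time search.
The sweep includes a rescue move: for a topic with no open words it
searches the best *pair* of words (one enriched, one depleted relative to
the shared model, drawn from the most over/under-attributed candidates)
and opens both jointly if that strictly lowers the objective.

**Topic-switch sweep.** Each `v_jd` is tentatively flipped. A close
renormalizes the document's responsibilities and proportions over the
remaining active topics (β stays fixed until the next parameter update); an
open gives the new topic the pseudo-proportion `1/M_d_new` before
renormalization. Flips that would leave a document topicless, strand a
topic's specific words with zero effective sample size, or divide by a
degenerate posterior are skipped as infeasible.

**Initialization.** The default (`init_scheme="nmf"`) seeds the topics with
a KL-divergence NMF of the count matrix (NNDSVD start) and blends each NMF
topic 0.7/0.3 toward `β0`. The blend matters: it damps the NMF's own
overfit word-level deviations below the switch-opening threshold while
leaving genuine topic anchors above it, so the first sweeps open only
well-supported words. Unregularized EM from a perturbed-global start (kept
as an option, with an optional β0-shrunk warmup) overfits sampling noise
before topic structure emerges, after which the first switch sweep
collapses the model into the absorbing all-closed state. A topic whose
open words lose all responsibility mass during the fit has its switches
closed (it reverts to shared emissions) and is subsequently pruned by the
topic-switch sweep.

Convergence: relative change of the end-of-iteration objective below
`rel_tol` (default 1e-6), capped at `max_outer_iters` (default 60;
non-convergence is a warning recorded in the trace, not an error).

## Order selection

Candidate orders run from `Mmax` down to `Mmin` in steps of `delta`
(defaults 1). At each order two fits are scored and the lower-BIC one kept:
a warm start from the previous model with its `delta` lowest-mass topics
pruned (mass = expected token count `Σ_d L_d α_jd v_jd`), and an
independent cold start. Warm-only continuation propagates whatever the
top-order fit found; the independent fit recovers from a poor start higher
up the sweep, and in practice decides most orders. Pruning renormalizes
each document's proportions over its surviving topics (a document left
topicless gets its heaviest surviving topic with proportion 1) and closes
zero-probability open switches so the pruned model's posterior is
well-defined everywhere. The selected order is the BIC argmin over the
sweep.

## Evaluation

Document-completion held-out likelihood: each test document's tokens are
split at random (default 50/50, seeded; both halves non-empty when
`L_d ≥ 2`); proportions are inferred on the observed half with the trained
structure frozen and all topics admitted (posterior/proportion iteration to
relative 1e-6 or 200 rounds); the held-out half is scored under the
inferred mixture. Label measures: per-topic class pmfs by
proportion-weighted frequency counting (with the label-set size `|C_d|` as
an additional per-occurrence weight), multi-label assignment by
thresholding `Σ_j α_jd p_j(c)` over a 101-point grid with the
precision/recall ratios as defined in the module docstring (they are
swapped relative to convention; a flag restores the standard definitions),
trapezoidal area under the curve sorted by recall (anchored at recall 0),
and single-label purity by dominant-topic hard assignment with
majority-class mapping.

## Synthetic benchmark

The generator follows the model's own generative process. Defaults: D=200
documents, N=300 words, M*=4 topics, document lengths uniform on [80, 120],
each topic active in a document with probability 0.5 (re-drawn until at
least one is active), proportions Dirichlet(0.8) over the active set
(documents are mostly dominated by one topic), 15% of eligible words
specific per topic, and half the vocabulary designated pure noise (all
switches closed). `β0` is a symmetric Dirichlet(1) draw; the noise pool is
the rare half of the vocabulary, so topic-specific candidates are frequent
words for which per-word evidence exists at this corpus size.

Topic-specific probabilities are planted *separated* from the shared model:
each specific word's emission ratio `β_jn/β0_n` is drawn around either 12
(enriched) or 0.02 (depleted), the up-probability set by the emission-mass
balance that the pmf constraint imposes, with a Dirichlet of concentration
25 around that base pattern controlling the spread. Separation is a design
requirement, not a convenience: with ratios drawn symmetrically around 1 a
large minority of planted switches carry less likelihood gain than their
coding cost, and — more fundamentally — the planted model's total
likelihood advantage over a single-topic model falls below the structure
penalty, so BIC *correctly* selects one topic on the generator's own data
and no fitter could recover the plant. The chosen ratios put the planted
structure 10²–10³ nats below the best structureless model.

Every vocabulary word unseen after sampling receives one token in a
seed-chosen document so the corpus invariant (each word occurs somewhere)
holds; at the default scale this almost never fires. Generation is a pure
function of the seed.

What the benchmark does *not* emulate: word burstiness within documents,
Zipfian tails beyond what the Dirichlet draw produces, document-length/
topic correlations, or label noise. Passing recovery tests therefore shows
the estimator works when the model is correctly specified and well
separated, not that it will match human topic judgments on real corpora.

## Known limitations

* Even at the planted order and with separated structure, fits routinely
  find switch configurations whose BIC equals or beats the ground truth
  while agreeing with it only partially (pooled switch F1 ≈ 0.45-0.55 at
  desk scale, against a ceiling of ≈ 0.8-0.9 for a search started at the
  truth): at ~20k tokens the objective does not uniquely identify all
  ~1200 binary switches. All-closed (noise-word) detection is much easier
  and is recovered at recall ≈ 0.99.
* Expected-complete-data scoring with fixed responsibilities systematically
  under-values *depleted* topic-specific words (words a topic avoids):
  keeping such a switch open lowers the fixed-responsibility score even
  when it raises the marginal likelihood. Depleted switches are mostly
  retained only through the emission-mass budget effect of their `β0`
  share.
* Dense responsibility arrays (D×N×M) make the implementation simple and
  fast at desk scale but memory-hungry for corpora beyond ~10⁴ documents
  or vocabulary; a sparse-responsibility backend would be needed for
  corpus sizes like the newswire benchmarks.
* The discrete search is greedy coordinate descent with two move types; it
  has no global guarantees, and different seeds can select neighboring
  model orders on weakly separated corpora.

## Problem sizes

The test suite and the acceptance script run the generator's default
conditions (D=200, N=300) with fits at M ≤ 8, order sweeps over M ∈ [1, 8],
and tiny hand-checkable instances (D ≤ 8, N ≤ 10) for the exhaustive
oracles; these sizes were chosen so every exhaustive cross-check remains
enumerable and a full run completes in minutes on one CPU.
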