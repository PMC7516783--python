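# parsitopic

Sparse ("parsimonious") topic modeling for bag-of-words corpora, with joint
structure learning by a customized Bayesian information criterion.

Classical admixture topic models give every topic a probability for every
word and place every topic in every document. For corpora where most words
are topical noise — newswire, abstracts, clinical text — that is both
wasteful and statistically fragile. This package implements a switch-based
alternative aimed at text-mining practitioners who want *interpretable,
sparse* topics and a principled, label-free way to choose the number of
topics:

* a **topic switch** `v_jd ∈ {0,1}` says whether topic *j* occurs in
  document *d*; proportions satisfy `Σ_j α_jd v_jd = 1`,
* a **word switch** `u_jn ∈ {0,1}` says whether word *n* is topic-specific
  under topic *j* (probability `β_jn`) or follows a single corpus-wide
  shared distribution `β0` (estimated once from global frequencies and
  frozen); each topic's emission row `u_jn β_jn + (1−u_jn) β0_n` sums to 1,
* a word whose switches are closed under **all** topics is *wholly
  uninformative* and gets an especially cheap description length.

The likelihood is `p(χ) = Π_d Π_i Σ_j α_jd v_jd [β_jn^{u_jn} β0_n^{1−u_jn}]`,
and everything — parameters, both switch matrices, and the number of topics
*M* — is chosen by minimizing a customized BIC whose parameter costs use
per-parameter effective sample sizes (`L_d` for proportions, `L̄_j = Σ_d L_d
v_jd` for topic-specific words) and whose word-switch coding distinguishes
all-closed, all-open, and mixed columns. Optimization is a generalized EM:
posterior responsibilities, closed-form parameter updates, then discrete
switch search (all switches of a word updated jointly across topics; topic
switches visited one by one), with every accepted move strictly decreasing
the objective. Model order is selected top-down from `Mmax` by pruning the
lowest-mass topics and refitting.

## Worked example

```python
import parsitopic as pt
from parsitopic.order_selection import all_closed_fraction

corpus, truth = pt.generate(pt.SyntheticConfig(seed=0))   # planted structure
model, trace = pt.fit(corpus, 4, pt.FitConfig(seed=0))

print(f"documents: {corpus.num_docs}, vocabulary: {corpus.num_words}, tokens: {corpus.total_tokens}")
print(f"converged: {trace.converged} after {trace.n_iters} iterations")
for name, value in pt.bic(model, corpus).as_dict().items():
    print(f"{name:18s} {value:12.2f}")
print(f"all-closed fraction: {all_closed_fraction(model):.3f}")
```

On the default synthetic conditions (200 documents, 300 words, 4 planted
topics, half the vocabulary pure noise) this prints:

```
documents: 200, vocabulary: 300, tokens: 19801
converged: True after 16 iterations
order_cost               277.26
topic_config_cost        299.39
alpha_cost                94.51
word_cost               1700.90
neg_loglik            101532.03
total                 103904.09
all-closed fraction: 0.833
```

`order_cost` (= D·log M) and `topic_config_cost` price which topics occur in
each document, `alpha_cost` the document proportions, `word_cost` the word
switches and word probabilities, and the total is the BIC the fit descends.
The fitted model declares 83% of the vocabulary wholly uninformative — the
sparsity the cheap all-closed coding is designed to produce (detection
recall of the planted noise words is 0.99 here).

The same pipeline is scriptable from a shell:

```bash
parsitopic simulate --outdir sim --seed 0
parsitopic fit      --counts sim/counts.txt --vocab sim/vocab.txt -M 4 --outdir fit
parsitopic select   --counts sim/counts.txt --vocab sim/vocab.txt --mmax 8 --outdir sel
parsitopic evaluate --model fit/model.json --counts sim/counts.txt \
                    --vocab sim/vocab.txt --outdir eval
```

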