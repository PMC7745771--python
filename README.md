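# rhoshrink

Shrinkage estimation of microbial associations under count-data
normalization, with matrix-comparison metrics, clustering, and relevance
networks for downstream analysis.

## The problem

Amplicon and metagenomic surveys deliver a count table `W` (n samples × p
OTUs/ASVs) that is compositional — each row carries only relative
information at an arbitrary sequencing depth — and zero-inflated.
Estimating the p × p matrix of taxon–taxon linear associations from such
data requires (i) a normalization or transformation `X = f(W)` and (ii) an
association estimator that behaves well when n is small relative to p,
which is the common regime in clinical microbiome studies.

`rhoshrink` implements both ingredients and the machinery to study them:

- **Eight normalizations**: total sum scaling (`tss`), cumulative sum
  scaling (`css`), common sum scaling (`com`), relative log expression
  (`rle`), inverse hyperbolic sine (`asinh`), Wrench compositional
  correction (`wren`), a variance-stabilizing transform (`vst`), and the
  centered log-ratio transform (`clr`).
- **Association estimators**: sample covariance/Pearson correlation, the
  symmetric proportionality

  `ρ_p(X_i, X_k) = 1 − var(X_i − X_k) / (var(X_i) + var(X_k))
               = 2 cov(X_i, X_k) / (var(X_i) + var(X_k))`

  on clr-transformed data, and their Schäfer–Strimmer shrinkage versions.
  Off-diagonal correlations are shrunk toward zero with a data-driven
  intensity λ₁\*, variances toward their median with λ₂\*, and the
  **shrinkage proportionality**

  `ρ*(X_i, X_k) = 2 s*_ik / (s*_ii + s*_kk)`

  is built from the shrunk covariance entries `s*`. With λ₁ = λ₂ = 0, ρ\*
  reduces exactly to ρ_p.
- **Comparison metrics**: Frobenius distance, spectral (operator 2-norm)
  distance, the correlation matrix distance (CMD), classical MDS
  embeddings, and moment summaries (mean/variance/skewness/kurtosis) of
  off-diagonal association values.
- **Downstream analysis**: spectral and Ward hierarchical clustering of
  taxa with taxonomy-based purity scores, relevance networks over the
  top-k |association| pairs, categorical assortativity, fast-greedy
  modularity, and consensus networks across methods.
- **A synthetic-data generator** (logistic-normal-multinomial with sparse
  latent block correlation, heavy-tailed library sizes, and extra-zero
  masking) so every claim is testable without external data, and a
  **workflow engine** that measures sample-size consistency of estimates
  against a large-sample reference.

## Worked example

```python
from rhoshrink import (MicrobialAssociation, assortativity_categorical,
                       block_spec, make_taxonomy, modularity_communities,
                       simulate_counts)

spec = block_spec(p=100, n=150, within=0.6, seed=7, zero_inflation=0.1)
sim = simulate_counts(spec)              # CountMatrix + latent truth
tax = make_taxonomy(spec)                # taxonomy aligned to latent blocks

model = MicrobialAssociation(sim.counts, normalization="clr", metric="rho",
                             shrink="auto", taxonomy=tax)
res = model.fit()
print(res.summary())
```

```
Microbial association estimate
==============================================
No. samples:                150
No. taxa:                   100
Normalization:              clr
Association metric:         rho_star
Shrinkage:                  Schafer-Strimmer
  lambda1 (correlation):    0.4876
  lambda2 (variance):       0.0956
----------------------------------------------
Off-diagonal association values
  mean:                     -0.0036
  variance:                 0.0033
  skewness:                 1.0526
  kurtosis:                 4.8247
==============================================
```

At n = 150 samples for p = 100 taxa the estimated λ₁\* ≈ 0.49: roughly half
of every off-diagonal correlation is attributed to sampling noise and
removed. The positive skewness of the association distribution is the
compositional signature seen in real survey data. Downstream:

```python
net = res.relevance_network(top_k=200)
print("genus assortativity:", assortativity_categorical(net, tax))  # 0.948
_, q = modularity_communities(net)
print("max modularity Q:", q)                                       # 0.821
```

The top-200 network is strongly assortative and modular because its edges
concentrate inside the planted taxonomic blocks.

The same pipeline runs from the shell: `rhoshrink synth`, `rhoshrink
normalize`, `rhoshrink associate`, and `rhoshrink run --config
experiment.yaml` for the full consistency experiment (see
`rhoshrink <cmd> --help`).

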