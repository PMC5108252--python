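# selscape

Tools for linking three matrices that summarize selection and evolution of
multivariate phenotypes, built around a case study of ambush bugs
(*Phymata*): the **γ-matrix** of nonlinear (sexual) selection gradients, the
intraspecific phenotypic covariance matrix **P**, and the among-taxon
divergence matrix **D**. The package asks, quantitatively, whether the
direction of strongest stabilizing sexual selection is also the direction of
least standing variation and least macroevolutionary divergence — the
"selective line of least resistance" hypothesis.

Intended users: evolutionary biologists doing phenotypic selection analysis
and P/G/D-matrix comparisons.

## What it computes

- **Selection gradients** (Lande–Arnold): OLS of relative fitness *w* on
  variance-standardized traits *z* gives the directional gradients **β**;
  adding squared and cross-product terms gives the quadratic/correlational
  gradients **γ** (squared-term coefficients doubled, the standard
  correction). `SelectionSurface(w, Z).fit()` returns a results object with
  estimates, SEs, fit statistics and `summary()`.
- **Canonical analysis**: eigendecomposition γ = MΛMᵀ. The axis with the
  largest-magnitude negative eigenvalue, **m_max**, is the direction of
  strongest stabilizing selection. Eigenvalue significance by permutation of
  fitness across individuals (rank-matched null eigenvalue distributions).
- **Projection pursuit**: the unit direction whose cubic-smoothing-spline
  fit to relative fitness cross-validates best — a surface-direction
  estimate that avoids the low-variance bias of canonical axes.
- **P** from common-garden samples pooled across years (within-year mean
  standardization removes between-year mean shifts) with delete-one
  jackknife SEs; **D** as the covariance of mean-standardized taxon means,
  or a MANOVA moment estimator from individual-level data.
- **Alignment**: vector correlations ρ = |m·v| between m_max and the
  minimum-variance eigenvectors p_min / d_min, with within-trait
  column-shuffle permutation tests; directional variances e(m) = mᵀAm and
  random-direction averages (E[e] = trace(A)/p).
- **Flury CPC hierarchy**: equality ⊃ proportionality ⊃ common principal
  components ⊃ CPC(1) ⊃ unrelated, with jump-up χ² tests, step tests and
  AIC model building, for comparing P with D.
- **Sexual dimorphism**: per-taxon Mahalanobis distance between male and
  female mean-standardized trait means.
- **Synthetic data**: generators for all three sample types (selection
  sample under a quadratic or Gaussian fitness surface, two-year P sample,
  taxon means around a grand mean), so the whole chain is testable without
  the original individual-level data, which was never deposited.

The published summary tables (taxon means, gradients, P, D, canonical axes)
ship as packaged fixtures under `selscape.datasets`.

## Worked example

```python
import numpy as np
import selscape as ss

# canonical analysis of the published variance-standardized gamma
grads = ss.datasets.load_selection_gradients()
can = ss.canonical_analysis(grads)
print(np.round(can.lambdas, 3))        # [ 0.181 -0.094 -0.522]
print(np.round(can.m_vectors[2], 3))   # [-0.111  0.803 -0.586]  (= m_max, sign conventional)

# divergence matrix from the 37 museum taxon means
taxa = ss.datasets.load_taxon_summaries()
ref = ss.datasets.load_reference_means()       # P. a. americana trait means
D = ss.d_matrix_from_means(taxa, ref)
print(np.round(10 * np.diag(D.matrix), 3))     # [0.335 0.1   0.236]

# alignment of selection with variance and divergence
P = ss.datasets.load_p_matrix()
m_max = ss.datasets.load_canonical_vectors()["m_max"]
print(round(ss.vector_correlation(m_max, ss.min_eigenvector(P)), 2))  # 0.78
print(round(ss.vector_correlation(m_max, ss.min_eigenvector(D)), 2))  # 0.82

# Flury hierarchy comparing P (108 males) with D (37 taxa)
fits = ss.flury_hierarchy(P, 108, D, 37)
print(round(fits[0].chi2_jumpup, 2))           # 150.85, df 6: equality rejected
print(ss.best_model(fits, "model_building_aic"))  # 'cpc'
```

The eigenvalues say curvature of the fitness surface is mostly negative
(stabilizing), strongest along m_max, an axis dominated by dorsal melanism.
The ρ values of 0.78 and 0.82 mean that the directions of least phenotypic
variance and least among-species divergence both lie close to that axis,
while the CPC result says P and D share eigenvectors (but not scale) —
micro- and macroevolutionary variation are structured alike.

A command-line layer mirrors the library
(`selscape gradients|canonical|ppr|pmatrix|dmatrix|align|evar|cpc|dimorphism|simulate|run`);
`selscape run --seed 1 --out report.json` executes the whole chain and
writes a JSON report.

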