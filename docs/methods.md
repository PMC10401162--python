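# Methods

## Model and assumptions

A *feature space* is a set of K tasks, task k holding m_k sample
embeddings in a common dimension d. Each task is treated as a discrete
empirical measure — by default uniform weights over its samples; user
weights on the probability simplex are accepted but non-default, since
nothing in the analysis requires non-uniform masses.

The ground cost between samples is the cosine distance raised to the
Wasserstein order p: `c(x, y) = (1 − cos(x, y))^p ∈ [0, 2^p]`. Cosine
is the right base metric here because embedding similarity in high
dimension is directional, and `cos_sim = 1 − cos_dist` lets a bounded
*similarity* be defined directly from the transport distance:
`OTsim = 1 − W_p ∈ [−1, 1]`. Zero-norm vectors have no direction, so
they are rejected as degenerate rather than silently mapped anywhere.

The OTFRM of task k is the ratio of within-task cohesion to
between-task similarity:

```
OTFRM(k) = intra(k) / inter(k)
intra(k) = 2/(m_k(m_k−1)) Σ_{i<j} cos(x_i, x_j)        (all unique pairs)
inter(k) = 1/(K−1) Σ_{l≠k} (1 − W_p(C_k, C_l))
```

Assumptions worth keeping in mind: the measure is purely geometric (it
knows nothing about labels within a task); both components are bounded
by construction, but the ratio is meaningful only when the denominator
is safely positive (see guards); and comparisons across spaces are fair
only under the same OT configuration.

## Solvers

**Entropic (default).** `min ⟨C, π⟩ − εH(π)` over couplings with the
prescribed marginals, `H(π) = −Σ π_ij log π_ij`, solved by log-domain
Sinkhorn iterations (stable for small ε). The *reported* cost is the
sharp `⟨C, π*⟩` under the converged entropic plan — the entropy term is
excluded — so the self-distance tends to 0 as ε → 0 and `cost^{1/p}`
keeps its p-Wasserstein meaning. ε defaults to 0.1, the value used for
task-similarity scoring throughout.

**Exact.** The unregularized Kantorovich LP solved with HiGHS
(`scipy.optimize.linprog`), guarded to m·n ≤ 10⁴. It serves two roles:
a clean solver for small instances (exact zero diagonal, exact
symmetry) and the independent oracle against which the Sinkhorn path is
validated — the test-suite requires agreement within 10⁻³ at ε = 10⁻³
on random cosine-cost instances.

## Numerical choices

- **Marginal tolerance.** Convergence is declared when the coupling's
  row/column sums match the marginals within `marginal_tol` (sup-norm),
  default 10⁻⁶. With cosine costs (range up to 2) and ε = 0.1, the
  Sinkhorn contraction factor approaches 1 on near-antipodal inputs and
  the achievable residual plateaus around 10⁻⁷; 10⁻⁶ is reliably
  reachable and perturbs transport costs by < 2·10⁻⁶. Iterations stop
  at `max_iter` (default 10 000) with a logged warning if the residual
  is within 10× the tolerance, and a hard convergence error beyond
  that.
- **Ratio guard.** The OTFRM denominator must exceed 10⁻⁸; otherwise an
  explicit ill-conditioned-ratio error carries both components rather
  than returning ±∞. The same guard governs the stage ratios PT/RI and
  FT/PT, reported as undefined (`None`) when the denominator stage
  fails it.
- **Subsampling.** Tasks larger than `subsample_cap` (default 2000) are
  subsampled without replacement by a seeded generator before the
  O(mn) cost matrix is formed.
- **Tie-breaks.** Transfer-source ranking sorts by ascending W_p with
  lexicographic task_id tie-break, making the order deterministic.
- **Wasserstein order.** p defaults to 1 (costs are then plain cosine
  distances and `W_1 ≤ 2` directly); configurable.
- **Spearman's ρ** is computed in-house — average-rank transform with
  tie averaging, then the Pearson product-moment formula on ranks — so
  the statistic can be verified against a brute-force oracle; constant
  vectors raise rather than returning 0.
- **Degenerate metrics.** Classification metrics with a zero
  denominator (e.g. precision with no positive predictions) are
  reported as an explicit undefined marker, never as 0.
- **Loss clamping.** Predicted confidences are clamped at 10⁻¹² before
  logs; no semantic effect at tested scales.

## Synthetic data: what it emulates, what it does not

`generate_feature_space` draws K isotropic Gaussian clusters (sd σ per
coordinate). Cluster means are placed at *exact* pairwise distance
δ·σ: K mutually orthonormal directions (QR of a Gaussian matrix,
available whenever K + 1 ≤ d) scaled by δ·σ/√2, around a shared
centroid of norm 2σ. The centroid reflects the positive mean pairwise
cosine similarity that real embedding spaces exhibit; with a zero
global mean, cosine statistics at δ = 0 fluctuate around zero and
ratio-based scores become sign-unstable for reasons unrelated to the
measure. δ is therefore one interpretable knob: 0 reproduces the fully
mixed picture of untrained representations, 4 the tight separated
clusters of fine-tuned ones.

`generate_stage_snapshots` shares cluster directions and per-sample
noise across the three stages, so the ascending separations (default
0 / 1 / 4) are the *only* difference between the randomly-initialized,
pretrained and fine-tuned spaces. This is what makes per-task score
monotonicity across stages a sharp property at moderate sample sizes
rather than a statistical tendency.

`generate_annotated_corpus` produces random amino-acid sequences with
non-overlapping spans per annotation kind (motif/domain/region, up to 3
each, lengths 1–12) whose category frequencies follow a Zipf law
(exponent 2 by default over the category inventory) — the long-tailed
shape that motivates both the `Other`-merging step and the equalized
focal loss. `simulate_adaptation_outcomes` generates adaptation
performance changes linear in task distance plus Gaussian noise, the
generative contract under which a negative rank correlation is the
correct detection.

All generators draw from named seed-derived streams
(`SeedSequence([seed, crc32(name)])`): adding a generator never shifts
another's stream, and identical spec + seed reproduces output bitwise.

What the synthetic model deliberately does *not* emulate: manifold
structure, anisotropic within-task covariance, heavy tails, or
task-size imbalance of real embedding corpora. Passing tests
demonstrate that the measure and its machinery behave correctly on
controlled geometry — not that any particular real representation will
show the same effect sizes.

## BIOES encoding

Coordinates are 1-based inclusive, matching UniProt feature
conventions, converted to 0-based arrays at the boundary. Each
annotation kind is encoded on its own tag track, since categories are
kind-qualified; overlaps across kinds are legal (different tracks),
overlaps within a kind are rejected at construction. A combined
single-track mode exists but errors on cross-kind overlap. Tags are
spelled `B-<Category>` etc.; decoding enforces the grammar (every
non-O run is S or B (I)* E with a consistent category) and reports the
1-based position of the first violation. The long-tail merge threshold
is a free parameter: real inventories depend on the annotation
snapshot, so no default threshold is claimed to reproduce any
particular merged-category count.

## Equalized focal loss

Parameters: α_t (positive/negative balance, default 1), γ_b > 0 (basic
focusing factor; it divides the weighting factor, hence the positivity
requirement), s ≥ 0 (scale of the imbalance-driven variable factor),
and per-category balance values g_j ∈ [0, 1] supplied by the caller —
how g_j is accumulated during training is the caller's policy, the loss
only requires the value. With g_j = 1 the loss reduces exactly to the
focal form with unit weight (property-tested); with g_j → 0 the
category's focusing factor grows to γ_b + s and its weight to
(γ_b + s)/γ_b. The combined pretraining objective is exposed as a
weighted sum of a cross-entropy term and an EFL term with unit default
weights.

## Problem sizes and design scope

The test-suite and the acceptance script run on small instances by
design: OT oracle comparisons at m, n ≤ 8 (where the LP is exact and
cheap), stage dynamics at K = 6, m = 50, d = 16, corpus roundtrips at
1000 short sequences. These sizes give sharp, deterministic checks;
the library itself scales to larger spaces via the Sinkhorn path and
the subsample cap. Known limitations: no unbalanced OT (task measures
must have equal mass), no Gromov-style comparison across different
embedding dimensions, and the exact solver is intentionally
size-guarded.
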