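# Methods

## Model and assumptions

The package treats each atom's sampled coordinates (after optional
rigid-body superposition of all frames onto a reference frame) as draws
from a Gaussian mixture with at most `K_cap` components.  A component
("mode") is a quasi-stable position; the mixture assumption is that an
atom's conformational substates are well separated relative to their
within-substate spread, which holds for the switching events the method
targets (site changes of several Å against sub-Å fluctuations) and
degrades gracefully otherwise: overlapping substates simply merge into
one broader mode and the statistic falls back toward the conventional
DCC.

Correlation between modes k and l of atoms i and j is the cosine between
the occupancy-weighted deviation vectors
√γ_t·(r_i(t) − μ_k) and √γ_t·(r_j(t) − μ_l) over the 3T frame
dimensions, with γ_t the product of the two posterior responsibilities.
Using the *same* weight in numerator and both denominator terms is what
guarantees |mDCC| ≤ 1 (Cauchy–Schwarz); it also means the statistic is a
correlation *conditional on joint occupancy*, not an unconditional one.
With one mode per atom at the sample mean, γ_t ≡ 1 and the statistic
reduces exactly to DCC (this identity is tested to 1e-10).

## Fitting

* Initialisation: labels from k-means started from uniformly random
  assignments (not random centroids), run to Lloyd convergence.
* Refinement: variational Bayes with a Dirichlet weight prior
  (concentration 1/K_cap, sparsity-leaning so surplus components drain),
  Gaussian–Wishart mean/precision prior (prior mean = cloud mean, β₀ = 1,
  ν₀ = 4, covariance prior = I · mean per-axis variance).  Convergence at
  per-sample ELBO change < 1e-6, cap 500 iterations.  The update loop is
  scikit-learn's `BayesianGaussianMixture`, subclassed only to accept the
  k-means responsibilities as the starting point.
* Restarts: 4 k-means starts plus 1 random-responsibility start, keeping
  the highest-ELBO solution.  The extra random-responsibility start is
  load-bearing: coordinate marginals of deterministic oscillations are
  bimodal-shaped (arcsine-like), and k-means labels always propose a split
  that is a *local* VB optimum, while the merged single-mode solution has
  the higher ELBO.  Multistart with ELBO selection finds it; a single
  k-means start does not.
* Pruning: modes with π < 0.01 are removed and weights renormalised (a
  mixture must stay a probability density); the largest mode is always
  kept.  Covariance eigenvalues are floored at 1e-6 Å² so constant
  coordinates cannot produce singular modes.
* Per-atom seeds derive from `SeedSequence(base_seed, spawn_key=(atom_id,))`,
  so results are independent of fitting order and safely parallelisable.

## Thresholds and numerical choices

* Co-occurrence omission: a mode pair is dropped when Σ_t γ_t <
  max(10 frames, 0.05·T).  A cosine over a few dozen partially-occupied
  frames is dominated by noise; the 5 % floor also drops pairs involving
  short transition segments (e.g. the drift ramp of the toy system, which
  occupies 4 % of the frames and forms its own low-weight mode).  Both
  the absolute and fractional floors are configurable.
* Undefined values (zero displacement variance, zero weighted norm, zero
  mass) are reported as missing, never as 0 — zero is a meaningful
  correlation value.
* Network edge rule: max-mDCC ≥ 0.5 AND distance between the maximising
  mode centers < 5.0 Å; the transient flag fires when the pair's DCC is
  below 0.5 (or undefined).  Betweenness is the classical unnormalised
  count over unordered pairs with endpoints excluded; percentile
  selections use ⌈p%·n⌉ with all boundary ties included, which keeps the
  result deterministic and seed-free.  Edge distance deliberately uses
  the argmax mode centers, not the minimum atom distance: the contact
  that carries the correlation is the one between the occupied substates.
* Superposition defaults to ON (reference = first analysed frame, fit
  over heavy atoms) because displacement statistics are meaningless under
  global rigid-body drift; it is a no-op for the synthetic generators,
  which have no global motion.

## Synthetic generators

The generators produce statistical stand-ins, not physical dynamics: noise
is per-step independent Gaussian with no autocorrelation, which keeps the
closed-form expectations exact.

* **Two-particle toy** (1,000 steps): shared sinusoid in x (amplitude
  1.0 Å, period 50), independent x-noise σ = 0.13 Å, y/z noise 0.02 Å;
  particle 1 ramps linearly 1.94 Å along y over steps 480–520.  Closed
  forms: Var_sin = amp²/2; DCC = Var_sin/√((Var_sin+σₓ²+2σ_yz²+Var_y)·
  (Var_sin+σₓ²+2σ_yz²)) ≈ 0.580; per-mode cosine = Var_sin/(Var_sin+σₓ²+
  2σ_yz²) ≈ 0.966.  The constants are chosen so these evaluate to the
  reference values (DCC ≈ 0.58, mode-pair mDCC ≈ 0.97).  The 40-step ramp
  necessarily forms a third mode of weight ≈ 0.03 — it is a genuine
  cluster, separated by many σ from both endpoints at any noise level
  compatible with the closed forms above — whose mode pairs fall below
  the 5 % co-occurrence floor and are omitted, leaving two surviving
  modes for particle 1 and one for particle 2.
* **Cluster clouds**: labelled isotropic Gaussians for mixture-recovery
  tests (default scenario 500+500 points, 10 Å apart, unit σ).
* **Flip system** (3 atoms, 1,000 steps): atom A alternates between two
  sites 8 Å apart in four dwell segments, sharing an isotropic
  σ = 0.3 Å signal with B at site 1 and with C at site 2, over
  σ = 0.1 Å jitter.  Expected within-site coupling ≈ 0.9 at near-zero
  global DCC — the transient-contact scenario.

Because the generators lack autocorrelated dynamics, solvent effects and
anisotropic wells, passing tests demonstrate the correctness of the
statistics and their implementation, not the physics of any particular
molecular system.

## Problem sizes

The shipped analyses run at desk scale: 1,000-frame trajectories with 2–4
atoms, mixture fits on ≤ 1,000 points, networks of ≤ 13 nodes for the
exhaustive betweenness cross-checks, and 20-seed repetition loops for the
stochastic recovery claims.  All-pairs mode correlation is O(N²·K²·T);
for large systems the residue-map stage accepts contact-restricted atom
subsets and the representative-atom variant (Cα / C5′) as the standard
cost reducers.

## Known limitations

* Mode models are fitted per atom independently; no shared clustering
  across atoms, no model selection beyond weight pruning (no BIC scans),
  no non-Gaussian substates.
* No lagged or time-delayed correlation, and no mutual-information
  generalisation; the statistic is linear within each mode pair.
* The VB fit can land in a split local optimum on heavily non-Gaussian
  unimodal clouds in rare seed/noise combinations (observed roughly once
  in 20 toy realisations even with 5 restarts); the multistart default
  makes this rare but cannot exclude it.
* GraphML/TSV export is the visualisation boundary: no layout or
  rendering.
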