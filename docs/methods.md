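# Methods

This note documents the models, numerical choices, and open design
decisions behind `endonet`, and what the synthetic-data tests do and do not
demonstrate about real data.

## The analysis model

**Connectivity.** Functional connectivity between two nodes is the Pearson
correlation of their preprocessed time series. Correlation matrices are
proportionally thresholded: the strongest `density` fraction (default 0.2)
of the N(N−1)/2 connection weights is retained per subject, where
"strongest" means largest *signed* correlation — negative ties are
conventionally excluded at 20% density, and a magnitude-ranked variant
(`absolute_threshold_mode`) is available behind a flag. The retained count
is round-half-away-from-zero of `density · N(N−1)/2` (6631 at N = 258),
and ties at the cut are broken by (row, col) lexicographic order so the
edge set is reproducible. Whole-brain connectivity defaults to the mean
over retained edges; a companion `all_pairs` mode divides the retained sum
by all pairs, since either construction is defensible for group-mean
summaries.

**Graph metrics.** The weighted clustering coefficient uses the Onnela
geometric-mean form with weights scaled by the network maximum — the
de-facto standard for weighted undirected matrices in the complex-network
literature, which the source description does not pin down further. Global
efficiency maps weights to lengths by the standard reciprocal transform
`l = 1/w`; disconnected pairs contribute 0. Both are normalized by the
ensemble mean over 100 random networks (see below). Whether raw or
normalized weights feed the metrics before null division is not fully
determined by the method description; metrics here are computed on the raw
thresholded weights, and both raw and normalized values are reported side
by side.

**Null ensemble.** Each null network preserves, exactly: node count, edge
count, the binary degree sequence (via 10·E attempted double-edge swaps),
and the weight multiset. The strength sequence cannot in general be
preserved exactly on a rewired topology, so weights are reassigned by
greedy rank matching: weights are placed in descending order, each on the
unassigned edge whose endpoints have the largest residual target strengths,
decrementing the residuals. On 258-node, 6631-edge networks the resulting
strength sequences correlate with the original at r ≈ 0.999 (the
acceptance property requires ≥ 0.9).

**Node disruption index.** For subject strengths `s` and a reference
template `s̄` (the control-group mean strength profile), the NDI is the OLS
slope of `s − s̄` on `s̄`, with intercept. Identities used as exact tests:
NDI(s̄, s̄) = 0, NDI(k·s̄, s̄) = k − 1, NDI(s̄ + c, s̄) = 0 with intercept c.
Control subjects are evaluated against the full-group template by default;
a leave-one-out mode excludes each control from their own template.
Alternative templates (sibling- or ASC-group means) are supported for
group-homogeneity analyses.

**Hubs.** Hubs are the top round(0.2·N) nodes by strength (52 at N = 258),
ties broken by node id; counts are tallied over the 9 analysed networks.
The alternative hub definition exposed behind `method="degree"` ranks by
binary degree; it is provided as a robustness check only, with no claim of
equivalence to any particular published variant.

**Motion QC.** FD is the sum of absolute backward differences of the six
realignment parameters, rotations converted to displacement at a 50 mm
radius. The subject-level motion scalar for the edgewise profile is
configurable (`max_fd` default, `mean_fd`, `max_spike`). The
distance-ordered moving average uses a centred window of 5% of edges
(minimum 3), shrinking at the boundaries; the reported slope is fitted by
OLS on the raw per-edge correlations (fitting the smoothed curve is
available via `fit_on="moving_average"`), per mm and reported per metre.
Permutation p-values use the add-one estimator
`p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)`, so 100 permutations bound p
below by 1/101.

**Statistics.** One-way fixed-effects ANOVA with (k−1, N−k) degrees of
freedom, computable identically from raw data or from group means/SDs/sizes
(`SSB = Σ n_g(m_g − m̄)²`, `SSW = Σ (n_g−1)sd_g²`). Note that for a
3 × 14 design this gives df = (2, 39); published tables sometimes print
(2, 41)-style df, which is a software notation idiosyncrasy this package
does not replicate. t-tests are Student (pooled variance), matching
df = 26 for two groups of 14. The endophenotype classifier requires a
significant ANOVA, strictly monotone group means (CON > SIB > ASC, or
inverted for a reversed pattern), and a significant ASC-vs-CON planned
comparison; the SIB-vs-CON test is reported but not required. No
multiple-comparison correction is applied anywhere; reports carry the
number of tests performed.

## Preprocessing choices

The 32-regressor confound model is {8 base, 8 backward-difference
derivatives (leading zero), 16 squares of those}; the derivative is a plain
difference (no Δt division). Constant and exactly duplicated confound
columns are absorbed/dropped; any remaining rank deficiency is an error
that names the redundant columns. The band-pass is an ideal zero-phase DFT
mask — deterministic, idempotent and exactly linear, matching the
"0.01 Hz high-pass, optional 0.1 Hz low-pass" description at bin
resolution. Despiking (off by default for synthetic runs, where the
generator produces no signal spikes) clips values beyond 4 MADs from a
window-7 running median. Stage order is despike → regress → filter;
regressing before filtering avoids reintroducing confound energy into the
passband.

## The synthetic cohort

The generator emulates the *statistical* structure the analysis assumes,
not fMRI physics:

- **Design**: 3 groups × 14 subjects, 258 nodes in 14 networks, TR = 2 s,
  T = 300 timepoints by default.
- **Signal**: `x_it = g·h_i·F_t + w·G_t^net(i) + c₁U_t + c₂V_t + ε_it`,
  all factors independent unit-variance Gaussian series band-limited to
  0.01–0.1 Hz, ε white with sd 1. The implied noiseless covariance is
  positive semidefinite by construction. Defaults: global coupling
  g = 0.8 / 0.6 / 0.4 for CON / SIB / ASC (the hypoconnectivity gradient;
  no published effect size exists for it, so these are calibration choices
  giving clearly separated but sub-ceiling group means), within-network
  loading w = 0.5, confound loadings 0.2.
- **Node heterogeneity**: per-node multipliers `h_i ~ U[0.5, 1.5]` on the
  global coupling, drawn once per cohort and shared by all subjects. Real
  strength profiles are heterogeneous and stable across individuals
  (hubs); without this the group-average strength template would carry no
  node-level signal and the NDI could not distinguish groups.
  `node_coupling_spread = 0` recovers the exchangeable-node model, for
  which the closed-form correlations (within-network r → 1, cross-network
  r → g²/(g²+w²) as noise → 0) are verified by test.
- **Parcellation**: centroids uniform in a 70 × 85 × 60 mm ellipsoid
  (rejection sampling), near-equal network sizes. The packaged 264-node
  file is such a synthetic stand-in (flagged `synthetic` in its name) with
  the 6 lowest-z nodes marked excluded, leaving the 258 analysis nodes;
  only relative distances matter for the artifact model.
- **Motion**: per-parameter Gaussian random walk (0.02 mm / 4·10⁻⁴ rad per
  step, giving mean FD ≈ 0.1 mm) plus persistent translation-level shifts
  of 0.5 mm at rate 0.02/frame. The optional artifact adds
  `gain · FD(t) · u_i(t)` where `u` is a spatially correlated Gaussian
  field with covariance `exp(−d_ij/scale)` — a valid kernel in ℝ³ — so FC
  inflation decays with inter-node distance. The artifact test condition
  (gain 5, scale 60 mm) was fixed so the artifact amplitude at typical FD
  is comparable to the factor loadings, i.e. non-negligible but not
  dominant.

What passing tests show: the pipeline recovers a planted connectivity
gradient, orders group-mean NDI correctly, stays calibrated under a true
null, and detects a planted distance-dependent artifact. What they do not
show: robustness to haemodynamics, task-evoked structure, spatially
structured noise, scanner drift, or realistic motion spectra — none of
which the generator models (conditions differ only by seed and label).

## Problem sizes and determinism

Stochastic properties are asserted at sizes chosen to make the checks sharp
but quick: permutation-test calibration over 200 cohorts of 20 subjects ×
20 nodes; artifact-slope sign and endophenotype recovery over 20 seeded
cohorts each (full 258-node cohorts for the latter); 2000 simulations for
ANOVA type-I calibration; 200 random graphs (N ≤ 6) against brute-force
clustering/efficiency oracles at 1e-10. Every random stage derives its seed
from a master seed and the stage name via SHA-256, so reports are
byte-identical across reruns and changing one stage's randomness never
perturbs another. Cohorts written to disk round-trip at 12 significant
digits; pipeline runs with an output directory consume the cohort as
written, so cached reruns are bit-identical.

## Known limitations

- The NDI of control subjects uses the full-group template by default, so
  small positive biases toward 0 are expected for controls; leave-one-out
  is available but changes the template per subject.
- The greedy strength-matching heuristic preserves strengths approximately;
  on very small or rigid topologies (e.g. triangles) rewiring is a no-op
  and nulls reduce to weight permutations.
- `anova_from_summary` inherits the rounding of its input summaries;
  reconstructed F statistics are only as precise as the printed means/SDs.
- The despike stand-in (running-median/MAD clip) is a simple, testable
  choice; published despiking tools differ in detail.
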