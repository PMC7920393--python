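# Methods

## Model

Seizure propagation is modeled as threshold dynamics on a weighted directed
network. Region *i* has a slow variable *z_i* with *z_i*(0) = 0 and

    dz_i/dt = f_q(c_i, y_i),    y_i(t) = Σ_j w_ij · H(z_j(t) − 1),

crossing the threshold *z* = 1 at the onset time *t_i* = min{t : z_i ≥ 1}.
`w_ij` is the connection strength from region *j* to region *i*; the
connectome is normalized so `max_i Σ_j w_ij = 1`, which confines the input
*y* to [0, 1]. The excitation function is
`f_q(c, y) = exp(f̂_q(c, y))` with `f̂_q` the bilinear interpolant through
the anchors (c, y) ∈ {−1, 1} × {0, 1} with values `q_aa, q_ab,
q_ba = q_aa + q_ba*, q_bb = q_ab + q_bb*`; the starred parameters are
nonnegative so `f_q` is nondecreasing in *c*. The same bilinear formula
extrapolates outside the anchor square (with c ~ N(0, 1), |c| > 1 is
routine). The exponent is clipped to |f̂| ≤ 60 — rates between e⁻⁶⁰ and
e⁶⁰ s⁻¹ — purely to keep arithmetic finite while samplers explore extreme
hyperparameters; the clip zeroes the local gradient far outside any region
of posterior mass.

Assumptions worth keeping in mind: a region is binary (healthy/seizing),
never stops seizing once recruited, and the dynamics (through *q*) is shared
across seizures and patients — only the excitabilities *c* and the
connectome differ between seizures. Seizure offset is not modeled, which is
why the seizure time limit exists at all.

## Constants

| constant | default | unit | role |
|---|---|---|---|
| `t_lim` | 90 | s | seizure time limit; onset ≥ t_lim ⇒ non-seizing |
| `sigma_t` | 5 | s | onset observation noise SD |
| `sigma_q` | 30 | — | (half-)normal hyperprior scale on q |
| `t1` | 30 | s | alignment time of the earliest observed onset |
| `T` | 5 | s | tolerance of the onset prediction accuracy |
| `c_h` | 2 | — | high-excitability threshold; p(c > c_h) scores the EZ |
| `delta` | 5 | — | band-power factor declaring ictal activity |

All are exposed via `ModelConstants` and serialized in one JSON schema.
Times are seconds throughout, rates 1/s.

## Exact simulation and inversion

Between threshold crossings the right-hand side is constant, so the forward
problem is solved exactly event-by-event: the next event is
`min_i (1 − z_i)/rate_i` over non-seized regions; all regions reaching the
threshold at the same instant are switched before inputs are recomputed
(simultaneous crossings are measure-zero in *c*; processing them one at a
time with zero-length intervals is equivalent). The Heaviside convention is
H(0) = 1: a region counts as seizing from its onset instant. A first-order
fixed-step integrator (`simulate_dense`, left-endpoint Heaviside, default
dt = 1 ms) serves as an independent oracle; its onset error is bounded by
the per-event recursion `Δ_i ≤ (max predecessor Δ + dt)·ρ_i + dt` with ρ_i
the max/min rate ratio the region traverses, and the test suite asserts
this bound on random instances.

With complete noiseless onsets, each *c_i* solves
`Σ_k f_q(c_i, y^(k)) Δt_k = 1` over the constant-input intervals before
*t_i*; the left side is continuous and strictly increasing in *c_i* (range
(0, ∞)) whenever `q_ba* + q_bb* > 0`, so the root is unique. It is bracketed
by geometric expansion from [−50, 50] and bisected to |Δc| < 1e−10. The
degenerate case `q_ba* = q_bb* = 0` (rate independent of *c*) is reported as
non-identifiable. Onsets containing +∞ are rejected: the exact inversion is
defined only for fully seizing, fully observed networks.

Classification conventions: seizing iff *t_i* < *t_lim* (the boundary
*t_i* = *t_lim* is non-seizing, matching the strict inequality used by the
state accuracy); +∞ marks "never seized within t_max" and serializes as
`inf` in CSV.

## Statistical models and sampling

Single-seizure: `c ~ N(0, I)`, `t = P_{W,q}(c)`,
`t̃_i ~ N(min(t_i, t_lim), σ_t)` for observed seizing regions and
`t_lim ~ N(min(t_i, t_lim), σ_t)` for observed non-seizing regions — a
one-sided soft penalty applied exactly as written, with no renormalization;
once the simulated onset passes t_lim the term saturates and its gradient
vanishes. Hidden regions contribute nothing. Multi-seizure adds
`q_aa, q_ab ~ N(0, σ_q)`, `q_ba*, q_bb* ~ HalfNormal(σ_q)` and couples the
seizures only through *q*.

Onset times are piecewise-smooth in (c, q): derivatives are exact within a
fixed event order and the order switches on a measure-zero set. The solver
therefore propagates forward-mode tangents (all *n* excitabilities plus the
four raw hyperparameters) through the event cascade, giving exact gradients
of the log posterior almost everywhere; at the `min(t, t_lim)` kink the
saturated branch's zero gradient acts as a subgradient. Sampling uses a
No-U-Turn sampler (slice variant with doubling, divergence guard at energy
error 1000) with dual-averaging step-size adaptation (target acceptance
0.8) and Stan-style windowed diagonal mass-matrix estimation. Validity does
not depend on gradient smoothness: the slice acceptance uses the exact log
density, so kinks cost efficiency, not correctness. The half-normal
parameters are sampled on the log scale with the Jacobian correction.
Chains initialize from the prior for *c*; for the hyperparameters the
unconstrained components start from standard-normal draws rather than the
σ_q = 30 prior, whose tails produce degenerate all-instant or never-seizing
cascades that waste warmup. An affine-invariant ensemble backend (emcee) is
available as a gradient-free fallback and as an independent cross-check on
small problems; defaults are 2 chains (single-seizure) and 4 chains
(multi-seizure) with 500 warmup + 500 kept draws.

Diagnostics are split-chain R̂ and N_eff (arviz; N_eff capped at the total
draw count, the classical definition). A chain is flagged *stuck* when its
within-chain log-posterior variance falls below 1e−8 (configurable); fits
with all chains stuck must be discarded, and leave-one-out automatically
excludes and logs them.

## Preprocessing

Connectome: streamline counts are divided by target-region volume; for each
anterior/posterior hippocampus pair both directed entries gain the 98th
percentile (linear interpolation, computed over **all** entries of the
volume-scaled matrix; a flag restricts to nonzero entries) to compensate
gray-matter connections invisible to tractography; then the global
ingoing-sum normalization. The pipeline is scale invariant in the counts.

SEEG onset detection: log-power (natural log, so the threshold `log δ`
matches a δ-fold power change) in 1–12.4 Hz and 12.4–100 Hz bands from a
DPSS multitaper sliding-window estimate — 2 s windows, 1 s steps, 3 tapers,
time-bandwidth 4. The exact spectrogram configuration is secondary because
the 20 s mask smoothing dominates the timing; all of it is exposed as
keyword configuration. The baseline is the mean log-power over the 60 s
preceding the clinician's mark, ending at the mark (the mark itself is not
included). The printed mask rule is one-sided (`> log δ`); a `two_sided`
option also triggers on δ-fold decreases but is off by default — the
one-sided rule is what the mask formula states. The mask is smoothed with a
centered, area-normalized 20 s rectangular window (zero-padded at the
edges), re-binarized at 0.5, and seizure intervals strictly shorter than
20 s are deleted.

Mapping: a channel joins its nearest region (minimum Euclidean distance
from the contact midpoint to the region's voxels, 0 inside) unless the
ambiguity rule `d2/(d1 + 0.5 mm) < 2` leaves it unassigned. No upper
distance cap is applied, but midpoints more than 5 mm from gray matter are
logged as suspicious. Region status and onset come from the median of the
assigned channel onsets with non-seizing channels at +∞ and *lower*
interpolation for even counts (sorted element ⌊(k−1)/2⌋); this coincides
with the channel-majority rule, even splits resolving to seizing. Seizures
are aligned so the earliest onset sits at t1 = 30 s, onsets beyond t_lim
become non-seizing, seizures with no seizing region are excluded, and only
seizures strictly longer than 30 s enter a cohort.

## Validation machinery

State prediction accuracy is the fraction of posterior onset draws on the
correct side of t_lim; onset prediction accuracy the fraction within T = 5 s
of the truth, evaluated only for seizing regions with onset < t_lim − T.
The unweighted estimate replaces the posterior draw set by the other
observed onsets; the weighted estimate weights region *j* by
`w_ij + w_ji`, normalized once (the standard weighted average — "each onset
repeated proportionally to the weight"). Virtual resection removes the
resected set (resection extent strictly above 50%), re-simulates every
posterior excitability draw on the surviving subnetwork, and counts regions
with recruitment probability strictly above 50% at t_lim; n_preop counts
over all original regions, n_postop over survivors, and the
thresholding-free variant reports mean recruitment probability with
resected regions contributing 0 post-op. Per-patient aggregation over
seizures defaults to the mean (min available). Precision/recall compare
`{i : p(c_i > c_h) > p_t}` with the resected set over a threshold grid;
at zero predictions precision is reported as 1 with an explicit flag and
such points are dropped from curves by default. Permutation feature
importance is `i_j = s − mean_k s_{k,j}` over K = 30 reshuffles of column
*j*, for any fitted regressor exposing predict/score (the regressor itself
is deliberately pluggable).

## Synthetic data

The generators mirror the model's own generative assumptions: networks with
Bernoulli(density)-masked log-normal(0, 1) weights (heavy-tailed like
streamline counts) under the standard normalization; seizures with
c ~ N(0, 1), exact forward simulation, uniformly random hidden sets, and
Gaussian onset noise clipped to (0, t_lim]; band-limited-noise SEEG
channels whose variance steps gain-fold at onset; and resection scenarios
(true-EZ or random-k). Defaults are the study conditions used by the test
suite: n = 20 regions, 30 seizures (15 patients × 2, one network per
patient), hidden fraction 0.3, noise σ_t = 5 s, and a default true
q = (−4, 0, 2, 3) — moderately coupled dynamics in which isolated regions
seize within t_lim only if excitable while seizing input accelerates
recruitment, chosen once as a realistic middle ground between uncoupled
and instantaneous-cascade regimes. These sizes keep a hierarchical fit in
the one-minute range while still constraining all four hyperparameters.

What the synthetic data does **not** emulate: real SEEG morphology (spikes,
DC shifts, artifacts — only band-power structure), biased electrode
implantation (hidden sets are uniform, real implantations target suspected
regions), patient-level heterogeneity of dynamics, and parcellation/
source-projection errors. Passing tests therefore demonstrate internal
consistency of model, inversion, and scoring — not clinical performance.

## Known limitations and numerical caveats

- The generative noise clip at (0, t_lim] and the pseudo-likelihood for
  non-seizing regions mean posterior credible intervals are only
  approximately calibrated; repeated-cohort coverage of 90% hyperparameter
  intervals can run a few points below nominal. Simulation-based
  calibration in a regime where the generator matches the likelihood
  exactly (part of the test suite) shows uniform ranks and near-nominal
  coverage, i.e. the sampler itself is unbiased.
- `q_bb*` (excitability–input interaction) is weakly identified at cohort
  scales of tens of seizures; its posterior leans on the half-normal prior.
- Gradient-based sampling relies on the realized event order; posteriors
  concentrated exactly on an order-switch boundary would mix slowly (not
  observed in practice).
- The event-driven solver is exact, so all numerical tolerances live in the
  inversion (bisection 1e−10), the dense oracle (first-order in dt), and
  MCMC (divergence guard 1000, stuck-chain variance 1e−8).
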