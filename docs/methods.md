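# Methods

`moraltrace` re-implements, on synthetic data, the computational analysis
of a repeated moral-decision experiment: participants repeatedly transmit
trivia answers across 9 runs of 20 questions, choosing between the
correct answer and an incorrect answer that usually carries a larger coin
reward, with the history of their own previous choices (cumulative
responses, CR) displayed from run 2 onward.  The pipeline quantifies
choice conflict from cursor trajectories, choice consistency from
response entropy and CR, decomposes decisions with a hierarchical
multi-attribute drift–diffusion model (DDM), and links the fitted
parameters to synthetic neural-pattern similarity and connectivity-graph
structure.

## Task generator and study conditions

The generator (`moraltrace.synth`) is first-class, tested code.  Its
defaults encode the study conditions:

* **Design.** 9 runs × 20 questions per subject; integer rewards uniform
  on 1–9 coins; in 80% of cells the incorrect answer's reward strictly
  exceeds the correct answer's (the realized design; the conservative
  "over half" setting is one argument away); the correct answer's side
  is balanced left/right within each run.
* **Choices and RTs** come from the diffusion model itself (Euler–
  Maruyama at dt = 1 ms, unit diffusion): the upper boundary is the
  dishonest choice, responses slower than the 4 s window are timeouts and
  never advance the CR counters.  Default group-level parameters produce
  a pooled lie rate near one third with wide between-subject spread, a larger
  consistency (CR) weight than reward weight, response times that shorten
  across runs (threshold slope α_s < 0), and a slight initial bias toward
  honesty — the qualitative behavioral signature the analyses assume.
* **Trajectories** are a damped-attractor polyline from (0, 0) to the
  chosen top corner whose pull toward the unchosen side scales with a
  supplied conflict scalar plus endpoint-pinned smooth noise.  This is
  fixture machinery, not a cognitive model; its only contract is that the
  standardized AUC grows with the conflict scalar and is zero for a
  straight noise-free path.
* **Neural patterns** plant an inter-subject representational geometry
  via a random-Fourier-feature embedding of each subject's 2-D parameter
  vector (weights of relative CR and relative reward): for voxel k the
  signal is cos(ω_k·p + b_k) with ω_k ~ N(0, 1/ℓ²), so expected pattern
  correlation decays as the Gaussian kernel of parameter distance.  The
  `signal` proportion mixes this embedding with independent noise;
  signal = 0 is an exact null.  The length scale ℓ defaults to the RMS
  pairwise parameter distance.
* **ROI time series** are per-run multivariate Gaussians with a latent
  correlation structure; specified edges receive per-run increments so a
  rising coupling is recoverable downstream.

What the generator does **not** emulate: questionnaire scores, scanner
noise spectra, hemodynamics, motion artifacts, spatial voxel structure,
or any systematic mapping from trial events to BOLD.  Passing tests
therefore demonstrate the correctness and calibration of the estimators
under the assumed statistical structure, not their robustness to real
fMRI preprocessing.

## Mouse tracking

Raw pixel trajectories are affinely rescaled so the start button maps to
(0, 0) and the screen's top corners to (±1, 1); right-ending paths are
mirrored to the left; time is normalized to 101 equally spaced bins by
linear interpolation.  The conflict metric is the signed shoelace area
between the path and the straight start→end chord: excursions toward the
unchosen option count positive, overshoot on the chosen side negative
(the standard mouse-tracking sign convention; an absolute-value variant
is available).  Self-intersecting paths contribute algebraically; y is
not forced monotone.  The 60 Hz source rate is metadata only.

## Response consistency

Per subject, the lie rate p is the mean of the dishonesty indicator over
non-timeout trials and consistency is the binary entropy
H(p) = −p log₂ p − (1−p) log₂(1−p) (0·log 0 := 0), maximal at p = ½.
Trial-level consistency uses the CR counters; relative CR is the
incorrect-minus-correct count and the history response h ∈ {−1, 0, +1}
is the previous run's choice for the same question.  All relative
quantities are incorrect-minus-correct, so positive reward or CR
differences should push toward lying.

## Diffusion-model family

Seven nested models share drift
v_t = (w_r + δ_r·s̃)·R̃_t + (w_c + δ_c·s̃)·C̃_t [+ w_h·h_t],
threshold a_t = exp(α0 + α_s·s̃) (log link guarantees a > 0), bias
z_t = logistic(ζ0 [+ ζ_s·s̃] [+ ζ_h·h_t]), and a subject-level
non-decision time t0 — without t0 no diffusion model can fit the RT
floor, so it is included even though it is a nuisance parameter.  s̃ is
the run index mapped linearly to [−1, 1] (a 3-session coding is a config
option).  M1 fixes δ_r = δ_c = 0 and has no ζ_s; M2/M3/M4 free δ_c, δ_r,
or both; M5 adds ζ_s; M6 adds ζ_h; M7 instead adds w_h to the drift.

**Covariate normalization.** The default is design-referenced and
causal: R̃ is the within-subject z-score of the relative reward over the
full design (known before any choice), and C̃ divides relative CR by
√(run−1), its standard deviation under exchangeable coin-flip choices.
Because both rules are computable before the choice is made, the same
transformation serves generation and fitting, which makes
simulate→fit parameter recovery well-posed: a z-score over the realized
table would depend on the subject's own choices and put the generating
and recovered weights on different scales.  Within-subject z-scoring of
both quantities remains available (`normalization="zscore"`) for use on
observed data.

**Likelihood.** The Wiener first-passage density is evaluated with the
standard pair of series expansions (image-charge sum for small
normalized time, spectral sine series for large), switching to whichever
needs fewer terms at an absolute tolerance of 1e-7; upper-boundary
densities evaluate the lower-boundary formula at (−v, 1−z).  Trials with
RT outside [0.3, 4.0] s are excluded with a counted warning.  The lower
cut is a contaminant filter for real data: synthetic data generated by
the model itself contain no contaminant fast guesses, so recovery
studies fit with the window open (`rt_min=0`) — excluding legitimate
model RTs without a truncation correction measurably attenuates the
session-slope parameters.  Timeouts (responses slower than the 4 s
window) are excluded without a censoring term, matching the study
procedure; at the defaults they are ~0.3% of trials and the residual
bias is well inside posterior uncertainty.

**Estimation.** Subjects are draws from group-level normals on the link
scale; priors are weakly informative (group means N(0, 2²), except the
threshold intercept centered at 0.5 and t0 at 0.3 s; group SDs
half-normal(1)).  The sampler is adaptive Metropolis-within-Gibbs run
entirely inside a numba-compiled kernel: subject parameters update in
three blocks (drift weights; threshold/bias; t0) with proposal scales
adapted toward 30% acceptance during burn-in and frozen afterwards;
group means are conjugate; group SDs update by Metropolis on the log
scale.  Two interweaved non-centered moves — translating the group mean
together with all subject values, and rescaling all subject deviations
together with the group SD, alternating across iterations with their own
adapted scales — break the funnel that otherwise traps weakly identified
session-slope parameters.  Defaults are desk-scale: 4 chains × 3,000
iterations with 1,000 burn-in and no thinning, chosen so that all
split-chain R-hat statistics (group means and SDs) fall below 1.1 on the
shipped synthetic fixtures; larger settings are plain constructor
arguments.  Group SDs are floored at 1e-4 to avoid degenerate collapse.

**Comparison and checking.** DIC focuses on the subject-level
parameters: D̄ is the posterior-mean deviance over a subsample of draws,
D̂ the deviance at posterior means, pD = D̄ − D̂ and DIC = D̂ + 2pD.
Posterior probabilities of parameter statements (e.g. w_c > 0,
|w_c| > |w_r|) are fractions of group-mean draws.  Posterior predictive
checks re-simulate the full design per posterior draw and compare
per-run choice proportions and RT quantiles (0.1–0.9) with central 95%
predictive intervals.

## Sensitivity and mediation

The minimum detectable correlation solves
atanh(r)·√(n−3) = z_{1−α/tails} + z_{power} (Fisher-z approximation);
at n = 34, 80% power, two-tailed α = .05 it returns 0.46.  A generic
Monte-Carlo power routine takes a data generator and a fitting function
and reports the rejection proportion per effect size with binomial
standard errors.  Mediation uses the product-of-coefficients
decomposition with OLS paths (a: m~x; b, c′: y~x+m; c: y~x); the
c = c′ + a·b identity is exact.  Intervals are percentile, via
nonparametric bootstrap over subjects (default 5,000 resamples) or
Monte-Carlo sampling of (a, b) from their normal sampling distributions.

## Neural similarity and IS-RSA

Template similarity is the Pearson correlation between a pattern and a
reference map inside the map's suprathreshold mask (z > 3.0); run trends
are tested by pooling subject × run values and regressing on the run
index (F-test with partial eta squared), plus a per-subject last-minus-
first change score.  IS-RSA correlates (Spearman) the condensed model
RDM (pairwise Euclidean distance in (v_CR, v_reward) space) with the
condensed neural RDM (1 − inter-subject pattern correlation, so a
positive rho means parameter-similar subjects have similar patterns);
significance comes from jointly permuting rows and columns of the model
RDM (default 10,000 shuffles), reporting both the plain exceedance
proportion and the (1+k)/(1+n) convention.  The permutation is one-sided
by default (two-sided optional).  FDR across parcels is
Benjamini–Hochberg at q = 0.05.

## Connectivity graphs

Per run, connectivity is the Fisher z-transform of pairwise Pearson
correlations of ROI time courses (z capped at atanh(1−1e-7)).  For graph
metrics, negative edges are zeroed by default (absolute-value weighting
optional) and edge length is 1/weight.  Global efficiency is the mean
inverse shortest-path length over ordered pairs (disconnected pairs
contribute 0); betweenness is weighted shortest-path betweenness with
equal tie splitting, normalized by (n−1)(n−2)/2.  The canonical node set
is the nine regions spanning cognitive-control, self-referential and
reward networks (DLPFC, IFG, ACC, PCC, bilateral TPJ, NAcc, caudate,
precuneus), but the module is node-set agnostic.  Brain–behavior
associations use Pearson r with a Fisher-z 95% CI.

## Pipeline

One validated YAML config (pydantic schema: unknown keys rejected by
name, errors aggregated) drives the stages simulate → mouse tracking →
behavior → DDM fitting/comparison → PPC → mediation → IS-RSA →
connectivity → report.  Stages exchange delimited text and JSON in a run
directory, are individually skippable and resumable, and a manifest
stores the config hash, seed and stage list.  All floats are serialized
with fixed formats so identical configs give byte-identical outputs.
The CLI (`moraltrace`) exposes each stage as a subcommand plus `all`.

## Problem sizes

Test and demo problem sizes are deliberately desk-scale, chosen as the
smallest sizes at which each check is statistically meaningful: the
density oracle uses 4×10⁵ Euler trials per parameter set at dt = 1e-4;
the parameter-recovery study 10 simulated datasets of 20 subjects × 180
trials with 3 chains × 3,000 iterations; the DIC model-recovery study 10
datasets of 16 subjects against models {M1, M4, M5}; IS-RSA calibration
500 null replicates at 1,000 permutations and power at 100 seeds; the
demo pipeline 10 subjects with reduced MCMC.

## Known limitations

* The sampler is random-walk based; posteriors with strong subject-level
  correlations mix more slowly than gradient-based samplers would, which
  is why the interweaved moves and the convergence contract (R-hat < 1.1
  at defaults) matter.
* DIC is reported because it is the family's conventional comparison
  criterion for hierarchical models; it is known to favor complexity
  mildly and no cross-validated criterion is provided.
* Parameter recovery is demonstrated under the generator's own
  normalization convention; applying the z-score convention to data
  generated under another convention rescales the recovered weights.
* The trajectory and neural generators are deliberately simple; effects
  that depend on richer temporal or spatial structure are out of reach
  of the shipped tests.
* Inter-trial variability parameters (sv, st, sz) are not modeled.
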