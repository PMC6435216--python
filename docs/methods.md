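# Methods

## The generative model

Each cortical source contains three neuronal subpopulations — spiny
stellate cells, inhibitory interneurons and pyramidal cells — coupled by
four intrinsic gains. Every synapse is a second-order convolution
kernel

    v'' = H κ u − 2 κ v' − κ² v

driven by presynaptic firing `u`; firing is a sigmoid of membrane
potential, linearized at the operating point with a constant slope, so
the whole network is a linear stochastic state-space system (8 states
per source). Extrinsic connections are typed by the cortical hierarchy
and target different subpopulations: forward → stellate cells,
backward → pyramidal and inhibitory populations, lateral → all three.
Each carries a free log gain `g`; the effective coupling is
`baseline · exp(g)`, strictly excitatory by construction.

Fixed constants (units, value, rationale):

| constant | value | meaning |
|---|---|---|
| H_e, H_i | 4, 32 mV | excitatory / inhibitory synaptic gain |
| κ_e, κ_i | 1/8 ms⁻¹, 1/16 ms⁻¹ | synaptic rate constants |
| γ₁..γ₄ | 128·(1, 4/5, 1/4, 1/4) | intrinsic coupling gains |
| baselines | 64 / 16 / 4 | forward / backward / lateral extrinsic coupling before exp-scaling |
| slope | 0.2 | linearized sigmoid slope |
| drive | 16 | innovation input amplitude (unit convention) |
| delays | 2 ms intrinsic, 16 ms extrinsic | conduction delays |

These are conventional magnitudes for convolution-based mass models.
Two interact critically: the sigmoid slope and the extrinsic baselines
jointly set both the stability margin and how visible between-source
coupling is in the cross-spectrum. A single common baseline large
enough for forward gains to be identifiable from windowed CSD
destabilizes the 4–5-source preset networks through their reciprocal
forward/backward loops; the conventional asymmetry — strong driving
forward connections, weaker modulatory backward and lateral ones —
gives both preset networks a comfortable stability margin at the prior
mean while keeping forward coupling identifiable on the 2-node test
network. Delays are folded into the Jacobian by the first-order Taylor
correction `(I + J∘D)⁻¹J` rather than state augmentation, keeping the
resolvent small.

The predicted channel CSD on the analysis grid is

    S(f) = L T(f) G_u(f) T(f)ᴴ Lᵀ + G_n(f)

with `T(f) = C (i2πf·I − J)⁻¹ B` the transfer function from per-source
innovations to pyramidal depolarization, innovation spectra
`G_u(f) = exp(a₀)(1 + exp(a₁)/f)` per source, and channel noise
`G_n(f) = (exp(b₀) + exp(b₁)/f)·I`. The gain matrix `L` is
user-supplied (head-model computation is out of scope); synthetic
cohorts draw Haar-random orthonormal columns, because near-collinear
source topographies — which plain unit-norm random columns produce with
non-negligible probability — make sources unresolvable for any method,
a degeneracy real lead fields of well-separated cortical patches do not
exhibit.

## Priors and the feature space

Free parameters per window: one log gain per extrinsic connection
(prior N(0, 1/16)), one innovation log-amplitude per source and three
global spectral/noise log-amplitudes (prior variance 1/8, noise floor
centred at e⁻² below the neuronal spectrum). The data vector of a
window is the non-redundant stacking of its Hermitian CSD matrices —
the real upper triangle plus the imaginary strictly-upper triangle per
frequency. Stacking *every* matrix entry would count each off-diagonal
degree of freedom twice and make posteriors overconfident by √2 under
the iid feature-noise model; with the non-redundant stacking, nominal
90% credible intervals for an injected gain perturbation achieve close
to nominal coverage (tested).

Observation noise on the features is a single estimated log-precision
λ with hyperprior N(0, 16). A tight hyperprior here would pin the
noise precision regardless of data scale; a weakly-informative one lets
variational Laplace estimate the noise level, which is what makes the
likelihood weighting meaningful across data scales.

## Variational Laplace

Gauss-Newton ascent on the Laplace free energy (accuracy − KL
complexity) with Levenberg–Marquardt damping; rejected candidate steps
restore the previous state, so the accepted free-energy trace is
non-decreasing by construction. The log-precision λ is updated by
damped Newton steps inside each iteration. Derivatives of the forward
map are central finite differences (step 10⁻⁴); the `CsdModel` fast
path batches all perturbed resolvent solves and reuses the base
transfer function for spectral parameters (which do not enter the
dynamics), and is verified against the reference implementation to
10⁻¹⁰. Convergence: |ΔF| < 0.01 for 4 consecutive accepted iterations,
at most 64 iterations. For a linear forward map and fixed noise the
scheme terminates at the exact conjugate posterior (tested to 10⁻⁶),
and its free energy equals the analytic log evidence.

Parameters whose dynamics become unstable (a Jacobian eigenvalue with
non-negative real part) return non-finite predictions and the candidate
step is rejected; the prior means of all built-in networks are stable.

## PEB, BMR and the second-level scales

The between-window model is `θ = (X ⊗ I_B)β + ε` with
`Σ(γ)⁻¹ = I_W ⊗ (Q0 + e^{−γ}Q1)`. Because every window is summarised
by a Gaussian prior/posterior pair, replacing the window prior with the
empirical prior N((x_iᵀ⊗I_B)β, V(γ)) is an analytic Bayesian model
reduction, and for fixed γ the problem is conjugate: β has a
closed-form posterior, only the scalar γ is optimised numerically
(bounded scalar search, Laplace correction for its posterior width).
The scales:

- `Q0 = 10⁻⁴·I` — a precision floor.
- `Q1 = 16·pC⁻¹`, i.e. between-window random effects carry covariance
  `pC/16` (sd 1/16 ≈ 0.06 on log gains) scaled by `e^γ`. This is the
  standard empirical-Bayes default of 1/16 of the prior variance and
  matches the magnitude of window-to-window fluctuation the generator
  injects (sd 0.05).
- β prior `Ξ = I_P ⊗ pC`, zero mean: with unit-norm DCT columns and
  bounded constant/decay columns, every regressor coefficient gets the
  same prior scale as the parameter it modulates. (Scaling Ξ down by a
  norm of the design would make the prior *tighten* as windows are
  added, which is backwards.)
- γ hyperprior N(0, 1). With a single precision component, γ must be
  free to absorb first-level estimation error on top of the true window
  noise; pinned tighter, that excess variance is soaked up by whichever
  basis function fits it best and produces spurious evidence for
  temporal structure under a constant-only truth (observed directly in
  null-calibration pilots).

Second-level models were estimated for forward, backward and lateral
connections separately, to avoid over-parameterization. All 16 on/off
combinations of the four temporal basis functions are scored by BMR,
with a switched-off regressor's coefficients given prior variance
10⁻⁸ (an effective delta at zero). Evidence is pooled over subjects by
summing log evidences (fixed effects); posterior model probabilities
are the softmax of the pooled evidences.

At the third level subjects' β posteriors enter the same machinery
with a constant-only design; between-subject random effects carry the
full prior covariance Ξ scaled by `e^γ` — subjects are a priori far
more heterogeneous than consecutive windows of one subject (the
generator's subject dispersion is 0.2, about the β prior sd).

## Iterative first-level refinement

`peb_fit` guards against local minima: windows are inverted, a
constant-only PEB estimates the between-window mean of the
*connectivity* block, and windows are re-inverted with the prior mean
re-centred there (original covariance kept). Only the connectivity
field is re-centred — empirically shrinking the spectral/noise nuisance
parameters lets them drift from round to round. A round is accepted
only if the hierarchical free energy (window free energies plus the
PEB correction) improves, so the outer trace is monotone; afterwards
each window posterior is reduced analytically under the empirical
prior N(mean, V(γ̂)), which is the partial-pooling estimate. Downstream
PEB calls are told the empirical prior actually used (`bmr_prior`) so
that BMR divides out the right prior while the variance scales stay
anchored to the original pC.

## Greedy search and BMA

Group-level coefficients are pruned greedily: at each step the single
pruning that most increases (or least decreases) the free energy is
applied if the evidence does not fall, ties going to the lowest index.
The search finishes with an exhaustive sweep over all on/off
combinations of the 8 parameters with the smallest individual evidence
contribution (256 models; fewer if the model has fewer parameters), and
the posterior is averaged over that set weighted by evidence. A
parameter's Pp is the summed probability of the models retaining it;
parameters off in every averaged model have BMA mean exactly 0.
Trajectories are `X·β̂` per connection with bands at ±z₀.₉₅ posterior
standard deviations propagated through the design
(half-width `z·√(xₙᵀ Σ_β xₙ)`).

## The synthetic cohorts (study conditions)

The generator works at the CSD-feature level (no raw EEG synthesis; no
artefacts, volume-conduction errors or non-stationary spectra — passing
tests certify the statistical machinery, not robustness to real-world
EEG confounds). Defaults:

- group decay coefficient −0.4 on every forward connection, 0
  elsewhere; subject-specific DCT coefficient dispersion 0.2; window
  noise sd 0.05 on log gains; stability enforced by rejection (≤100
  redraws per window).
- observation noise: iid sd 0.02 (0.01 in the recovery suites) on the
  non-redundant CSD features, i.e. roughly 10–20% of the typical
  feature amplitude — moderate sensor-level noise.
- frequency grid 4–40 Hz in 4 Hz steps and 8-subject, 20-window,
  2-node cohorts in the recovery suites; these desk-scale sizes keep a
  20-seed suite within minutes while leaving the effects several
  posterior standard deviations from zero.
- seeds: subject s uses `master + (s+1)·10⁴`; everything is
  reproducible bit for bit from the master seed.

Known limitations, stated plainly: per-coefficient group Pp has the
nominal ~5–10% chance of exceeding .95 when the true group mean is zero
but subjects genuinely vary — that is calibrated posterior behaviour,
not a defect, and the dissociation checks therefore ask about the
*typical* (median) DCT coefficient. One-subject "groups" shrink mildly
toward zero because a lone subject cannot inform the between-subject
variance. Backward and lateral gains are harder to identify than
forward ones at these baselines, mirroring their weaker spectral
footprint.

## Feature extraction for real recordings

EDF+ recordings load through a thin adapter (optional `mne`
dependency). Channels are projected onto the top-m principal spatial
components of the whole-recording covariance (m = 8 by default) so all
windows share one projection; windows are consecutive, non-overlapping,
exactly `fs·win_s` samples each with the remainder dropped. Per-window
CSD matrices come from a least-squares multivariate autoregressive
model of order 8 (`S(f) = A(f)⁻¹ Σ_ε A(f)⁻ᴴ`), ridge-regularised by
10⁻⁶·trace only when singular; the univariate spectrum matches the
AR(1) closed form within 10% on long samples (tested). The
explained-variance diagnostic is `100·(1 − SS_res/SS_tot)` over the
stacked real and imaginary parts of all CSD entries.
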