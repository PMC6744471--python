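# Methods

## Single-turnover induction model

A single-turnover flash is short and intense enough to reduce the primary
quinone acceptor Q_A exactly once in every PSII. If photons arrive with
flux Φ (photons Å⁻² s⁻¹), the probability that a center with functional
cross-section σ (Å² quantum⁻¹) is still open at time t follows one-hit
Poisson statistics, so the closed fraction is `C(t) = 1 − exp(−σ·Φ·t)` and
the fluorescence yield rises as

    F(t) = F₀ + (F_m − F₀) · C(t) · (1 − p) / (1 − p·C(t)),

where `p ∈ [0, 1)` is the probability that an exciton reaching a closed
center migrates to a neighbouring open one (excitonic connectivity). With
`p = 0` this is exactly the cumulative one-hit Poisson rise. The default
fit holds `p = 0`; on an 80 µs grid with ~160 samples, a free connectivity
parameter is weakly identified and invites over-parameterisation, so it is
opt-in and bounded to [0, 0.8].

Unit conventions: flash power in W cm⁻² converts to photon flux as
`P·λ/(hc)` per cm², divided by 10¹⁶ Å² cm⁻² (1 W cm⁻² at 450 nm ≈ 226.5
photons Å⁻² s⁻¹); irradiance in µmol photons m⁻² s⁻¹ converts as
`E·N_A·10⁻⁶/10²⁰`. All cross-sections are reported in Å²
(1 m² = 10²⁰ Å²). With the default flash (80 µs, 1 W cm⁻², 450 nm) the
fluence is ≈ 0.0181 photons Å⁻², closing > 99.9% of centers for any
σ ≥ 400 Å² — a genuinely saturating single turnover.

Fitting is bounded nonlinear least squares (scipy `least_squares`, trf)
with relative termination tolerances of 1e-10 and at most 500 function
evaluations. Self-initialisation is deterministic and scale-free:
F₀⁰ = mean of the first 3 samples, F_m⁰ = mean of the last 3, and
σ⁰ = (initial slope)/(F_v⁰·Φ) from a linear fit to the first quarter of
the rise. Degenerate inputs (no rise, zero flux, non-finite samples) raise
`ValueError`; mere non-convergence is reported via the `converged` flag.
Times are flash-onset-relative in µs, sampled at bin starts (default
interval 0.5 µs — the sampling rate is a free instrument choice).

## Quenching-parameter calculus

Per light step of a rapid light curve (default: 15 steps,
0–800 µmol photons m⁻² s⁻¹, 1 min each):

* `NPQ = F_m/F_m′ − 1`, with the reference F_m set **by default to the
  first light-step F_m′** rather than a dark-acclimated F_m, because
  dark-acclimated diatom F_m is typically lower than the first-step F_m′;
  the convention deliberately allows negative NPQ when F_m′ rises above
  the reference. A dark-F_m override is available.
* Yield partition: `Y(II) = (F_m′−F′)/F_m′`, `Y(NPQ) = F′/F_m′ − F′/F_m`,
  `Y(NO) = F′/F_m`; the three sum to 1 by construction and satisfy
  `Y(NPQ) = NPQ·Y(NO)` identically.
* `qL = ((F_m′−F′)/(F_m′−F₀′))·(F₀′/F′)` (lake model), with F₀′ measured
  after 1 s darkness — long enough for centers to re-open, short enough
  that quenching does not relax. Dark steps (E = 0) get qL = 1 from the
  formula; no special-casing.
* `ETR = Φ(E)·σ′·(F_v′/F_m′)/(F_v/F_m)` in electrons PSII⁻¹ s⁻¹ (the
  quanta-flux conversion makes the units absolute; the unconverted relative
  ETR is exposed alongside). The dark-acclimated F_v/F_m is a required
  input (default 0.65, typical for healthy *P. tricornutum*), as instrument
  protocols often do not store it with the light curve.
* `DES = Dt/(Dd+Dt)` for xanthophyll de-epoxidation.

## σ–Y(NPQ) filtering, regression, extrapolation

qE-type quenching shrinks σ<sub>PSII</sub>; slowly relaxing qI-type
quenching raises Y(NPQ) without moving σ. The retention rules applied per
curve before pooling are:

1. points with strictly negative Y(NPQ) are removed (Y = 0 is kept);
2. points above 600 µmol photons m⁻² s⁻¹ are removed;
3. for every point after the first, if Y(NPQ) increased relative to the
   previous measured step while σ decreased by less than 5% of that
   curve's total measured decrease (max σ − min σ), the point is removed.

Reasons are assigned first-match-wins in the order listed; the "previous
step" is the previous *measured* step whether or not it was retained, in a
single pass over the original sequence (the alternative — chaining from
the previous retained point — is defensible but makes the rule
order-dependent in a way a single-pass reading avoids). The first point
has no previous step and is exempt from rule 3. A curve with no net σ
decrease degenerates rule 3's threshold to zero (any non-decrease while Y
rises is dropped) and is flagged in the report.

The pooled fit is ordinary least squares of σ on Y(NPQ) over all strains,
replicates and both acclimations, with classical t-based 95% intervals
(n − 2 df); per-strain fits are available but are not the headline output.
The extrapolation `σ(Y=1) = intercept + slope` estimates the residual
cross-section with all regulated antenna quenched. A switch recomputes the
regression from the 1-s-dark readouts (σ′₁ₛ) instead.

For comparison, the PSII core cross-section is computed from first
principles as `a*·n_chl·M_chl/N_A` (m², then ×10²⁰ → Å²) with defaults
a\* = 9.8 m² (g chl a)⁻¹ (chlorophyll-a-specific absorption coefficient
for blue light), n_chl = 70 (chlorophyll a per dimeric PSII core) and
M_chl = 893.5 g mol⁻¹. These defaults give 101.8 Å². The literature
commonly quotes ≈ 112 Å² for nominally the same inputs; since the molar
mass or coefficient behind that figure is not stated, the report carries
the computed value and the 112 Å² reference side by side and never
substitutes one for the other. All three constants are exposed.

## Lifetime fitting

Decay histograms are fit by iterative reconvolution: the model
`Σ A_k exp(−t/τ_k)` is convolved discretely with the measured IRF
(normalised to unit sum) and compared to the data with Poisson weights
`1/√max(counts, 1)`; an optional sub-bin time shift between IRF and decay
axes can be fitted. Fourier-domain deconvolution is deliberately avoided
for stability on short grids. Lifetimes are reported sorted ascending.
The headline average is amplitude-weighted, `Σ A_k τ_k / Σ A_k` — the
conventional choice for quenching analyses, where the quantity of interest
is the rate-constant picture of a quencher opening a new non-radiative
channel; the intensity-weighted variant `Σ A_k τ_k² / Σ A_k τ_k` is
reported alongside. Reduced χ² uses Poisson weights and n − n_params
degrees of freedom.

## The synthetic strain panel

The generator emulates an eight-phenotype *P. tricornutum* panel —
wild-type, Lhcx1 and Lhcx2 knockouts, and complemented lines — as
phenomenological parameter bundles. Its purpose is to give every
downstream stage data with the right statistical structure, not to model
Lhcx biochemistry or xanthophyll-cycle kinetics.

Per light step at irradiance E (noise-free core):

* qE yield: `Y_qE(E) = qe_ymax · E^h/(e50^h + E^h)`. Defaults e50 = 160
  µmol m⁻² s⁻¹, h = 3.5, chosen so qE becomes apparent near 100, rises
  rapidly to ~350 and is near-flat beyond — the observed phenomenology of
  these strains; the Lhcx2-complemented knockout uses e50 = 310 (delayed
  qE onset). `qe_ymax` per strain and acclimation encodes the ordering
  x2KO+x2 > wild-type = x2KO = x2KO+x3 > x1KO+x3a > x1KO+x2a > x1KO =
  x1KO+x4a, with the Lhcx1 knockouts at zero under LL (0.35 for LL
  wild-type, 0.60 for HL) — qE requires diatoxanthin, so a DTT-treated or
  de-epoxidation-incapable strain has an *effective* qe_ymax of zero
  regardless of its nominal value (implemented as a derived property so
  the same strain object can be simulated with and without DTT).
* qI: `qI(E) = qi_slope·E`, a slow σ-independent quenching term. The
  uniform default 1e-4 NPQ/(µmol m⁻² s⁻¹) (≈ 0.08 NPQ at 800) keeps the
  slow component "slight" relative to qE, consistent with the observed
  near-identity of the Y(NPQ)=1 extrapolation and the core cross-section;
  qE-less cells photoinhibit more strongly in reality, but per-strain
  slopes are deliberately not modelled.
* σ link (the generative assumption the regression is meant to recover):
  `σ′ = σ_dark − (σ_dark − σ_core)·Y_qE`, exactly linear, with defaults
  σ_dark = 525 Å² and σ_core = 110 Å². qE-less strains instead show an
  apparent σ *rise* with closure, `+κ·σ_dark·C(E)` (default κ = 0.06),
  mimicking connectivity: in a connected antenna bed, closing centers
  enlarges the apparent target area of the remainder.
* Closure is a puddle model `C(E) = E/(E + 150)` (half-saturation
  consistent with electron transport saturating near 130 µmol m⁻² s⁻¹),
  and `F′ = F₀′ + (F_m′ − F₀′)·C`. F₀′ uses the Oxborough–Baker estimate
  `F₀/(F_v/F_m + F₀/F_m′)` unless the protocol measures it after 1 s dark,
  in which case the true value (plus noise) is emitted; σ′₁ₛ equals σ′
  because 1 s of darkness does not relax quenching.
* The qE quencher amplitude solves `Y_qE = (F′/F_m)·NPQ_qE`
  self-consistently (fixed-point iteration to 1e-13; convergent because F′
  depends only weakly on NPQ), then `F_m′ = F_m/(1 + NPQ_qE + qI)`.
  Consequently, when qI = 0 the downstream-computed (σ′, Y(NPQ)) pairs lie
  *exactly* on the generative line — the property the exact-recovery tests
  exploit. Note that exact recovery also requires κ = 0: with qI = 0 a
  qE-less strain's Y(NPQ) is identically zero, so its connectivity-driven
  σ-rise points sit off the line at Y = 0 and the drop rule (which needs Y
  to increase) cannot remove them.
* Noise is multiplicative Gaussian, independent per readout (F′, F_m′,
  F₀′, σ′, σ′₁ₛ), seeded per (seed, strain, acclimation, replicate) so
  replicates are reproducible bit-for-bit. After noising, F′ is clipped
  into [F₀′, F_m′] so every emitted record is physically ordered (this
  matters only near E = 0, where F′ = F₀′ exactly and independent noise
  would otherwise invert the pair). Decay histograms use Poisson counting
  noise instead.

NPQ time courses (strong-light induction then dim-light recovery) use
`NPQ(t) = NPQ_qE,ss·(1 − e^{−t/τ_ind}) + r_qI·t` during the light phase
(τ_ind = 60 s) and exponential qE relaxation (τ_rel = 120 s, chosen so
recovery completes within an 18-min dim phase) with frozen qI afterwards;
`r_qI = qi_slope·E/60 s` so one 60-s light-curve step accrues the same qI
as the light curve at that irradiance.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real data: instrument drift and autofluorescence
baselines, state transitions, σ wavelength dependence, PSI contamination
of the fluorescence signal, photoinhibition kinetics beyond the linear qI
term, per-strain differences in qI, and the gated F₀/F_m lifetime
acquisition protocol (only single decay histograms are modelled).

## Problem sizes and numerical conventions

The test suite and the reproduction script use an LL+HL panel of 8 strains
× 5–6 replicates × 15 steps at 2% relative noise (≈ 1300 points, ≈ 650
retained), 200-replicate Monte-Carlo for the induction noise floor, and
1600-bin decay histograms with a 50 ps Gaussian IRF — sizes at which every
estimate is stable to well within the tolerances asserted. Seeds are
explicit everywhere; light-curve RNG streams are keyed by (seed, strain
name, acclimation, replicate) via CRC-32 labels so adding strains never
perturbs existing streams.

## Known limitations

* The σ–Y(NPQ) link is generatively exact-linear; real antenna quenching
  need not be, and the regression's 95% band quantifies only sampling
  error, not model error.
* With qI present, retained points still carry a small qI contribution in
  Y(NPQ), so the extrapolated intercept is biased a few Å² above σ_core
  even at zero measurement noise; the filtering reduces, but cannot
  eliminate, this bias.
* The connectivity parameter in induction fits is bounded, not
  regularised; on very noisy transients the (σ, p) pair can trade off.
* CSV is the only interchange format; no vendor instrument files are read.
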