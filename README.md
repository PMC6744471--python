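# sigmaqe

Analysis tools linking rapidly inducible thermal energy dissipation (qE) to
the functional absorption cross-section of photosystem II (σ<sub>PSII</sub>)
in diatoms, built around single-turnover variable-fluorescence measurements
of *Phaeodactylum tricornutum* Lhcx mutants.

## The scientific problem

Diatoms dissipate excess absorbed light as heat through qE, which requires
the xanthophyll diatoxanthin and Lhcx proteins. A central biophysical
question is *where* that quenching acts: if qE detaches or quenches the
peripheral antenna, the functional cross-section σ<sub>PSII</sub> — the
probability-weighted target area (Å² quantum⁻¹) for a photon to drive a
PSII charge separation — should shrink in proportion to the regulated
dissipation yield Y(NPQ), extrapolating at Y(NPQ) = 1 to the bare PSII core;
if quenching acted in the core itself, the extrapolation would approach
zero. `sigmaqe` implements the full measurement-analysis chain needed to
test this:

1. **Induction fitting** (`sigmaqe.induction`): during an 80 µs, 1 W cm⁻²,
   450 nm single-turnover flash the fluorescence yield rises from F₀ to
   F<sub>m</sub> as centers close following the cumulative one-hit Poisson
   law `C(t) = 1 − exp(−σ·j(t))` with photon fluence `j`; nonlinear least
   squares recovers (F₀, F<sub>m</sub>, σ<sub>PSII</sub>), optionally with
   an excitonic connectivity parameter `p`.
2. **Quenching calculus** (`sigmaqe.params`): per light step of a rapid
   light curve, NPQ = F<sub>m</sub>/F<sub>m</sub>′ − 1 (reference
   F<sub>m</sub> set to the first light-step F<sub>m</sub>′), the yield
   partition Y(II) + Y(NPQ) + Y(NO) = 1, qL and 1−qL, the absolute electron
   transport rate E·σ′·(F<sub>v</sub>′/F<sub>m</sub>′)/(F<sub>v</sub>/F<sub>m</sub>)
   in electrons PSII⁻¹ s⁻¹, and the pigment de-epoxidation state
   DES = Dt/(Dd+Dt).
3. **σ–Y(NPQ) regression** (`sigmaqe.regression`): per-curve filtering that
   removes points where Y(NPQ) rose without a commensurate σ decrease
   (< 5% of the curve's total measured decrease), points above
   600 µmol photons m⁻² s⁻¹ and negative-Y(NPQ) points; pooled OLS with
   95% CIs; extrapolation to Y(NPQ) = 1; and a first-principles PSII core
   cross-section `a*·n_chl·M_chl/N_A` for comparison.
4. **Lifetime fitting** (`sigmaqe.lifetime`): iterative-reconvolution
   fitting of picosecond decay histograms to a sum of three exponentials
   deconvolved from the instrument response function, reporting
   amplitude-weighted average lifetimes.
5. **Synthetic strain panel** (`sigmaqe.panel`): a generator for the
   eight-phenotype mutant panel (wild-type, Lhcx1/Lhcx2 knockouts and
   complemented lines) with graded qE capacity, a slow σ-independent qI
   component, connectivity-driven σ rise in qE-less strains, and seeded
   measurement noise — so the whole chain is testable end to end.

## Worked example

Fit a noisy single-turnover transient and run the full pipeline:

```python
import sigmaqe as sq

flash = sq.FlashSpec(wavelength_nm=450.0, duration_us=80.0,
                     peak_power_w_cm2=1.0)
tr = sq.simulate_transient(1.0, 2.857, 500.0, 0.0, flash,
                           noise_rel_sd=0.01, seed=7)
fit = sq.fit_transient(tr)
print(f"sigma = {fit.sigma_psii:.1f} A2, Fo = {fit.fo:.3f}, "
      f"Fm = {fit.fm:.3f}, converged = {fit.converged}")
# sigma = 495.9 A2, Fo = 1.011, Fm = 2.859, converged = True

report = sq.run_all(sq.PipelineConfig(seed=1), "out/")
print(report.regression["sigma_at_ynpq1_A2"])   # 115.01
print(report.regression["r2"])                  # 0.9728
print(report.regression["core_sigma_computed_A2"])  # 101.78
```

The transient fit recovers the true σ<sub>PSII</sub> of 500 Å² to within
1% under 1% multiplicative noise. The pipeline simulates the default
LL + HL panel (8 strains × 5 replicates each, 2% noise), computes the
quenching parameters, filters and pools (σ′, Y(NPQ)) points, and regresses:
the intercept extrapolated to Y(NPQ) = 1 (115.0 Å² here) estimates the
residual cross-section when all regulated antenna is quenched, to be
compared with the PSII core cross-section computed from the default
constants (101.8 Å²; the literature figure for nominally the same inputs
is ~112 Å² — both are reported side by side). The same things can be done
from the shell via `sigmaqe simulate|fit-transient|params|regress|lifetime|run-all`.

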