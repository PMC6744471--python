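"""Synthetic strain-panel generator.

Produces fluorescence data (rapid light curves, single-turnover transients,
NPQ time courses, decay histograms) with the statistical structure the
downstream analysis assumes, for a panel of eight Phaeodactylum tricornutum
phenotypes with graded qE capacity (Lhcx knockouts and complemented lines).
Strains are phenomenological parameter bundles, not mechanistic models.

Generative model per light step at irradiance E:

* qE amplitude (as a Y(NPQ) contribution) follows a Hill saturation,
  ``Y_qE(E) = qe_ymax * E^h / (e50^h + E^h)``; strains lacking diatoxanthin
  formation (Lhcx1 knockouts under low light, or any DTT-treated strain)
  have an effective qe_ymax of 0.
* a slow, sigma-independent quenching component (qI-like) grows linearly,
  ``qI(E) = qi_slope * E``.
* the functional cross-section declines linearly with the qE yield down
  toward a residual core value:
  ``sigma' = sigma_dark - (sigma_dark - sigma_core) * Y_qE``;
  qE-less strains instead show an apparent sigma *rise* with center closure
  (excitonic connectivity), ``+ kappa_conn * sigma_dark * C(E)``.
* center closure follows a puddle model, ``C(E) = E / (E + K_HALF)``, and
  ``F' = Fo' + (Fm' - Fo') * C``; Fo' is the Oxborough-Baker estimate
  ``fo / (Fv/Fm + fo/Fm')`` unless the protocol measures it after 1 s dark.
* the qE quencher amplitude NPQ_qE is solved self-consistently from the
  identity Y(NPQ) = (F'/Fm) * NPQ, then Fm' = fm / (1 + NPQ_qE + qI).
* measurement noise is multiplicative Gaussian, independent per readout;
  decay histograms optionally get Poisson counting noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .induction import FlashSpec, FluorescenceTransient, model_transient
from .lifetime import IRF, DecayHistogram, convolve_decay
from .params import LightCurve, LightStepRecord

__all__ = [
    "StrainSpec",
    "ProtocolSpec",
    "PanelConfig",
    "K_HALF",
    "TAU_INDUCTION_S",
    "TAU_RELAXATION_S",
    "default_panel",
    "default_protocol",
    "simulate_light_curve",
    "simulate_panel",
    "simulate_transient",
    "simulate_npq_timecourse",
    "simulate_decay",
]

#: closure half-saturation irradiance (umol photons m^-2 s^-1); electron
#: transport in these cultures saturates at roughly 130 umol m^-2 s^-1
K_HALF = 150.0
#: qE induction time constant under strong light (s)
TAU_INDUCTION_S = 60.0
#: qE relaxation time constant in dim light (s)
TAU_RELAXATION_S = 120.0
#: reference step duration used to scale the qI rate in time courses (s)
_QI_TIME_REF_S = 60.0


@dataclass(frozen=True)
class StrainSpec:
    """Phenomenological phenotype of one strain.

    ``qe_ymax`` is the maximal Y(NPQ) attributable to qE; it is only
    expressed when diatoxanthin can form (``dt_capable`` and not
    ``dtt_treated``) — see :attr:`effective_qe_ymax`.
    """

    name: str
    qe_ymax: float
    e50: float = 160.0
    hill: float = 3.5
    qi_slope: float = 1e-4
    sigma_dark: float = 525.0
    sigma_core: float = 110.0
    fo: float = 1.0
    fm: float = 1.0 / 0.35  # dark Fv/Fm = 0.65
    kappa_conn: float = 0.06
    dt_capable: bool = True
    dtt_treated: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.qe_ymax < 1.0:
            raise ValueError("qe_ymax must be in [0, 1)")
        if self.e50 <= 0 or self.hill <= 0:
            raise ValueError("e50 and hill must be positive")
        if self.qi_slope < 0 or self.kappa_conn < 0:
            raise ValueError("qi_slope and kappa_conn must be non-negative")
        if not 0.0 < self.sigma_core < self.sigma_dark:
            raise ValueError("require 0 < sigma_core < sigma_dark")
        if not 0.0 < self.fo < self.fm:
            raise ValueError("require fm > fo > 0")

    @property
    def effective_qe_ymax(self) -> float:
        """qE amplitude actually expressed: zero without diatoxanthin."""
        if not self.dt_capable or self.dtt_treated:
            return 0.0
        return self.qe_ymax

    @property
    def fv_over_fm(self) -> float:
        return (self.fm - self.fo) / self.fm


@dataclass(frozen=True)
class ProtocolSpec:
    """Rapid-light-curve protocol."""

    step_irradiances: Sequence[float] = (
        0.0, 10.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0,
        250.0, 325.0, 400.0, 500.0, 600.0, 700.0, 800.0,
    )
    step_duration_s: float = 60.0
    dark_probe: bool = True
    flash: FlashSpec = field(
        default_factory=lambda: FlashSpec(
            wavelength_nm=450.0, duration_us=80.0, peak_power_w_cm2=1.0
        )
    )

    def __post_init__(self) -> None:
        e = np.asarray(self.step_irradiances, dtype=float)
        if e.size == 0:
            raise ValueError("protocol needs at least one light step")
        if np.any(e < 0) or np.any(np.diff(e) < 0):
            raise ValueError("irradiances must be non-negative, nondecreasing")
        if self.step_duration_s <= 0:
            raise ValueError("step duration must be positive")
        object.__setattr__(self, "step_irradiances", tuple(e.tolist()))


@dataclass(frozen=True)
class PanelConfig:
    """Full panel: strains x replicates under one protocol."""

    strains: Sequence[StrainSpec]
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    n_replicates: int = 5
    noise_rel_sd: float = 0.02
    seed: int = 0
    acclimation: str = "LL"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.noise_rel_sd < 0.5:
            raise ValueError("noise_rel_sd must be in [0, 0.5)")
        if not self.strains:
            raise ValueError("panel needs at least one strain")
        object.__setattr__(self, "strains", tuple(self.strains))


# qE amplitudes (maximal Y(NPQ)) per strain and acclimation, ordered
# x2KO+x2 > wild-type = x2KO = x2KO+x3 > x1KO+x3a > x1KO+x2a > x1KO = x1KO+x4a;
# under low light the Lhcx1 knockouts (unless complemented with Lhcx2/3)
# lack qE entirely, under 24-h high light every strain expresses some qE.
_QE_YMAX = {
    "LL": {
        "wild-type": 0.35,
        "x1KO": 0.0,
        "x1KO+x2a": 0.15,
        "x1KO+x3a": 0.25,
        "x1KO+x4a": 0.0,
        "x2KO": 0.35,
        "x2KO+x2": 0.45,
        "x2KO+x3": 0.35,
    },
    "HL": {
        "wild-type": 0.60,
        "x1KO": 0.15,
        "x1KO+x2a": 0.30,
        "x1KO+x3a": 0.45,
        "x1KO+x4a": 0.15,
        "x2KO": 0.60,
        "x2KO+x2": 0.70,
        "x2KO+x3": 0.60,
    },
}
# Lhcx1 complemented with Lhcx2 starts quenching at higher irradiance
_E50_OVERRIDE = {"x1KO+x2a": 310.0}


def default_panel(acclimation: str) -> List[StrainSpec]:
    """The eight-strain mutant panel for one acclimation condition.

    ``acclimation`` is "LL" (low light) or "HL" (24 h high light).
    """
    if acclimation not in _QE_YMAX:
        raise ValueError(
            f"unknown acclimation {acclimation!r}; expected 'LL' or 'HL'"
        )
    specs = []
    for name, ymax in _QE_YMAX[acclimation].items():
        specs.append(
            StrainSpec(
                name=name,
                qe_ymax=ymax,
                e50=_E50_OVERRIDE.get(name, 160.0),
            )
        )
    return specs


def default_protocol() -> ProtocolSpec:
    """15-step 0-800 umol m^-2 s^-1 blue-light curve, 1 min per step."""
    return ProtocolSpec()


def _rng_for(seed: int, *labels, replicate_index: int = 0) -> np.random.Generator:
    """Deterministic per-(seed, labels, replicate) generator."""
    keys = [int(seed) & 0x7FFFFFFF]
    keys.extend(zlib.crc32(str(lab).encode()) for lab in labels)
    keys.append(int(replicate_index))
    return np.random.default_rng(keys)


def _closure(e: float) -> float:
    return e / (e + K_HALF)


def _steady_state(strain: StrainSpec, e: float):
    """Noise-free per-step state (sigma', Fm', Fo', F', NPQ_qE, qI).

    NPQ_qE is the quencher amplitude whose Y(NPQ) contribution equals the
    target Hill value Y_qE(E); since Y(NPQ) = (F'/Fm)*NPQ and F' itself
    depends (weakly) on NPQ through Fm', the identity is solved by
    fixed-point iteration to 1e-13.
    """
    qe = strain.effective_qe_ymax
    y_qe = 0.0
    if qe > 0:
        y_qe = qe * e**strain.hill / (strain.e50**strain.hill + e**strain.hill)
    qi = strain.qi_slope * e
    c = _closure(e)
    sigma = strain.sigma_dark - (strain.sigma_dark - strain.sigma_core) * y_qe
    if qe == 0.0:
        sigma += strain.kappa_conn * strain.sigma_dark * c

    fv_fm = strain.fv_over_fm
    npq_qe = 0.0
    for _ in range(200):
        npq_tot = npq_qe + qi
        fm_p = strain.fm / (1.0 + npq_tot)
        fo_p = strain.fo / (fv_fm + strain.fo / fm_p)
        f_p = fo_p + (fm_p - fo_p) * c
        if y_qe == 0.0:
            break
        npq_new = y_qe * strain.fm / f_p
        if abs(npq_new - npq_qe) < 1e-13:
            npq_qe = npq_new
            break
        npq_qe = npq_new
    npq_tot = npq_qe + qi
    fm_p = strain.fm / (1.0 + npq_tot)
    fo_p = strain.fo / (fv_fm + strain.fo / fm_p)
    f_p = fo_p + (fm_p - fo_p) * c
    return sigma, fm_p, fo_p, f_p, npq_qe, qi


def simulate_light_curve(
    strain: StrainSpec,
    protocol: ProtocolSpec,
    noise_rel_sd: float = 0.0,
    seed: int = 0,
    replicate_index: int = 0,
    acclimation: str = "LL",
) -> LightCurve:
    """One rapid light curve for one strain and replicate.

    Reproducible: identical (seed, strain name, acclimation,
    replicate_index) give bit-identical output.  Noise multiplies each
    readout by an independent Gaussian factor N(1, noise_rel_sd); noisy F'
    is clipped into [Fo', Fm'] so every emitted record is physically
    ordered (relevant only at E=0 where F' = Fo' exactly).
    """
    if noise_rel_sd < 0:
        raise ValueError("noise_rel_sd must be non-negative")
    rng = _rng_for(seed, strain.name, acclimation, replicate_index=replicate_index)
    steps = []
    for k, e in enumerate(protocol.step_irradiances):
        sigma, fm_p, fo_p, f_p, _, _ = _steady_state(strain, e)
        if noise_rel_sd > 0:
            g = rng.normal(1.0, noise_rel_sd, size=5)
            fm_n = fm_p * g[0]
            fo_n = min(fo_p * g[1], fm_n * (1.0 - 1e-9))
            f_n = float(np.clip(f_p * g[2], fo_n, fm_n))
            sigma_n = sigma * g[3]
            sigma_1s_n = sigma * g[4]
        else:
            fm_n, fo_n, f_n, sigma_n, sigma_1s_n = fm_p, fo_p, f_p, sigma, sigma
        steps.append(
            LightStepRecord(
                step_index=k,
                e=e,
                f_prime=f_n,
                fm_prime=fm_n,
                fo_prime=fo_n,
                sigma_prime=sigma_n,
                sigma_prime_1s=sigma_1s_n,
            )
        )
    return LightCurve(
        strain=strain.name,
        acclimation=acclimation,
        replicate=replicate_index,
        steps=steps,
        fv_over_fm_dark=strain.fv_over_fm,
    )


def simulate_panel(config: PanelConfig) -> List[LightCurve]:
    """All light curves for a panel configuration."""
    curves = []
    for strain in config.strains:
        for rep in range(config.n_replicates):
            curves.append(
                simulate_light_curve(
                    strain,
                    config.protocol,
                    noise_rel_sd=config.noise_rel_sd,
                    seed=config.seed,
                    replicate_index=rep,
                    acclimation=config.acclimation,
                )
            )
    return curves


def simulate_transient(
    fo: float,
    fm: float,
    sigma_psii: float,
    connectivity_p: float,
    flash: FlashSpec,
    noise_rel_sd: float = 0.0,
    seed: int = 0,
) -> FluorescenceTransient:
    """Single-turnover induction transient with multiplicative noise."""
    clean = model_transient(fo, fm, sigma_psii, connectivity_p, flash)
    if noise_rel_sd == 0:
        return clean
    rng = _rng_for(seed, "transient")
    noisy = clean.signal * rng.normal(1.0, noise_rel_sd, size=clean.signal.size)
    return FluorescenceTransient(
        times_us=clean.times_us, signal=np.maximum(noisy, 0.0), flash=flash
    )


def simulate_npq_timecourse(
    strain: StrainSpec,
    hl_irradiance: float = 1700.0,
    hl_duration_s: float = 600.0,
    recovery_irradiance: float = 40.0,
    recovery_duration_s: float = 1080.0,
    seed: int = 0,
    dt_s: float = 10.0,
) -> pd.DataFrame:
    """NPQ induction/recovery time course (10 min strong light, then dim).

    During the light phase NPQ(t) = NPQ_qE_ss(E) * (1 - exp(-t/tau_ind))
    + r_qI * t; during recovery the qE term relaxes exponentially
    (tau_rel) while the qI term stays put.  The qI rate is scaled so that
    after one 60-s light-curve step it matches the light-curve qI at the
    same irradiance.  Strains without effective qE show only the linear
    term.  Deterministic (noise-free); the seed argument is accepted for
    interface symmetry with the other simulators.
    """
    if hl_duration_s <= 0 or recovery_duration_s <= 0:
        raise ValueError("durations must be positive")
    _, _, _, _, npq_qe_ss, _ = _steady_state(strain, hl_irradiance)
    r_qi = strain.qi_slope * hl_irradiance / _QI_TIME_REF_S

    t = np.arange(0.0, hl_duration_s + recovery_duration_s + dt_s / 2, dt_s)
    npq = np.empty_like(t)
    hl = t <= hl_duration_s
    npq[hl] = npq_qe_ss * -np.expm1(-t[hl] / TAU_INDUCTION_S) + r_qi * t[hl]
    qe_end = npq_qe_ss * -np.expm1(-hl_duration_s / TAU_INDUCTION_S)
    qi_end = r_qi * hl_duration_s
    dt_rec = t[~hl] - hl_duration_s
    npq[~hl] = qe_end * np.exp(-dt_rec / TAU_RELAXATION_S) + qi_end
    return pd.DataFrame({"time_s": t, "NPQ": npq})


def simulate_decay(
    amplitudes: Sequence[float],
    lifetimes_ns: Sequence[float],
    irf: IRF,
    baseline: float = 0.0,
    noise_model: str = "none",
    seed: int = 0,
) -> DecayHistogram:
    """Fluorescence decay histogram: triexponential convolved with the IRF.

    ``noise_model`` is "none" (exact model counts) or "poisson"
    (counting statistics).
    """
    model = convolve_decay(amplitudes, lifetimes_ns, baseline, irf)
    if noise_model == "none":
        counts = model
    elif noise_model == "poisson":
        rng = _rng_for(seed, "decay")
        counts = rng.poisson(np.maximum(model, 0.0)).astype(float)
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    return DecayHistogram(times_ns=irf.times_ns.copy(), counts=counts)
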