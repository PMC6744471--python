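"""Quenching-parameter calculus for rapid light curves.

Given per-light-step fluorescence readouts (F', Fm', Fo') and functional
cross-sections (sigma', sigma'_1s), computes the standard variable-
fluorescence parameters:

* ``NPQ = Fm/Fm' - 1``, with the reference Fm set by convention to the
  first light-step Fm' (dark-acclimated diatom Fm is typically lower than
  the first-step Fm', so the first-step convention avoids spuriously large
  NPQ; it also allows NPQ to go negative when Fm' rises above the
  reference).
* the quantum-yield partition Y(II) + Y(NPQ) + Y(NO) = 1, where
  Y(II) = (Fm'-F')/Fm' is PSII photochemistry, Y(NO) = F'/Fm is
  non-regulated loss and Y(NPQ) = F'/Fm' - F'/Fm is regulated thermal
  dissipation,
* qL = ((Fm'-F')/(Fm'-Fo')) * (Fo'/F'), the lake-model fraction of open
  centers; 1-qL is the excitation pressure on the plastoquinone pool,
* the absolute electron transport rate per PSII,
  ETR = E * sigma' * (Fv'/Fm')/(Fv/Fm), with E converted to photon flux in
  photons A^-2 s^-1 so ETR carries units of electrons PSII^-1 s^-1,
* the xanthophyll de-epoxidation state DES = Dt/(Dd+Dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .induction import photon_flux_from_quanta

__all__ = [
    "LightStepRecord",
    "LightCurve",
    "PigmentRecord",
    "npq",
    "quantum_yields",
    "q_l",
    "etr",
    "des",
    "compute_params",
]


@dataclass(frozen=True)
class LightStepRecord:
    """One light step of a rapid light curve.

    ``fo_prime`` is measured after 1 s darkness (short enough that
    quenching does not relax but reaction centers re-open);
    ``sigma_prime_1s`` is the cross-section from the same 1-s-dark probe.
    """

    step_index: int
    e: float
    f_prime: float
    fm_prime: float
    fo_prime: float
    sigma_prime: float
    sigma_prime_1s: float

    def __post_init__(self) -> None:
        if self.e < 0:
            raise ValueError(f"step {self.step_index}: negative irradiance")
        if min(self.f_prime, self.fm_prime, self.fo_prime) <= 0:
            raise ValueError(
                f"step {self.step_index}: fluorescence values must be positive"
            )
        if not (self.fo_prime <= self.f_prime <= self.fm_prime):
            raise ValueError(
                f"step {self.step_index}: require Fo' <= F' <= Fm' "
                f"(got {self.fo_prime:g}, {self.f_prime:g}, {self.fm_prime:g})"
            )
        if self.sigma_prime <= 0 or self.sigma_prime_1s <= 0:
            raise ValueError(f"step {self.step_index}: sigma must be positive")


@dataclass
class LightCurve:
    """A rapid light curve for one strain x replicate x acclimation."""

    strain: str
    acclimation: str
    replicate: int
    steps: List[LightStepRecord]
    fm_ref: Optional[float] = None
    fv_over_fm_dark: float = 0.65

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("light curve has no steps")
        idx = [s.step_index for s in self.steps]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(
                f"curve {self.strain}/{self.acclimation}/r{self.replicate}: "
                "step_index must be strictly increasing"
            )
        if not 0.0 < self.fv_over_fm_dark < 1.0:
            raise ValueError("fv_over_fm_dark must be in (0, 1)")
        if self.fm_ref is None:
            self.fm_ref = self.steps[0].fm_prime
        if self.fm_ref <= 0:
            raise ValueError("fm_ref must be positive")


@dataclass(frozen=True)
class PigmentRecord:
    """Xanthophyll-cycle pigments per chlorophyll a (mol / 100 mol chl a)."""

    dd: float
    dt: float
    chla: float = 100.0

    def __post_init__(self) -> None:
        if self.dd < 0 or self.dt < 0 or self.chla < 0:
            raise ValueError("pigment amounts must be non-negative")


def npq(fm_ref: float, fm_prime: float) -> float:
    """Stern-Volmer style NPQ = Fm/Fm' - 1; may be negative."""
    if fm_ref <= 0 or fm_prime <= 0:
        raise ValueError("fm_ref and fm_prime must be positive")
    return fm_ref / fm_prime - 1.0


def quantum_yields(
    f_prime: float, fm_prime: float, fm_ref: float
) -> Tuple[float, float, float]:
    """Yield partition (Y(II), Y(NPQ), Y(NO)); sums to 1 by construction."""
    if f_prime <= 0 or fm_prime <= 0 or fm_ref <= 0:
        raise ValueError("fluorescence inputs must be positive")
    if f_prime > fm_prime:
        raise ValueError("require f_prime <= fm_prime")
    y_ii = (fm_prime - f_prime) / fm_prime
    y_npq = f_prime / fm_prime - f_prime / fm_ref
    y_no = f_prime / fm_ref
    return y_ii, y_npq, y_no


def q_l(f_prime: float, fm_prime: float, fo_prime: float) -> float:
    """Lake-model fraction of open PSII centers, in [0, 1]."""
    if fm_prime <= fo_prime:
        raise ValueError("qL undefined: fm_prime must exceed fo_prime")
    if not fo_prime <= f_prime <= fm_prime:
        raise ValueError("require fo_prime <= f_prime <= fm_prime")
    return ((fm_prime - f_prime) / (fm_prime - fo_prime)) * (fo_prime / f_prime)


def etr(
    e: float, sigma_prime: float, fv_fm_prime: float, fv_fm_dark: float
) -> float:
    """Absolute electron transport rate, electrons PSII^-1 s^-1."""
    if fv_fm_dark <= 0:
        raise ValueError("fv_fm_dark must be positive")
    return photon_flux_from_quanta(e) * sigma_prime * (fv_fm_prime / fv_fm_dark)


def des(pigments: PigmentRecord) -> float:
    """De-epoxidation state Dt/(Dd+Dt), in [0, 1]."""
    pool = pigments.dd + pigments.dt
    if pool <= 0:
        raise ValueError("DES undefined: Dd + Dt must be positive")
    return pigments.dt / pool


def compute_params(
    curve: LightCurve, fm_ref: Optional[float] = None
) -> pd.DataFrame:
    """Per-step quenching parameters for one light curve.

    ``fm_ref`` defaults to the curve's reference Fm (itself defaulting to
    the first light-step Fm').  Returns one row per step with the
    fluorescence pass-throughs needed downstream plus NPQ, the yield
    partition, qL, 1-qL and ETR (absolute and relative).
    """
    ref = curve.fm_ref if fm_ref is None else fm_ref
    rows = []
    for s in curve.steps:
        try:
            npq_v = npq(ref, s.fm_prime)
            y_ii, y_npq, y_no = quantum_yields(s.f_prime, s.fm_prime, ref)
            ql_v = q_l(s.f_prime, s.fm_prime, s.fo_prime)
            fv_fm_prime = (s.fm_prime - s.fo_prime) / s.fm_prime
            etr_v = etr(s.e, s.sigma_prime, fv_fm_prime, curve.fv_over_fm_dark)
        except ValueError as exc:
            raise ValueError(f"step_index {s.step_index}: {exc}") from exc
        rows.append(
            {
                "strain": curve.strain,
                "acclimation": curve.acclimation,
                "replicate": curve.replicate,
                "step": s.step_index,
                "E_umol_m2_s": s.e,
                "F_prime": s.f_prime,
                "Fm_prime": s.fm_prime,
                "Fo_prime": s.fo_prime,
                "sigma_A2": s.sigma_prime,
                "sigma_1s_A2": s.sigma_prime_1s,
                "NPQ": npq_v,
                "Y_NPQ": y_npq,
                "Y_NO": y_no,
                "Y_II": y_ii,
                "qL": ql_v,
                "one_minus_qL": 1.0 - ql_v,
                "ETR_e_per_PSII_s": etr_v,
                "ETR_rel": s.e * s.sigma_prime
                * fv_fm_prime / curve.fv_over_fm_dark,
            }
        )
    return pd.DataFrame(rows)
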