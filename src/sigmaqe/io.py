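"""File I/O: the flat light-curve CSV dialect shared by all stages, plus
transient and decay-histogram readers/writers.

Light-curve CSV columns (one row per light step, UTF-8, '.' decimal):
``strain,acclimation,replicate,step,E_umol_m2_s,F_prime,Fm_prime,Fo_prime,
sigma_A2,sigma_1s_A2``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .induction import FlashSpec, FluorescenceTransient
from .lifetime import IRF, DecayHistogram
from .params import LightCurve, LightStepRecord

__all__ = [
    "LIGHT_CURVE_COLUMNS",
    "read_light_curves",
    "write_light_curves",
    "read_transient",
    "write_transient",
    "read_decay",
    "write_decay",
    "read_irf",
    "write_irf",
]

LIGHT_CURVE_COLUMNS = [
    "strain",
    "acclimation",
    "replicate",
    "step",
    "E_umol_m2_s",
    "F_prime",
    "Fm_prime",
    "Fo_prime",
    "sigma_A2",
    "sigma_1s_A2",
]


def write_light_curves(curves: Sequence[LightCurve], path) -> None:
    """Write light curves to the flat CSV dialect."""
    rows = []
    for c in curves:
        for s in c.steps:
            rows.append(
                (
                    c.strain, c.acclimation, c.replicate, s.step_index,
                    s.e, s.f_prime, s.fm_prime, s.fo_prime,
                    s.sigma_prime, s.sigma_prime_1s,
                )
            )
    df = pd.DataFrame(rows, columns=LIGHT_CURVE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_light_curves(path, fv_over_fm_dark: float = 0.65) -> List[LightCurve]:
    """Read light curves from CSV, validating columns and row invariants.

    Rows are grouped into curves by (strain, acclimation, replicate) in
    file order.  A header-only file yields an empty list.  Validation
    errors cite the offending column or 1-based data row.
    """
    df = pd.read_csv(path)
    missing = [c for c in LIGHT_CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        return []

    curves: List[LightCurve] = []
    order: List[Tuple] = []
    grouped: dict = {}
    for i, row in enumerate(df.itertuples(index=False)):
        key = (row.strain, row.acclimation, int(row.replicate))
        try:
            rec = LightStepRecord(
                step_index=int(row.step),
                e=float(row.E_umol_m2_s),
                f_prime=float(row.F_prime),
                fm_prime=float(row.Fm_prime),
                fo_prime=float(row.Fo_prime),
                sigma_prime=float(row.sigma_A2),
                sigma_prime_1s=float(row.sigma_1s_A2),
            )
        except ValueError as exc:
            raise ValueError(f"row {i + 1}: {exc}") from exc
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(rec)

    for key in order:
        strain, acclimation, replicate = key
        try:
            curves.append(
                LightCurve(
                    strain=str(strain),
                    acclimation=str(acclimation),
                    replicate=replicate,
                    steps=grouped[key],
                    fv_over_fm_dark=fv_over_fm_dark,
                )
            )
        except ValueError as exc:
            raise ValueError(str(exc)) from exc
    return curves


def write_transient(transient: FluorescenceTransient, path) -> None:
    """Two-column CSV (t_us,signal) with flash metadata in '#' comments."""
    flash = transient.flash
    meta = {
        "wavelength_nm": flash.wavelength_nm,
        "duration_us": flash.duration_us,
        "sampling_interval_us": flash.sampling_interval_us,
        "photon_flux": flash.photon_flux,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# flash {json.dumps(meta)}\n")
        fh.write("t_us,signal\n")
        for t, s in zip(transient.times_us, transient.signal):
            fh.write(f"{t:.17g},{s:.17g}\n")


def read_transient(path, flash: Optional[FlashSpec] = None) -> FluorescenceTransient:
    """Read a transient CSV; flash metadata from '#' comment or argument."""
    meta = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# flash "):
                meta = json.loads(line[len("# flash "):])
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    for col in ("t_us", "signal"):
        if col not in df.columns:
            raise ValueError(f"missing required column(s): {col}")
    if flash is None:
        if meta is None:
            raise ValueError("no flash metadata in file and none supplied")
        flash = FlashSpec(
            wavelength_nm=meta["wavelength_nm"],
            duration_us=meta["duration_us"],
            sampling_interval_us=meta["sampling_interval_us"],
            photon_flux=meta["photon_flux"],
        )
    return FluorescenceTransient(
        times_us=df["t_us"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        flash=flash,
    )


def write_decay(decay: DecayHistogram, path) -> None:
    pd.DataFrame({"t_ns": decay.times_ns, "counts": decay.counts}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_decay(path) -> DecayHistogram:
    df = pd.read_csv(path)
    for col in ("t_ns", "counts"):
        if col not in df.columns:
            raise ValueError(f"missing required column(s): {col}")
    return DecayHistogram(
        times_ns=df["t_ns"].to_numpy(float), counts=df["counts"].to_numpy(float)
    )


def write_irf(irf: IRF, path) -> None:
    pd.DataFrame({"t_ns": irf.times_ns, "response": irf.response}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_irf(path) -> IRF:
    df = pd.read_csv(path)
    for col in ("t_ns", "response"):
        if col not in df.columns:
            raise ValueError(f"missing required column(s): {col}")
    return IRF(
        times_ns=df["t_ns"].to_numpy(float),
        response=df["response"].to_numpy(float),
    )
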