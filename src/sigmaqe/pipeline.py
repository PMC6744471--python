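"""End-to-end pipeline: simulate -> parameter calculus -> filter/regress ->
report, with one configuration document and deterministic outputs.

A :class:`PipelineConfig` (built in code or parsed from a YAML/JSON
document) drives :func:`run_all`, which writes, into the output directory:

* ``curves.csv`` — simulated light curves (the shared CSV dialect),
* ``params.csv`` — per-step quenching parameters,
* ``retention.csv`` — per-point retention flags and omit reasons,
* ``regression.json`` — pooled regression summary and core comparison,
* ``report.json`` — run report (record counts, retention summary,
  config hash, package version).

Outputs are bit-identical for a fixed config and seed.  Unknown keys in a
config document are errors (typo protection).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from . import __version__
from .io import write_light_curves
from .panel import (
    FlashSpec,
    PanelConfig,
    ProtocolSpec,
    StrainSpec,
    default_panel,
    default_protocol,
    simulate_panel,
)
from .params import LightCurve, compute_params
from .regression import CoreParams, QeReport, qe_report

logger = logging.getLogger("sigmaqe")

__all__ = ["PipelineConfig", "RunReport", "run_all", "config_from_dict"]


@dataclass(frozen=True)
class PipelineConfig:
    """One document configuring every pipeline stage."""

    acclimations: Sequence[str] = ("LL", "HL")
    strains: Optional[Sequence[StrainSpec]] = None  # None -> default panel
    protocol: ProtocolSpec = field(default_factory=default_protocol)
    n_replicates: int = 5
    noise_rel_sd: float = 0.02
    seed: int = 0
    fv_over_fm_dark: float = 0.65
    one_second_dark: bool = False
    drop_fraction: float = 0.05
    e_max: float = 600.0
    core_params: CoreParams = field(default_factory=CoreParams)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.noise_rel_sd < 0.5:
            raise ValueError("noise_rel_sd must be in [0, 0.5)")
        for a in self.acclimations:
            if self.strains is None and a not in ("LL", "HL"):
                raise ValueError(f"unknown acclimation {a!r}")


@dataclass
class RunReport:
    """Summary of one pipeline run."""

    n_curves: int
    n_steps: int
    n_points_retained: int
    n_points_omitted: int
    retention_by_curve: dict
    regression: dict
    config_hash: str
    version: str


def _take(d: dict, key, default):
    return d.pop(key) if key in d else default


def config_from_dict(doc: dict) -> PipelineConfig:
    """Build a PipelineConfig from a parsed YAML/JSON document.

    Unknown keys anywhere in the document raise ``ValueError``.
    """
    doc = dict(doc)
    strains = None
    if "strains" in doc:
        raw = doc.pop("strains")
        strains = []
        for s in raw:
            s = dict(s)
            try:
                strains.append(StrainSpec(**s))
            except TypeError as exc:
                raise ValueError(f"bad strain entry: {exc}") from exc
    protocol = default_protocol()
    if "protocol" in doc:
        p = dict(doc.pop("protocol"))
        flash = default_protocol().flash
        if "flash" in p:
            f = dict(p.pop("flash"))
            try:
                flash = FlashSpec(**f)
            except TypeError as exc:
                raise ValueError(f"bad flash entry: {exc}") from exc
        try:
            protocol = ProtocolSpec(flash=flash, **p)
        except TypeError as exc:
            raise ValueError(f"bad protocol entry: {exc}") from exc
    core = CoreParams()
    if "core_params" in doc:
        c = dict(doc.pop("core_params"))
        try:
            core = CoreParams(**c)
        except TypeError as exc:
            raise ValueError(f"bad core_params entry: {exc}") from exc
    cfg_kwargs = {}
    for key in (
        "acclimations", "n_replicates", "noise_rel_sd", "seed",
        "fv_over_fm_dark", "one_second_dark", "drop_fraction", "e_max",
    ):
        if key in doc:
            cfg_kwargs[key] = doc.pop(key)
    if doc:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(doc))}")
    if "acclimations" in cfg_kwargs:
        cfg_kwargs["acclimations"] = tuple(cfg_kwargs["acclimations"])
    return PipelineConfig(
        strains=strains, protocol=protocol, core_params=core, **cfg_kwargs
    )


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        try:
            return asdict(o)
        except TypeError:
            return repr(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: PipelineConfig, out_dir) -> RunReport:
    """Run the full pipeline and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)

    curves: List[LightCurve] = []
    for acclim in config.acclimations:
        strains = (
            list(config.strains) if config.strains is not None
            else default_panel(acclim)
        )
        panel = PanelConfig(
            strains=strains,
            protocol=config.protocol,
            n_replicates=config.n_replicates,
            noise_rel_sd=config.noise_rel_sd,
            seed=config.seed,
            acclimation=acclim,
        )
        curves.extend(simulate_panel(panel))
    for c in curves:
        c.fv_over_fm_dark = config.fv_over_fm_dark
    logger.info("simulated %d light curves", len(curves))

    tables = [compute_params(c) for c in curves]
    params_df = pd.concat(tables, ignore_index=True)

    report = qe_report(
        curves,
        params_tables=tables,
        one_second_dark=config.one_second_dark,
        drop_fraction=config.drop_fraction,
        e_max=config.e_max,
        core_params=config.core_params,
    )
    retention = report.retention_table()

    by_curve = {}
    for (strain, acclim, rep), grp in retention.groupby(
        ["strain", "acclimation", "replicate"], sort=True
    ):
        key = f"{strain}/{acclim}/r{rep}"
        by_curve[key] = int(grp["retained"].sum())
        logger.info(
            "curve %s: %d/%d points retained", key, by_curve[key], len(grp)
        )
        for _, row in grp[~grp["retained"]].iterrows():
            logger.debug(
                "curve %s step %d omitted: %s", key, row["step"],
                row["omit_reason"],
            )

    write_light_curves(curves, out / "curves.csv")
    params_df.to_csv(out / "params.csv", index=False, float_format="%.17g")
    retention.to_csv(out / "retention.csv", index=False, float_format="%.17g")
    summary = report.summary_dict()
    summary["config_hash"] = cfg_hash
    (out / "regression.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )

    run_report = RunReport(
        n_curves=len(curves),
        n_steps=int(len(params_df)),
        n_points_retained=int(retention["retained"].sum()),
        n_points_omitted=int((~retention["retained"]).sum()),
        retention_by_curve=by_curve,
        regression=summary,
        config_hash=cfg_hash,
        version=__version__,
    )
    (out / "report.json").write_text(
        json.dumps(asdict(run_report), indent=2, sort_keys=True) + "\n"
    )
    return run_report
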