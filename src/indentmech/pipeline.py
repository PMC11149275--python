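"""End-to-end orchestration: curves -> moduli -> group statistics; volumes -> BV/TV.

Per-specimen failures never abort a cohort run: each failure becomes a
report row with its reason, mirroring how individual noisy curves are
discarded while the rest of the cohort is analyzed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import groupstats
from .bvtv import CylinderROI, apply_threshold, bvtv, cylinder_mask, load_volume
from .curves import (CurveDialect, ProtocolSpec, read_curve, read_specimen_table)
from .errors import IndentmechError
from .hayes import equilibrium_modulus, solve_kappa, tangent_modulus
from .phases import Phase, extract_phase, segment_phases
from .processing import (DEFAULT_R2_THRESHOLD, DEFAULT_TAIL_FRACTION,
                         DEFAULT_UPPER_FRACTION, equilibrium_load,
                         fit_loading_slope, qc_gate, smooth_curve)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults follow the study protocol."""

    curve_dir: str = "."
    specimen_table: str = "specimens.csv"
    volume_dir: str | None = None
    output_dir: str = "out"
    dialect: CurveDialect = field(default_factory=CurveDialect)
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    sg_window: int | None = None
    sg_polyorder: int = 3
    upper_fraction: float = DEFAULT_UPPER_FRACTION
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    tail_fraction: float = DEFAULT_TAIL_FRACTION
    kappa_step: float = 0.01
    roi: CylinderROI = field(default_factory=CylinderROI)
    threshold: float | str = "otsu"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.name == "dialect":
                val = CurveDialect.from_dict(val)
            elif f.name == "protocol":
                val = ProtocolSpec(**val)
            elif f.name == "roi":
                val = CylinderROI(**{k: tuple(v) if k == "center_mm" else v
                                     for k, v in val.items()})
            kw[f.name] = val
        return cls(**kw)

    def log_settings(self) -> None:
        for f in dataclasses.fields(self):
            log.info("config %s = %r", f.name, getattr(self, f.name))


def analyze_specimen(curve, geom, config: RunConfig) -> dict:
    """Run one curve through segment -> smooth -> fit -> gate -> moduli."""
    seg = segment_phases(curve, config.protocol)
    loading = extract_phase(curve, seg, Phase.LOADING)
    hold = extract_phase(curve, seg, Phase.HOLD)
    loading = smooth_curve(loading, config.sg_window, config.sg_polyorder)
    hold = smooth_curve(hold, config.sg_window, config.sg_polyorder)
    fit = fit_loading_slope(loading, config.upper_fraction)
    decision = qc_gate(fit, config.r2_threshold)
    kappa = solve_kappa(geom.alpha, geom.poisson_nu, step=config.kappa_step)
    row = {
        "sample_id": curve.sample_id,
        "alpha": geom.alpha, "nu": geom.poisson_nu, "kappa": kappa,
        "slope_n_per_um": fit.slope_n_per_um, "r_squared": fit.r_squared,
        "qc_status": "accepted" if decision.accepted else "rejected",
        "qc_reason": decision.reason or "",
        "e_tan_mpa": np.nan, "e_eq_mpa": np.nan,
        "p_eq_n": np.nan, "x0_um": np.nan,
        "relaxation_rate_n_per_s": np.nan,
    }
    if decision.accepted:
        row["e_tan_mpa"] = tangent_modulus(fit, geom, kappa)
        eq = equilibrium_load(hold, config.tail_fraction)
        row["p_eq_n"] = eq.p_eq_n
        row["x0_um"] = eq.x0_eq_um
        row["relaxation_rate_n_per_s"] = eq.relaxation_rate_n_per_s
        row["e_eq_mpa"] = equilibrium_modulus(eq.p_eq_n, eq.x0_eq_um, geom, kappa)
    return row


def run_indentation(config: RunConfig, curves: dict | None = None,
                    specimens: list | None = None) -> dict:
    """Process a cohort of indentation curves and compare groups.

    ``curves``/``specimens`` may be passed in memory (e.g. from the
    synthetic generator); otherwise they are read from ``config``.
    Returns a dict with ``results`` (per-specimen DataFrame), ``summary``,
    ``anova`` and ``tukey`` tables, and writes CSV/JSON reports.
    """
    config.log_settings()
    if specimens is None:
        specimens = read_specimen_table(config.specimen_table)
    rows = []
    groups = {}
    for sample_id, geom, group in specimens:
        groups[sample_id] = group
        try:
            if curves is not None:
                curve = curves[sample_id]
            else:
                curve = read_curve(os.path.join(config.curve_dir, f"{sample_id}.csv"),
                                   config.dialect, sample_id=sample_id)
            row = analyze_specimen(curve, geom, config)
            row["sample_id"] = sample_id
        except (IndentmechError, KeyError, OSError) as exc:
            log.warning("specimen %s failed: %s", sample_id, exc)
            row = {"sample_id": sample_id, "qc_status": "failed",
                   "qc_reason": f"{type(exc).__name__}: {exc}"}
        row["group"] = group
        rows.append(row)
    results = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)

    accepted = results[results["qc_status"] == "accepted"]
    stats = {}
    for outcome in ("e_tan_mpa", "e_eq_mpa"):
        tidy = accepted[["sample_id", "group", outcome]].rename(columns={outcome: "value"})
        tidy = tidy.dropna(subset=["value"])
        try:
            stats[outcome] = {
                "summary": groupstats.summarize(tidy),
                "anova": groupstats.anova(tidy, factors="group"),
                "tukey": groupstats.tukey_hsd(tidy),
            }
        except IndentmechError as exc:
            log.warning("group statistics for %s skipped: %s", outcome, exc)

    os.makedirs(config.output_dir, exist_ok=True)
    results.to_csv(os.path.join(config.output_dir, "moduli.csv"), index=False)
    report = {"n_specimens": len(results),
              "n_accepted": int((results["qc_status"] == "accepted").sum()),
              "rejected": results.loc[results["qc_status"] != "accepted",
                                      ["sample_id", "qc_reason"]].to_dict("records")}
    for outcome, tables in stats.items():
        tables["summary"].to_csv(os.path.join(config.output_dir, f"{outcome}_summary.csv"))
        tables["anova"].to_csv(os.path.join(config.output_dir, f"{outcome}_anova.csv"))
        tables["tukey"].to_csv(os.path.join(config.output_dir, f"{outcome}_tukey.csv"),
                               index=False)
    with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return {"results": results, "stats": stats, "report": report}


def run_bvtv(config: RunConfig, volumes: dict | None = None) -> pd.DataFrame:
    """Threshold -> cylinder mask -> BV/TV for each specimen volume."""
    config.log_settings()
    if volumes is None:
        vol_dir = config.volume_dir or config.curve_dir
        names = sorted(f for f in os.listdir(vol_dir) if f.endswith((".tif", ".tiff")))
        volumes = {os.path.splitext(f)[0]: os.path.join(vol_dir, f) for f in names}
    rows = []
    for sample_id, vol in sorted(volumes.items()):
        try:
            if isinstance(vol, (str, os.PathLike)):
                vol = load_volume(vol)
            binary, thr = apply_threshold(vol, config.threshold)
            mask = cylinder_mask(vol.values.shape, vol.voxel_size_mm, config.roi,
                                 origin_mm=vol.origin_mm)
            ratio = bvtv(binary, mask)
            rows.append({"sample_id": sample_id, "threshold": thr,
                         "bv": int(np.count_nonzero(binary.values[mask])),
                         "tv": int(mask.sum()), "bvtv": ratio, "status": "ok"})
        except (IndentmechError, OSError) as exc:
            log.warning("volume %s failed: %s", sample_id, exc)
            rows.append({"sample_id": sample_id, "status": f"failed: {exc}"})
    df = pd.DataFrame(rows)
    os.makedirs(config.output_dir, exist_ok=True)
    df.to_csv(os.path.join(config.output_dir, "bvtv.csv"), index=False)
    return df
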