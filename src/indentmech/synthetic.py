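"""Synthetic stress-relaxation curves, cohorts and voxel phantoms.

The viscoelastic surrogate is a standard linear solid (SLS) with relaxation
modulus ``G(t) = E_inf + (E_0 - E_inf) exp(-t/tau)``.  Displacement follows
the indentation protocol (preload dwell, 25 um/s ramp to 50 um, 13 s hold,
25 um/s unload); load is the hereditary integral of G against the
displacement rate, mapped to force through the same Hayes factor
``2 R kappa / (1 - nu^2)`` the analysis inverts.  Ramp and hold segments
use the closed-form integral, so there is no numerical convolution error;
ground truth (phase boundaries, moduli, kappa, analytic upper-35% secant
slope) accompanies every curve.

The preload is equilibrated against ``E_inf`` (the tissue is assumed fully
relaxed under the 0.1 N preload before the ramp starts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import IndentationCurve, ProtocolSpec, SpecimenGeometry
from .errors import ValidationError
from .bvtv import CylinderROI, VoxelVolume, cylinder_mask
from .hayes import hayes_force_factor, solve_kappa


@dataclass(frozen=True)
class SLSParams:
    """Standard-linear-solid material plus specimen geometry."""

    e_inf_mpa: float
    e_0_mpa: float
    tau_s: float
    geometry: SpecimenGeometry

    def __post_init__(self):
        if not (self.e_0_mpa >= self.e_inf_mpa > 0):
            raise ValidationError(
                f"need E_0 >= E_inf > 0, got E_0={self.e_0_mpa}, E_inf={self.e_inf_mpa}")
        if not (self.tau_s > 0):
            raise ValidationError(f"tau must be > 0, got {self.tau_s}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian measurement noise, seeded."""

    load_sigma_n: float = 0.0
    displacement_sigma_um: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.load_sigma_n < 0 or self.displacement_sigma_um < 0:
            raise ValidationError("noise sigmas must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    e_inf_mpa: float
    e_0_mpa: float
    tau_s: float
    kappa: float
    loading_start: int
    loading_end: int
    hold_end: int
    preload_displacement_um: float
    secant_slope_n_per_um: float
    e_tan_secant_mpa: float


def _g_integral(u, e_inf, e_0, tau):
    """int_0^u G(s) ds for the SLS relaxation modulus, 0 for u <= 0."""
    u = np.maximum(np.asarray(u, dtype=float), 0.0)
    return e_inf * u + (e_0 - e_inf) * tau * (1.0 - np.exp(-u / tau))


def generate_sls_curve(params: SLSParams, protocol: ProtocolSpec | None = None,
                       rate_hz: float = 100.0, noise: NoiseSpec | None = None,
                       preload_duration_s: float = 2.0,
                       kappa: float | None = None,
                       sample_id: str = "synthetic") -> tuple[IndentationCurve, GroundTruth]:
    """Simulate one ramp-hold-unload test of an SLS specimen.

    ``kappa=None`` solves the Hayes correction for the specimen geometry;
    pass ``kappa=1.0`` for the half-space (Hertz-limit) variant used in
    closed-form cross-checks.
    """
    if protocol is None:
        protocol = ProtocolSpec()
    if rate_hz < 20.0:
        raise ValidationError(f"sampling rate must be >= 20 Hz, got {rate_hz}")
    geom = params.geometry
    if kappa is None:
        kappa = solve_kappa(geom.alpha, geom.poisson_nu)
    c = hayes_force_factor(geom, kappa)  # N per (MPa * um)

    v = protocol.ramp_rate_um_per_s
    t_pre = preload_duration_s
    t_ramp = protocol.ramp_duration_s
    t_hold = protocol.hold_duration_s
    t_total = t_pre + 2.0 * t_ramp + t_hold
    dt = 1.0 / rate_hz
    n = int(round(t_total / dt)) + 1
    t = np.arange(n) * dt

    x_pre = protocol.preload_n / (c * params.e_inf_mpa)  # relaxed preload depth

    u = t - t_pre  # time since ramp start
    x = np.clip(u * v, 0.0, protocol.ramp_depth_um)
    u2 = u - (t_ramp + t_hold)  # time since unload start
    x = x - np.clip(u2 * v, 0.0, protocol.ramp_depth_um)
    x = x + x_pre

    e_inf, e_0, tau = params.e_inf_mpa, params.e_0_mpa, params.tau_s
    p = protocol.preload_n + c * v * (
        _g_integral(u, e_inf, e_0, tau)
        - _g_integral(u - t_ramp, e_inf, e_0, tau)
        - _g_integral(u2, e_inf, e_0, tau)
        + _g_integral(u2 - t_ramp, e_inf, e_0, tau)
    )

    if noise is not None and (noise.load_sigma_n > 0 or noise.displacement_sigma_um > 0):
        rng = np.random.default_rng(noise.seed)
        p = p + rng.normal(0.0, noise.load_sigma_n, n)
        x = x + rng.normal(0.0, noise.displacement_sigma_um, n)

    # ground-truth phase boundaries: nearest samples to the trajectory corners
    i_l0 = int(round(t_pre / dt))
    i_l1 = int(round((t_pre + t_ramp) / dt))
    i_h1 = int(round((t_pre + t_ramp + t_hold) / dt))

    # analytic secant slope of the noiseless ramp over its upper 35% span
    t_a, t_b = 0.65 * t_ramp, t_ramp
    p_a, p_b = (c * v * _g_integral(t_a, e_inf, e_0, tau),
                c * v * _g_integral(t_b, e_inf, e_0, tau))
    secant = float((p_b - p_a) / (v * (t_b - t_a)))
    e_tan_secant = secant * (1.0 - geom.poisson_nu ** 2) / (
        2.0 * geom.indenter_radius_um * kappa) * 1.0e6

    curve = IndentationCurve(time=t, displacement=x, load=p, sample_id=sample_id,
                             sampling_rate_hint=rate_hz)
    truth = GroundTruth(e_inf_mpa=e_inf, e_0_mpa=e_0, tau_s=tau, kappa=float(kappa),
                        loading_start=i_l0, loading_end=i_l1, hold_end=i_h1,
                        preload_displacement_um=float(x_pre),
                        secant_slope_n_per_um=secant,
                        e_tan_secant_mpa=float(e_tan_secant))
    return curve, truth


@dataclass(frozen=True)
class CohortGroupSpec:
    """Normal parameter distributions (truncated at physical bounds) for one group."""

    label: str
    n: int
    e_inf_mean_mpa: float
    e_inf_sd_mpa: float = 0.0
    stiffening_ratio_mean: float = 3.0  # E_0 / E_inf
    stiffening_ratio_sd: float = 0.0
    tau_mean_s: float = 1.0
    tau_sd_s: float = 0.0

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if self.e_inf_mean_mpa <= 0 or self.tau_mean_s <= 0:
            raise ValidationError(f"group {self.label!r}: means must be positive")
        if self.stiffening_ratio_mean < 1.0:
            raise ValidationError(f"group {self.label!r}: E_0/E_inf ratio must be >= 1")


def _truncated_normal(rng, mean, sd, low, size):
    """Draw N(mean, sd) resampling below ``low`` (physical bound)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out < low
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, low, None)


def generate_cohort(group_specs: list[CohortGroupSpec],
                    geometry: SpecimenGeometry | None = None,
                    protocol: ProtocolSpec | None = None,
                    rate_hz: float = 100.0,
                    load_noise_sigma_n: float = 0.0,
                    displacement_noise_sigma_um: float = 0.0,
                    seed: int = 0):
    """Simulate a multi-group cohort.

    Returns ``(curves, specimen_rows, truth_table)`` where ``curves`` maps
    sample_id -> IndentationCurve, ``specimen_rows`` is the
    (sample_id, geometry, group) list consumed by the pipeline, and
    ``truth_table`` is a tidy DataFrame of the generating parameters.
    """
    if geometry is None:
        geometry = SpecimenGeometry(thickness_um=525.0)
    if protocol is None:
        protocol = ProtocolSpec()
    rng = np.random.default_rng(seed)
    curves: dict[str, IndentationCurve] = {}
    rows = []
    truth_records = []
    for spec in group_specs:
        e_inf = _truncated_normal(rng, spec.e_inf_mean_mpa, spec.e_inf_sd_mpa, 0.01, spec.n)
        ratio = _truncated_normal(rng, spec.stiffening_ratio_mean,
                                  spec.stiffening_ratio_sd, 1.0, spec.n)
        tau = _truncated_normal(rng, spec.tau_mean_s, spec.tau_sd_s, 0.05, spec.n)
        for i in range(spec.n):
            sid = f"{spec.label}_{i + 1:02d}"
            params = SLSParams(e_inf_mpa=float(e_inf[i]),
                               e_0_mpa=float(e_inf[i] * ratio[i]),
                               tau_s=float(tau[i]), geometry=geometry)
            noise = NoiseSpec(load_sigma_n=load_noise_sigma_n,
                              displacement_sigma_um=displacement_noise_sigma_um,
                              seed=int(rng.integers(0, 2 ** 31 - 1)))
            curve, truth = generate_sls_curve(params, protocol, rate_hz=rate_hz,
                                              noise=noise, sample_id=sid)
            curves[sid] = curve
            rows.append((sid, geometry, spec.label))
            truth_records.append({
                "sample_id": sid, "group": spec.label,
                "e_inf_mpa": truth.e_inf_mpa, "e_0_mpa": truth.e_0_mpa,
                "tau_s": truth.tau_s, "kappa": truth.kappa,
                "e_tan_secant_mpa": truth.e_tan_secant_mpa,
            })
    return curves, rows, pd.DataFrame(truth_records)


def generate_voxel_phantom(shape: tuple[int, int, int],
                           voxel_size_mm: float | tuple[float, float, float],
                           roi: CylinderROI, bone_fraction: float,
                           structure: str = "random", seed: int = 0,
                           bone_value: float = 100.0):
    """Voxel phantom with a known bone fraction inside the cylindrical ROI.

    ``structure``: ``random`` (Bernoulli per voxel), ``lattice`` (exact count,
    evenly interleaved) or ``solid`` (exact count, contiguous fill).  Returns
    ``(VoxelVolume, realized_fraction)``; the volume is grayscale
    (0 / bone_value) so the thresholding stage is exercised.
    """
    if not (0.0 <= bone_fraction <= 1.0):
        raise ValidationError(f"bone_fraction must lie in [0,1], got {bone_fraction}")
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValidationError(f"invalid volume shape {shape}")
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (float(voxel_size_mm),) * 3
    values = np.zeros(shape, dtype=np.float32)
    mask = cylinder_mask(shape, voxel_size_mm, roi)
    idx = np.flatnonzero(mask.ravel())
    n_in = idx.size
    if structure == "random":
        rng = np.random.default_rng(seed)
        bone = rng.random(n_in) < bone_fraction
    elif structure == "lattice":
        k = int(round(bone_fraction * n_in))
        bone = np.zeros(n_in, dtype=bool)
        if k > 0:
            bone[np.linspace(0, n_in - 1, k).round().astype(int)] = True
    elif structure == "solid":
        k = int(round(bone_fraction * n_in))
        bone = np.zeros(n_in, dtype=bool)
        bone[:k] = True
    else:
        raise ValidationError(f"unknown phantom structure {structure!r}")
    flat = values.ravel()
    flat[idx[bone]] = bone_value
    realized = float(bone.sum()) / n_in if n_in else 0.0
    vol = VoxelVolume(values=values, voxel_size_mm=voxel_size_mm)
    return vol, realized
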