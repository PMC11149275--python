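"""Layered-elastic correction for flat-punch indentation (Hayes model).

A rigid flat-ended cylindrical punch of radius ``R`` indents an elastic
layer of thickness ``h`` bonded to a rigid half-space (subchondral bone).
The indentation modulus is

    E = P (1 - nu^2) / (2 R x0 kappa(alpha, nu)),      alpha = R / h,

where ``kappa >= 1`` corrects the half-space (Hertz) flat-punch result for
the confinement of the thin bonded layer; ``kappa -> 1`` as ``alpha -> 0``.

kappa is obtained from the classical mixed boundary-value problem.  The
bonded layer's surface compliance relative to a half-space is, in Hankel
space with ``x = xi * h`` and ``k = 3 - 4 nu``,

    W(x) = (2 k sinh 2x - 4 x) / (2 k cosh 2x + 4 x^2 + k^2 + 1),

(derived from the Love-function solution of a layer bonded to a rigid base;
``W -> 1`` for a thick layer, ``W -> 0`` for a vanishing one).  Reducing the
punch problem by the Lebedev-Ufliand cosine-transform substitution yields a
Fredholm integral equation of the second kind on the punch radius,

    w(t) - (1/pi) int_0^1 [K(t + s) + K(t - s)] w(s) ds = 1,
    K(u) = alpha int_0^inf (1 - W(y)) cos(alpha u y) dy,

and kappa = int_0^1 w(t) dt.  The production solver discretizes on a uniform
grid of step 0.01 (Nystrom, trapezoidal weights); a fine-mesh
Richardson-extrapolated variant serves as an independent numerical oracle.
"""

from __future__ import annotations

import functools
import io
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .curves import SpecimenGeometry
from .errors import (DomainError, ExtrapolationError, NumericalError,
                     ParameterError, QCRejectedError)

#: 1 N/um^2 expressed in MPa
MPA_PER_N_PER_UM2 = 1.0e6

DEFAULT_STEP = 0.01


def layer_compliance(y, nu: float):
    """Relative surface compliance W(y) of a bonded layer, y = xi*h.

    W is 0 at y=0, increases to 1 (half-space) as y -> inf.
    """
    y = np.asarray(y, dtype=float)
    k = 3.0 - 4.0 * nu
    num = 2.0 * k * np.sinh(2.0 * y) - 4.0 * y
    den = 2.0 * k * np.cosh(2.0 * y) + 4.0 * y * y + k * k + 1.0
    return num / den


def _kernel_deviation(y, nu: float):
    """1 - W(y), written to avoid cancellation (decays like y^2 exp(-2y))."""
    y = np.asarray(y, dtype=float)
    k = 3.0 - 4.0 * nu
    num = 2.0 * k * np.exp(-2.0 * y) + 4.0 * y * y + 4.0 * y + k * k + 1.0
    den = 2.0 * k * np.cosh(2.0 * y) + 4.0 * y * y + k * k + 1.0
    return num / den


def _check_domain(alpha: float, nu: float) -> None:
    if not (alpha > 0):
        raise DomainError(f"alpha must be > 0, got {alpha}")
    if not (0.0 <= nu < 0.5):
        raise DomainError(
            f"nu must lie in [0, 0.5); the incompressible bonded layer is "
            f"singular (got {nu})")


def _kernel_values(u: np.ndarray, alpha: float, nu: float, y_max: float) -> np.ndarray:
    """K(u) = alpha * int_0^y_max (1 - W(y)) cos(alpha u y) dy for each u.

    Gauss-Legendre panel quadrature; panel width shrinks with alpha so the
    cosine is resolved.  The integrand decays ~exp(-2y), so truncation at
    y_max = 40 is already far below 1e-12.
    """
    width = min(1.0, 4.0 / max(alpha, 1.0))
    n_panels = int(math.ceil(y_max / width))
    gx, gw = np.polynomial.legendre.leggauss(16)
    edges = np.linspace(0.0, y_max, n_panels + 1)
    half = 0.5 * (edges[1:] - edges[:-1])
    mid = 0.5 * (edges[1:] + edges[:-1])
    y = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
    w = (half[:, None] * gw[None, :]).ravel()
    fa = _kernel_deviation(y, nu) * w
    if not np.isfinite(fa).all():
        raise NumericalError("kernel quadrature produced non-finite values")
    # K for all u at once: cos(alpha * outer(u, y)) @ (weights * integrand)
    return alpha * (np.cos(alpha * np.outer(u, y)) @ fa)


def _solve_kappa_impl(alpha: float, nu: float, step: float, y_max: float) -> float:
    m = int(round(1.0 / step))
    t = np.linspace(0.0, 1.0, m + 1)
    # kernel argument |t_i +/- t_j| lies on the same uniform grid
    u = np.linspace(0.0, 2.0, 2 * m + 1)
    K = _kernel_values(u, alpha, nu, y_max)
    i = np.arange(m + 1)
    Kplus = K[i[:, None] + i[None, :]]
    Kminus = K[np.abs(i[:, None] - i[None, :])]
    wtrap = np.full(m + 1, step)
    wtrap[0] = wtrap[-1] = 0.5 * step
    M = (Kplus + Kminus) * wtrap[None, :] / math.pi
    A = np.eye(m + 1) - M
    omega = np.linalg.solve(A, np.ones(m + 1))
    kappa = float(np.trapezoid(omega, t))
    if not np.isfinite(kappa) or kappa <= 0:
        raise NumericalError(
            f"kappa solve diverged (alpha={alpha}, nu={nu}, step={step})")
    return kappa


@functools.lru_cache(maxsize=4096)
def _solve_kappa_cached(alpha: float, nu: float, step: float, y_max: float) -> float:
    return _solve_kappa_impl(alpha, nu, step, y_max)


def solve_kappa(alpha: float, nu: float, step: float = DEFAULT_STEP,
                y_max: float = 40.0) -> float:
    """Hayes correction factor kappa(alpha, nu), always >= 1.

    Parameters
    ----------
    alpha : R/h aspect ratio, > 0.
    nu : Poisson's ratio in [0, 0.5).
    step : uniform Nystrom step over the punch radius (default 0.01).
    y_max : truncation of the exponentially decaying kernel integral.
    """
    _check_domain(alpha, nu)
    if not (0.0 < step <= 0.1):
        raise ParameterError(f"step must lie in (0, 0.1], got {step}")
    return _solve_kappa_cached(float(alpha), float(nu), float(step), float(y_max))


def solve_kappa_reference(alpha: float, nu: float) -> float:
    """Fine-mesh Richardson-extrapolated kappa (independent numerical oracle).

    Solves at steps 0.002 and 0.001 with a doubled kernel truncation and
    extrapolates the O(step^2) trapezoidal error to zero.
    """
    _check_domain(alpha, nu)
    k2 = _solve_kappa_cached(float(alpha), float(nu), 0.002, 80.0)
    k1 = _solve_kappa_cached(float(alpha), float(nu), 0.001, 80.0)
    return (4.0 * k1 - k2) / 3.0


@dataclass(frozen=True)
class KappaTable:
    """Precomputed kappa over an (alpha, nu) grid, bilinearly interpolable."""

    alpha_grid: np.ndarray
    nu_grid: np.ndarray
    kappa: np.ndarray  # shape (n_alpha, n_nu)
    solver_step: float = DEFAULT_STEP

    def __post_init__(self):
        a = np.asarray(self.alpha_grid, dtype=float)
        n = np.asarray(self.nu_grid, dtype=float)
        k = np.asarray(self.kappa, dtype=float)
        object.__setattr__(self, "alpha_grid", a)
        object.__setattr__(self, "nu_grid", n)
        object.__setattr__(self, "kappa", k)
        if k.shape != (a.size, n.size):
            raise ParameterError("kappa matrix shape does not match grids")

    def to_csv(self, path) -> None:
        """Self-describing long-format text table (alpha, nu, kappa)."""
        with open(path, "w") as fh:
            fh.write("# indentmech kappa table\n")
            fh.write(f"# solver_step = {self.solver_step!r}\n")
            fh.write("alpha,nu,kappa\n")
            for i, a in enumerate(self.alpha_grid):
                for j, n in enumerate(self.nu_grid):
                    fh.write(f"{float(a)!r},{float(n)!r},{float(self.kappa[i, j])!r}\n")

    @classmethod
    def from_csv(cls, path) -> "KappaTable":
        step = DEFAULT_STEP
        lines = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "solver_step" in line:
                        step = float(line.split("=")[1])
                else:
                    lines.append(line)
        import pandas as pd
        df = pd.read_csv(io.StringIO("".join(lines)))
        alphas = np.unique(df["alpha"].to_numpy())
        nus = np.unique(df["nu"].to_numpy())
        k = np.full((alphas.size, nus.size), np.nan)
        ai = {a: i for i, a in enumerate(alphas)}
        nj = {n: j for j, n in enumerate(nus)}
        for _, row in df.iterrows():
            k[ai[row["alpha"]], nj[row["nu"]]] = row["kappa"]
        return cls(alpha_grid=alphas, nu_grid=nus, kappa=k, solver_step=step)


def build_kappa_table(alpha_grid, nu_grid, step: float = DEFAULT_STEP) -> KappaTable:
    alphas = np.asarray(alpha_grid, dtype=float)
    nus = np.asarray(nu_grid, dtype=float)
    if np.any(np.diff(alphas) <= 0) or np.any(np.diff(nus) < 0):
        raise ParameterError("grids must be sorted ascending")
    k = np.empty((alphas.size, nus.size))
    for i, a in enumerate(alphas):
        for j, n in enumerate(nus):
            try:
                k[i, j] = solve_kappa(a, n, step=step)
            except Exception as exc:
                raise NumericalError(f"kappa solve failed at alpha={a}, nu={n}: {exc}")
    return KappaTable(alpha_grid=alphas, nu_grid=nus, kappa=k, solver_step=step)


def interpolate_kappa(table: KappaTable, alpha: float, nu: float) -> float:
    """Bilinear kappa lookup; refuses to extrapolate outside the table hull."""
    a, n = table.alpha_grid, table.nu_grid
    if a.size == 1 or n.size == 1:
        # degenerate grid: nearest lookup only at exact coordinates
        if a.size == 1 and not np.isclose(alpha, a[0]):
            raise ExtrapolationError("alpha outside single-point table")
        if n.size == 1 and not np.isclose(nu, n[0]):
            raise ExtrapolationError("nu outside single-point table")
        i = int(np.argmin(np.abs(a - alpha)))
        j = int(np.argmin(np.abs(n - nu)))
        return float(table.kappa[i, j])
    interp = RegularGridInterpolator((a, n), table.kappa, method="linear",
                                     bounds_error=True)
    try:
        return float(interp([[alpha, nu]])[0])
    except ValueError:
        raise ExtrapolationError(
            f"(alpha={alpha}, nu={nu}) outside table hull "
            f"alpha:[{a[0]}, {a[-1]}], nu:[{n[0]}, {n[-1]}]")


@dataclass(frozen=True)
class ModulusResult:
    """Tangent and equilibrium moduli of one specimen with their inputs."""

    sample_id: str
    e_tan_mpa: float | None
    e_eq_mpa: float | None
    kappa_used: float
    slope_n_per_um: float | None
    p_eq_n: float | None
    x0_um: float | None
    r_squared: float | None
    qc_status: str


def hayes_force_factor(geom: SpecimenGeometry, kappa: float) -> float:
    """N per (MPa * um) of displacement: P = factor * E * x0.

    factor = 2 R kappa / (1 - nu^2), with R in um and E in MPa.
    """
    return 2.0 * geom.indenter_radius_um * kappa / (1.0 - geom.poisson_nu ** 2) / MPA_PER_N_PER_UM2


def tangent_modulus(fit, geom: SpecimenGeometry, kappa: float,
                    qc_decision=None) -> float:
    """Tangent modulus E_tan (MPa) from the upper-35% loading slope.

    ``fit`` may be a LinearFit or a bare slope in N/um.  If a QC decision is
    supplied and the fit was rejected, the computation is refused.
    """
    if qc_decision is not None and not qc_decision.accepted:
        raise QCRejectedError(f"fit rejected by QC: {qc_decision.reason}")
    slope = getattr(fit, "slope_n_per_um", fit)
    return float(slope) * (1.0 - geom.poisson_nu ** 2) / (
        2.0 * geom.indenter_radius_um * kappa) * MPA_PER_N_PER_UM2


def equilibrium_modulus(p_eq_n: float, x0_um: float, geom: SpecimenGeometry,
                        kappa: float) -> float:
    """Equilibrium modulus E_eq (MPa) from the relaxed hold-phase load."""
    if not (x0_um > 0):
        raise DomainError(f"equilibrium displacement must be > 0, got {x0_um}")
    return p_eq_n * (1.0 - geom.poisson_nu ** 2) / (
        2.0 * geom.indenter_radius_um * x0_um * kappa) * MPA_PER_N_PER_UM2
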