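"""Dynamic squeeze flow of a power-law fluid between tongue and palate.

A disk of liquid (radius ``R``, initial height ``h0``) is squeezed by a
constant normal force ``F_N`` while the tongue translates at constant
lateral speed ``V``.  In the thin-gap (lubrication) limit, with the lateral
shear dominating the squeeze contribution (``V >> alpha``), the gap obeys

    dh/dt = - F_N * h**(n+2) * V**(1-n) / (3 pi kappa n R**4)

whose separable solution is

    h(t) = h0 * (1 + ((n+1)/n) * F_N * h0**(n+1) * V**(1-n) * t
                     / (c * pi * kappa * R**4)) ** (-1/(n+1))

with bracket constant ``c = 3`` (the value consistent with the load
integral; variant ``"derivation"``).  The published closed form also
circulates with ``c = 2`` (variant ``"main_text"``); both are provided and
the ``main_text`` variant is the default for reproducing the sensory
analysis.  The two variants differ only through this constant, so
``gap(main_text) <= gap(derivation)`` and the stresses order the other way.

The perceived stimulus is the lateral shear stress on the tongue,
``sigma(t) = kappa * (V / h(t))**n``.

The module also exposes the underlying lubrication fields (velocity
profile across the gap, parabolic pressure field over the disk) and the
``alpha/V`` ratio that quantifies the validity of the Taylor expansion
used to linearize the velocity profile.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import InvalidInputError, NumericalError
from .oral_geometry import OralParameters
from .rheology import PowerLawFluid

__all__ = [
    "VARIANTS",
    "GapTrace",
    "LubricationField",
    "gap_at_time",
    "tongue_stress",
    "integrate_gap_ode",
    "velocity_profile",
    "pressure_field",
    "approximation_ratio",
]

logger = logging.getLogger(__name__)

#: bracket denominator constant per closed-form variant
VARIANTS = {"main_text": 2.0, "derivation": 3.0}

GAP_FLOOR = 1e-9  # m; films thinner than this are outside the model's scope

ArrayLike = Union[float, np.ndarray]


def _check_variant(variant: str) -> float:
    try:
        return VARIANTS[variant]
    except KeyError:
        raise InvalidInputError(
            f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}"
        ) from None


def _bracket_rate(fluid: PowerLawFluid, params: OralParameters, const: float) -> float:
    """Coefficient ``B`` such that ``h(t) = h0 * (1 + B t)**(-1/(n+1))``."""
    n, kappa = fluid.n, fluid.kappa
    return (
        ((n + 1.0) / n)
        * params.F_N
        * params.h0 ** (n + 1.0)
        * params.V ** (1.0 - n)
        / (const * math.pi * kappa * params.R**4)
    )


def gap_at_time(
    fluid: PowerLawFluid,
    params: OralParameters,
    t: ArrayLike,
    variant: str = "main_text",
) -> ArrayLike:
    """Closed-form gap ``h(t)`` in m; ``t`` (s) may be an array.

    For ``n == 1`` the exponent ``V**(1-n)`` is exactly 1, so the result is
    independent of the tongue speed, as it must be for a Newtonian fluid.
    """
    const = _check_variant(variant)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    rate = _bracket_rate(fluid, params, const)
    h = params.h0 * (1.0 + rate * t) ** (-1.0 / (fluid.n + 1.0))
    return float(h) if h.ndim == 0 else h


def tongue_stress(
    fluid: PowerLawFluid,
    params: OralParameters,
    t: ArrayLike,
    variant: str = "main_text",
) -> ArrayLike:
    """Total lateral shear stress on the tongue,
    ``sigma(t) = kappa * (V / h(t))**n`` in Pa."""
    h = gap_at_time(fluid, params, t, variant)
    sigma = fluid.kappa * (params.V / np.asarray(h)) ** fluid.n
    return float(sigma) if np.ndim(sigma) == 0 else sigma


@dataclass
class GapTrace:
    """Time series of gap and tongue stress for one fluid / parameter set."""

    times: np.ndarray  # s
    gap: np.ndarray  # m
    stress: np.ndarray  # Pa
    variant: str
    fluid: PowerLawFluid
    params: OralParameters
    floored: bool = False  # True if the gap hit GAP_FLOOR

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.gap = np.asarray(self.gap, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if not (self.times.size == self.gap.size == self.stress.size):
            raise InvalidInputError("trace arrays must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "gap_m": self.gap, "stress_pa": self.stress}
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the trace as CSV with metadata in ``#``-comment header lines."""
        path = Path(path)
        header = (
            f"# variant: {self.variant}\n"
            f"# fluid: kappa={self.fluid.kappa!r} n={self.fluid.n!r} "
            f"label={self.fluid.label!r}\n"
            f"# params: {self.params.to_dict()!r}\n"
        )
        path.write_text(header + self.to_frame().to_csv(index=False))


def integrate_gap_ode(
    fluid: PowerLawFluid,
    params: OralParameters,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> GapTrace:
    """Numerically integrate the load-balance ODE for the gap.

    This is the independent oracle for the ``derivation`` closed form:
    adaptive Runge-Kutta (RK45) on
    ``dh/dt = -F_N h**(n+2) V**(1-n) / (3 pi kappa n R**4)`` from
    ``h(0) = h0``.  The gap is floored at ``GAP_FLOOR`` (film rupture is not
    modelled); flooring is flagged on the returned trace and logged.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise InvalidInputError("t_grid must be a 1-D array")
    if t_grid[0] != 0:
        raise InvalidInputError("t_grid must start at 0")
    if t_grid.size > 1 and not np.all(np.diff(t_grid) > 0):
        raise InvalidInputError("t_grid must be strictly ascending")

    n, kappa = fluid.n, fluid.kappa
    if t_grid[-1] == 0.0:  # degenerate grid: nothing to integrate
        h = np.full(t_grid.shape, params.h0)
        return GapTrace(
            times=t_grid,
            gap=h,
            stress=kappa * (params.V / h) ** n,
            variant="derivation",
            fluid=fluid,
            params=params,
        )
    coeff = params.F_N * params.V ** (1.0 - n) / (3.0 * math.pi * kappa * n * params.R**4)

    def rhs(_t, y):
        h = max(y[0], GAP_FLOOR)
        return [-coeff * h ** (n + 2.0)]

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1]) if t_grid.size > 1 else 0.0),
        [params.h0],
        t_eval=t_grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalError(f"gap ODE integration failed: {sol.message}")
    h = sol.y[0]
    floored = bool(np.any(h <= GAP_FLOOR))
    if floored:
        logger.warning(
            "gap reached the %.0e m floor; film rupture is not modelled", GAP_FLOOR
        )
        h = np.maximum(h, GAP_FLOOR)
    stress = kappa * (params.V / h) ** n
    return GapTrace(
        times=t_grid,
        gap=h,
        stress=stress,
        variant="derivation",
        fluid=fluid,
        params=params,
        floored=floored,
    )


def closing_rate(
    fluid: PowerLawFluid, params: OralParameters, h: float
) -> float:
    """Gap closing rate ``-dh/dt > 0`` at gap ``h`` under the imposed load
    (inversion of the load integral): ``F_N h**(n+2) V**(1-n) /
    (3 pi kappa n R**4)``."""
    if not (h > 0):
        raise InvalidInputError("h must be strictly positive")
    n = fluid.n
    return (
        params.F_N
        * h ** (n + 2.0)
        * params.V ** (1.0 - n)
        / (3.0 * math.pi * fluid.kappa * n * params.R**4)
    )


@dataclass
class LubricationField:
    """Resolved lubrication quantities; 1-D (across-gap) and 2-D (over-disk)
    parts are populated by :func:`velocity_profile` and
    :func:`pressure_field` respectively."""

    z_grid: Optional[np.ndarray] = None  # m, 0 (tongue) .. h (palate)
    u_x: Optional[np.ndarray] = None  # m/s
    x_grid: Optional[np.ndarray] = None  # m
    y_grid: Optional[np.ndarray] = None  # m
    pressure: Optional[np.ndarray] = None  # Pa, 2-D over (y, x)
    dPdx: Optional[float] = None  # Pa/m
    tau_zr: Optional[np.ndarray] = None  # Pa, shear-stress profile
    c1: Optional[float] = None  # integration constant (exact, from BC)
    c1_taylor: Optional[float] = None  # first-order Taylor estimate of c1
    alpha: Optional[float] = None  # characteristic squeeze velocity, m/s
    hdot: Optional[float] = None  # gap closing rate, m/s
    load: Optional[float] = None  # N, quadrature of pressure over the disk


def _solve_c1(p: float, v_over_alpha: float) -> float:
    """Root of ``(c1 + 1/2)**p - (c1 - 1/2)**p == V/alpha`` with c1 >= 1/2.

    The left side is strictly increasing in ``c1`` and equals 1 at
    ``c1 = 1/2``, so a unique root exists iff ``V/alpha >= 1``.
    """
    if v_over_alpha < 1.0:
        raise NumericalError(
            "V/alpha < 1: outside the lateral-shear-dominated regime; "
            "the linearized velocity profile does not apply"
        )

    def g(c1: float) -> float:
        return (c1 + 0.5) ** p - (c1 - 0.5) ** p - v_over_alpha

    lo, hi = 0.5, 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise NumericalError("failed to bracket the c1 root")
    c1 = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    # Newton polish to push the no-slip residual to machine precision
    for _ in range(3):
        dg = p * ((c1 + 0.5) ** (p - 1.0) - (c1 - 0.5) ** (p - 1.0))
        if dg == 0:
            break
        c1 -= g(c1) / dg
        c1 = max(c1, 0.5)
    return c1


def velocity_profile(
    fluid: PowerLawFluid,
    h: float,
    V: float,
    dPdx: float,
    n_z: int = 201,
) -> LubricationField:
    """Across-gap velocity profile ``u_x(z)`` at one location.

    ``z`` runs from the moving tongue (``z = 0``, ``u_x = V``) to the
    stationary palate (``z = h``, ``u_x = 0``).  For ``dPdx == 0`` the
    profile is the pure Couette line.  Otherwise the power-law profile is
    evaluated on the branch matching ``sign(dPdx)``, with the integration
    constant ``c1`` obtained exactly from the no-slip condition at the
    tongue (its first-order Taylor estimate
    ``(n/(n+1))**n * (V/alpha)**n`` is returned alongside for reference).
    """
    if not (h > 0):
        raise InvalidInputError("h must be strictly positive")
    if not (V > 0):
        raise InvalidInputError("V must be strictly positive")
    if n_z < 2:
        raise InvalidInputError("n_z must be at least 2")

    n, kappa = fluid.n, fluid.kappa
    z = np.linspace(0.0, h, n_z)
    zeta = 0.5 - z / h  # +1/2 at the tongue, -1/2 at the palate

    if dPdx == 0.0:
        u = V * (1.0 - z / h)
        return LubricationField(z_grid=z, u_x=u, dPdx=0.0, alpha=0.0, c1=None)

    p = (n + 1.0) / n
    alpha = (h * n / (n + 1.0)) * (h * abs(dPdx) / kappa) ** (1.0 / n)
    c1 = _solve_c1(p, V / alpha)
    c1_taylor = (n / (n + 1.0)) ** n * (V / alpha) ** n

    if dPdx < 0:
        # favourable gradient: Poiseuille contribution adds to the drag flow
        u = alpha * ((c1 + 0.5) ** p - (c1 - zeta) ** p)
    else:
        u = alpha * ((c1 + zeta) ** p - (c1 - 0.5) ** p)

    # shear-stress profile tau = kappa * |du/dz|**(n-1) * du/dz
    dudz = np.gradient(u, z)
    tau = kappa * np.abs(dudz) ** (n - 1.0) * dudz

    return LubricationField(
        z_grid=z,
        u_x=u,
        dPdx=float(dPdx),
        tau_zr=tau,
        c1=c1,
        c1_taylor=c1_taylor,
        alpha=alpha,
    )


def pressure_field(
    fluid: PowerLawFluid,
    params: OralParameters,
    h: float,
    hdot: float,
    n_grid: int = 201,
) -> LubricationField:
    """Parabolic pressure field over the contact disk and its load.

    ``P(x, y) = 6 kappa n hdot (R^2 - x^2 - y^2) / (h**(n+2) V**(1-n))``
    inside the disk, zero on and outside the rim (``hdot`` is the positive
    closing rate).  The load is computed by midpoint quadrature of ``P`` on
    the Cartesian grid masked to the disk; analytically it equals
    ``3 pi kappa n hdot R**4 / (h**(n+2) V**(1-n))``.
    """
    if not (h > 0):
        raise InvalidInputError("h must be strictly positive")
    if hdot < 0:
        raise InvalidInputError("hdot must be given as a positive closing rate")
    if n_grid < 3:
        raise InvalidInputError("n_grid must be at least 3")

    n, kappa, R, V = fluid.n, fluid.kappa, params.R, params.V
    amp = 6.0 * kappa * n * hdot / (h ** (n + 2.0) * V ** (1.0 - n))
    x = np.linspace(-R, R, n_grid)
    y = np.linspace(-R, R, n_grid)
    X, Y = np.meshgrid(x, y)
    inside = X**2 + Y**2 <= R**2
    P = np.where(inside, amp * (R**2 - X**2 - Y**2), 0.0)
    dx = x[1] - x[0]
    load = float(P.sum() * dx * dx)

    return LubricationField(
        x_grid=x,
        y_grid=y,
        pressure=P,
        hdot=float(hdot),
        load=load,
    )


def approximation_ratio(
    fluid: PowerLawFluid,
    params: OralParameters,
    t: float,
    variant: str = "derivation",
) -> float:
    """Worst-case ``alpha/V`` over the disk at time ``t``.

    ``alpha`` is the characteristic squeeze-driven velocity scale
    ``(h n/(n+1)) (h |dP/dx| / kappa)**(1/n)``; the pressure gradient of the
    parabolic field is maximal at the rim along the sliding direction.
    Values well below 1 indicate the Taylor linearization of the velocity
    profile is justified.  Returns 0 when there is no squeezing
    (``hdot == 0``, e.g. zero load).
    """
    if t < 0:
        raise InvalidInputError("time must be non-negative")
    h = gap_at_time(fluid, params, t, variant)
    hdot = closing_rate(fluid, params, h)
    if hdot == 0.0:
        return 0.0
    n, kappa = fluid.n, fluid.kappa
    dPdx_max = (
        12.0 * kappa * n * hdot * params.R / (h ** (n + 2.0) * params.V ** (1.0 - n))
    )
    alpha = (h * n / (n + 1.0)) * (h * dPdx_max / kappa) ** (1.0 / n)
    return alpha / params.V
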