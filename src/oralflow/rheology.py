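"""Power-law (Ostwald-de Waele) fluid characterization.

A power-law fluid obeys ``sigma = kappa * gamma_dot**n`` with consistency
``kappa`` (Pa s^n) and flow index ``n`` (dimensionless, ``n == 1`` is
Newtonian).  This module holds the fluid representation, evaluation of
stress / apparent viscosity, and estimation of ``(kappa, n)`` from a
measured flow curve by least squares on log-transformed data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InvalidInputError

__all__ = [
    "PowerLawFluid",
    "PowerLawFit",
    "FlowCurve",
    "fit_power_law",
    "stress_at_rate",
    "apparent_viscosity",
    "read_flow_curve",
    "write_flow_curve",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class PowerLawFluid:
    """Shear-thinning fluid with stress ``kappa * rate**n``.

    Parameters
    ----------
    kappa
        Consistency parameter, Pa s^n.  Equals the viscosity when ``n == 1``.
    n
        Flow (power-law) index; ``n < 1`` means shear-thinning.
    label
        Free-text identifier, e.g. a sample number.
    """

    kappa: float
    n: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise InvalidInputError(f"kappa must be > 0, got {self.kappa}")
        if not (self.n > 0):
            raise InvalidInputError(f"n must be > 0, got {self.n}")

    def stress(self, gamma_dot: ArrayLike) -> ArrayLike:
        """Shear stress at shear rate ``gamma_dot`` (1/s), in Pa."""
        return stress_at_rate(self, gamma_dot)

    def viscosity(self, gamma_dot: ArrayLike) -> ArrayLike:
        """Apparent viscosity at shear rate ``gamma_dot`` (1/s), in Pa s."""
        return apparent_viscosity(self, gamma_dot)


@dataclass(frozen=True)
class PowerLawFit(PowerLawFluid):
    """Result of a flow-curve fit; usable anywhere a fluid is expected."""

    r_squared: float = float("nan")
    n_points: int = 0

    def to_record(self) -> dict:
        return {
            "label": self.label,
            "kappa": self.kappa,
            "n": self.n,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_record(), indent=2) + "\n")


@dataclass
class FlowCurve:
    """One measured flow curve: shear rate (1/s) vs shear stress (Pa).

    Temperature is metadata only; no correction is applied.
    """

    shear_rate: np.ndarray
    shear_stress: np.ndarray
    temperature: float = 40.0
    label: str = ""

    def __post_init__(self) -> None:
        self.shear_rate = np.asarray(self.shear_rate, dtype=float)
        self.shear_stress = np.asarray(self.shear_stress, dtype=float)
        if self.shear_rate.ndim != 1 or self.shear_stress.ndim != 1:
            raise InvalidInputError("flow-curve arrays must be 1-D")
        if self.shear_rate.size != self.shear_stress.size:
            raise InvalidInputError(
                "shear_rate and shear_stress must have equal length"
            )
        if self.shear_rate.size < 3:
            raise InvalidInputError("a flow curve needs at least 3 points")
        if not np.all(self.shear_rate > 0):
            raise InvalidInputError("all shear rates must be strictly positive")
        if not np.all(np.diff(self.shear_rate) > 0):
            raise InvalidInputError("shear rates must be strictly increasing")
        if not np.all(self.shear_stress > 0):
            raise InvalidInputError("all stresses must be strictly positive")

    def __len__(self) -> int:
        return int(self.shear_rate.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shear_rate": self.shear_rate,
                "shear_stress": self.shear_stress,
                "temperature": self.temperature,
            }
        )


def stress_at_rate(fluid: PowerLawFluid, gamma_dot: ArrayLike) -> ArrayLike:
    """Shear stress ``kappa * gamma_dot**n`` in Pa; ``gamma_dot`` in 1/s."""
    gamma_dot = np.asarray(gamma_dot, dtype=float)
    if np.any(gamma_dot <= 0):
        raise InvalidInputError("shear rate must be strictly positive")
    out = fluid.kappa * gamma_dot**fluid.n
    return float(out) if out.ndim == 0 else out


def apparent_viscosity(fluid: PowerLawFluid, gamma_dot: ArrayLike) -> ArrayLike:
    """Apparent viscosity ``kappa * gamma_dot**(n-1)`` in Pa s."""
    gamma_dot = np.asarray(gamma_dot, dtype=float)
    if np.any(gamma_dot <= 0):
        raise InvalidInputError("shear rate must be strictly positive")
    out = fluid.kappa * gamma_dot ** (fluid.n - 1.0)
    return float(out) if out.ndim == 0 else out


def fit_power_law(curve: FlowCurve, method: str = "loglog") -> PowerLawFit:
    """Estimate ``(kappa, n)`` from a flow curve.

    The default ``loglog`` method is ordinary least squares of
    ``log(stress)`` on ``log(rate)`` (natural log internally; the base does
    not affect the estimates).  This weights all decades of shear rate
    equally, which is appropriate for curves spanning several orders of
    magnitude of rate.  ``method="nls"`` refines the log-log estimate by
    nonlinear least squares in linear stress space.

    Returns a :class:`PowerLawFit` carrying ``r_squared`` (of the log-log
    regression) and ``n_points``.
    """
    if method not in ("loglog", "nls"):
        raise InvalidInputError(f"unknown fit method {method!r}")
    x = np.log(curve.shear_rate)
    y = np.log(curve.shear_stress)
    slope, intercept = np.polyfit(x, y, 1)
    kappa, n = math.exp(intercept), float(slope)

    if method == "nls":
        popt, _ = curve_fit(
            lambda g, k, m: k * g**m,
            curve.shear_rate,
            curve.shear_stress,
            p0=(kappa, n),
            maxfev=10000,
        )
        kappa, n = float(popt[0]), float(popt[1])

    resid = y - (np.log(kappa) + n * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(
        kappa=kappa,
        n=n,
        label=curve.label,
        r_squared=r_squared,
        n_points=len(curve),
    )


def log_loss(curve: FlowCurve, kappa: float, n: float) -> float:
    """Sum of squared residuals of log stress vs log rate for ``(kappa, n)``.

    This is the objective minimized by :func:`fit_power_law`; exposed so
    callers (and tests) can compare candidate parameter pairs directly.
    """
    pred = np.log(kappa) + n * np.log(curve.shear_rate)
    return float(np.sum((np.log(curve.shear_stress) - pred) ** 2))


def read_flow_curve(path: Union[str, Path], label: str = "") -> FlowCurve:
    """Read a flow curve from delimited text with ``shear_rate`` /
    ``shear_stress`` columns (optional ``temperature``); one curve per file.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"shear_rate", "shear_stress"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"missing columns in {path}: {sorted(missing)}")
    temperature = float(df["temperature"].iloc[0]) if "temperature" in df else 40.0
    return FlowCurve(
        shear_rate=df["shear_rate"].to_numpy(),
        shear_stress=df["shear_stress"].to_numpy(),
        temperature=temperature,
        label=label or path.stem,
    )


def write_flow_curve(curve: FlowCurve, path: Union[str, Path]) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    curve.to_frame().to_csv(path, sep=sep, index=False)
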