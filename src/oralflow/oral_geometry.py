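"""Biophysical parameters of the tongue-palate system.

The oral cavity is reduced to two parallel plates: a soft tongue pressed
against a much stiffer palate with a constant lingual force while moving
laterally.  This module holds the parameter set, the Hertz-type contact
estimates (tongue deformation and contact radius) that justify the
parallel-plate reduction, and the initial-gap geometry of the trapped bolus.

All quantities are plain SI floats (N, m, m^3, s, Pa); the contact angle
``theta`` is carried in degrees as metadata only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import InvalidInputError

__all__ = [
    "OralParameters",
    "ValidityReport",
    "default_oral_parameters",
    "hertz_deformation",
    "contact_radius",
    "initial_gap",
    "parallel_plate_validity",
]

logger = logging.getLogger(__name__)

_POSITIVE_FIELDS = (
    "V",
    "V0",
    "R",
    "h0",
    "t_assess",
    "R_tongue",
    "E_tongue",
    "E_palate",
)


def initial_gap(V0: float, R: float) -> float:
    """Initial tongue-palate gap of a bolus of volume ``V0`` (m^3) spread
    over a disk of radius ``R`` (m): ``h0 = V0 / (pi R^2)``."""
    if not (V0 > 0 and R > 0):
        raise InvalidInputError("V0 and R must be strictly positive")
    return V0 / (math.pi * R**2)


@dataclass(frozen=True)
class OralParameters:
    """Constants of the tongue-palate squeeze system.

    ``h0`` defaults to the volume-conserving value ``V0 / (pi R^2)``; a
    user-supplied override is accepted but logged, since it breaks the
    volume-consistency invariant.
    """

    F_N: float = 0.5  # lingual normal force, N
    V: float = 0.15  # lateral tongue speed, m/s
    V0: float = 4e-6  # bolus volume, m^3
    R: float = 0.025  # liquid contact radius on the tongue, m
    h0: Optional[float] = None  # initial gap, m (None -> derived)
    t_assess: float = 1.2  # assessment (residence) time, s
    R_tongue: float = 0.05  # tongue radius of curvature, m
    E_tongue: float = 3e3  # tongue Young's modulus, Pa
    E_palate: float = 4e7  # palate Young's modulus, Pa
    theta: float = 30.0  # contact angle, degrees (metadata)
    h0_derived: bool = field(init=False, default=True, repr=False)

    def __post_init__(self) -> None:
        if self.h0 is None:
            object.__setattr__(self, "h0", initial_gap(self.V0, self.R))
            object.__setattr__(self, "h0_derived", True)
        else:
            object.__setattr__(self, "h0_derived", False)
            logger.warning(
                "h0 overridden to %.4g m; volume consistency h0*pi*R^2 == V0 "
                "is not enforced",
                self.h0,
            )
        # F_N may be zero to express the unloaded (no-squeeze) limit
        if self.F_N < 0:
            raise InvalidInputError(f"F_N must be non-negative, got {self.F_N}")
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if not (value > 0):
                raise InvalidInputError(f"{name} must be > 0, got {value}")
        if not (self.E_tongue < self.E_palate):
            raise InvalidInputError(
                "E_tongue must be smaller than E_palate "
                f"({self.E_tongue} >= {self.E_palate})"
            )
        if self.h0_derived:
            assert abs(self.h0 * math.pi * self.R**2 - self.V0) <= 1e-12 * self.V0

    def with_overrides(self, **kwargs) -> "OralParameters":
        """Return a copy with the given fields replaced."""
        unknown = set(kwargs) - {f for f in self.__dataclass_fields__ if f != "h0_derived"}
        if unknown:
            raise InvalidInputError(f"unknown parameter keys: {sorted(unknown)}")
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("h0_derived")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OralParameters":
        unknown = set(d) - {f for f in cls.__dataclass_fields__ if f != "h0_derived"}
        if unknown:
            raise InvalidInputError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "OralParameters":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise InvalidInputError(f"{path} does not contain a key-value map")
        return cls.from_dict(data)


def default_oral_parameters() -> OralParameters:
    """The default biophysical parameter set (tablespoon bolus, licking-test
    contact radius, 1.2 s assessment time)."""
    return OralParameters()


def hertz_deformation(F_N: float, R_tongue: float, E_tongue: float) -> float:
    """Hertz-type indentation of the soft tongue pressed with force ``F_N``:

    ``delta = (9 F_N^2 / (16 R_tongue E_tongue^2))**(1/3)``

    ``F_N`` may be zero (no load, no deformation); the geometry and modulus
    must be strictly positive.
    """
    if F_N < 0:
        raise InvalidInputError("F_N must be non-negative")
    if not (R_tongue > 0 and E_tongue > 0):
        raise InvalidInputError("R_tongue and E_tongue must be strictly positive")
    return (9.0 * F_N**2 / (16.0 * R_tongue * E_tongue**2)) ** (1.0 / 3.0)


def contact_radius(delta: float, R_tongue: float) -> float:
    """Hertzian contact radius ``a = sqrt(delta * R_tongue)`` for an
    indentation ``delta`` of a sphere of radius ``R_tongue``."""
    if not (delta > 0 and R_tongue > 0):
        raise InvalidInputError("delta and R_tongue must be strictly positive")
    return math.sqrt(delta * R_tongue)


@dataclass(frozen=True)
class ValidityReport:
    """Outcome of the parallel-plate sanity checks."""

    delta: float  # tongue indentation, m
    contact_radius: float  # Hertz contact radius, m
    geometry_ok: bool  # delta < R_tongue
    stiffness_ok: bool  # E_tongue / E_palate < 1e-2

    @property
    def valid(self) -> bool:
        return self.geometry_ok and self.stiffness_ok


def parallel_plate_validity(params: OralParameters) -> ValidityReport:
    """Check that the two-parallel-plate reduction is justified: the tongue
    indentation must stay below its radius of curvature and the tongue must
    be far softer than the palate (modulus ratio below 1e-2)."""
    delta = hertz_deformation(params.F_N, params.R_tongue, params.E_tongue)
    a = contact_radius(delta, params.R_tongue) if delta > 0 else 0.0
    return ValidityReport(
        delta=delta,
        contact_radius=a,
        geometry_ok=delta < params.R_tongue,
        stiffness_ok=(params.E_tongue / params.E_palate) < 1e-2,
    )
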