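"""Packaged reference dataset and synthetic-data generators.

``table1_samples`` returns the 20 reference products (three sets of
bouillons and xanthan-gum solutions) with their fitted power-law
parameters and panel thickness scores; the table ships as an installed
CSV whose SHA-256 checksum is pinned so transcription errors fail loudly.

The synthetic generators produce flow curves with multiplicative
lognormal noise (relative error is the natural rheometer error model) and
panel score tables with additive normal noise, both with known ground
truth for round-trip / parameter-recovery testing.  All randomness flows
from ``SyntheticSpec.seed`` through ``numpy.random.SeedSequence``:
stream 0 feeds flow-curve noise and stream 1 feeds panel noise, so the
two generators are independent yet jointly reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .oral_geometry import OralParameters
from .psychophysics import SCORE_SCALE, SensorySample
from .rheology import FlowCurve, PowerLawFluid
from .squeeze_flow import tongue_stress

__all__ = [
    "TABLE1_SHA256",
    "SyntheticSpec",
    "table1_frame",
    "table1_samples",
    "table1_checksum",
    "generate_flow_curve",
    "generate_panel_scores",
]

#: pinned checksum of the installed table1.csv
TABLE1_SHA256 = "4e6b72a4ba1ca03e06802e6e41c4eb6dd29a420db3337470ce1fbfb625d206f3"


def _table1_bytes() -> bytes:
    return resources.files("oralflow").joinpath("data/table1.csv").read_bytes()


def table1_checksum() -> str:
    """SHA-256 of the installed reference table."""
    return hashlib.sha256(_table1_bytes()).hexdigest()


def table1_frame() -> pd.DataFrame:
    """The reference table as a DataFrame
    (columns ``id, kappa, n, score_mean, score_sem, set_label``)."""
    if table1_checksum() != TABLE1_SHA256:
        raise InvalidInputError(
            "packaged table1.csv checksum mismatch; the data file is corrupted"
        )
    import io

    df = pd.read_csv(io.BytesIO(_table1_bytes()), dtype={"id": str})
    return df


def table1_samples(sets: Optional[Sequence[str]] = None) -> List[SensorySample]:
    """The 20 reference products, optionally filtered by set label."""
    df = table1_frame()
    if sets is not None:
        df = df[df["set_label"].isin(set(sets))]
    return [
        SensorySample(
            id=row.id,
            kappa=float(row.kappa),
            n=float(row.n),
            score_mean=float(row.score_mean),
            score_sem=float(row.score_sem),
            set_label=row.set_label,
        )
        for row in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth recipe for synthetic inputs.

    ``true_law`` is a parameter mapping like
    ``{"law": "weber_fechner", "a": 3.0, "b": 4.0}`` or
    ``{"law": "stevens", "c": 0.5, "k": 3.0, "m": 0.2}``.
    """

    seed: int = 0
    rates: np.ndarray = field(
        default_factory=lambda: np.logspace(-1, 3, 30)
    )  # 1/s
    noise_sd_rel: float = 0.0  # relative sd of the multiplicative stress noise
    n_panelists: int = 12
    panel_noise_sd: float = 0.0  # score units
    true_law: dict = field(
        default_factory=lambda: {"law": "weber_fechner", "a": 3.0, "b": 4.0}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if self.noise_sd_rel < 0 or self.panel_noise_sd < 0:
            raise InvalidInputError("noise levels must be non-negative")
        if self.n_panelists < 1:
            raise InvalidInputError("need at least one panelist")
        if self.true_law.get("law") not in ("weber_fechner", "stevens"):
            raise InvalidInputError("true_law['law'] must name a supported law")

    def rng(self, stream: int) -> np.random.Generator:
        """Child generator for the given stream index (the splitting rule)."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(stream + 1)[stream]
        )


def _law_value(true_law: dict, sigma: np.ndarray) -> np.ndarray:
    if true_law["law"] == "weber_fechner":
        return true_law["a"] + true_law["b"] * np.log10(sigma)
    return true_law["c"] + true_law["k"] * sigma ** true_law["m"]


def generate_flow_curve(fluid: PowerLawFluid, spec: SyntheticSpec) -> FlowCurve:
    """Synthetic flow curve: exact power-law stresses times mean-one
    multiplicative lognormal noise of relative sd ``noise_sd_rel``."""
    rates = spec.rates
    stresses = fluid.kappa * rates**fluid.n
    if spec.noise_sd_rel > 0:
        s = np.sqrt(np.log1p(spec.noise_sd_rel**2))
        noise = np.exp(spec.rng(0).normal(-0.5 * s * s, s, size=rates.shape))
        stresses = stresses * noise
    return FlowCurve(
        shear_rate=rates,
        shear_stress=stresses,
        label=fluid.label or "synthetic",
    )


def generate_panel_scores(
    fluids: Sequence[PowerLawFluid],
    params: OralParameters,
    spec: SyntheticSpec,
    variant: str = "main_text",
) -> pd.DataFrame:
    """Raw per-panelist score table drawn from a known psychophysical law.

    For each fluid the tongue stress at ``params.t_assess`` is computed,
    the true law applied, and each panelist's score drawn with additive
    ``Normal(0, panel_noise_sd)`` noise, then clamped to the 0-15 scale.
    Columns: ``product, panelist, stress_pa, true_score, score``.
    """
    rng = spec.rng(1)
    rows = []
    for i, fluid in enumerate(fluids):
        sigma = float(tongue_stress(fluid, params, params.t_assess, variant))
        true = float(_law_value(spec.true_law, np.asarray(sigma)))
        noise = (
            rng.normal(0.0, spec.panel_noise_sd, size=spec.n_panelists)
            if spec.panel_noise_sd > 0
            else np.zeros(spec.n_panelists)
        )
        scores = np.clip(true + noise, *SCORE_SCALE)
        for j in range(spec.n_panelists):
            rows.append(
                {
                    "product": fluid.label or f"fluid_{i}",
                    "panelist": j,
                    "stress_pa": sigma,
                    "true_score": true,
                    "score": float(scores[j]),
                }
            )
    return pd.DataFrame(rows)
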