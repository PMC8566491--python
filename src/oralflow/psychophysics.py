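"""Psychophysical laws linking tongue stress to perceived thickness.

Two candidate laws relate the computed tongue stress ``sigma`` (the
stimulus) to the panel thickness score ``S`` on the 0-15 category scale:

* Weber-Fechner (logarithmic, 2 parameters): ``S = a + b * log10(sigma)``
  -- ``b`` is the score change per decade of stress.
* Stevens (power, 3 parameters): ``S = c + k * sigma**m``.

The power law degenerates into the logarithmic one as ``m -> 0`` with
``k -> inf``; the Stevens fit therefore bounds the exponent away from zero
(``min_exponent``, default 0.05) so the two laws remain distinct models.

Fits are unweighted by default; inverse-SEM^2 weighting is opt-in for the
Weber-Fechner fit.  ``chi`` on a fit is the vector of raw residuals
(observed - predicted, score units); SEM-standardized residuals are
available where SEMs are known.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import FittingError, InvalidInputError
from .oral_geometry import OralParameters
from .rheology import PowerLawFluid
from .squeeze_flow import tongue_stress

__all__ = [
    "SCORE_SCALE",
    "SensorySample",
    "PsychoFit",
    "ComparisonReport",
    "PanelSummary",
    "fit_weber_fechner",
    "fit_stevens",
    "compare_fits",
    "predict_thickness",
    "panel_summary",
]

logger = logging.getLogger(__name__)

SCORE_SCALE = (0.0, 15.0)  # the 16-point category scale


@dataclass(frozen=True)
class SensorySample:
    """One product: rheology parameters plus its panel thickness score."""

    id: str
    kappa: float  # Pa s^n
    n: float  # flow index
    score_mean: float  # 0-15 scale
    score_sem: float  # same scale
    set_label: str  # set1 / set2 / set3

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise InvalidInputError(f"kappa must be > 0, got {self.kappa}")
        if not (0 < self.n <= 1):
            raise InvalidInputError(f"n must be in (0, 1], got {self.n}")
        if not (SCORE_SCALE[0] <= self.score_mean <= SCORE_SCALE[1]):
            raise InvalidInputError(
                f"score_mean must be within {SCORE_SCALE}, got {self.score_mean}"
            )
        if self.score_sem < 0:
            raise InvalidInputError(f"score_sem must be >= 0, got {self.score_sem}")

    @property
    def fluid(self) -> PowerLawFluid:
        return PowerLawFluid(kappa=self.kappa, n=self.n, label=self.id)


@dataclass
class PsychoFit:
    """A fitted psychophysical law with residual diagnostics."""

    law: str  # "weber_fechner" | "stevens"
    params: dict  # {a, b} or {c, k, m}
    residuals: np.ndarray  # observed - predicted, score units
    chi: np.ndarray  # residual vector (alias of residuals; see module doc)
    rmse: float
    sse: float
    n_params: int
    fitted_on: list = field(default_factory=list)
    param_se: Optional[dict] = None  # standard errors (Weber-Fechner OLS)
    standardized_chi: Optional[np.ndarray] = None  # residuals / SEM, if SEMs given

    def __post_init__(self) -> None:
        expected = {"weber_fechner": 2, "stevens": 3}
        if self.law not in expected:
            raise InvalidInputError(f"unknown law {self.law!r}")
        if self.n_params != expected[self.law]:
            raise InvalidInputError(
                f"{self.law} has {expected[self.law]} parameters, got {self.n_params}"
            )

    def predict(self, stress):
        """Evaluate the fitted law at stress(es) in Pa (no clamping)."""
        stress = np.asarray(stress, dtype=float)
        if np.any(stress <= 0):
            raise InvalidInputError("stress must be strictly positive")
        if self.law == "weber_fechner":
            out = self.params["a"] + self.params["b"] * np.log10(stress)
        else:
            out = self.params["c"] + self.params["k"] * stress ** self.params["m"]
        return float(out) if out.ndim == 0 else out

    def to_record(self) -> dict:
        rec = {
            "law": self.law,
            "params": {k: float(v) for k, v in self.params.items()},
            "rmse": float(self.rmse),
            "sse": float(self.sse),
            "n_params": self.n_params,
            "fitted_on": list(self.fitted_on),
            "residuals": [float(r) for r in self.residuals],
        }
        if self.param_se is not None:
            rec["param_se"] = {k: float(v) for k, v in self.param_se.items()}
        return rec


def _validate_xy(stresses, scores, min_len: int):
    stresses = np.asarray(stresses, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if stresses.ndim != 1 or scores.ndim != 1 or stresses.size != scores.size:
        raise InvalidInputError("stresses and scores must be equal-length 1-D arrays")
    if stresses.size < min_len:
        raise InvalidInputError(f"need at least {min_len} samples")
    if np.any(stresses <= 0):
        raise InvalidInputError("all stresses must be strictly positive")
    return stresses, scores


def fit_weber_fechner(
    stresses: Sequence[float],
    scores: Sequence[float],
    sems: Optional[Sequence[float]] = None,
    weighted: bool = False,
    ids: Optional[Sequence[str]] = None,
) -> PsychoFit:
    """Least-squares fit of ``S = a + b * log10(sigma)``.

    Unweighted OLS by default; with ``weighted=True`` (requires ``sems``)
    each sample is weighted by ``1/sem**2``.  Standard errors of ``(a, b)``
    are reported from the usual linear-regression formulas.
    """
    stresses, scores = _validate_xy(stresses, scores, 3)
    x = np.log10(stresses)
    if np.ptp(x) == 0:
        raise InvalidInputError(
            "all stresses identical: the log-linear design matrix is rank-deficient"
        )
    if weighted:
        if sems is None:
            raise InvalidInputError("weighted fit requires sems")
        sems_arr = np.asarray(sems, dtype=float)
        if np.any(sems_arr <= 0):
            raise InvalidInputError("weights require strictly positive SEMs")
        w = 1.0 / sems_arr**2
    else:
        w = np.ones_like(x)

    X = np.column_stack([np.ones_like(x), x])
    Xw = X * w[:, None]
    beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ scores, rcond=None)
    a, b = float(beta[0]), float(beta[1])

    pred = a + b * x
    resid = scores - pred
    sse = float(np.sum(w * resid**2))
    dof = max(x.size - 2, 1)
    s2 = float(np.sum(w * resid**2) / dof)
    cov = s2 * np.linalg.inv(Xw.T @ X)
    se = {"a": math.sqrt(cov[0, 0]), "b": math.sqrt(cov[1, 1])}

    std_chi = None
    if sems is not None:
        sems_arr = np.asarray(sems, dtype=float)
        with np.errstate(divide="ignore"):
            std_chi = np.where(sems_arr > 0, resid / sems_arr, np.inf)

    return PsychoFit(
        law="weber_fechner",
        params={"a": a, "b": b},
        residuals=resid,
        chi=resid.copy(),
        rmse=float(np.sqrt(np.mean(resid**2))),
        sse=sse,
        n_params=2,
        fitted_on=list(ids) if ids is not None else [],
        param_se=se,
        standardized_chi=std_chi,
    )


#: deterministic multi-start exponents for the Stevens fit
STEVENS_STARTS = (0.1, 0.3, 0.5, 1.0)


def fit_stevens(
    stresses: Sequence[float],
    scores: Sequence[float],
    min_exponent: float = 0.05,
    max_exponent: float = 5.0,
    ids: Optional[Sequence[str]] = None,
) -> PsychoFit:
    """Nonlinear least-squares fit of ``S = c + k * sigma**m``.

    Starts from each exponent in :data:`STEVENS_STARTS` with ``(c, k)``
    initialized by linear least squares at that fixed exponent; the
    converged fit with the lowest SSE wins (ties broken by the smallest
    ``m``).  ``k`` is constrained non-negative and ``m`` to
    ``[min_exponent, max_exponent]`` -- the lower bound excludes the
    ``m -> 0`` degeneracy in which the power law collapses onto the
    logarithmic one.
    """
    stresses, scores = _validate_xy(stresses, scores, 4)
    if not (0 < min_exponent < max_exponent):
        raise InvalidInputError("need 0 < min_exponent < max_exponent")

    best = None  # (sse, m, params_vector)
    lower = np.array([-np.inf, 0.0, min_exponent])
    upper = np.array([np.inf, np.inf, max_exponent])

    def model_resid(p):
        return p[0] + p[1] * stresses ** p[2] - scores

    for m0 in STEVENS_STARTS:
        m0 = min(max(m0, min_exponent), max_exponent)
        basis = np.column_stack([np.ones_like(stresses), stresses**m0])
        ck, *_ = np.linalg.lstsq(basis, scores, rcond=None)
        p0 = np.array([ck[0], max(ck[1], 1e-12), m0])
        try:
            res = least_squares(
                model_resid,
                p0,
                bounds=(lower, upper),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=50000,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.debug("Stevens start m0=%g failed: %s", m0, exc)
            continue
        if not res.success:
            continue
        sse = float(np.sum(res.fun**2))
        if (
            best is None
            or sse < best[0] * (1.0 - 1e-10)
            or (abs(sse - best[0]) <= best[0] * 1e-10 and res.x[2] < best[1])
        ):
            best = (sse, float(res.x[2]), res.x)

    if best is None:
        raise FittingError(
            "Stevens fit did not converge from any start "
            f"(starts tried: {STEVENS_STARTS})"
        )

    c, k, m = (float(v) for v in best[2])
    pred = c + k * stresses**m
    resid = scores - pred
    return PsychoFit(
        law="stevens",
        params={"c": c, "k": k, "m": m},
        residuals=resid,
        chi=resid.copy(),
        rmse=float(np.sqrt(np.mean(resid**2))),
        sse=float(best[0]),
        n_params=3,
        fitted_on=list(ids) if ids is not None else [],
    )


@dataclass
class ComparisonReport:
    """Train/test comparison of the two psychophysical laws."""

    weber_fechner: PsychoFit
    stevens: PsychoFit
    variant: str
    train_ids: list
    test_ids: list
    train_stresses: np.ndarray
    test_stresses: np.ndarray
    train_rmse: dict  # law -> RMSE on the training samples
    test_rmse: dict  # law -> RMSE on the held-out samples (empty test -> nan)
    test_residuals: dict  # law -> array of held-out residuals
    preferred: Optional[str]  # law with lower test RMSE (None if no test set)

    def to_record(self) -> dict:
        return {
            "variant": self.variant,
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "weber_fechner": self.weber_fechner.to_record(),
            "stevens": self.stevens.to_record(),
            "train_rmse": {k: float(v) for k, v in self.train_rmse.items()},
            "test_rmse": {k: float(v) for k, v in self.test_rmse.items()},
            "preferred": self.preferred,
        }


def sample_stress(
    sample: SensorySample, params: OralParameters, variant: str = "main_text"
) -> float:
    """Tongue stress for one sensory sample at the assessment time."""
    return float(tongue_stress(sample.fluid, params, params.t_assess, variant))


def compare_fits(
    train: Sequence[SensorySample],
    test: Sequence[SensorySample],
    params: OralParameters,
    variant: str = "main_text",
    weighted: bool = False,
) -> ComparisonReport:
    """Fit both laws on ``train`` and evaluate both on ``test`` unchanged.

    Stresses are computed from each sample's rheology at
    ``params.t_assess``.  The held-out samples never influence the fitted
    parameters; ``preferred`` names the law with the lower test RMSE.
    """
    if len(train) == 0:
        raise InvalidInputError("training set must be non-empty")
    tr_sigma = np.array([sample_stress(s, params, variant) for s in train])
    tr_score = np.array([s.score_mean for s in train])
    tr_sem = np.array([s.score_sem for s in train])
    tr_ids = [s.id for s in train]

    wf = fit_weber_fechner(tr_sigma, tr_score, sems=tr_sem, weighted=weighted, ids=tr_ids)
    st = fit_stevens(tr_sigma, tr_score, ids=tr_ids)

    te_ids = [s.id for s in test]
    te_sigma = np.array([sample_stress(s, params, variant) for s in test])
    te_score = np.array([s.score_mean for s in test])

    test_rmse = {}
    test_resid = {}
    for fit in (wf, st):
        if len(test) == 0:
            test_rmse[fit.law] = float("nan")
            test_resid[fit.law] = np.array([])
        else:
            resid = te_score - fit.predict(te_sigma)
            test_resid[fit.law] = resid
            test_rmse[fit.law] = float(np.sqrt(np.mean(resid**2)))

    preferred = None
    if len(test) > 0:
        preferred = min(test_rmse, key=test_rmse.get)

    return ComparisonReport(
        weber_fechner=wf,
        stevens=st,
        variant=variant,
        train_ids=tr_ids,
        test_ids=te_ids,
        train_stresses=tr_sigma,
        test_stresses=te_sigma,
        train_rmse={wf.law: wf.rmse, st.law: st.rmse},
        test_rmse=test_rmse,
        test_residuals=test_resid,
        preferred=preferred,
    )


def predict_thickness(
    fluid: PowerLawFluid,
    params: OralParameters,
    fit: PsychoFit,
    variant: str = "main_text",
) -> float:
    """Predicted thickness score for a fluid: apply the fitted law to the
    tongue stress at ``params.t_assess``, clamped to the 0-15 scale (a
    clamp is reported as a warning)."""
    sigma = float(tongue_stress(fluid, params, params.t_assess, variant))
    raw = float(fit.predict(sigma))
    lo, hi = SCORE_SCALE
    if raw < lo or raw > hi:
        clamped = min(max(raw, lo), hi)
        warnings.warn(
            f"predicted score {raw:.3g} outside the {SCORE_SCALE} scale; "
            f"clamped to {clamped:g}",
            stacklevel=2,
        )
        return clamped
    return raw


@dataclass(frozen=True)
class PanelSummary:
    """Per-product summary of raw panel scores."""

    mean: float
    sem: float
    mu: float  # normal-fit location (MLE)
    sigma_dist: float  # normal-fit scale (MLE)
    n: int


def panel_summary(raw_scores: Sequence[float]) -> PanelSummary:
    """Mean, SEM (``sd/sqrt(n)``, with ``ddof=1``) and maximum-likelihood
    normal parameters of one product's raw panel scores."""
    scores = np.asarray(raw_scores, dtype=float)
    if scores.ndim != 1 or scores.size < 2:
        raise InvalidInputError("need at least 2 scores")
    mu, sigma_dist = stats.norm.fit(scores)
    return PanelSummary(
        mean=float(np.mean(scores)),
        sem=float(np.std(scores, ddof=1) / math.sqrt(scores.size)),
        mu=float(mu),
        sigma_dist=float(sigma_dist),
        n=int(scores.size),
    )
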