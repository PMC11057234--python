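"""Weighted combination of the four slant estimators and its fitting.

The perspective estimate gets weight lambda, a monotone function of the
angular image size gamma: alpha = tan(gamma/2), phi = 2 atan(alpha tan t),
lambda = (1 - cos phi)/2, with t a shared constant (75 degrees by
default). The remaining weight goes to a linear combination of the three
constraint-based estimates with coefficients beta fitted by least
squares to per-trial response slants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .family import SLANT_MAX_RAD, SLANT_MIN_RAD

__all__ = [
    "ModelCoefficients",
    "TrialEstimates",
    "ResponseRecord",
    "lambda_weight",
    "theta_lm",
    "predict_slant",
    "fit_coefficients",
    "fit_by_group",
    "simulate_observer",
]

RESPONSE_MIN_DEG = math.degrees(SLANT_MIN_RAD)
RESPONSE_MAX_DEG = math.degrees(SLANT_MAX_RAD)

_THETA_NAMES = ("theta_v2s3", "theta_s3v", "theta_sym2")


@dataclass
class ModelCoefficients:
    """Intercept + weights on (theta_v2s3, theta_s3v, theta_sym2), plus
    the fixed rotation constant t of the lambda weighting."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    t_deg: float = 75.0

    def __post_init__(self):
        vals = (self.beta0, self.beta1, self.beta2, self.beta3)
        if not all(np.isfinite(vals)):
            raise ValueError("coefficients must be finite")
        if not (0.0 < self.t_deg < 90.0):
            raise ValueError("t must be in (0, 90) degrees")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])


@dataclass
class TrialEstimates:
    """The four per-trial slant estimates plus the angular size of the
    reference image and grouping metadata."""

    theta_v2s3: float
    theta_s3v: float
    theta_sym2: float
    theta_persp: float
    gamma_deg: float
    trial_id: int = -1
    object_type: str = ""
    projection: str = ""
    slant_true_deg: float = float("nan")


@dataclass
class ResponseRecord:
    estimates: TrialEstimates
    response_slant_deg: float
    subject: str = "sim"


def lambda_weight(gamma_deg: float, t_deg: float = 75.0) -> float:
    """Perspective reliability weight in [0, 1], monotone in gamma."""
    if not (0.0 <= gamma_deg < 180.0):
        raise ValueError("gamma must be in [0, 180) degrees")
    alpha = math.tan(math.radians(gamma_deg) / 2.0)
    phi = 2.0 * math.atan(alpha * math.tan(math.radians(t_deg)))
    return (1.0 - math.cos(phi)) / 2.0


def theta_lm(est: TrialEstimates, coef: ModelCoefficients) -> float:
    """Linear combination of the three constraint-based estimates."""
    return (
        coef.beta0
        + coef.beta1 * est.theta_v2s3
        + coef.beta2 * est.theta_s3v
        + coef.beta3 * est.theta_sym2
    )


def predict_slant(
    est: TrialEstimates, coef: ModelCoefficients, clamp: bool = True
) -> float:
    """lambda-weighted convex combination of the perspective estimate and
    the linear-model estimate, clamped to the adjustable range."""
    lam = lambda_weight(est.gamma_deg, coef.t_deg)
    theta = lam * est.theta_persp + (1.0 - lam) * theta_lm(est, coef)
    if clamp:
        theta = min(max(theta, RESPONSE_MIN_DEG), RESPONSE_MAX_DEG)
    return theta


def _design(records: list[ResponseRecord], t_deg: float):
    lam = np.array([lambda_weight(r.estimates.gamma_deg, t_deg) for r in records])
    thetas = np.array(
        [
            [r.estimates.theta_v2s3, r.estimates.theta_s3v, r.estimates.theta_sym2]
            for r in records
        ]
    )
    persp = np.array([r.estimates.theta_persp for r in records])
    resp = np.array([r.response_slant_deg for r in records])
    X = (1.0 - lam)[:, None] * np.column_stack([np.ones(len(records)), thetas])
    y = resp - lam * persp
    return X, y, lam, persp, resp


def fit_coefficients(
    records: list[ResponseRecord],
    t_deg: float = 75.0,
    refine_t: bool = False,
) -> tuple[ModelCoefficients, dict]:
    """Least-squares fit of beta0..beta3 minimizing the squared error
    between the full model prediction and the response slants (linear in
    beta once the lambda-weighted perspective term is absorbed).

    With ``refine_t`` the constant t is additionally optimized by a 1-D
    bounded search on the same objective.
    """
    if len(records) < 5:
        raise ValueError("need at least 5 records to fit 4 coefficients")

    def solve(t):
        X, y, lam, persp, resp = _design(records, t)
        if np.linalg.matrix_rank(X) < 4:
            bad = _collinear_columns(X)
            raise ValueError(
                f"rank-deficient design; collinear estimator columns: {bad}"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ beta + lam * persp
        sse = float(np.sum((pred - resp) ** 2))
        return beta, sse

    if refine_t:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda t: solve(t)[1], bounds=(1.0, 89.0), method="bounded"
        )
        t_deg = float(res.x)
    beta, sse = solve(t_deg)
    coef = ModelCoefficients(*beta, t_deg=t_deg)
    diag = {"n_trials": len(records), "rmse_deg": math.sqrt(sse / len(records))}
    return coef, diag


def _collinear_columns(X: np.ndarray) -> list[str]:
    names = ["intercept", *_THETA_NAMES]
    bad = []
    for k in range(X.shape[1]):
        others = np.delete(X, k, axis=1)
        proj, *_ = np.linalg.lstsq(others, X[:, k], rcond=None)
        resid = X[:, k] - others @ proj
        scale = np.linalg.norm(X[:, k])
        if scale == 0 or np.linalg.norm(resid) < 1e-9 * max(scale, 1.0):
            bad.append(names[k])
    return bad or names


def fit_by_group(
    records: list[ResponseRecord],
    keys: tuple[str, ...] = ("object_type",),
    t_deg: float = 75.0,
    refine_t: bool = False,
) -> dict[tuple, tuple[ModelCoefficients, dict]]:
    """Separate fits per group (e.g. per object type and/or subject)."""

    def group_of(r: ResponseRecord):
        out = []
        for k in keys:
            out.append(getattr(r, k) if hasattr(r, k) else getattr(r.estimates, k))
        return tuple(out)

    groups: dict[tuple, list[ResponseRecord]] = {}
    for r in records:
        groups.setdefault(group_of(r), []).append(r)
    return {
        g: fit_coefficients(rs, t_deg=t_deg, refine_t=refine_t)
        for g, rs in sorted(groups.items())
    }


def simulate_observer(
    trials: list[TrialEstimates],
    coef: ModelCoefficients,
    response_noise_deg: float = 0.0,
    seed: int | None = None,
    subject: str = "sim",
) -> list[ResponseRecord]:
    """Responses of a synthetic observer that follows the model exactly,
    plus clamped Gaussian response noise. Reproducible by seed."""
    rng = np.random.default_rng(seed)
    records = []
    for est in trials:
        resp = predict_slant(est, coef, clamp=False)
        if response_noise_deg > 0:
            resp += rng.normal(0.0, response_noise_deg)
        resp = min(max(resp, RESPONSE_MIN_DEG), RESPONSE_MAX_DEG)
        records.append(ResponseRecord(est, float(resp), subject))
    return records
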