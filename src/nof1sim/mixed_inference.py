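"""Maximum-likelihood inference for the random-intercept linear mixed model.

The working model for N-of-1 and crossover data is

    Y = X beta + b_i + eps,   b_i ~ Normal(0, sigma_mu^2),
                              eps ~ Normal(0, sigma_eps^2),

with one random intercept per patient.  Both ``beta`` and ``sigma_eps^2``
have closed-form profile maximizers given the variance ratio
``lambda = sigma_mu^2 / sigma_eps^2``, so the full ML fit reduces to a
bounded one-dimensional search over ``log lambda``.  This keeps a single fit
cheap enough for Monte-Carlo studies that need millions of fits.

Hypothesis testing follows the two-model deviance recipe: an intercept-only
model and an intercept-plus-treatment model are both fitted by ML (never
REML -- deviance differences for fixed effects are only valid under ML), and
the deviance difference is referred to a chi-squared distribution with one
degree of freedom.  Parallel-RCT data, with a single observation per
patient, are analyzed by ordinary least squares instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .trial_sim import TrialDataset

__all__ = [
    "FitResult",
    "TestOutcome",
    "FitError",
    "fit_random_intercept_ml",
    "lrt_treatment",
    "fit_ols",
    "profile_deviance",
]

_LAMBDA_BOUNDS = (1e-10, 1e10)
_LOG_LAMBDA_BOUNDS = (math.log(_LAMBDA_BOUNDS[0]), math.log(_LAMBDA_BOUNDS[1]))
_XATOL = 1e-9  # absolute tolerance on log(lambda) == relative tolerance on lambda
_VAR_FLOOR = 1e-24  # lower bound on the profiled error variance (degenerate data)


class FitError(RuntimeError):
    """Raised when a model fit fails (rank deficiency or non-convergence)."""


@dataclass
class FitResult:
    """One ML fit of the random-intercept model on one design's data."""

    fixed_effects: np.ndarray
    fixed_effect_names: tuple[str, ...]
    var_patient: float
    var_error: float
    deviance: float
    blups: dict[int, float]
    n_obs: int
    converged: bool

    @property
    def treatment_effect(self) -> float | None:
        if "treatment" in self.fixed_effect_names:
            return float(self.fixed_effects[self.fixed_effect_names.index("treatment")])
        return None

    def to_json(self) -> str:
        return json.dumps(
            {
                "fixed_effects": {
                    name: float(b)
                    for name, b in zip(self.fixed_effect_names, self.fixed_effects)
                },
                "var_patient": float(self.var_patient),
                "var_error": float(self.var_error),
                "deviance": round(float(self.deviance), 6),
                "blups": {int(k): float(v) for k, v in self.blups.items()},
                "n_obs": int(self.n_obs),
                "converged": bool(self.converged),
            }
        )


@dataclass
class TestOutcome:
    """Result of one hypothesis test of no treatment effect."""

    statistic: float
    p_value: float
    rejected: bool
    alpha: float = 0.05
    method: str = "lrt_chisq1"
    effect: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "statistic": float(self.statistic),
                "p_value": float(self.p_value),
                "rejected": bool(self.rejected),
                "alpha": float(self.alpha),
                "method": self.method,
                "effect": None if self.effect is None else float(self.effect),
            }
        )


# ---------------------------------------------------------------------------
# profiled likelihood machinery


class _SuffStats:
    """Per-dataset sufficient statistics for the profiled log-likelihood.

    With W_i = I - (lambda / (1 + lambda n_i)) J inside patient i, every
    quantity in the profiled deviance is a function of X'X, X'y, y'y and the
    per-patient column sums of X and y, so the grid of candidate lambdas is
    evaluated in O(G p^2) each, independent of the number of observations.
    Records must be grouped contiguously by patient (the simulators
    guarantee this).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, patient_id: np.ndarray):
        starts = np.flatnonzero(
            np.concatenate(([True], patient_id[1:] != patient_id[:-1]))
        )
        if len(np.unique(patient_id)) != len(starts):
            order = np.argsort(patient_id, kind="stable")
            X, y, patient_id = X[order], y[order], patient_id[order]
            starts = np.flatnonzero(
                np.concatenate(([True], patient_id[1:] != patient_id[:-1]))
            )
        self.group_ids = patient_id[starts]
        self.counts = np.diff(np.append(starts, len(y))).astype(np.float64)
        self.n_obs = len(y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.Sx = np.add.reduceat(X, starts, axis=0)
        self.Sy = np.add.reduceat(y, starts)
        self.SxtSx = self.Sx.T @ self.Sx
        self.SxtSy = self.Sx.T @ self.Sy
        self.SytSy = float(self.Sy @ self.Sy)
        self.balanced = bool(np.all(self.counts == self.counts[0]))

    def profile(self, lam: float):
        """Profiled (beta, sigma_eps^2, deviance) at a fixed variance ratio."""
        if self.balanced:
            c = lam / (1.0 + lam * self.counts[0])
            A = self.XtX - c * self.SxtSx
            b = self.Xty - c * self.SxtSy
            yWy = self.yty - c * self.SytSy
            logdet = len(self.counts) * math.log1p(lam * self.counts[0])
        else:
            c = lam / (1.0 + lam * self.counts)
            cSx = self.Sx * c[:, None]
            A = self.XtX - cSx.T @ self.Sx
            b = self.Xty - cSx.T @ self.Sy
            yWy = self.yty - float((c * self.Sy) @ self.Sy)
            logdet = float(np.log1p(lam * self.counts).sum())
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            raise FitError("rank-deficient design matrix in mixed-model fit") from None
        rss = yWy - float(b @ beta)
        sigma2 = max(rss / self.n_obs, _VAR_FLOOR)
        deviance = self.n_obs * (math.log(2.0 * math.pi * sigma2) + 1.0) + logdet
        return beta, sigma2, deviance

    def blups(self, lam: float, beta: np.ndarray) -> np.ndarray:
        """Empirical-Bayes random-intercept predictions E[b_i | y, theta]."""
        c = lam / (1.0 + lam * self.counts)
        return c * (self.Sy - self.Sx @ beta)


def _design_matrix(
    data: TrialDataset, include_treatment: bool, include_carryover_covariate: bool
):
    cols = [np.ones(data.n_records)]
    names = ["intercept"]
    if include_carryover_covariate:
        cols.append(data.prev_treated.astype(np.float64))
        names.append("prev_treated")
    if include_treatment:
        cols.append(data.treatment.astype(np.float64))
        names.append("treatment")
    return np.column_stack(cols), tuple(names)


def profile_deviance(
    data: TrialDataset,
    lam: float,
    include_treatment: bool = True,
    include_carryover_covariate: bool = False,
) -> float:
    """Profiled ML deviance at a fixed variance ratio ``lam = sigma_mu^2/sigma_eps^2``.

    At ``lam = 0`` this equals the -2 log-likelihood of the corresponding
    OLS fit with the ML variance estimate.
    """
    X, _ = _design_matrix(data, include_treatment, include_carryover_covariate)
    ss = _SuffStats(X, data.outcome, data.patient_id)
    return ss.profile(lam)[2]


def fit_random_intercept_ml(
    data: TrialDataset,
    include_treatment: bool = True,
    include_carryover_covariate: bool = False,
) -> FitResult:
    """Fit the random-intercept model by full maximum likelihood.

    Profiles the fixed effects and the error variance out analytically and
    minimizes the profiled deviance over ``log lambda`` on
    ``lambda in [1e-10, 1e10]`` (relative tolerance 1e-9).  Requires at
    least two observations per patient; single-observation-per-patient data
    (the parallel RCT) must be analyzed with :func:`fit_ols`.
    """
    X, names = _design_matrix(data, include_treatment, include_carryover_covariate)
    ss = _SuffStats(X, data.outcome, data.patient_id)
    if ss.counts.min() < 2:
        raise ValueError(
            "mixed-model fit needs >= 2 observations per patient; "
            "use fit_ols for single-observation (parallel RCT) data"
        )

    res = optimize.minimize_scalar(
        lambda t: ss.profile(math.exp(t))[2],
        bounds=_LOG_LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": _XATOL},
    )
    lam = float(math.exp(res.x))
    # the bounded search cannot place an iterate exactly on the boundary;
    # prefer the boundary when it is at least as good (variance component 0)
    beta, sigma2, deviance = ss.profile(lam)
    b0, s0, d0 = ss.profile(_LAMBDA_BOUNDS[0])
    if d0 <= deviance:
        lam, beta, sigma2, deviance = _LAMBDA_BOUNDS[0], b0, s0, d0
    blup_values = ss.blups(lam, beta)
    return FitResult(
        fixed_effects=beta,
        fixed_effect_names=names,
        var_patient=lam * sigma2,
        var_error=sigma2,
        deviance=deviance,
        blups=dict(zip(ss.group_ids.tolist(), blup_values.tolist())),
        n_obs=ss.n_obs,
        converged=bool(res.success) and math.isfinite(deviance),
    )


def lrt_treatment(
    data: TrialDataset, adjust_carryover: bool = False, alpha: float = 0.05
) -> TestOutcome:
    """Deviance likelihood-ratio test of no treatment effect (1 df).

    Fits the intercept-only and intercept-plus-treatment random-intercept
    models by ML and refers their deviance difference to chi-squared(1).
    With ``adjust_carryover`` both models additionally include the
    previous-period-treated fixed effect, so the test keeps one degree of
    freedom.  Raises :class:`FitError` if either fit fails to converge.
    """
    null_fit = fit_random_intercept_ml(
        data, include_treatment=False, include_carryover_covariate=adjust_carryover
    )
    alt_fit = fit_random_intercept_ml(
        data, include_treatment=True, include_carryover_covariate=adjust_carryover
    )
    if not (null_fit.converged and alt_fit.converged):
        raise FitError("mixed-model fit did not converge")
    statistic = max(null_fit.deviance - alt_fit.deviance, 0.0)
    p_value = float(stats.chi2.sf(statistic, df=1))
    return TestOutcome(
        statistic=statistic,
        p_value=p_value,
        rejected=p_value < alpha,
        alpha=alpha,
        method="lrt_chisq1",
        effect=alt_fit.treatment_effect,
    )


def fit_ols(data: TrialDataset, alpha: float = 0.05) -> TestOutcome:
    """Two-sided OLS Wald test of the treatment effect for parallel-RCT data.

    Ordinary least squares of outcome on intercept + treatment with a binary
    regressor; the Wald t-test of the treatment coefficient (N - 2 df) is
    computed in closed form.
    """
    y = data.outcome
    z = data.treatment.astype(bool)
    n1, n0 = int(z.sum()), int((~z).sum())
    if n0 == 0 or n1 == 0:
        # counted as an analysis failure (and an excluded replicate) upstream
        raise FitError(f"both arms must be populated (placebo={n0}, treatment={n1})")
    effect = float(y[z].mean() - y[~z].mean())
    rss = float(((y[z] - y[z].mean()) ** 2).sum() + ((y[~z] - y[~z].mean()) ** 2).sum())
    dof = n0 + n1 - 2
    if dof <= 0:
        raise ValueError("need at least 3 patients for the OLS test")
    s2 = rss / dof
    se = math.sqrt(s2 * (1.0 / n0 + 1.0 / n1)) if s2 > 0 else 0.0
    if se == 0.0:
        tstat = 0.0 if effect == 0.0 else math.inf
    else:
        tstat = effect / se
    p_value = float(2.0 * stats.t.sf(abs(tstat), df=dof))
    return TestOutcome(
        statistic=abs(tstat),
        p_value=p_value,
        rejected=p_value < alpha,
        alpha=alpha,
        method="ols_wald",
        effect=effect,
    )
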