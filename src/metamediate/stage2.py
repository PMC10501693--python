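"""Stage 2: WLS fit of the mediation path model to pooled correlations.

The three-variable mediation model has paths a (exposure -> mediator),
b (mediator -> outcome) and c' (direct exposure -> outcome).  Its implied
correlation triple is (a, c' + a*b, b + a*c').  The model is fitted by
minimizing the weighted least squares discrepancy

    F(theta) = (r_hat - rho(theta))' acov^{-1} (r_hat - rho(theta))

with the Stage-1 asymptotic covariance as weight matrix; F_min is on the
chi-square scale.  Unconstrained, the model is saturated (df = 0) and
reproduces the pooled triple exactly; the closed-form inversion is used
as the starting point, so that case converges immediately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._linalg import is_positive_definite, triple_to_matrix
from .stage1 import PooledCorrelations

__all__ = [
    "MediationFit",
    "IndirectEstimate",
    "closed_form_saturated",
    "implied_triple",
    "fit_wls",
    "indirect_effect",
]

PATH_NAMES = ("a", "b", "c_prime")
_Z95 = stats.norm.ppf(0.975)


@dataclass
class MediationFit:
    """Fitted mediation paths with SEs, CIs and the WLS discrepancy."""

    paths: np.ndarray  # (3,): a, b, c_prime
    se: np.ndarray  # (3,)
    ci: np.ndarray  # (3, 2) 95% Wald intervals
    cov: np.ndarray  # (3, 3) covariance of the path estimates
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    discrepancy: float  # F_min on the chi-square scale
    df: int
    converged: bool = True

    @property
    def a(self) -> float:
        return float(self.paths[0])

    @property
    def b(self) -> float:
        return float(self.paths[1])

    @property
    def c_prime(self) -> float:
        return float(self.paths[2])


@dataclass
class IndirectEstimate:
    estimate: float
    ci: tuple[float, float]
    method: str
    se: float | None = None

    @property
    def significant(self) -> bool:
        lo, hi = self.ci
        return lo > 0 or hi < 0


def implied_triple(paths) -> np.ndarray:
    """Model-implied (r_XM, r_XY, r_MY) = (a, c' + a*b, b + a*c')."""
    a, b, c = np.asarray(paths, dtype=float)
    return np.array([a, c + a * b, b + a * c])


def _jacobian(paths) -> np.ndarray:
    """d implied_triple / d (a, b, c')."""
    a, b, c = paths
    return np.array([[1.0, 0.0, 0.0], [b, a, 1.0], [c, 1.0, a]])


def closed_form_saturated(rho) -> np.ndarray:
    """Algebraic inversion of the saturated mediation model.

    a = r_XM; b and c' are the regression coefficients of the outcome on
    mediator and exposure: b = (r_MY - r_XM r_XY) / (1 - r_XM^2),
    c' = (r_XY - r_XM r_MY) / (1 - r_XM^2).
    """
    r_xm, r_xy, r_my = np.asarray(rho, dtype=float)
    den = 1.0 - r_xm**2
    if den <= 1e-12:
        raise ValueError("degenerate mediator: |r_XM| = 1")
    return np.array(
        [r_xm, (r_my - r_xm * r_xy) / den, (r_xy - r_xm * r_my) / den]
    )


def _delta_indirect(paths, cov) -> tuple[float, float, tuple[float, float]]:
    a, b = paths[0], paths[1]
    ab = a * b
    var = b**2 * cov[0, 0] + a**2 * cov[1, 1] + 2 * a * b * cov[0, 1]
    se = float(np.sqrt(max(var, 0.0)))
    return float(ab), se, (float(ab - _Z95 * se), float(ab + _Z95 * se))


def fit_wls(
    pooled: PooledCorrelations, constraints: dict[str, float] | None = None
) -> MediationFit:
    """Weighted least squares fit of the mediation model.

    ``constraints`` optionally fixes named paths ("a", "b", "c_prime")
    at given values; each fixed path adds one model degree of freedom.
    SEs come from the inverse Hessian of F/2 at the optimum (J' W J over
    the free parameters); the indirect effect a*b carries a delta-method
    95% CI.
    """
    rho = np.asarray(pooled.rho, dtype=float)
    if not is_positive_definite(triple_to_matrix(rho)):
        raise ValueError("pooled correlation triple is not PD; rerun Stage 1")
    try:
        W = np.linalg.inv(pooled.acov)
        np.linalg.cholesky(W)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "Stage-1 asymptotic covariance is not PD; rerun Stage 1"
        ) from exc

    constraints = dict(constraints or {})
    unknown = set(constraints) - set(PATH_NAMES)
    if unknown:
        raise ValueError(f"unknown path name(s) in constraints: {sorted(unknown)}")
    free = np.array([p not in constraints for p in PATH_NAMES])
    n_fixed = int((~free).sum())

    start = closed_form_saturated(rho)
    for k, p in enumerate(PATH_NAMES):
        if p in constraints:
            start[k] = constraints[p]

    def full(theta_free):
        th = start.copy()
        th[free] = theta_free
        return th

    def objective(theta_free):
        th = full(theta_free)
        res = rho - implied_triple(th)
        return float(res @ W @ res)

    def gradient(theta_free):
        th = full(theta_free)
        res = rho - implied_triple(th)
        return (-2.0 * _jacobian(th).T @ W @ res)[free]

    if free.any():
        opt = optimize.minimize(
            objective, start[free], jac=gradient, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 500},
        )
        if not opt.success and np.max(np.abs(gradient(opt.x))) > 1e-6:
            warnings.warn(
                f"WLS fit did not fully converge (best F = {opt.fun:.3e})",
                stacklevel=2,
            )
        theta = full(opt.x)
        fmin = float(opt.fun)
        converged = bool(opt.success or np.max(np.abs(gradient(opt.x))) <= 1e-6)
    else:
        theta = start
        fmin = objective(np.empty(0))
        converged = True

    J = _jacobian(theta)
    cov = np.zeros((3, 3))
    se = np.zeros(3)
    if free.any():
        Jf = J[:, free]
        cov_free = np.linalg.inv(Jf.T @ W @ Jf)
        cov[np.ix_(free, free)] = cov_free
        se[free] = np.sqrt(np.diag(cov_free))
    ci = np.column_stack([theta - _Z95 * se, theta + _Z95 * se])
    ind, ind_se, ind_ci = _delta_indirect(theta, cov)
    return MediationFit(
        paths=theta, se=se, ci=ci, cov=cov,
        indirect=ind, indirect_se=ind_se, indirect_ci=ind_ci,
        discrepancy=max(fmin, 0.0), df=n_fixed, converged=converged,
    )


def _profile_ci(fit: MediationFit, pooled: PooledCorrelations) -> tuple[float, float]:
    """Likelihood-style CI from the WLS discrepancy profile over a*b."""
    W = np.linalg.inv(pooled.acov)
    rho = pooled.rho
    crit = stats.chi2.ppf(0.95, 1)

    def profile_F(ind_value):
        def obj(th):
            res = rho - implied_triple(th)
            return float(res @ W @ res)

        cons = {"type": "eq", "fun": lambda th: th[0] * th[1] - ind_value}
        start = fit.paths.copy()
        # move the start onto the constraint surface
        if abs(start[0]) > 1e-6:
            start[1] = ind_value / start[0]
        else:
            start[0] = np.sign(start[0]) * 0.05 or 0.05
            start[1] = ind_value / start[0]
        opt = optimize.minimize(
            obj, start, method="SLSQP", constraints=[cons],
            options={"maxiter": 300, "ftol": 1e-14},
        )
        return float(opt.fun)

    f0 = fit.discrepancy
    target = f0 + crit

    def root_fn(v):
        return profile_F(v) - target

    ind = fit.indirect
    step = max(4 * fit.indirect_se, 0.01)
    lo_bracket = ind - step
    while root_fn(lo_bracket) < 0:
        lo_bracket -= step
    hi_bracket = ind + step
    while root_fn(hi_bracket) < 0:
        hi_bracket += step
    lo = optimize.brentq(root_fn, lo_bracket, ind, xtol=1e-8)
    hi = optimize.brentq(root_fn, ind, hi_bracket, xtol=1e-8)
    return float(lo), float(hi)


def indirect_effect(
    fit: MediationFit,
    pooled: PooledCorrelations,
    method: str = "delta",
    n_boot: int = 2000,
    seed: int | None = None,
) -> IndirectEstimate:
    """Indirect effect a*b with a 95% confidence interval.

    ``method`` is one of:

    - ``delta``: Var(ab) = b^2 Var(a) + a^2 Var(b) + 2ab Cov(a, b).
    - ``profile``: invert the WLS discrepancy profile over a*b at the
      chi-square(1) 95% critical value.
    - ``bootstrap``: parametric resampling of the pooled triple from
      N(rho_hat, acov), closed-form refit, percentile interval.
    """
    if method == "delta":
        est, se, ci = _delta_indirect(fit.paths, fit.cov)
        return IndirectEstimate(estimate=est, ci=ci, method="delta", se=se)
    if method == "profile":
        return IndirectEstimate(
            estimate=fit.indirect, ci=_profile_ci(fit, pooled), method="profile"
        )
    if method == "bootstrap":
        if n_boot < 200:
            warnings.warn(
                f"bootstrap with {n_boot} < 200 replicates is unreliable",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        filled = 0
        while filled < n_boot:
            batch = rng.multivariate_normal(pooled.rho, pooled.acov,
                                            size=2 * (n_boot - filled))
            for r_star in batch:
                if np.any(np.abs(r_star) >= 1) or not is_positive_definite(
                    triple_to_matrix(r_star)
                ):
                    continue
                th = closed_form_saturated(r_star)
                draws[filled] = th[0] * th[1]
                filled += 1
                if filled == n_boot:
                    break
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return IndirectEstimate(
            estimate=fit.indirect, ci=(float(lo), float(hi)), method="bootstrap"
        )
    raise ValueError(f"unknown CI method {method!r}")
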