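"""Stage 1: random-effects multivariate meta-analysis of correlation triples.

Each study contributes the correlation elements it observed; the marginal
normal likelihood over those elements (full-information ML for
missing-by-design reporting) is maximized jointly in the pooled triple
``rho`` and the element-wise between-study variances ``tau^2``.  Within-
study sampling covariances follow the normal-theory (Olkin-Siegel)
fourth-moment formulas evaluated at a fixed-effects reference triple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from ._linalg import (
    PAIR_NAMES,
    PAIR_POSITIONS,
    is_positive_definite,
    nearest_correlation_triple,
    triple_to_matrix,
)
from .effects import CorrelationSet

__all__ = [
    "SamplingCov",
    "PooledCorrelations",
    "sampling_covariance",
    "fixed_effects_pool",
    "fit_random_effects",
    "heterogeneity_stats",
    "pool",
    "ConvergenceError",
]

_GRAD_TOL = 1e-6


class ConvergenceError(RuntimeError):
    """The likelihood optimizer failed after all restarts."""


@dataclass
class SamplingCov:
    """Normal-theory covariance of one study's observed sample correlations."""

    study_id: str
    V: np.ndarray  # (d, d) over the observed elements
    indices: np.ndarray  # which of (XM, XY, MY) the rows refer to


@dataclass
class PooledCorrelations:
    """Stage-1 output: pooled triple, its covariance and heterogeneity."""

    rho: np.ndarray  # (3,) pooled (rho_XM, rho_XY, rho_MY)
    acov: np.ndarray  # (3, 3) asymptotic covariance of rho
    tau2: np.ndarray  # (3,) between-study variances
    fe_rho: np.ndarray  # fixed-effects reference triple (tau^2 = 0)
    n_studies: int = 0
    n_total: int = 0
    n_observed: int = 0  # total observed elements across studies
    Q: float | None = None
    df: int | None = None
    p_Q: float | None = None
    i2: np.ndarray | None = None  # per-element I^2
    i2_mean: float | None = None
    projected: bool = False  # pooled triple needed a PSD repair
    loglik: float | None = None
    tau2_fixed_zero: np.ndarray = field(
        default_factory=lambda: np.zeros(3, dtype=bool)
    )


def _corr_cov_element(R: np.ndarray, pos_ij, pos_kl) -> float:
    """Asymptotic n*Cov(r_ij, r_kl) under multivariate normality."""
    i, j = pos_ij
    k, l = pos_kl
    term = 0.5 * R[i, j] * R[k, l] * (
        R[i, k] ** 2 + R[i, l] ** 2 + R[j, k] ** 2 + R[j, l] ** 2
    )
    term += R[i, k] * R[j, l] + R[i, l] * R[j, k]
    term -= (
        R[i, j] * R[i, k] * R[i, l]
        + R[i, j] * R[j, k] * R[j, l]
        + R[i, k] * R[j, k] * R[k, l]
        + R[i, l] * R[j, l] * R[k, l]
    )
    return term


def correlation_acov(reference, n: int, indices=None) -> np.ndarray:
    """Normal-theory covariance matrix of sample correlations.

    ``reference`` is a complete triple (r_XM, r_XY, r_MY); ``indices``
    restricts to a subset of elements.  Var(r_ij) = (1 - rho_ij^2)^2 / n.
    """
    R = triple_to_matrix(reference)
    if indices is None:
        indices = np.arange(3)
    indices = np.asarray(indices, dtype=int)
    d = indices.size
    V = np.empty((d, d))
    for a, ia in enumerate(indices):
        for b, ib in enumerate(indices):
            V[a, b] = _corr_cov_element(R, PAIR_POSITIONS[ia], PAIR_POSITIONS[ib])
    return V / n


def sampling_covariance(cset: CorrelationSet, reference) -> SamplingCov:
    """Within-study sampling covariance of a study's observed correlations.

    Evaluated at a complete, admissible ``reference`` triple (by default
    the fixed-effects pooled estimate — see :func:`fixed_effects_pool`),
    restricted to the study's observed elements.
    """
    reference = np.asarray(reference, dtype=float)
    if not is_positive_definite(triple_to_matrix(reference)):
        raise ValueError(f"reference triple {reference.tolist()} is not PD")
    if cset.n < 4:
        raise ValueError(f"study {cset.study_id}: n={cset.n} < 4")
    idx = cset.observed_indices
    V = correlation_acov(reference, cset.n, idx)
    return SamplingCov(study_id=cset.study_id, V=V, indices=idx)


def _check_coverage(sets: list[CorrelationSet]) -> None:
    counts = np.zeros(3, dtype=int)
    for s in sets:
        counts += s.mask
    missing = [PAIR_NAMES[k] for k in range(3) if counts[k] == 0]
    if missing:
        raise ValueError(f"element(s) {missing} observed in no study")


def _naive_reference(sets: list[CorrelationSet]) -> np.ndarray:
    """n-weighted element-wise mean of observed correlations (PSD-repaired)."""
    num = np.zeros(3)
    den = np.zeros(3)
    for s in sets:
        idx = s.observed_indices
        num[idx] += s.n * s.r[idx]
        den[idx] += s.n
    ref = num / den
    ref, _ = nearest_correlation_triple(ref, max_element_change=None)
    return np.clip(ref, -0.999, 0.999)


def fixed_effects_pool(
    sets: list[CorrelationSet], Vs: list[SamplingCov]
) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed-effects (tau^2 = 0) pooled triple and its covariance."""
    A = np.zeros((3, 3))
    bvec = np.zeros(3)
    for s, sv in zip(sets, Vs):
        idx = sv.indices
        Winv = np.linalg.inv(sv.V)
        A[np.ix_(idx, idx)] += Winv
        bvec[idx] += Winv @ s.r[idx]
    acov = np.linalg.inv(A)
    return acov @ bvec, acov


def _study_covariances(
    sets: list[CorrelationSet],
) -> tuple[list[SamplingCov], np.ndarray, np.ndarray]:
    """Two-pass construction of within-study covariances.

    Pass 0 evaluates the Olkin-Siegel formulas at an n-weighted element
    mean; the resulting GLS fixed-effects pool is the reference at which
    the final covariances (used for FIML, Q, and I^2) are evaluated.
    """
    ref0 = _naive_reference(sets)
    Vs0 = [sampling_covariance(s, ref0) for s in sets]
    fe_rho, _ = fixed_effects_pool(sets, Vs0)
    fe_rho, _ = nearest_correlation_triple(
        np.clip(fe_rho, -0.999, 0.999), max_element_change=None
    )
    Vs = [sampling_covariance(s, fe_rho) for s in sets]
    fe_rho2, fe_acov = fixed_effects_pool(sets, Vs)
    return Vs, fe_rho, fe_acov


def _pattern_groups(sets, Vs):
    """Group studies by observation pattern for batched likelihood evaluation."""
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(sets):
        groups.setdefault(tuple(s.observed_indices.tolist()), []).append(i)
    out = []
    for idx, members in groups.items():
        idx_arr = np.array(idx, dtype=int)
        r_stack = np.stack([sets[i].r[idx_arr] for i in members])
        V_stack = np.stack([Vs[i].V for i in members])
        out.append((idx_arr, r_stack, V_stack))
    return out


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


def _nll(params, patterns, tau_free):
    """Negative marginal log-likelihood (constants dropped)."""
    rho = np.tanh(params[:3])
    tau2 = np.where(tau_free, _softplus(params[3:]), 0.0)
    total = 0.0
    d_range = {}
    for idx, r_stack, V_stack in patterns:
        d = idx.size
        Sig = V_stack.copy()
        rng = d_range.setdefault(d, np.arange(d))
        Sig[:, rng, rng] += tau2[idx]
        try:
            L = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
        res = r_stack - rho[idx]
        sol = np.linalg.solve(Sig, res[..., None])[..., 0]
        total += 0.5 * (logdet + (res * sol).sum())
    return total


def fit_random_effects(
    sets: list[CorrelationSet], fix_tau2_zero: bool = False
) -> PooledCorrelations:
    """FIML random-effects pooling of incomplete correlation triples.

    Maximizes sum_i -1/2 [log|Sigma_i| + (r_i - mu_i)' Sigma_i^-1
    (r_i - mu_i)] over the pooled triple and diagonal tau^2, where
    Sigma_i = V_i + diag(tau^2) restricted to the study's observed
    elements.  The asymptotic covariance of the pooled triple is the
    inverse of its observed information, sum_i P_i' Sigma_i^-1 P_i.
    """
    if len(sets) < 1:
        raise ValueError("no studies to pool")
    _check_coverage(sets)
    Vs, fe_rho, fe_acov = _study_covariances(sets)
    patterns = _pattern_groups(sets, Vs)

    counts = np.zeros(3, dtype=int)
    for s in sets:
        counts += s.mask
    tau_free = counts >= 2
    if fix_tau2_zero or len(sets) == 1:
        tau_free = np.zeros(3, dtype=bool)
    elif not tau_free.all():
        singles = [PAIR_NAMES[k] for k in range(3) if not tau_free[k]]
        warnings.warn(
            f"element(s) {singles} observed in < 2 studies: tau^2 fixed at 0",
            stacklevel=2,
        )

    x0 = np.concatenate([np.arctanh(np.clip(fe_rho, -0.99, 0.99)),
                         _softplus_inv(np.full(3, 0.005))])
    bounds = [(-5.0, 5.0)] * 3 + [(-25.0, 5.0)] * 3

    best = None
    rng = np.random.default_rng(12345)  # deterministic restart jitter
    for attempt in range(6):
        start = x0 if attempt == 0 else x0 + rng.normal(0, 0.3, size=6)
        res = optimize.minimize(
            _nll,
            start,
            args=(patterns, tau_free),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": _GRAD_TOL},
        )
        if res.success and np.isfinite(res.fun) and (
            best is None or not best.success or res.fun < best.fun
        ):
            best = res
            break
        if best is None or (not best.success and res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun) or not best.success:
        grad_norm = float(np.max(np.abs(best.jac))) if best is not None else np.nan
        raise ConvergenceError(
            f"random-effects pooling failed after restarts "
            f"(gradient infinity-norm {grad_norm:.3e})"
        )

    rho = np.tanh(best.x[:3])
    tau2 = np.where(tau_free, _softplus(best.x[3:]), 0.0)
    # softplus floor: snap numerically-zero variances to exact zero
    tau2[tau2 < 1e-10] = 0.0

    projected = False
    if not is_positive_definite(triple_to_matrix(rho)):
        rho, projected = nearest_correlation_triple(rho, max_element_change=None)
        warnings.warn(
            "pooled triple was not positive definite; projected to the "
            "nearest correlation matrix",
            stacklevel=2,
        )

    # observed information for the mean parameters at the estimates
    A = np.zeros((3, 3))
    for s, sv in zip(sets, Vs):
        idx = sv.indices
        Sig = sv.V + np.diag(tau2[idx])
        A[np.ix_(idx, idx)] += np.linalg.inv(Sig)
    acov = np.linalg.inv(A)

    return PooledCorrelations(
        rho=rho,
        acov=acov,
        tau2=tau2,
        fe_rho=fe_rho,
        n_studies=len(sets),
        n_total=int(sum(s.n for s in sets)),
        n_observed=int(counts.sum()),
        projected=projected,
        loglik=-float(best.fun),
        tau2_fixed_zero=~tau_free,
    )


def heterogeneity_stats(
    sets: list[CorrelationSet], pooled: PooledCorrelations
) -> PooledCorrelations:
    """Complete a Stage-1 result with Q, I^2 and their bookkeeping.

    Q is the fixed-effects weighted sum of squared deviations from the
    GLS pooled triple over all observed elements, referred to chi^2 with
    df = (observed elements) - 3.  Per-element I^2 uses the
    Higgins-Thompson typical within-study variance
    v~ = (k-1) * sum(w) / ((sum w)^2 - sum(w^2)), w = 1/Var(r_i).
    """
    Vs, fe_rho, _ = _study_covariances(sets)
    n_obs = sum(int(s.mask.sum()) for s in sets)
    df = n_obs - 3
    if df <= 0:
        raise ValueError(f"too few observed elements for heterogeneity (df={df})")
    Q = 0.0
    for s, sv in zip(sets, Vs):
        idx = sv.indices
        resid = s.r[idx] - fe_rho[idx]
        Q += float(resid @ np.linalg.solve(sv.V, resid))
    p_Q = float(stats.chi2.sf(Q, df))

    i2 = np.zeros(3)
    for k in range(3):
        w = np.array(
            [1.0 / sv.V[list(sv.indices).index(k), list(sv.indices).index(k)]
             for sv in Vs if k in sv.indices]
        )
        if w.size >= 2:
            v_typ = (w.size - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
            i2[k] = pooled.tau2[k] / (pooled.tau2[k] + v_typ)
        else:
            i2[k] = 0.0
    i2 = np.clip(i2, 0.0, 1.0)
    return replace(
        pooled, Q=Q, df=df, p_Q=p_Q, i2=i2, i2_mean=float(i2.mean())
    )


def pool(sets: list[CorrelationSet], fix_tau2_zero: bool = False) -> PooledCorrelations:
    """Full Stage 1: random-effects pooling plus heterogeneity statistics."""
    pooled = fit_random_effects(sets, fix_tau2_zero=fix_tau2_zero)
    try:
        return heterogeneity_stats(sets, pooled)
    except ValueError:
        return pooled  # too few elements for Q; pooled estimates still valid
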