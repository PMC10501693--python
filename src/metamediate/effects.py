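"""Effect-size ingestion.

Converts the heterogeneous effect sizes studies report (correlations,
standardized regression betas, path-model coefficients) into one
correlation set per study over the three relations of the mediation
system: exposure-mediator (XM), exposure-outcome (XY) and
mediator-outcome (MY).  Multiple within-study effects for the same
relation are aggregated into a composite in Fisher-z space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._linalg import (
    PAIR_INDEX,
    PAIR_NAMES,
    InadmissibleMatrixError,
    is_positive_definite,
    matrix_to_triple,
    nearest_correlation_triple,
)

__all__ = [
    "EffectEntry",
    "StudyRecord",
    "CorrelationSet",
    "beta_to_r",
    "path_model_implied_correlations",
    "fisher_z_aggregate",
    "build_correlation_sets",
    "EffectConversionError",
]

#: |beta| above which the beta-to-r conversion is outside its documented
#: validity range and a warning is emitted.
BETA_CONVERSION_SAFE_RANGE = 0.5

_CLAMP = 0.999

DESIGNS = ("cross_sectional", "longitudinal")
REGIONS = ("western", "non_western")
EFFECT_TYPES = ("correlation", "std_beta", "path_model")


class EffectConversionError(ValueError):
    """An effect size cannot be converted to a correlation."""


@dataclass
class EffectEntry:
    """One reported effect from one study.

    ``pair`` names the relation it informs ("XM", "XY" or "MY"); a
    ``path_model`` entry carries a full coefficient set and informs all
    three relations, so its ``pair`` is ignored.
    """

    study_id: str
    pair: str
    effect_type: str
    value: float | None = None
    path_payload: dict | np.ndarray | None = None

    def __post_init__(self):
        if self.effect_type not in EFFECT_TYPES:
            raise ValueError(f"unknown effect_type {self.effect_type!r}")
        if self.effect_type != "path_model":
            if self.pair not in PAIR_NAMES:
                raise ValueError(f"unknown pair {self.pair!r}")
            if self.value is None:
                raise ValueError("correlation/std_beta entry requires a value")
            if self.effect_type == "correlation" and not -1 < self.value < 1:
                raise EffectConversionError(
                    f"study {self.study_id}: correlation {self.value} outside (-1, 1)"
                )
        elif self.path_payload is None:
            raise ValueError("path_model entry requires path_payload")


@dataclass
class StudyRecord:
    """A study: sample size, subgroup labels, sensitivity flags, effects."""

    study_id: str
    n: int
    design: str = "cross_sectional"
    region: str = "western"
    flag_nightmare_overlap: bool = False
    flag_under5: bool = False
    entries: list[EffectEntry] = field(default_factory=list)

    def __post_init__(self):
        if self.n < 4:
            raise ValueError(
                f"study {self.study_id}: n={self.n} < 4 (correlation sampling "
                "variance undefined)"
            )
        if self.design not in DESIGNS:
            raise ValueError(f"study {self.study_id}: unknown design {self.design!r}")
        if self.region not in REGIONS:
            raise ValueError(f"study {self.study_id}: unknown region {self.region!r}")


@dataclass
class CorrelationSet:
    """One study's observed correlation triple with availability mask."""

    study_id: str
    r: np.ndarray  # shape (3,), NaN where unobserved
    mask: np.ndarray  # shape (3,), bool
    n: int

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"study {self.study_id}: no observed elements")
        if not np.array_equal(self.mask, ~np.isnan(self.r)):
            raise ValueError(
                f"study {self.study_id}: mask inconsistent with missing values"
            )
        obs = self.r[self.mask]
        if np.any(np.abs(obs) >= 1):
            raise ValueError(f"study {self.study_id}: correlation outside (-1, 1)")

    @property
    def observed_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def observed_values(self) -> np.ndarray:
        return self.r[self.mask]


def beta_to_r(beta: float, study_id: str | None = None) -> float:
    """Convert a standardized regression coefficient to a correlation.

    Uses the empirical imputation r = 0.98*beta + 0.05*lambda with
    lambda = 1 when beta is non-negative, clamped to (-0.999, 0.999).
    Values of |beta| beyond 0.5 are outside the regime the conversion was
    calibrated on and trigger a warning (but still convert).
    """
    if abs(beta) >= 1:
        who = f" in study {study_id}" if study_id else ""
        raise EffectConversionError(f"invalid std_beta {beta}{who}: |beta| >= 1")
    if abs(beta) > BETA_CONVERSION_SAFE_RANGE:
        warnings.warn(
            f"beta={beta} outside the documented validity range "
            f"(|beta| <= {BETA_CONVERSION_SAFE_RANGE}) of the beta-to-r conversion",
            stacklevel=2,
        )
    lam = 1.0 if beta >= 0 else 0.0
    return float(np.clip(0.98 * beta + 0.05 * lam, -_CLAMP, _CLAMP))


def _payload_to_B(path_payload) -> np.ndarray:
    """Coefficient matrix B (rows = dependent variables) in (X, M, Y) order."""
    if isinstance(path_payload, dict):
        missing = {"a", "b", "c_prime"} - set(path_payload)
        if missing:
            raise ValueError(f"path_payload missing coefficients: {sorted(missing)}")
        B = np.zeros((3, 3))
        B[1, 0] = path_payload["a"]
        B[2, 0] = path_payload["c_prime"]
        B[2, 1] = path_payload["b"]
        return B
    B = np.asarray(path_payload, dtype=float)
    if B.shape != (3, 3):
        raise ValueError("path_payload matrix must be 3x3 in (X, M, Y) order")
    return B


def path_model_implied_correlations(path_payload) -> np.ndarray:
    """Model-implied correlation triple of a recursive standardized path model.

    With coefficient matrix B (strictly lower triangular in causal order)
    and diagonal residual variances Psi chosen so that all variances are 1,
    the implied covariance is Sigma = (I-B)^-1 Psi (I-B)^-T.  For the
    mediation model {a: X->M, b: M->Y, c_prime: X->Y} this reduces to
    (r_XM, r_XY, r_MY) = (a, c' + a*b, b + a*c').

    ``path_payload`` is either a dict with keys ``a``, ``b``, ``c_prime``
    or a full 3x3 coefficient matrix in (X, M, Y) order.
    """
    B = _payload_to_B(path_payload)
    if np.any(np.triu(B) != 0):
        raise EffectConversionError(
            "non-recursive path model: coefficient matrix must be strictly "
            "lower triangular in (X, M, Y) causal order"
        )
    A = np.linalg.inv(np.eye(3) - B)  # lower triangular, unit diagonal
    psi = np.empty(3)
    for i in range(3):
        psi[i] = 1.0 - sum(A[i, k] ** 2 * psi[k] for k in range(i))
        if psi[i] <= 0:
            raise InadmissibleMatrixError(
                f"inadmissible paths: residual variance of variable {i} is "
                f"{psi[i]:.4f} <= 0"
            )
    Sigma = A @ np.diag(psi) @ A.T
    r = matrix_to_triple(Sigma)
    if np.any(np.abs(r) >= 1) or not is_positive_definite(Sigma):
        raise InadmissibleMatrixError(
            f"inadmissible paths: implied correlations {r.tolist()}"
        )
    return r


def fisher_z_aggregate(values) -> float:
    """Composite of several correlations: back-transformed mean Fisher z.

    Unweighted across within-study effects for the same relation.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("nothing to aggregate: empty list of correlations")
    if np.any(np.abs(values) >= 1):
        raise ValueError("correlations must lie strictly within (-1, 1)")
    return float(np.tanh(np.mean(np.arctanh(values))))


def _convert_entry(entry: EffectEntry, provenance: list[str]) -> list[tuple[int, float]]:
    """Convert one entry to (pair index, correlation) contributions."""
    sid = entry.study_id
    if entry.effect_type == "correlation":
        return [(PAIR_INDEX[entry.pair], float(entry.value))]
    if entry.effect_type == "std_beta":
        r = beta_to_r(entry.value, study_id=sid)
        provenance.append(
            f"{sid}: converted std_beta {entry.value:+.4f} -> r {r:+.4f} ({entry.pair})"
        )
        return [(PAIR_INDEX[entry.pair], r)]
    # path_model: informs all three relations
    r = path_model_implied_correlations(entry.path_payload)
    provenance.append(
        f"{sid}: path model -> implied triple "
        f"({r[0]:+.4f}, {r[1]:+.4f}, {r[2]:+.4f})"
    )
    return list(enumerate(r.tolist()))


def build_correlation_sets(
    records: list[StudyRecord], provenance: list[str] | None = None
) -> list[CorrelationSet]:
    """Convert and aggregate each study's entries into one CorrelationSet.

    Every conversion, composite aggregation, PSD repair and dropped study
    is appended to ``provenance`` (a plain list of strings) when given.
    Studies with zero usable relations are dropped with a warning, never
    silently.
    """
    log = provenance if provenance is not None else []
    sets: list[CorrelationSet] = []
    for rec in records:
        per_pair: dict[int, list[float]] = {}
        for entry in rec.entries:
            if entry.study_id != rec.study_id:
                raise ValueError(
                    f"entry study_id {entry.study_id!r} does not match record "
                    f"{rec.study_id!r}"
                )
            try:
                contribs = _convert_entry(entry, log)
            except (EffectConversionError, InadmissibleMatrixError) as exc:
                log.append(f"{rec.study_id}: entry skipped ({exc})")
                warnings.warn(f"study {rec.study_id}: entry skipped ({exc})", stacklevel=2)
                continue
            for k, val in contribs:
                per_pair.setdefault(k, []).append(val)
        if not per_pair:
            log.append(f"{rec.study_id}: dropped (no usable effects)")
            warnings.warn(
                f"study {rec.study_id} dropped: no usable effects", stacklevel=2
            )
            continue
        r = np.full(3, np.nan)
        for k, vals in per_pair.items():
            if len(vals) > 1:
                r[k] = fisher_z_aggregate(vals)
                log.append(
                    f"{rec.study_id}: Fisher-z composite of {len(vals)} effects "
                    f"for {PAIR_NAMES[k]} -> {r[k]:+.4f}"
                )
            else:
                r[k] = vals[0]
        mask = ~np.isnan(r)
        if mask.all():
            try:
                r_fix, changed = nearest_correlation_triple(r)
            except InadmissibleMatrixError as exc:
                log.append(f"{rec.study_id}: dropped ({exc})")
                warnings.warn(f"study {rec.study_id} dropped: {exc}", stacklevel=2)
                continue
            if changed:
                log.append(
                    f"{rec.study_id}: non-PSD triple projected to nearest "
                    f"correlation matrix (max change "
                    f"{np.abs(r_fix - r).max():.4f})"
                )
                r = r_fix
        sets.append(CorrelationSet(study_id=rec.study_id, r=r, mask=mask, n=rec.n))
    return sets
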