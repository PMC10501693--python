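"""Subgroup moderation and sensitivity analyses.

Moderation is tested by fitting Stage 1 and Stage 2 separately per
subgroup, then refitting a joint model in which the three mediation
paths are constrained equal across groups.  Because each unconstrained
group model is saturated (discrepancy 0), the constrained joint minimum
F is itself the chi-square difference statistic, with df equal to the
number of constrained paths (3 for the omnibus test).

Sensitivity analyses re-run the whole pipeline after excluding studies
carrying stated flags and report main vs. sensitivity estimates side by
side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effects import CorrelationSet, StudyRecord, build_correlation_sets
from .stage1 import PooledCorrelations, pool
from .stage2 import PATH_NAMES, MediationFit, closed_form_saturated, fit_wls, implied_triple, _jacobian

__all__ = [
    "GroupFit",
    "SubgroupResult",
    "SensitivityResult",
    "group_labels",
    "split_and_fit",
    "equality_constraint_test",
    "sensitivity_run",
    "EXCLUSION_FLAGS",
]

GROUPINGS = ("design", "region")
EXCLUSION_FLAGS = ("nightmare_overlap", "under5", "beta_converted")


@dataclass
class GroupFit:
    label: str
    pooled: PooledCorrelations
    fit: MediationFit
    n_studies: int
    n_total: int


@dataclass
class SubgroupResult:
    grouping: str
    groups: dict[str, GroupFit]
    delta_chi2: float
    df: int
    p: float
    per_path: dict[str, tuple[float, int, float]] = field(default_factory=dict)


@dataclass
class SensitivityResult:
    exclusions: tuple[str, ...]
    n_excluded: int
    excluded_ids: list[str]
    main: MediationFit
    sensitivity: MediationFit
    comparison: pd.DataFrame


def group_labels(records: list[StudyRecord], grouping: str) -> dict[str, str]:
    """study_id -> subgroup value for a grouping column."""
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    return {rec.study_id: getattr(rec, grouping) for rec in records}


def split_and_fit(
    sets: list[CorrelationSet], labels: dict[str, str]
) -> dict[str, GroupFit]:
    """Independent Stage-1 + Stage-2 runs per subgroup."""
    values = sorted({labels[s.study_id] for s in sets})
    if len(values) < 2:
        raise ValueError(
            f"degenerate split: grouping takes a single value {values!r}"
        )
    out: dict[str, GroupFit] = {}
    for v in values:
        members = [s for s in sets if labels[s.study_id] == v]
        if not members:
            raise ValueError(f"empty subgroup {v!r}")
        pooled = pool(members)
        fit = fit_wls(pooled)
        out[v] = GroupFit(
            label=v, pooled=pooled, fit=fit,
            n_studies=len(members), n_total=int(sum(s.n for s in members)),
        )
    return out


def _joint_constrained_F(
    groups: list[GroupFit], shared: tuple[str, ...]
) -> float:
    """Minimized joint WLS discrepancy with the given paths shared."""
    shared_idx = [PATH_NAMES.index(p) for p in shared]
    free_idx = [k for k in range(3) if k not in shared_idx]
    rhos = [g.pooled.rho for g in groups]
    Ws = [np.linalg.inv(g.pooled.acov) for g in groups]
    starts = [closed_form_saturated(r) for r in rhos]
    shared_start = np.mean([s[shared_idx] for s in starts], axis=0)

    def unpack(x):
        thetas = []
        pos = len(shared_idx)
        for g in range(len(groups)):
            th = np.empty(3)
            th[shared_idx] = x[: len(shared_idx)]
            th[free_idx] = x[pos : pos + len(free_idx)]
            pos += len(free_idx)
            thetas.append(th)
        return thetas

    def objective(x):
        return sum(
            float((r - implied_triple(th)) @ W @ (r - implied_triple(th)))
            for r, W, th in zip(rhos, Ws, unpack(x))
        )

    def gradient(x):
        g_shared = np.zeros(len(shared_idx))
        g_free = []
        for r, W, th in zip(rhos, Ws, unpack(x)):
            res = r - implied_triple(th)
            g_full = -2.0 * _jacobian(th).T @ W @ res
            g_shared += g_full[shared_idx]
            g_free.append(g_full[free_idx])
        return np.concatenate([g_shared] + g_free)

    x0 = np.concatenate([shared_start] + [s[free_idx] for s in starts])
    opt = optimize.minimize(
        objective, x0, jac=gradient, method="BFGS",
        options={"gtol": 1e-12, "maxiter": 1000},
    )
    return max(float(opt.fun), 0.0)


def equality_constraint_test(
    groups: dict[str, GroupFit], constrained: tuple[str, ...] = PATH_NAMES,
    grouping: str = "", per_path_tests: bool = True,
) -> SubgroupResult:
    """Chi-square difference test of path equality across two subgroups.

    The unconstrained multi-group model is saturated per group (F = 0),
    so the constrained joint minimum is the chi-square increase directly;
    df = number of constrained paths x (groups - 1).  When the omnibus
    three-path test is requested, single-path tests (df = 1 each) are
    reported as secondary output.
    """
    if not constrained:
        raise ValueError("constraint set is empty")
    if len(groups) != 2:
        raise ValueError("equality test requires exactly two groups")
    glist = list(groups.values())
    dchi2 = _joint_constrained_F(glist, tuple(constrained))
    df = len(constrained) * (len(glist) - 1)
    p = float(stats.chi2.sf(dchi2, df))
    per_path = {}
    if per_path_tests and set(constrained) == set(PATH_NAMES):
        for path in PATH_NAMES:
            d1 = _joint_constrained_F(glist, (path,))
            per_path[path] = (d1, 1, float(stats.chi2.sf(d1, 1)))
    return SubgroupResult(
        grouping=grouping, groups=groups, delta_chi2=dchi2, df=df, p=p,
        per_path=per_path,
    )


def _is_flagged(rec: StudyRecord, flag: str) -> bool:
    if flag == "nightmare_overlap":
        return rec.flag_nightmare_overlap
    if flag == "under5":
        return rec.flag_under5
    if flag == "beta_converted":
        return any(e.effect_type == "std_beta" for e in rec.entries)
    raise ValueError(f"unknown exclusion flag {flag!r}; expected {EXCLUSION_FLAGS}")


def sensitivity_run(
    records: list[StudyRecord],
    exclusions: tuple[str, ...] | set[str],
    main: MediationFit | None = None,
    provenance: list[str] | None = None,
) -> SensitivityResult:
    """Re-run the pipeline excluding flagged studies; compare to the main fit."""
    exclusions = tuple(sorted(set(exclusions)))
    log = provenance if provenance is not None else []
    if main is None:
        main = fit_wls(pool(build_correlation_sets(records, log)))
    excluded = [r.study_id for r in records
                if any(_is_flagged(r, f) for f in exclusions)]
    kept = [r for r in records if r.study_id not in set(excluded)]
    if not kept:
        raise ValueError(f"exclusion set {exclusions} removes every study")
    for sid in excluded:
        log.append(f"{sid}: excluded by sensitivity flags {list(exclusions)}")
    sens = fit_wls(pool(build_correlation_sets(kept, log)))

    rows = []
    for k, name in enumerate(PATH_NAMES):
        rows.append((name, main.paths[k], sens.paths[k]))
    rows.append(("indirect", main.indirect, sens.indirect))
    comparison = pd.DataFrame(rows, columns=["parameter", "main", "sensitivity"])
    comparison["abs_diff"] = (comparison["main"] - comparison["sensitivity"]).abs()
    return SensitivityResult(
        exclusions=exclusions, n_excluded=len(excluded), excluded_ids=excluded,
        main=main, sensitivity=sens, comparison=comparison,
    )
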