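"""Small linear-algebra helpers shared across the pipeline.

The correlation vector convention throughout the package is
``(r_XM, r_XY, r_MY)`` with matrix variable order ``(X, M, Y)``:
X = exposure, M = mediator, Y = outcome.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.correlation_tools import corr_nearest

#: matrix positions of the three correlation elements in (X, M, Y) order
PAIR_POSITIONS = ((0, 1), (0, 2), (1, 2))
PAIR_NAMES = ("XM", "XY", "MY")
PAIR_INDEX = {"XM": 0, "XY": 1, "MY": 2}

_PD_TOL = 1e-10


class InadmissibleMatrixError(ValueError):
    """A correlation triple does not form a positive-definite matrix."""


def triple_to_matrix(r) -> np.ndarray:
    """Expand a correlation triple (r_XM, r_XY, r_MY) to a 3x3 matrix."""
    r = np.asarray(r, dtype=float)
    R = np.eye(3)
    for k, (i, j) in enumerate(PAIR_POSITIONS):
        R[i, j] = R[j, i] = r[k]
    return R


def matrix_to_triple(R) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    return np.array([R[i, j] for i, j in PAIR_POSITIONS])


def is_positive_definite(R, tol: float = _PD_TOL) -> bool:
    return bool(np.linalg.eigvalsh(np.asarray(R, dtype=float)).min() > tol)


def nearest_correlation_triple(r, max_element_change: float = 0.05):
    """Project a non-PD triple to the nearest correlation matrix.

    Uses Higham's alternating-projection method.  Raises
    :class:`InadmissibleMatrixError` when any element must move by more
    than ``max_element_change`` to reach admissibility (the input is then
    considered unusable rather than silently rewritten).

    Returns ``(repaired_triple, changed)``.
    """
    r = np.asarray(r, dtype=float)
    R = triple_to_matrix(r)
    if is_positive_definite(R):
        return r, False
    R_fix = corr_nearest(R, threshold=1e-8, n_fact=1000)
    r_fix = matrix_to_triple(R_fix)
    delta = np.abs(r_fix - r).max()
    if max_element_change is not None and delta > max_element_change:
        raise InadmissibleMatrixError(
            f"nearest-correlation repair moved an element by {delta:.4f} "
            f"(> {max_element_change}); triple {r.tolist()} is inadmissible"
        )
    return r_fix, True
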