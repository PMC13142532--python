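"""Simplex-constrained least squares (shared by archetypes and hull projection)."""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls

# Weight of the sum-to-one penalty row. Large enough that the constraint holds to
# ~1e-10 after renormalization, small enough to keep the augmented system
# well-conditioned at float64.
_PENALTY = 1e5


def simplex_lstsq(basis: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Solve min_s ||basis.T @ s - target||^2 subject to s >= 0, sum(s) = 1.

    Parameters
    ----------
    basis
        (k, d) array whose rows span the simplex (e.g. archetype coordinates).
    target
        (d,) point to approximate.

    Returns
    -------
    (k,) mixture weights on the probability simplex.

    The equality constraint is enforced by augmenting the design with a heavily
    weighted row of ones and solving the resulting NNLS problem, then
    renormalizing. Duplicate basis rows are handled (NNLS picks a vertex of the
    solution face), satisfying the minimal-ambiguity contract for degenerate input.
    """
    k = basis.shape[0]
    scale = max(np.abs(basis).max(), np.abs(target).max(), 1.0)
    a = np.vstack([basis.T / scale, np.full((1, k), _PENALTY)])
    b = np.concatenate([target / scale, [_PENALTY]])
    s, _ = nnls(a, b)
    total = s.sum()
    if total <= 0:  # pragma: no cover - cannot happen with finite penalty
        return np.full(k, 1.0 / k)
    return s / total


def simplex_lstsq_rows(basis: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Row-wise :func:`simplex_lstsq`: returns (n, k) weights for (n, d) targets."""
    return np.vstack([simplex_lstsq(basis, t) for t in targets])
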