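"""Restricted quadratic spline bases.

Restricted quadratic splines (RQS) are the workhorse for smooth non-linear
trends in epidemiological regression: piecewise-quadratic in the predictor,
constrained ("restricted") to be linear beyond the final knot so that fitted
curves do not explode in the sparse upper tail.  With knots
``k_1 < k_2 < ... < k_K`` the basis consists of the identity column ``x``
plus, for ``j = 1..K-1``,

    s_j(x) = [ ((x - k_j)_+)^2 - ((x - k_K)_+)^2 ] / (k_K - k_1)

where ``(u)_+ = max(u, 0)``.  Each ``s_j`` is continuous with a continuous
first derivative, vanishes below ``k_j``, and has constant slope
``2 (k_K - k_j) / (k_K - k_1)`` above ``k_K``, so any linear combination is
linear beyond the last knot.

Two knot-placement rules are provided: empirical percentiles (used for the
gestational-age trend in the reference growth model) and equally spaced
interior knots (used for continuous adjustment covariates in the outcome
models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KnotSet", "percentile_knots", "equally_spaced_knots", "rqs_basis"]


@dataclass(frozen=True)
class KnotSet:
    """A strictly increasing set of spline knots on a predictor's scale."""

    knots: tuple[float, ...]
    placement_rule: str = "manual"

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        if len(knots) < 3:
            raise ValueError(f"need at least 3 knots, got {len(knots)}")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing: {knots}")
        object.__setattr__(self, "knots", knots)

    def __len__(self) -> int:
        return len(self.knots)

    @property
    def n_basis_columns(self) -> int:
        """Linear column plus K-1 restricted-quadratic columns."""
        return len(self.knots)


def percentile_knots(values, probs=(5, 35, 65, 95)) -> KnotSet:
    """Place knots at empirical percentiles of observed predictor values.

    Uses the linear-interpolation quantile definition.  Requires at least 20
    distinct values; coincident knots (heavily tied data) are an error
    because the basis would be rank-deficient.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if np.unique(values).size < 20:
        raise ValueError(
            f"need >= 20 distinct values to place percentile knots, "
            f"got {np.unique(values).size}"
        )
    knots = np.percentile(values, probs, method="linear")
    if np.any(np.diff(knots) <= 0):
        raise ValueError(f"coincident percentile knots: {knots}")
    return KnotSet(tuple(knots), placement_rule=f"percentile{tuple(probs)}")


def equally_spaced_knots(values, k: int = 3) -> KnotSet:
    """Place ``k`` knots equally spaced strictly inside the observed range.

    Knot ``j`` sits at ``min + j * (max - min) / (k + 1)`` for ``j = 1..k``,
    so no knot coincides with either extreme.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    lo, hi = float(np.min(values)), float(np.max(values))
    if not hi > lo:
        raise ValueError(f"degenerate predictor range [{lo}, {hi}]")
    knots = lo + np.arange(1, k + 1) * (hi - lo) / (k + 1)
    return KnotSet(tuple(knots), placement_rule=f"equally_spaced({k})")


def rqs_basis(x, knots: KnotSet) -> np.ndarray:
    """Evaluate the restricted quadratic spline basis at ``x``.

    Returns an array of shape ``(n, K)``: column 0 is ``x`` itself and
    columns ``1..K-1`` are the restricted-quadratic terms ``s_j(x)``
    (no intercept column).  Scalar input yields shape ``(1, K)``.
    """
    if not isinstance(knots, KnotSet):
        knots = KnotSet(tuple(knots))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = np.asarray(knots.knots)
    k1, kK = k[0], k[-1]
    last = np.maximum(x - kK, 0.0) ** 2
    cols = [x]
    for kj in k[:-1]:
        cols.append((np.maximum(x - kj, 0.0) ** 2 - last) / (kK - k1))
    return np.column_stack(cols)
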