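"""Orthogonal polynomial time bases for growth curve analysis.

A growth curve model regresses a time course on polynomial functions of
time.  Raw powers of time are highly collinear, so the basis is
orthogonalized: each column is orthogonal to the constant vector and to
every lower-order column, and scaled to unit norm.  With this
construction the intercept estimates the average level over the window,
the linear term the overall slope, the quadratic the primary curvature,
and the cubic a secondary inflection — each estimated independently of
the others on a balanced time grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PolyBasis", "orthogonal_poly_basis"]


@dataclass(frozen=True)
class PolyBasis:
    """Orthonormal polynomial basis evaluated on a fixed time grid.

    Attributes
    ----------
    times : ndarray
        The evaluation grid (typically bin midpoints, ms).
    order : int
        Highest polynomial degree (columns ``poly1 .. poly{order}``).
    columns : ndarray, shape (len(times), order)
        Basis values; mutually orthogonal, orthogonal to the constant
        vector, unit Euclidean norm.
    """

    times: np.ndarray
    order: int
    columns: np.ndarray = field(repr=False)

    @property
    def names(self) -> list[str]:
        return [f"poly{k}" for k in range(1, self.order + 1)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.columns, columns=self.names).assign(time_ms=self.times)

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the basis polynomials at arbitrary times.

        Each column of the basis is a polynomial of degree <= order; the
        unique interpolating polynomial through the grid values is
        evaluated at ``t``.  On the construction grid this reproduces
        ``columns`` exactly.
        """
        t = np.asarray(t, dtype=float)
        out = np.empty((t.size, self.order), dtype=float)
        # center to keep the Vandermonde solve well conditioned
        c = self.times.mean()
        s = max(self.times.std(), 1.0)
        for j in range(self.order):
            coef = np.polynomial.polynomial.polyfit(
                (self.times - c) / s, self.columns[:, j], deg=self.order
            )
            out[:, j] = np.polynomial.polynomial.polyval((t - c) / s, coef)
        return out


def orthogonal_poly_basis(times, order: int = 3) -> PolyBasis:
    """Construct an orthonormal polynomial basis at the given time points.

    Equivalent to orthogonalizing ``[t, t^2, ..., t^order]`` against the
    constant vector and against each other (Gram–Schmidt), with unit-norm
    columns and signs fixed so each column correlates positively with the
    raw power it represents (the convention of R's ``poly``).

    Parameters
    ----------
    times : array-like
        Time points; must contain at least ``order + 1`` distinct values.
    order : int
        Polynomial order, default 3 (linear, quadratic, cubic).

    Raises
    ------
    ValueError
        If there are fewer than ``order + 1`` distinct time points.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if order < 1:
        raise ValueError("order must be >= 1")
    if np.unique(times).size < order + 1:
        raise ValueError(
            f"need at least {order + 1} distinct time points for order {order}, "
            f"got {np.unique(times).size}"
        )
    tc = (times - times.mean()) / max(times.std(), np.finfo(float).tiny)
    vander = np.column_stack([tc**k for k in range(order + 1)])
    q, r = np.linalg.qr(vander)
    cols = q[:, 1:]
    # sign convention: positive projection onto the corresponding raw power
    for j in range(order):
        sgn = np.sign(cols[:, j] @ vander[:, j + 1])
        if sgn < 0:
            cols[:, j] = -cols[:, j]
    cols = cols / np.linalg.norm(cols, axis=0)
    return PolyBasis(times=times, order=order, columns=cols)
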