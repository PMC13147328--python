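"""Local polynomial regression (LOESS) with GCV-based span selection.

A tricube-weighted local polynomial smoother built from its explicit
smoother (hat) matrix: each fitted value is a known linear combination of
the observations, so the generalized cross-validation score

    GCV(span) = n * RSS / (n - trace(L))^2

is available exactly for every candidate span. This is the smoother behind
QC-based signal-drift correction, where a per-feature drift curve is fitted
to pooled-QC intensities against injection index.

Evaluation outside the span of the training points extends the boundary
fitted values as constants (a drift estimate is not extrapolated beyond the
QCs that anchor it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LoessFit", "loess_gcv_fit", "SharedGridLoess", "DEFAULT_SPAN_GRID"]

#: Candidate spans searched when none are given: 0.20, 0.25, ..., 0.95.
DEFAULT_SPAN_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.20, 1.0, 0.05), 2))


def _hat_rows(x_train: np.ndarray, x_eval: np.ndarray, span: float,
              degree: int) -> np.ndarray:
    """Rows of the smoother matrix: fitted(x_eval) = H @ y.

    Each row is e0' (X'WX)^-1 X'W for the local design centered at the
    evaluation point, with tricube weights over the span-defined
    neighborhood.
    """
    n = x_train.size
    m = x_eval.size
    k = max(int(np.ceil(span * n)), degree + 2)
    k = min(k, n)
    d = np.abs(x_train[None, :] - x_eval[:, None])  # (m, n)
    dmax = np.sort(d, axis=1)[:, k - 1]
    dmax = np.where(dmax <= 0, 1.0, dmax)
    u = np.clip(d / dmax[:, None], 0.0, 1.0)
    w = (1.0 - u**3) ** 3

    # abscissa scaled by the local bandwidth keeps the design well-conditioned
    t = (x_train[None, :] - x_eval[:, None]) / dmax[:, None]  # (m, n)
    X = np.stack([t**p for p in range(degree + 1)], axis=2)  # (m, n, d+1)
    Xw = X * w[:, :, None]
    A = np.einsum("mnp,mnq->mpq", Xw, X)  # (m, d+1, d+1)
    # tiny ridge guards near-singular local designs (e.g. replicated x)
    diag = np.einsum("mpp->mp", A).max(axis=1)
    A += 1e-12 * diag[:, None, None] * np.eye(degree + 1)
    e0 = np.zeros((m, degree + 1))
    e0[:, 0] = 1.0
    z = np.linalg.solve(A, e0[..., None])[..., 0]  # (m, d+1)
    return np.einsum("mp,mnp->mn", z, Xw)  # (m, n)


@dataclass
class LoessFit:
    """A fitted local polynomial smoother at a GCV-selected span."""

    span: float
    degree: int
    fitted: np.ndarray          # fitted values at the training x
    gcv: float
    x_train: np.ndarray
    y_train: np.ndarray

    def predict(self, x_new) -> np.ndarray:
        """Evaluate the smoother; constant extension outside the x range."""
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        clipped = np.clip(x_new, self.x_train.min(), self.x_train.max())
        H = _hat_rows(self.x_train, clipped, self.span, self.degree)
        return H @ self.y_train


def loess_gcv_fit(
    x, y, degree: int = 2, span_grid=None
) -> LoessFit:
    """Fit LOESS at every candidate span and keep the GCV minimizer.

    Requires at least ``degree + 2`` distinct x values. Spans whose
    effective degrees of freedom exhaust the data (trace(L) >= n) are
    discarded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.unique(x).size < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} distinct x values")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    spans = DEFAULT_SPAN_GRID if span_grid is None else tuple(span_grid)

    n = x.size
    best = None
    for span in spans:
        L = _hat_rows(x, x, span, degree)
        fitted = L @ y
        rss = float(np.sum((y - fitted) ** 2))
        tr = float(np.trace(L))
        # GCV needs residual degrees of freedom; near-interpolating spans
        # have tr -> n and a meaningless score
        if tr > n - 1 or not np.isfinite(tr):
            continue
        gcv = n * rss / (n - tr) ** 2
        if not np.isfinite(gcv):
            continue
        if best is None or gcv < best.gcv:
            best = LoessFit(span=float(span), degree=degree, fitted=fitted,
                            gcv=gcv, x_train=x, y_train=y)
    if best is None:
        raise ValueError("no candidate span produced a valid fit")
    return best


class SharedGridLoess:
    """Span search shared across many series observed at the same x.

    The hat matrix depends only on (x, span, degree), so when thousands of
    features share one QC injection grid the per-span smoother matrices are
    computed once and applied to all features at matrix speed.
    """

    def __init__(self, x_train, degree: int = 2, span_grid=None):
        self.x = np.asarray(x_train, dtype=float)
        self.degree = degree
        self.spans = list(DEFAULT_SPAN_GRID if span_grid is None else span_grid)
        if np.unique(self.x).size < degree + 2:
            raise ValueError(f"need at least degree + 2 = {degree + 2} distinct x values")
        n = self.x.size
        self._L, self._trace, kept = [], [], []
        for span in self.spans:
            L = _hat_rows(self.x, self.x, span, degree)
            tr = float(np.trace(L))
            if tr > n - 1 or not np.isfinite(tr):
                continue
            self._L.append(L)
            self._trace.append(tr)
            kept.append(span)
        if not self._L:
            raise ValueError("no candidate span produced a valid fit")
        self.spans = kept

    def select_spans(self, Y: np.ndarray) -> np.ndarray:
        """Per-row GCV-minimizing span index for Y (rows x len(x))."""
        n = self.x.size
        gcv = np.empty((len(self._L), Y.shape[0]))
        for s, (L, tr) in enumerate(zip(self._L, self._trace)):
            fitted = Y @ L.T
            rss = np.sum((Y - fitted) ** 2, axis=1)
            gcv[s] = n * rss / (n - tr) ** 2
        return np.argmin(gcv, axis=0)

    def predict(self, Y: np.ndarray, span_idx: np.ndarray, x_eval) -> np.ndarray:
        """Fitted values at x_eval for every row, using its selected span."""
        x_eval = np.asarray(x_eval, dtype=float)
        clipped = np.clip(x_eval, self.x.min(), self.x.max())
        out = np.empty((Y.shape[0], x_eval.size))
        for s in np.unique(span_idx):
            H = _hat_rows(self.x, clipped, self.spans[s], self.degree)
            rows = span_idx == s
            out[rows] = Y[rows] @ H.T
        return out
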