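"""Vectorised monotone piecewise-cubic curves.

Measured stimulation-to-torque sweeps are tabulated functions that must be
evaluated and, more importantly, *inverted* (torque -> stimulation) many
thousands of times while building lookup tables. The curves are smooth and
monotone on their reference joint, so a Fritsch-Carlson monotone cubic
Hermite interpolant gives near machine-precision round trips from a
101-sample sweep while never overshooting the data. Everything here operates
column-wise on arrays of curves sharing one abscissa grid, with a different
query point per column, which scipy's interpolators do not vectorise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MonotoneCurveSet", "pchip_slopes"]


def pchip_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fritsch-Carlson endpoint-corrected derivative estimates.

    Parameters
    ----------
    x : (k,) strictly increasing abscissae.
    y : (k, ...) ordinates; slopes are computed along axis 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = x.shape[0]
    if k < 2:
        raise ValueError("need at least two samples")
    h = np.diff(x).reshape((k - 1,) + (1,) * (y.ndim - 1))
    delta = np.diff(y, axis=0) / h
    d = np.zeros_like(y)
    if k == 2:
        d[0] = delta[0]
        d[1] = delta[0]
        return d

    # interior: weighted harmonic mean where secants agree in sign, else 0
    h0, h1 = h[:-1], h[1:]
    d0, d1 = delta[:-1], delta[1:]
    w1 = 2.0 * h1 + h0
    w2 = h1 + 2.0 * h0
    with np.errstate(divide="ignore", invalid="ignore"):
        whmean = (w1 + w2) / (w1 / np.where(d0 == 0.0, 1.0, d0)
                              + w2 / np.where(d1 == 0.0, 1.0, d1))
    agree = (d0 * d1) > 0.0
    d[1:-1] = np.where(agree, whmean, 0.0)

    # one-sided endpoint formula with shape-preserving clips
    def _edge(h_a, h_b, del_a, del_b):
        val = ((2.0 * h_a + h_b) * del_a - h_a * del_b) / (h_a + h_b)
        val = np.where(np.sign(val) != np.sign(del_a), 0.0, val)
        cap = (np.sign(del_a) != np.sign(del_b)) & (np.abs(val) > 3.0 * np.abs(del_a))
        return np.where(cap, 3.0 * del_a, val)

    d[0] = _edge(h[0], h[1], delta[0], delta[1])
    d[-1] = _edge(h[-1], h[-2], delta[-1], delta[-2])
    return d


class MonotoneCurveSet:
    """A bundle of monotone curves y_j(x) on a shared grid.

    ``y`` has shape ``(k,) + cols`` where ``cols`` indexes independent
    curves. Evaluation and inversion accept one query per curve.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        self._shape = y.shape[1:]
        self.y = y.reshape(y.shape[0], -1)  # (k, M)
        self.d = pchip_slopes(self.x, self.y)

    @property
    def n_curves(self) -> int:
        return self.y.shape[1]

    def _cells(self, xq: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.x, xq, side="right") - 1
        return np.clip(idx, 0, self.x.shape[0] - 2)

    def _hermite(self, idx, t, cols):
        h = self.x[idx + 1] - self.x[idx]
        yi = self.y[idx, cols]
        yj = self.y[idx + 1, cols]
        di = self.d[idx, cols]
        dj = self.d[idx + 1, cols]
        t2 = t * t
        t3 = t2 * t
        val = ((2 * t3 - 3 * t2 + 1) * yi + (t3 - 2 * t2 + t) * h * di
               + (-2 * t3 + 3 * t2) * yj + (t3 - t2) * h * dj)
        dval = ((6 * t2 - 6 * t) * yi + (3 * t2 - 4 * t + 1) * h * di
                + (-6 * t2 + 6 * t) * yj + (3 * t2 - 2 * t) * h * dj) / h
        return val, dval

    def evaluate(self, xq) -> np.ndarray:
        """Evaluate curve j at xq[j]; xq scalar or shaped like the columns."""
        xq = np.broadcast_to(np.asarray(xq, dtype=float), self._shape).reshape(-1)
        cols = np.arange(self.n_curves)
        idx = self._cells(xq)
        t = (xq - self.x[idx]) / (self.x[idx + 1] - self.x[idx])
        val, _ = self._hermite(idx, t, cols)
        return val.reshape(self._shape)

    def invert(self, target, clip: bool = True):
        """Solve y_j(x) = target[j] for each curve (non-decreasing curves).

        Ties on flat stretches resolve to the lowest x. Targets outside the
        tabulated range are clamped to the end abscissae and flagged.

        Returns
        -------
        x : ndarray shaped like the columns
        clipped : boolean ndarray, True where the target exceeded the range
        """
        tgt = np.broadcast_to(np.asarray(target, dtype=float), self._shape).reshape(-1)
        cols = np.arange(self.n_curves)
        lo_y = self.y[0, cols]
        hi_y = self.y[-1, cols]
        clipped = (tgt < lo_y - 1e-12) | (tgt > hi_y + 1e-12)
        if clip:
            tgt = np.clip(tgt, lo_y, hi_y)

        # strict '<' sends exact ties to the first (lowest-x) matching cell
        cnt = (self.y[:, cols] < tgt[None, :]).sum(axis=0)
        idx = np.clip(cnt - 1, 0, self.x.shape[0] - 2)

        # safeguarded Newton on the Hermite cubic within the cell
        ta = np.zeros_like(tgt)
        tb = np.ones_like(tgt)
        t = np.full_like(tgt, 0.5)
        h = self.x[idx + 1] - self.x[idx]
        for _ in range(40):
            val, dval = self._hermite(idx, t, cols)
            err = val - tgt
            ta = np.where(err < 0, t, ta)
            tb = np.where(err > 0, t, tb)
            with np.errstate(divide="ignore", invalid="ignore"):
                step = err / (dval * h)
            tn = t - np.where(np.isfinite(step), step, 0.0)
            bad = (tn <= ta) | (tn >= tb) | ~np.isfinite(tn)
            t = np.where(bad, 0.5 * (ta + tb), tn)
            if np.max(tb - ta) < 1e-14:
                break
        xq = self.x[idx] + t * h
        # flat-at-origin curves: target 0 on an all-zero prefix -> x = x[0]
        xq = np.where(np.abs(tgt - lo_y) < 1e-15, self.x[0], xq)
        return xq.reshape(self._shape), clipped.reshape(self._shape)
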