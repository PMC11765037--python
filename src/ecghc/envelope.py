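"""Cmin/Cmax envelope of the entropy-complexity plane.

For a fixed alphabet size L, the statistical complexity C of a probability
distribution with normalized entropy H is not free: it is bounded between
two curves Cmin(H) and Cmax(H).  Both extremes are attained on one-parameter
families of distributions that have m components exactly zero (m = 0..L-2)
and, of the remaining s = L - m components, one free component p in [0, 1]
with the other s - 1 components sharing the rest of the mass equally.

Within one family branch, the entropy is monotone in p on each side of the
uniform point p = 1/s, so the boundary value of C at a requested H can be
found exactly by bisection on p; the envelope at H is the min/max of C over
all branches that reach that H.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ordinal import disequilibrium_normalization

__all__ = ["ComplexityEnvelope", "complexity_envelope"]


def _branch_entropy(p: np.ndarray, s: int) -> np.ndarray:
    """Shannon entropy of (p, (1-p)/(s-1) x (s-1), 0 x m) in nats."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] -= p[pos] * np.log(p[pos])
    rest = (1.0 - p) / (s - 1)
    pos = rest > 0
    out[pos] -= (1.0 - p[pos]) * np.log(rest[pos])
    return out


def _branch_complexity(p: np.ndarray, s: int, L: int, q0: float) -> np.ndarray:
    """C = H*Q for the branch distribution, evaluated without materializing it."""
    p = np.asarray(p, dtype=float)
    ln_l = math.log(L)
    S = _branch_entropy(p, s)
    # entropy of the mixture with the uniform distribution over L
    a = (p + 1.0 / L) / 2.0  # the free component
    b = ((1.0 - p) / (s - 1) + 1.0 / L) / 2.0  # s-1 equal components
    c = 1.0 / (2.0 * L)  # the m zero components
    m = L - s
    S_mix = -a * np.log(a) - (s - 1) * b * np.log(b)
    if m:
        S_mix -= m * c * math.log(c)
    jsd = np.maximum(S_mix - S / 2.0 - ln_l / 2.0, 0.0)
    return (S / ln_l) * (q0 * jsd)


def _branch_bounds_at(h: np.ndarray, L: int, q0: float):
    """Yield branch complexities at entropy h for every monotone sub-branch."""
    ln_l = math.log(L)
    target_S = np.asarray(h, dtype=float) * ln_l
    for s in range(2, L + 1):
        uniform_p = 1.0 / s
        s_max = math.log(s)
        # (lo, hi, S at lo, S at hi): entropy is monotone on each interval
        sides = [
            (uniform_p, 1.0, s_max, 0.0),  # S decreasing in p
            (0.0, uniform_p, math.log(s - 1) if s > 2 else 0.0, s_max),
        ]
        for lo, hi, s_lo, s_hi in sides:
            smin, smax = min(s_lo, s_hi), max(s_lo, s_hi)
            mask = (target_S >= smin - 1e-12) & (target_S <= smax + 1e-12)
            if not mask.any():
                continue
            t = np.clip(target_S[mask], smin, smax)
            a = np.full(t.size, lo)
            b = np.full(t.size, hi)
            increasing = s_hi > s_lo
            for _ in range(60):
                mid = (a + b) / 2.0
                sm = _branch_entropy(mid, s)
                too_low = (sm < t) if increasing else (sm > t)
                a = np.where(too_low, mid, a)
                b = np.where(too_low, b, mid)
            c = _branch_complexity((a + b) / 2.0, s, L, q0)
            yield mask, c


@dataclass(frozen=True)
class ComplexityEnvelope:
    """Cmin/Cmax bounds of the H x C plane for alphabet size L.

    ``grid`` holds (H, Cmin, Cmax) triples on a uniform H grid for export
    and plotting; containment checks use the exact boundary evaluated by
    bisection rather than interpolation of the grid.
    """

    L: int
    grid: np.ndarray  # shape (n_grid, 3): H, Cmin, Cmax

    def cmin_at(self, h) -> np.ndarray:
        return self._bound_at(h, np.minimum, np.inf)

    def cmax_at(self, h) -> np.ndarray:
        return self._bound_at(h, np.maximum, -np.inf)

    def _bound_at(self, h, reduce, init) -> np.ndarray:
        h_arr = np.atleast_1d(np.asarray(h, dtype=float))
        q0 = disequilibrium_normalization(self.L)
        out = np.full(h_arr.shape, init)
        for mask, c in _branch_bounds_at(h_arr, self.L, q0):
            out[mask] = reduce(out[mask], c)
        out[~np.isfinite(out)] = 0.0
        # boundary points carry exactly zero complexity
        out[np.abs(h_arr) <= 1e-12] = 0.0
        out[np.abs(h_arr - 1.0) <= 1e-12] = 0.0
        return out if np.ndim(h) else out[0]

    def contains(self, h, c, tol: float = 1e-6) -> np.ndarray:
        """Whether (H, C) points lie within [Cmin - tol, Cmax + tol]."""
        h_arr = np.atleast_1d(np.asarray(h, dtype=float))
        c_arr = np.atleast_1d(np.asarray(c, dtype=float))
        ok = (c_arr >= self.cmin_at(h_arr) - tol) & (c_arr <= self.cmax_at(h_arr) + tol)
        return ok if np.ndim(h) else bool(ok[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.grid, columns=["H", "Cmin", "Cmax"])


def complexity_envelope(L: int, n_grid: int = 512) -> ComplexityEnvelope:
    """Evaluate the Cmin/Cmax envelope on a uniform H grid in [0, 1].

    Parameters
    ----------
    L : int
        Alphabet size (D! for ordinal patterns), >= 2.
    n_grid : int
        Number of grid points, >= 10.
    """
    if L < 2:
        raise ValueError("alphabet size L must be >= 2")
    if n_grid < 10:
        raise ValueError("n_grid must be >= 10")
    env = ComplexityEnvelope(L=L, grid=np.empty((0, 3)))
    h = np.linspace(0.0, 1.0, n_grid)
    grid = np.column_stack([h, env.cmin_at(h), env.cmax_at(h)])
    return ComplexityEnvelope(L=L, grid=grid)
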