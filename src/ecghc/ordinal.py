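"""Bandt-Pompe ordinal pattern machinery and information quantifiers.

A scalar series is mapped to symbols by the rank ordering of length-``D``
subsequences taken every ``tau`` samples.  The resulting probability
distribution over the ``D!`` ordinal patterns supports the normalized
permutation entropy H, the Jensen-Shannon divergence between distributions,
the disequilibrium Q (normalized Jensen-Shannon distance to the uniform
distribution) and the statistical complexity C = H*Q.

Pattern enumeration convention
------------------------------
Patterns are indexed 1..D! by the position of the window's rank word in the
reverse-lexicographic ordering of the permutations of (1..D): the fully
descending window is type 1 and the fully ascending window is type D!.
For D = 3 the order is (321), (312), (231), (213), (132), (123), so e.g. the
window (1, 2, 5) has type 6 and (5, 4, 3) has type 1.  Ties are broken by
temporal order (the earlier sample ranks lower).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OrdinalPDF",
    "HCPoint",
    "encode_patterns",
    "estimate_pdf",
    "shannon_entropy",
    "normalized_entropy",
    "jensen_shannon_divergence",
    "disequilibrium",
    "disequilibrium_normalization",
    "statistical_complexity",
]

#: warn when a series yields fewer windows than this multiple of D!
_SPARSE_WINDOW_FACTOR = 5


@dataclass(frozen=True)
class OrdinalPDF:
    """Probability distribution over the D! ordinal patterns of a series.

    Parameters
    ----------
    probs : ndarray, shape (D!,)
        Pattern probabilities, indexed by pattern type - 1.
    D : int
        Embedding dimension (subsequence length).
    tau : int
        Embedding delay in samples.
    n_windows : int
        Number of subsequences counted (0 for analytically constructed
        distributions).
    """

    probs: np.ndarray
    D: int
    tau: int
    n_windows: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        L = math.factorial(self.D)
        if p.shape != (L,):
            raise ValueError(
                f"probs has length {p.shape}, expected D! = {L} for D={self.D}"
            )
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()!r}, expected 1")

    @property
    def L(self) -> int:
        """Alphabet size D!."""
        return math.factorial(self.D)

    @classmethod
    def uniform(cls, D: int, tau: int = 1) -> "OrdinalPDF":
        L = math.factorial(D)
        return cls(np.full(L, 1.0 / L), D, tau)

    @classmethod
    def degenerate(cls, D: int, pattern: int, tau: int = 1) -> "OrdinalPDF":
        """All mass on one pattern type (1-based index)."""
        L = math.factorial(D)
        p = np.zeros(L)
        p[pattern - 1] = 1.0
        return cls(p, D, tau)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"pattern": np.arange(1, self.L + 1), "probability": self.probs}
        )


@dataclass(frozen=True)
class HCPoint:
    """A point in the entropy-complexity plane.

    H is the normalized permutation entropy in [0, 1], Q the disequilibrium
    in [0, 1] and C = H*Q the statistical complexity.
    """

    H: float
    C: float
    Q: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.H <= 1 + 1e-9 and -1e-9 <= self.Q <= 1 + 1e-9):
            raise ValueError(f"H={self.H}, Q={self.Q} outside [0, 1]")
        if abs(self.C - self.H * self.Q) > 1e-12:
            raise ValueError("C must equal H*Q")


def _window_matrix(x: np.ndarray, D: int, tau: int) -> np.ndarray:
    n = x.size - (D - 1) * tau
    idx = np.arange(n)[:, None] + tau * np.arange(D)[None, :]
    return x[idx]


def encode_patterns(
    series,
    D: int,
    tau: int = 1,
    *,
    tie_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Assign an ordinal pattern type in 1..D! to every embedded window.

    Parameters
    ----------
    series : array_like
        One-dimensional real series.
    D : int
        Embedding dimension, >= 2.
    tau : int
        Embedding delay in samples, >= 1.
    tie_jitter : float
        If nonzero, add uniform noise of this half-width before ranking so
        that ties are broken randomly instead of by temporal order.  Off by
        default for reproducibility.
    rng : numpy.random.Generator, optional
        Source of jitter noise; required when ``tie_jitter`` > 0.

    Returns
    -------
    ndarray of int
        One type per window k = 0..K-(D-1)*tau-1 under the reverse-
        lexicographic enumeration (descending pattern = 1, ascending = D!).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if D < 2:
        raise ValueError("embedding dimension D must be >= 2")
    if tau < 1:
        raise ValueError("embedding delay tau must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    span = (D - 1) * tau
    if x.size < span + 1:
        raise ValueError(
            f"series of length {x.size} is too short for one window: "
            f"need at least (D-1)*tau + 1 = {span + 1} samples"
        )
    if tie_jitter > 0:
        if rng is None:
            raise ValueError("tie_jitter requires an rng")
        x = x + rng.uniform(-tie_jitter, tie_jitter, size=x.size)

    w = _window_matrix(x, D, tau)
    # rank of each sample within its window; stable sort ranks the earlier
    # of two tied samples lower (the standard Bandt-Pompe convention)
    order = np.argsort(w, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(D), w.shape), axis=1)
    # Lehmer code -> lexicographic rank of the rank word among permutations
    lex = np.zeros(w.shape[0], dtype=np.int64)
    for i in range(D - 1):
        inversions = np.sum(ranks[:, i + 1 :] < ranks[:, i : i + 1], axis=1)
        lex += inversions * math.factorial(D - 1 - i)
    return math.factorial(D) - lex  # reverse-lex, 1-based


def estimate_pdf(
    series,
    D: int,
    tau: int = 1,
    *,
    tie_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> OrdinalPDF:
    """Estimate the Bandt-Pompe PDF of a series by relative pattern counts.

    Each probability is the count of windows of that type divided by the
    total number of extracted windows, K - (D-1)*tau.  A warning is issued
    when the window count is small relative to the alphabet size D!, in
    which case the estimate is unreliable.
    """
    types = encode_patterns(series, D, tau, tie_jitter=tie_jitter, rng=rng)
    L = math.factorial(D)
    if types.size < _SPARSE_WINDOW_FACTOR * L:
        warnings.warn(
            f"only {types.size} windows for {L} patterns; the ordinal PDF "
            "estimate may be unreliable (series length should be much "
            "larger than D!)",
            stacklevel=2,
        )
    counts = np.bincount(types - 1, minlength=L)
    return OrdinalPDF(counts / types.size, D, tau, n_windows=int(types.size))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return max(float(-np.sum(p * np.log(p))), 0.0)


def shannon_entropy(pdf: OrdinalPDF | np.ndarray) -> float:
    """Shannon entropy S = -sum p_j ln p_j in nats, with 0 ln 0 = 0."""
    p = pdf.probs if isinstance(pdf, OrdinalPDF) else np.asarray(pdf, float)
    return _entropy(p)


def normalized_entropy(pdf: OrdinalPDF | np.ndarray) -> float:
    """Entropy normalized by its maximum ln L, dimensionless in [0, 1]."""
    p = pdf.probs if isinstance(pdf, OrdinalPDF) else np.asarray(pdf, float)
    return _entropy(p) / math.log(p.size)


def jensen_shannon_divergence(
    p: OrdinalPDF | np.ndarray, q: OrdinalPDF | np.ndarray
) -> float:
    """Jensen-Shannon divergence S[(p+q)/2] - S[p]/2 - S[q]/2 (nats).

    Symmetric, non-negative, zero iff p = q; its square root is a metric
    on probability distributions.
    """
    pa = p.probs if isinstance(p, OrdinalPDF) else np.asarray(p, float)
    qa = q.probs if isinstance(q, OrdinalPDF) else np.asarray(q, float)
    if pa.shape != qa.shape:
        raise ValueError(
            f"distributions live on different alphabets: {pa.size} vs {qa.size}"
        )
    d = _entropy((pa + qa) / 2.0) - _entropy(pa) / 2.0 - _entropy(qa) / 2.0
    return max(d, 0.0)  # guard tiny negative rounding


def disequilibrium_normalization(L: int) -> float:
    """Normalization constant Q0 = 1 / max_p JSD(p, uniform) for alphabet L.

    The maximizer over the simplex is a degenerate distribution; the maximum
    has the closed form evaluated here from the entropy expression of the
    Jensen-Shannon divergence.
    """
    delta = np.zeros(L)
    delta[0] = 1.0
    pe = np.full(L, 1.0 / L)
    return 1.0 / jensen_shannon_divergence(delta, pe)


def disequilibrium(p: OrdinalPDF | np.ndarray) -> float:
    """Normalized Jensen-Shannon distance to the uniform distribution.

    Q = Q0 * JSD(p, p_e) with Q0 such that Q = 1 at a degenerate
    distribution (the maximizer) and Q = 0 at the uniform distribution.
    """
    pa = p.probs if isinstance(p, OrdinalPDF) else np.asarray(p, float)
    pe = np.full(pa.size, 1.0 / pa.size)
    q = disequilibrium_normalization(pa.size) * jensen_shannon_divergence(pa, pe)
    return min(max(q, 0.0), 1.0)


def statistical_complexity(p: OrdinalPDF | np.ndarray) -> HCPoint:
    """Normalized entropy H, disequilibrium Q and complexity C = H*Q."""
    h = normalized_entropy(p)
    q = disequilibrium(p)
    return HCPoint(H=h, C=h * q, Q=q)
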