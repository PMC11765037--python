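"""f^(-k) noise synthesis and entropy-complexity plane landmarks.

Coloured Gaussian noises with power spectrum proportional to f^(-k)
("k-noises", white noise at k = 0, Brownian-like at k = 2) serve as
reference processes in the H x C plane: their mean location for a given
embedding traces a curve from the fully random corner (H = 1, C = 0)
towards lower entropy as k grows, against which ECG trajectories are read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ordinal import estimate_pdf, statistical_complexity

__all__ = ["KNoiseReference", "generate_knoise", "knoise_plane_landmarks"]


@dataclass(frozen=True)
class KNoiseReference:
    """Mean H x C location of an f^(-k) process for one embedding."""

    k: float
    H_ref: float
    C_ref: float
    n_realizations: int
    series_length: int
    seed: int


def generate_knoise(
    k: float, n: int, seed: "int | np.random.Generator" = 0
) -> np.ndarray:
    """Synthesize one standardized f^(-k) noise realization of length n.

    Spectral synthesis: a complex Gaussian spectrum is shaped by
    f^(-k/2) (the DC bin is zeroed), inverse-transformed and standardized
    to zero mean, unit variance.  A power of two ``n`` is recommended.
    Values of k outside [0, 3] are allowed but warned about.
    """
    if not 0 <= k <= 3:
        warnings.warn(f"k = {k} outside the calibrated range [0, 3]", stacklevel=2)
    if n < 2:
        raise ValueError("series length must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-k / 2.0)
    spectrum = amp * (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    )
    x = np.fft.irfft(spectrum, n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x /= sd
    return x


def knoise_plane_landmarks(
    k_values,
    D: int = 4,
    tau: int = 2,
    n: int = 2**16,
    n_realizations: int = 10,
    seed: int = 0,
) -> list[KNoiseReference]:
    """Locate f^(-k) processes in the H x C plane for one embedding.

    For each k the mean (H, C) over ``n_realizations`` independent
    realizations of length ``n`` is reported.  The same child seeds are
    used across k values so that curves for different k are comparable.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_realizations)
    out = []
    for k in k_values:
        H, C = [], []
        for child in children:
            rng = np.random.default_rng(child)
            x = generate_knoise(k, n, rng)
            hc = statistical_complexity(estimate_pdf(x, D, tau))
            H.append(hc.H)
            C.append(hc.C)
        out.append(
            KNoiseReference(
                k=float(k),
                H_ref=float(np.mean(H)),
                C_ref=float(np.mean(C)),
                n_realizations=n_realizations,
                series_length=n,
                seed=seed,
            )
        )
    return out
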