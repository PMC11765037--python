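"""R-wave detection, beat windowing, template acceptance and the RMS gate.

Beats are represented as fixed 512 ms windows of the vector-modulus series
centred on the R wave detected on lead II (256 samples before the R sample,
256 at and after, at 1 kHz).  A median template over candidate beats gates
acceptance by normalized cross-correlation; accepted beats are jitter-
corrected to the best integer-sample lag.  Record-level quality control
measures the high-passed RMS in the 20 ms segment before each Q onset and
excludes the record when the median exceeds the configured limit.

The R detector here is a deliberately simple energy detector (band-pass,
squared derivative, adaptive threshold with refractory period), shipped as
a stand-in for full wavelet-based ECG delineation; exact fiducials can be
supplied through the annotation sidecar instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .preprocess import VectorModulusSeries

__all__ = [
    "BeatSet",
    "detect_r_waves",
    "estimate_q_onsets",
    "extract_windows",
    "build_template",
    "accept_beats",
    "rms_noise_gate",
]

log = logging.getLogger(__name__)

#: physiological inter-beat interval range (seconds) used for flagging
RR_RANGE_S = (0.3, 2.0)


@dataclass(frozen=True)
class BeatSet:
    """Per-beat 512 ms windows of the modulus series with QC metadata."""

    r_samples: np.ndarray  # R-wave sample indices into the source record
    windows: np.ndarray  # (n_beats, window_len) modulus segments, uV
    fs: float
    accepted: np.ndarray | None = None  # bool per beat
    xcorr: np.ndarray | None = None  # max template correlation per beat
    shifts: np.ndarray | None = None  # applied jitter correction (samples)
    q_onsets: np.ndarray | None = None  # Q-point sample indices
    rms_pre_q: np.ndarray | None = None  # pre-Q high-passed RMS, uV
    record_passes_rms: bool | None = None

    @property
    def n_beats(self) -> int:
        return len(self.r_samples)

    @property
    def window_len(self) -> int:
        return self.windows.shape[1] if self.windows.ndim == 2 else 0

    def accepted_windows(self) -> np.ndarray:
        if self.accepted is None:
            return self.windows
        return self.windows[self.accepted]

    def to_frame(self):
        import pandas as pd

        n = self.n_beats

        def col(a, fill=np.nan):
            return a if a is not None else np.full(n, fill)

        return pd.DataFrame(
            {
                "beat": np.arange(n),
                "r_sample": self.r_samples,
                "xcorr": col(self.xcorr),
                "shift": col(self.shifts),
                "q_onset": col(self.q_onsets),
                "rms_pre_q": col(self.rms_pre_q),
                "accepted": col(self.accepted, False),
            }
        )


def _qrs_bandpass(x: np.ndarray, fs: float) -> np.ndarray:
    sos = signal.butter(3, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_r_waves(lead_ii: np.ndarray, fs: float) -> np.ndarray:
    """Detect R-wave sample indices on lead II.

    Band-pass 5-25 Hz, squared derivative, 120 ms moving integration, then
    peak picking with a 250 ms refractory period and an adaptive amplitude
    threshold.  Each detection is refined to the extremum of the band-passed
    signal within +/-60 ms.  Returns an empty array (with a warning) when no
    plausible beats are found.
    """
    x = np.asarray(lead_ii, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("R detection requires at least 2 s of signal")
    bp = _qrs_bandpass(x, fs)
    energy = np.gradient(bp) ** 2
    width = max(int(round(0.12 * fs)), 1)
    integrated = np.convolve(energy, np.ones(width) / width, mode="same")

    peaks, _ = signal.find_peaks(integrated, distance=int(round(0.25 * fs)))
    if peaks.size == 0:
        warnings.warn("no QRS candidates found", stacklevel=2)
        return np.array([], dtype=int)
    # adaptive threshold from the strong-candidate population
    strong = np.quantile(integrated[peaks], 0.75)
    floor = np.median(integrated) if integrated.size else 0.0
    threshold = max(0.2 * strong, 4.0 * floor)
    peaks = peaks[integrated[peaks] > threshold]
    if peaks.size == 0:
        warnings.warn("no QRS candidates above threshold", stacklevel=2)
        return np.array([], dtype=int)

    refine = int(round(0.06 * fs))
    r = []
    for p in peaks:
        lo, hi = max(p - refine, 0), min(p + refine + 1, x.size)
        r.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    r = np.unique(np.asarray(r, dtype=int))

    rr = np.diff(r) / fs
    n_bad = int(np.sum((rr < RR_RANGE_S[0]) | (rr > RR_RANGE_S[1])))
    if n_bad:
        log.warning("%d inter-beat intervals outside %s s", n_bad, RR_RANGE_S)
    return r


def estimate_q_onsets(
    lead_ii: np.ndarray,
    r_samples: np.ndarray,
    fs: float,
    slope_fraction: float = 0.05,
    max_before_ms: float = 80.0,
) -> np.ndarray:
    """Estimate Q onsets as the point where the QRS upslope dies away.

    Walking backwards from each R peak on the band-passed lead II, the Q
    onset is the first sample whose absolute slope falls below
    ``slope_fraction`` of the peak QRS slope, capped at ``max_before_ms``
    before the R sample.
    """
    bp = _qrs_bandpass(np.asarray(lead_ii, dtype=float), fs)
    slope = np.abs(np.gradient(bp))
    cap = int(round(max_before_ms / 1000.0 * fs))
    out = np.empty(len(r_samples), dtype=int)
    for i, r in enumerate(r_samples):
        lo = max(r - cap, 0)
        seg = slope[lo : r + 1]
        if seg.size == 0:
            out[i] = lo
            continue
        ipk = int(np.argmax(seg))  # steepest point of the QRS upstroke
        below = np.nonzero(seg[:ipk] < slope_fraction * seg[ipk])[0]
        out[i] = lo + (below[-1] if below.size else 0)
    return out


def extract_windows(
    modulus: VectorModulusSeries, r_samples: np.ndarray, window_ms: float = 512.0
) -> BeatSet:
    """Cut one fixed-length window of the modulus series per R wave.

    Windows have round(window_ms/1000 * fs) samples: half before the R
    sample and half at-and-after (half-open).  Beats too close to either
    record edge are dropped with a log entry.
    """
    r_samples = np.asarray(r_samples, dtype=int)
    w = int(round(window_ms / 1000.0 * modulus.fs))
    pre = w // 2
    post = w - pre
    n = modulus.n_samples
    keep = (r_samples >= pre) & (r_samples + post <= n)
    if np.any(~keep):
        log.info(
            "dropped %d beat(s) within %d samples of the record edge",
            int(np.sum(~keep)),
            pre,
        )
    kept = r_samples[keep]
    windows = (
        np.stack([modulus.values[r - pre : r + post] for r in kept])
        if kept.size
        else np.empty((0, w))
    )
    return BeatSet(r_samples=kept, windows=windows, fs=modulus.fs)


def build_template(windows: np.ndarray) -> np.ndarray:
    """Samplewise median across candidate beat windows.

    The median (rather than the mean) keeps the template robust to ectopic
    or noisy beats.
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2 or windows.shape[0] < 3:
        raise ValueError("template construction requires at least 3 beats")
    return np.median(windows, axis=0)


def _xcorr_best_lag(w: np.ndarray, template: np.ndarray, max_lag: int):
    """Max normalized (Pearson) correlation over lags within +/-max_lag."""
    best_c, best_lag = -1.0, 0
    n = w.size
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = w[lag:], template[: n - lag]
        else:
            a, b = w[: n + lag], template[-lag:]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            c = 1.0 if sa == sb else 0.0
        else:
            c = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if c > best_c:
            best_c, best_lag = c, lag
    return best_c, best_lag


def accept_beats(
    beat_set: BeatSet,
    template: np.ndarray,
    threshold: float = 0.75,
    max_lag_ms: float = 50.0,
    modulus: VectorModulusSeries | None = None,
) -> BeatSet:
    """Flag beats by template correlation and jitter-correct the accepted.

    Each window is compared with the template by normalized cross-
    correlation maximized over lags within +/-``max_lag_ms``; beats whose
    maximum exceeds ``threshold`` are accepted and shifted by the best
    integer lag.  When the source ``modulus`` series is supplied the
    corrected window is re-extracted from it; otherwise the window is
    shifted with edge padding.  The number of beats never changes.
    """
    template = np.asarray(template, dtype=float)
    if template.size != beat_set.window_len:
        raise ValueError("template length does not match beat windows")
    max_lag = int(round(max_lag_ms / 1000.0 * beat_set.fs))
    n = beat_set.n_beats
    xcorr = np.zeros(n)
    shifts = np.zeros(n, dtype=int)
    accepted = np.zeros(n, dtype=bool)
    windows = beat_set.windows.copy()
    pre = beat_set.window_len // 2
    post = beat_set.window_len - pre
    for i in range(n):
        c, lag = _xcorr_best_lag(beat_set.windows[i], template, max_lag)
        xcorr[i] = c
        if c <= threshold:
            continue
        accepted[i] = True
        shifts[i] = -lag
        if lag == 0:
            continue
        r = beat_set.r_samples[i] - lag
        if modulus is not None and r - pre >= 0 and r + post <= modulus.n_samples:
            windows[i] = modulus.values[r - pre : r + post]
        else:
            rolled = np.roll(beat_set.windows[i], -lag)
            if lag > 0:
                rolled[-lag:] = rolled[-lag - 1]
            else:
                rolled[:-lag] = rolled[-lag]
            windows[i] = rolled
    return replace(
        beat_set, windows=windows, accepted=accepted, xcorr=xcorr, shifts=shifts
    )


def rms_noise_gate(
    beat_set: BeatSet,
    pre_q_ms: float = 20.0,
    limit_uv: float = 20.0,
    hp_freq: float = 40.0,
) -> BeatSet:
    """Measure pre-Q high-frequency noise and gate the whole record.

    For each beat with a known Q onset, the beat window is high-passed at
    ``hp_freq`` and the RMS is taken over the ``pre_q_ms`` segment ending at
    the Q onset.  The record passes when the median per-beat RMS is at or
    below ``limit_uv`` (per-beat values are kept for diagnostics).
    """
    if beat_set.q_onsets is None:
        raise ValueError("Q onsets are required for the RMS noise gate")
    seg = int(round(pre_q_ms / 1000.0 * beat_set.fs))
    pre = beat_set.window_len // 2
    sos = signal.butter(2, hp_freq, btype="highpass", fs=beat_set.fs, output="sos")
    rms = np.full(beat_set.n_beats, np.nan)
    for i in range(beat_set.n_beats):
        q_rel = pre + (beat_set.q_onsets[i] - beat_set.r_samples[i])
        lo = q_rel - seg
        if lo < 0 or q_rel > beat_set.window_len:
            continue
        resid = signal.sosfiltfilt(sos, beat_set.windows[i])
        rms[i] = float(np.sqrt(np.mean(resid[lo:q_rel] ** 2)))
    valid = rms[np.isfinite(rms)]
    passes = bool(valid.size == 0 or np.median(valid) <= limit_uv)
    return replace(beat_set, rms_pre_q=rms, record_passes_rms=passes)
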