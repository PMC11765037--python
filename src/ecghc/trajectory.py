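"""Per-phase entropy-complexity trajectories and their statistics.

Each accepted beat contributes one ordinal PDF, one (H, C, Q) point and one
Jensen-Shannon divergence to the patient's Mean Control PDF (the average
PDF over all control beats).  Quantifiers are averaged in fixed windows
along each phase (30 s during occlusion, 15 s during recovery by default),
relative endpoint changes delta-H and delta-C summarize a trajectory, and
per-section divergences are compared across patients with a normality-gated
t / Mann-Whitney test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .ordinal import (
    HCPoint,
    OrdinalPDF,
    estimate_pdf,
    jensen_shannon_divergence,
    statistical_complexity,
)

__all__ = [
    "PhaseSeries",
    "Trajectory",
    "DeltaMetrics",
    "SectionComparison",
    "mean_control_pdf",
    "per_beat_quantifiers",
    "window_average",
    "delta_metrics",
    "delta_relative",
    "control_sections",
    "compare_sections",
    "control_region",
]

log = logging.getLogger(__name__)

PHASES = ("control", "occlusion", "recovery")


@dataclass(frozen=True)
class PhaseSeries:
    """Per-beat quantifiers for one phase of one record.

    ``beat_times`` are seconds from phase start (non-decreasing); the
    per-beat arrays H, C, Q and jsd are aligned with ``beat_pdfs``.
    """

    phase: str
    beat_times: np.ndarray
    beat_pdfs: tuple[OrdinalPDF, ...]
    H: np.ndarray
    C: np.ndarray
    Q: np.ndarray
    jsd: np.ndarray

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        t = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", t)
        if np.any(np.diff(t) < 0):
            raise ValueError("beat times must be non-decreasing")
        n = t.size
        for name in ("H", "C", "Q", "jsd"):
            a = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, a)
            if a.size != n:
                raise ValueError(f"{name} has {a.size} entries for {n} beats")
        if len(self.beat_pdfs) != n:
            raise ValueError("one PDF per beat is required")

    @property
    def n_beats(self) -> int:
        return self.beat_times.size

    def with_reference(self, reference: OrdinalPDF) -> "PhaseSeries":
        """Recompute per-beat JSD against a (Mean Control) reference PDF."""
        jsd = np.array(
            [jensen_shannon_divergence(p, reference) for p in self.beat_pdfs]
        )
        return replace(self, jsd=jsd)


@dataclass(frozen=True)
class Trajectory:
    """Window-averaged quantifiers along one phase.

    Windows tile the phase at a fixed width; windows without beats carry
    NaN means and n_beats = 0 (they are never interpolated).
    """

    phase: str
    window_centers: np.ndarray  # seconds from phase start
    H_mean: np.ndarray
    C_mean: np.ndarray
    jsd_mean: np.ndarray
    n_beats: np.ndarray

    @property
    def nonempty(self) -> np.ndarray:
        return self.n_beats > 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "phase": self.phase,
                "window_center_s": self.window_centers,
                "H": self.H_mean,
                "C": self.C_mean,
                "JSD": self.jsd_mean,
                "n_beats": self.n_beats,
            }
        )


@dataclass(frozen=True)
class DeltaMetrics:
    """Relative endpoint change (final - initial) / initial per quantifier."""

    delta_H: float
    delta_C: float


@dataclass(frozen=True)
class SectionComparison:
    """Cross-patient comparison of one control/PTCA section pair."""

    section_index: int
    values_a: np.ndarray
    values_b: np.ndarray
    test_used: str  # "t" or "mann-whitney"
    p_value: float
    significant: bool


def mean_control_pdf(control: "PhaseSeries | list[OrdinalPDF]") -> OrdinalPDF:
    """Average the control-beat PDFs componentwise (the Mean Control PDF).

    The arithmetic mean of valid distributions is again a distribution; a
    renormalization guards against accumulated rounding.
    """
    pdfs = control.beat_pdfs if isinstance(control, PhaseSeries) else tuple(control)
    if len(pdfs) < 1:
        raise ValueError("at least one accepted control beat is required")
    probs = np.mean([p.probs for p in pdfs], axis=0)
    probs = probs / probs.sum()
    return OrdinalPDF(
        probs,
        D=pdfs[0].D,
        tau=pdfs[0].tau,
        n_windows=int(sum(p.n_windows for p in pdfs)),
    )


def per_beat_quantifiers(
    windows: np.ndarray,
    beat_times: np.ndarray,
    phase: str,
    D: int = 4,
    tau: int = 2,
    reference: OrdinalPDF | None = None,
) -> PhaseSeries:
    """Compute ordinal PDF, H, C, Q and reference JSD for each beat window.

    ``windows`` holds one modulus segment per accepted beat (a 512-sample
    window yields 506 pattern windows at D = 4, tau = 2).  When no
    ``reference`` is given the JSD column is NaN; attach it later with
    :meth:`PhaseSeries.with_reference` once the Mean Control PDF exists.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    beat_times = np.asarray(beat_times, dtype=float)
    if windows.shape[0] != beat_times.size:
        raise ValueError("one time per beat window is required")
    pdfs, H, C, Q, jsd = [], [], [], [], []
    with warnings.catch_warnings():
        # beat windows are short by design; the sparse-PDF warning would
        # fire on every beat
        warnings.simplefilter("ignore", UserWarning)
        for w in windows:
            pdf = estimate_pdf(w, D, tau)
            hc = statistical_complexity(pdf)
            pdfs.append(pdf)
            H.append(hc.H)
            C.append(hc.C)
            Q.append(hc.Q)
            jsd.append(
                jensen_shannon_divergence(pdf, reference)
                if reference is not None
                else np.nan
            )
    return PhaseSeries(
        phase=phase,
        beat_times=beat_times,
        beat_pdfs=tuple(pdfs),
        H=np.array(H),
        C=np.array(C),
        Q=np.array(Q),
        jsd=np.array(jsd),
    )


def window_average(
    series: PhaseSeries,
    width_s: float,
    phase_duration_s: float | None = None,
    min_final_fraction: float = 0.5,
) -> Trajectory:
    """Average per-beat quantifiers in consecutive [i*w, (i+1)*w) windows.

    The phase is tiled from t = 0; a trailing partial window is kept only
    when the phase covers at least ``min_final_fraction`` of its width
    (otherwise its beats are dropped, with a log entry).
    """
    if width_s <= 0:
        raise ValueError("window width must be positive")
    duration = (
        phase_duration_s
        if phase_duration_s is not None
        else (series.beat_times[-1] if series.n_beats else 0.0)
    )
    n_full = int(duration // width_s)
    remainder = duration - n_full * width_s
    n_windows = n_full + (1 if remainder >= min_final_fraction * width_s else 0)
    n_windows = max(n_windows, 1)
    if remainder > 0 and n_windows == n_full:
        dropped = int(np.sum(series.beat_times >= n_full * width_s))
        if dropped:
            log.info(
                "dropped %d beat(s) in a trailing %.1f s partial window",
                dropped,
                remainder,
            )
    idx = np.floor(series.beat_times / width_s).astype(int)
    centers = (np.arange(n_windows) + 0.5) * width_s
    H = np.full(n_windows, np.nan)
    C = np.full(n_windows, np.nan)
    jsd = np.full(n_windows, np.nan)
    counts = np.zeros(n_windows, dtype=int)
    for i in range(n_windows):
        sel = idx == i
        counts[i] = int(np.sum(sel))
        if counts[i]:
            H[i] = np.mean(series.H[sel])
            C[i] = np.mean(series.C[sel])
            jsd[i] = np.nanmean(series.jsd[sel]) if np.any(np.isfinite(series.jsd[sel])) else np.nan
    return Trajectory(
        phase=series.phase,
        window_centers=centers,
        H_mean=H,
        C_mean=C,
        jsd_mean=jsd,
        n_beats=counts,
    )


def delta_relative(initial: float, final: float) -> float:
    """Signed relative change (final - initial) / initial."""
    if initial == 0:
        raise ZeroDivisionError("relative change undefined for a zero initial value")
    return (final - initial) / initial


def delta_metrics(traj: Trajectory) -> DeltaMetrics:
    """Relative change of H and C between the first and last non-empty windows."""
    idx = np.nonzero(traj.nonempty)[0]
    if idx.size < 2:
        raise ValueError("delta metrics require at least 2 non-empty windows")
    i, f = idx[0], idx[-1]
    return DeltaMetrics(
        delta_H=delta_relative(traj.H_mean[i], traj.H_mean[f]),
        delta_C=delta_relative(traj.C_mean[i], traj.C_mean[f]),
    )


def control_sections(control: PhaseSeries, n_sections: int) -> np.ndarray:
    """Mean control JSD in contiguous equal-duration sections.

    The section count is matched to the number of occlusion (or recovery)
    windows of the patient, e.g. 4 min of occlusion at 30 s windows gives
    8 occlusion windows and hence 8 control sections.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    if control.n_beats == 0:
        return np.full(n_sections, np.nan)
    duration = control.beat_times[-1] + 1e-9
    idx = np.minimum(
        (control.beat_times / duration * n_sections).astype(int), n_sections - 1
    )
    out = np.full(n_sections, np.nan)
    for i in range(n_sections):
        sel = idx == i
        if np.any(sel):
            out[i] = np.nanmean(control.jsd[sel])
    return out


def compare_sections(
    values_a: np.ndarray,
    values_b: np.ndarray,
    section_index: int = 0,
    alpha: float = 0.05,
) -> SectionComparison:
    """Compare per-patient section means between two conditions.

    Both samples are screened with the D'Agostino-Pearson normality test;
    if both are consistent with normality at ``alpha`` a two-tailed
    unpaired Student's t-test is used, otherwise a two-sided Mann-Whitney
    U test.  Samples too small for the normality test (n < 8) fall back to
    the non-parametric branch.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError("at least 3 patients per group are required")

    def _normal(x: np.ndarray) -> bool:
        if x.size < 8:  # skewness test undefined below 8 samples
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stats.normaltest(x).pvalue > alpha

    if _normal(a) and _normal(b) and a.std() > 0 and b.std() > 0:
        test_used = "t"
        p = float(stats.ttest_ind(a, b).pvalue)
    else:
        test_used = "mann-whitney"
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0  # identical samples: no evidence of a shift
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return SectionComparison(
        section_index=section_index,
        values_a=a,
        values_b=b,
        test_used=test_used,
        p_value=p,
        significant=bool(p < alpha),
    )


def control_region(trajectories: "list[Trajectory]") -> tuple[tuple[float, float], tuple[float, float]]:
    """Bounding box ((Hmin, Hmax), (Cmin, Cmax)) of control window means."""
    if not trajectories:
        raise ValueError("at least one control trajectory is required")
    H = np.concatenate([t.H_mean[t.nonempty] for t in trajectories])
    C = np.concatenate([t.C_mean[t.nonempty] for t in trajectories])
    if H.size == 0:
        raise ValueError("control trajectories contain no populated windows")
    return (float(H.min()), float(H.max())), (float(C.min()), float(C.max()))
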