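"""Synthetic phase-structured ECG cohorts for exercising the pipeline.

The generator emulates the study design — a 1 kHz 8-lead recording with a
five-minute control record and a PTCA record with annotated balloon
inflation/deflation — but not ischaemia physiology.  Each beat is a sum of
Gaussian-shaped P/QRS/T components of a three-dimensional cardiac dipole;
the 8 standard leads are obtained through the pseudoinverse of the Kors
matrix, so the analysis-side Kors transform recovers the dipole exactly.
Two qualitative occlusion profiles are provided:

* ``LAD-like`` — the ST-T component rises smoothly through the occlusion,
  merging the beat into a single dome-like waveform (more deterministic
  structure: entropy falls, complexity rises);
* ``RCA-like`` — after a quiescent first segment the T wave flattens and
  the broadband noise grows (more stochastic: entropy rises, complexity
  falls).

During recovery both profiles return to control morphology while the
broadband noise level ramps up moderately, emulating the increasingly
stochastic reperfusion signal.  All amplitudes are in microvolts; the
calibrated defaults live in the packaged YAML config.  Beat-level ground
truth (R times, Q onsets, phase labels, morphology trajectory) is emitted
alongside every record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import generator_defaults
from .preprocess import KORS_MATRIX, KORS_LEADS, MultiLeadECG, PhaseAnnotations

__all__ = [
    "BeatMorph",
    "SyntheticCohortSpec",
    "PatientRecord",
    "generate_synthetic_beat",
    "generate_record",
    "generate_cohort",
]

#: forward lead matrix: minimum-norm dipole-to-lead map consistent with the
#: Kors transform (KORS_MATRIX @ LEAD_FORWARD == identity)
LEAD_FORWARD = np.linalg.pinv(KORS_MATRIX)

# Gaussian beat components per dipole axis: (centre s rel R, width s, amp uV)
_AXIS_COMPONENTS = (
    # X
    (
        (-0.170, 0.025, 60.0),
        (-0.020, 0.008, -100.0),
        (0.000, 0.009, 950.0),
        (0.022, 0.009, -180.0),
    ),
    # Y
    (
        (-0.170, 0.025, 35.0),
        (-0.019, 0.008, -55.0),
        (0.002, 0.010, 520.0),
        (0.024, 0.010, -110.0),
    ),
    # Z
    (
        (-0.165, 0.025, -25.0),
        (-0.020, 0.008, 45.0),
        (0.001, 0.009, -320.0),
        (0.020, 0.009, 90.0),
    ),
)
_T_WAVE = ((0.150, 0.050), (280.0, 170.0, -110.0))  # (centre, width), axis amps
_ST_DOME = ((0.100, 0.070), (0.8, 0.5, -0.4))  # axis weights for st_amp
_Q_ONSET_BEFORE_R_S = 0.030
_BEAT_SUPPORT_S = 0.38  # dipole support on each side of R


@dataclass(frozen=True)
class BeatMorph:
    """Morphology of one beat: ST-T dome amplitude and T-wave scale."""

    st_amp: float = 40.0
    t_scale: float = 1.0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults follow the reference protocol: 24 patients (9 LAD-like,
    15 RCA-like), a 300 s control record, occlusion duration drawn around
    4 min 6 s +/- 90 s and recovery around 3.7 min.
    """

    n_patients: int = 24
    arteries: tuple[str, ...] = ()  # "LAD" / "RCA" per patient
    seed: int = 0
    fs: float = 1000.0
    heart_rate_bpm: float = 70.0
    control_duration_s: float = 300.0
    occlusion_duration_s: float | None = None  # None: sample per patient
    recovery_duration_s: float | None = None
    noise_rms_uv: float | None = None
    wander_amplitude_uv: float | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        arteries = self.arteries
        if not arteries:
            n_lad = round(self.n_patients * 9 / 24)
            arteries = ("LAD",) * n_lad + ("RCA",) * (self.n_patients - n_lad)
        if len(arteries) != self.n_patients:
            raise ValueError("one artery label per patient is required")
        if any(a not in ("LAD", "RCA") for a in arteries):
            raise ValueError("artery labels must be 'LAD' or 'RCA'")
        object.__setattr__(self, "arteries", tuple(arteries))
        for f in ("control_duration_s",):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: control and PTCA records plus ground truth."""

    patient_id: str
    artery: str
    control: MultiLeadECG
    ptca: MultiLeadECG
    control_truth: pd.DataFrame
    ptca_truth: pd.DataFrame


def _dipole_beat(t: np.ndarray, morph: BeatMorph) -> np.ndarray:
    """Dipole contribution (3, len(t)) of one beat at times t rel its R."""
    out = np.zeros((3, t.size))
    for axis, comps in enumerate(_AXIS_COMPONENTS):
        for c, w, a in comps:
            out[axis] += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    (tc, tw), t_amps = _T_WAVE
    for axis, a in enumerate(t_amps):
        out[axis] += morph.t_scale * a * np.exp(-0.5 * ((t - tc) / tw) ** 2)
    (sc, sw), s_wts = _ST_DOME
    for axis, wgt in enumerate(s_wts):
        out[axis] += morph.st_amp * wgt * np.exp(-0.5 * ((t - sc) / sw) ** 2)
    return out


def generate_synthetic_beat(
    morph: BeatMorph, fs: float, pad_s: float = 0.4
) -> tuple[np.ndarray, int, int]:
    """One noise-free 8-lead beat segment with fiducial ground truth.

    Returns ``(segment, r_index, q_index)`` where ``segment`` has shape
    (8, n) spanning ``pad_s`` seconds on each side of the R peak.
    Deterministic given the morphology parameters.
    """
    if fs < 250:
        raise ValueError("beat synthesis requires fs >= 250 Hz")
    n = int(round(2 * pad_s * fs))
    r_index = n // 2
    t = (np.arange(n) - r_index) / fs
    leads = LEAD_FORWARD @ _dipole_beat(t, morph)
    q_index = r_index - int(round(_Q_ONSET_BEFORE_R_S * fs))
    return leads, r_index, q_index


def _phase_profile(artery: str, phase: str, gd: dict):
    """Return morph(u, rng) -> (BeatMorph, noise_rms) for phase fraction u."""
    st0 = gd["st_amp_control_uv"]
    noise0 = gd["noise_rms_uv"]
    morph_cfg = gd["morph"]

    if phase == "control":
        return lambda u, rng: (BeatMorph(st_amp=st0), noise0)

    if phase == "occlusion" and artery == "LAD":
        st_max = morph_cfg["lad_occlusion"]["st_amp_max_uv"]

        def lad(u, rng):
            return BeatMorph(st_amp=st0 + (st_max - st0) * u), noise0

        return lad

    if phase == "occlusion" and artery == "RCA":
        cfg = morph_cfg["rca_occlusion"]

        def rca(u, rng):
            if u < cfg["quiescent_fraction"]:
                return BeatMorph(st_amp=st0), noise0
            v = (u - cfg["quiescent_fraction"]) / (1 - cfg["quiescent_fraction"])
            st = st0 + cfg["st_jitter_max_uv"] * v * rng.standard_normal()
            return (
                BeatMorph(st_amp=st, t_scale=1 - (1 - cfg["t_scale_min"]) * v),
                noise0 + (cfg["noise_rms_max_uv"] - noise0) * v,
            )

        return rca

    if phase == "recovery":
        cfg = morph_cfg["recovery"]
        st_start = cfg["lad_st_amp_start_uv"] if artery == "LAD" else st0

        def rec(u, rng):
            st = st_start + (st0 - st_start) * u
            return BeatMorph(st_amp=st), noise0 + (cfg["noise_rms_max_uv"] - noise0) * u

        return rec

    raise ValueError(f"unknown phase {phase!r} for artery {artery!r}")


def generate_record(
    phases: "list[tuple[str, float]]",
    artery: str,
    rng: np.random.Generator,
    gd: dict | None = None,
    fs: float | None = None,
    heart_rate_bpm: float | None = None,
    noise_rms_uv: float | None = None,
    wander_amplitude_uv: float | None = None,
) -> tuple[MultiLeadECG, pd.DataFrame]:
    """Generate one 8-lead record from an ordered list of (phase, duration).

    Returns the record (with phase annotations) and a beat-level ground
    truth table (R sample, Q onset sample, phase, ST amplitude, T scale).
    """
    gd = dict(gd or generator_defaults())
    fs = fs or gd["fs"]
    hr = heart_rate_bpm or gd["heart_rate_bpm"]
    if noise_rms_uv is not None:
        gd["noise_rms_uv"] = noise_rms_uv
    wander_amp = (
        wander_amplitude_uv
        if wander_amplitude_uv is not None
        else gd["wander_amplitude_uv"]
    )

    # snap phase durations to the sample grid so annotations stay in range
    phases = [(p, round(d * fs) / fs) for p, d in phases]
    total = sum(d for _, d in phases)
    n = int(round(total * fs))
    t_grid = np.arange(n) / fs
    dipole = np.zeros((3, n))
    noise_env = np.full(n, gd["noise_rms_uv"])

    truth_rows = []
    rr_mean = 60.0 / hr
    t_beat = 0.5 * rr_mean
    boundaries = np.cumsum([0.0] + [d for _, d in phases])
    pad = int(round(_BEAT_SUPPORT_S * fs))

    # per-phase noise envelope; the level is a slowly varying deterministic
    # function of the phase fraction, so a coarse grid suffices
    dummy = np.random.default_rng(0)
    for (phase, dur), t0 in zip(phases, boundaries[:-1]):
        profile = _phase_profile(artery, phase, gd)
        i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
        uu = (t_grid[i0:i1] - t0) / dur
        grid_u = np.linspace(0, 1, 33)
        grid_noise = np.array([profile(u, dummy)[1] for u in grid_u])
        noise_env[i0:i1] = np.interp(uu, grid_u, grid_noise)

    while t_beat < total - 0.5 * rr_mean:
        # locate the phase of this beat
        pi = int(np.searchsorted(boundaries, t_beat, side="right") - 1)
        pi = min(pi, len(phases) - 1)
        phase, dur = phases[pi]
        u = (t_beat - boundaries[pi]) / dur
        morph, _ = _phase_profile(artery, phase, gd)(u, rng)

        r_sample = int(round(t_beat * fs))
        lo, hi = max(r_sample - pad, 0), min(r_sample + pad, n)
        tt = (np.arange(lo, hi) - r_sample) / fs
        dipole[:, lo:hi] += _dipole_beat(tt, morph)
        truth_rows.append(
            {
                "r_sample": r_sample,
                "q_sample": r_sample - int(round(_Q_ONSET_BEFORE_R_S * fs)),
                "time_s": t_beat,
                "phase": phase,
                "st_amp_uv": morph.st_amp,
                "t_scale": morph.t_scale,
            }
        )
        t_beat += rr_mean * (1.0 + gd["rr_jitter"] * rng.standard_normal())

    leads = LEAD_FORWARD @ dipole
    # baseline wander, mains interference and broadband noise per lead
    for i in range(leads.shape[0]):
        phase_w = rng.uniform(0, 2 * np.pi)
        leads[i] += wander_amp * np.sin(2 * np.pi * gd["wander_freq_hz"] * t_grid + phase_w)
        leads[i] += gd["line_amplitude_uv"] * np.sin(
            2 * np.pi * gd["line_freq_hz"] * t_grid + rng.uniform(0, 2 * np.pi)
        )
        leads[i] += noise_env * rng.standard_normal(n)

    ann_kwargs: dict = {}
    for (phase, dur), t0 in zip(phases, boundaries[:-1]):
        if phase == "control":
            ann_kwargs["control"] = (t0, t0 + dur)
        elif phase == "occlusion":
            ann_kwargs["inflation"] = t0
            ann_kwargs["deflation"] = t0 + dur
        elif phase == "recovery":
            ann_kwargs["end"] = t0 + dur
    ecg = MultiLeadECG(
        samples=leads,
        lead_names=KORS_LEADS,
        fs=fs,
        annotations=PhaseAnnotations(**ann_kwargs),
    )
    return ecg, pd.DataFrame(truth_rows)


def _sample_duration(rng, mean, sd, lo, hi) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_cohort(spec: SyntheticCohortSpec) -> list[PatientRecord]:
    """Generate the control + PTCA record pair for every patient in a spec.

    Randomness flows from ``spec.seed`` through one spawned stream per
    patient, so cohorts are reproducible and patients independent.
    """
    gd = dict(generator_defaults())
    if spec.noise_rms_uv is not None:
        gd["noise_rms_uv"] = spec.noise_rms_uv
    if spec.wander_amplitude_uv is not None:
        gd["wander_amplitude_uv"] = spec.wander_amplitude_uv

    children = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    cohort = []
    for i, (artery, child) in enumerate(zip(spec.arteries, children)):
        rng = np.random.default_rng(child)
        occl = spec.occlusion_duration_s or _sample_duration(
            rng,
            gd["occlusion_mean_s"],
            gd["occlusion_sd_s"],
            *gd["occlusion_range_s"],
        )
        rec = spec.recovery_duration_s or _sample_duration(
            rng,
            gd["recovery_mean_s"],
            gd["recovery_sd_s"],
            *gd["recovery_range_s"],
        )
        control, control_truth = generate_record(
            [("control", spec.control_duration_s)],
            artery,
            rng,
            gd=gd,
            fs=spec.fs,
            heart_rate_bpm=spec.heart_rate_bpm,
        )
        ptca, ptca_truth = generate_record(
            [("occlusion", occl), ("recovery", rec)],
            artery,
            rng,
            gd=gd,
            fs=spec.fs,
            heart_rate_bpm=spec.heart_rate_bpm,
        )
        cohort.append(
            PatientRecord(
                patient_id=f"P{i + 1:03d}",
                artery=artery,
                control=control,
                ptca=ptca,
                control_truth=control_truth,
                ptca_truth=ptca_truth,
            )
        )
    return cohort
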