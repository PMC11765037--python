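"""Multi-lead ECG preprocessing: notch filter, baseline removal, Kors
transform to orthogonal XYZ leads, and the vectorcardiographic modulus.

All voltages are carried in microvolts end-to-end; callers must convert on
ingest.  The standard pipeline order is notch -> baseline -> Kors ->
modulus.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

__all__ = [
    "PhaseAnnotations",
    "MultiLeadECG",
    "VectorModulusSeries",
    "KORS_LEADS",
    "KORS_MATRIX",
    "notch_filter",
    "remove_baseline",
    "kors_transform",
    "vector_modulus",
]

#: Lead order expected by the Kors regression matrix.
KORS_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Kors regression matrix (rows X, Y, Z; columns in KORS_LEADS order),
#: the published least-squares reconstruction of the orthogonal
#: vectorcardiographic leads from the 8 independent standard leads
#: (Kors et al., Eur Heart J 1990).
KORS_MATRIX = np.array(
    [
        [0.38, -0.07, -0.13, 0.05, -0.01, 0.14, 0.06, 0.54],
        [-0.07, 0.93, 0.06, -0.02, -0.05, 0.06, -0.17, 0.13],
        [0.11, -0.23, -0.43, -0.06, -0.14, -0.20, -0.11, 0.31],
    ]
)


@dataclass(frozen=True)
class PhaseAnnotations:
    """Phase marks in seconds from record start.

    ``control`` delimits the control segment; ``inflation``/``deflation``
    bound the balloon occlusion; ``end`` closes the recovery segment.
    Records covering only a control period leave the balloon fields None.
    """

    control: tuple[float, float] | None = None
    inflation: float | None = None
    deflation: float | None = None
    end: float | None = None

    def __post_init__(self) -> None:
        if self.inflation is not None and self.deflation is not None:
            if not self.inflation < self.deflation:
                raise ValueError("inflation time must precede deflation time")

    def to_dict(self) -> dict:
        d = {}
        if self.control is not None:
            d["control"] = [float(self.control[0]), float(self.control[1])]
        for k in ("inflation", "deflation", "end"):
            v = getattr(self, k)
            if v is not None:
                d[k] = float(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseAnnotations":
        control = tuple(d["control"]) if "control" in d else None
        return cls(
            control=control,
            inflation=d.get("inflation"),
            deflation=d.get("deflation"),
            end=d.get("end"),
        )


@dataclass(frozen=True)
class MultiLeadECG:
    """Uniformly sampled multi-lead voltage record.

    ``samples`` has shape (n_leads, n_samples) in microvolts; ``lead_names``
    labels the rows; ``fs`` is the sampling rate in Hz.
    """

    samples: np.ndarray
    lead_names: tuple[str, ...]
    fs: float
    annotations: PhaseAnnotations | None = None

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "lead_names", tuple(self.lead_names))
        if s.shape[0] != len(self.lead_names):
            raise ValueError(
                f"{s.shape[0]} signal rows for {len(self.lead_names)} lead names"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.annotations is not None:
            dur = s.shape[1] / self.fs
            for name in ("inflation", "deflation", "end"):
                t = getattr(self.annotations, name)
                if t is not None and not (0 <= t <= dur + 1e-9):
                    raise ValueError(f"annotation {name}={t}s outside record [0, {dur}]s")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.lead_names.index(name)]
        except ValueError:
            raise KeyError(f"lead {name!r} not in record (has {self.lead_names})")


@dataclass(frozen=True)
class VectorModulusSeries:
    """Samplewise magnitude of the XYZ vectorcardiogram, in microvolts."""

    values: np.ndarray
    fs: float
    annotations: PhaseAnnotations | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v < 0):
            raise ValueError("vector modulus values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.size


def notch_filter(ecg: MultiLeadECG, line_freq: float = 60.0, half_width: float = 1.0) -> MultiLeadECG:
    """Suppress power-line interference with a 2nd-order Butterworth band-stop.

    The stop band spans ``line_freq`` +/- ``half_width`` Hz and is applied
    forward-backward (zero phase).  ``line_freq`` is configurable for 50 Hz
    mains datasets.
    """
    if ecg.fs <= 2 * line_freq:
        raise ValueError(
            f"sampling rate {ecg.fs} Hz too low to notch {line_freq} Hz"
        )
    sos = signal.butter(
        2,
        [line_freq - half_width, line_freq + half_width],
        btype="bandstop",
        fs=ecg.fs,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, ecg.samples, axis=1)
    return replace(ecg, samples=filtered)


def remove_baseline(
    ecg: MultiLeadECG, knots: np.ndarray, est_window_ms: float = 20.0
) -> MultiLeadECG:
    """Subtract a cubic-spline baseline anchored at per-beat fiducials.

    ``knots`` are sample indices of isoelectric points (one per beat,
    conventionally the midpoint of the 20 ms pre-Q segment).  The baseline
    estimate at each knot is the median voltage in a ``est_window_ms``
    window centred there; a cubic spline through the estimates is
    subtracted per lead, held constant beyond the outermost knots.
    """
    knots = np.asarray(knots, dtype=int)
    if knots.size < 4:
        raise ValueError("baseline removal requires at least 4 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    if knots[0] < 0 or knots[-1] >= ecg.n_samples:
        raise ValueError("knots outside record bounds")
    half = max(int(round(est_window_ms / 2000.0 * ecg.fs)), 1)
    out = np.empty_like(ecg.samples)
    t = np.arange(ecg.n_samples, dtype=float)
    for i, row in enumerate(ecg.samples):
        est = np.array(
            [np.median(row[max(k - half, 0) : k + half + 1]) for k in knots]
        )
        spline = CubicSpline(knots.astype(float), est, bc_type="not-a-knot")
        baseline = spline(np.clip(t, knots[0], knots[-1]))
        out[i] = row - baseline
    return replace(ecg, samples=out)


def kors_transform(ecg: MultiLeadECG, matrix: np.ndarray | None = None) -> MultiLeadECG:
    """Map the 8 independent standard leads to orthogonal X, Y, Z leads.

    Applies the Kors regression matrix samplewise.  Raises if any of the
    leads I, II, V1..V6 is absent; extra leads are ignored.
    """
    missing = [name for name in KORS_LEADS if name not in ecg.lead_names]
    if missing:
        raise ValueError(f"Kors transform requires leads {missing} (absent)")
    K = KORS_MATRIX if matrix is None else np.asarray(matrix, dtype=float)
    stack = np.vstack([ecg.lead(name) for name in KORS_LEADS])
    return replace(ecg, samples=K @ stack, lead_names=("X", "Y", "Z"))


def vector_modulus(xyz: MultiLeadECG) -> VectorModulusSeries:
    """Samplewise Euclidean magnitude M = sqrt(X^2 + Y^2 + Z^2)."""
    for name in ("X", "Y", "Z"):
        if name not in xyz.lead_names:
            raise ValueError(f"vector modulus requires lead {name!r}")
    stack = np.vstack([xyz.lead(n) for n in ("X", "Y", "Z")])
    return VectorModulusSeries(
        values=np.sqrt(np.sum(stack * stack, axis=0)),
        fs=xyz.fs,
        annotations=xyz.annotations,
    )
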