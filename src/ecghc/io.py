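"""Plain-text record I/O.

Records travel as CSV (first column ``time`` in seconds, one column per
lead in microvolts, header row of lead names) with a JSON sidecar carrying
the phase annotations in seconds — ``{"control": [t0, t1], "inflation": t2,
"deflation": t3, "end": t4}`` — and optionally exact fiducials
(``r_samples`` / ``q_samples``, 0-based sample indices) that bypass the
built-in detector.  The synthetic generator writes the same formats the
readers consume.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import MultiLeadECG, PhaseAnnotations

__all__ = [
    "read_record_csv",
    "write_record_csv",
    "read_sidecar",
    "write_sidecar",
    "sidecar_path",
]


def sidecar_path(record_path) -> Path:
    return Path(record_path).with_suffix(".json")


def read_record_csv(path, sidecar: bool = True) -> MultiLeadECG:
    """Read a multi-lead record from the plain CSV dialect.

    The sampling rate is inferred from the median time step.  When a
    sidecar JSON exists next to the file (same stem, ``.json``) its phase
    annotations are attached.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one lead")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.median(np.diff(t))
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError(f"{path}: time column is not strictly increasing")
    annotations = None
    if sidecar and sidecar_path(path).exists():
        annotations, _, _ = read_sidecar(sidecar_path(path))
    return MultiLeadECG(
        samples=df.iloc[:, 1:].to_numpy(dtype=float).T,
        lead_names=tuple(df.columns[1:]),
        fs=1.0 / dt,
        annotations=annotations,
    )


def write_record_csv(ecg: MultiLeadECG, path, float_format: str = "%.1f") -> None:
    """Write a record (and its annotation sidecar, if any) as CSV + JSON.

    ``float_format`` controls the lead voltages only; the time column keeps
    full sample-period precision so the rate survives the round trip.
    """
    t = np.arange(ecg.n_samples) / ecg.fs
    df = pd.DataFrame({"time": [f"{x:.6f}" for x in t]})
    for name, row in zip(ecg.lead_names, ecg.samples):
        df[name] = row
    df.to_csv(path, index=False, float_format=float_format)
    if ecg.annotations is not None:
        write_sidecar(sidecar_path(path), ecg.annotations)


def read_sidecar(path):
    """Read the sidecar JSON.

    Returns ``(annotations, r_samples, q_samples)``; the fiducial arrays
    are None when not supplied.
    """
    with open(path) as fh:
        d = json.load(fh)
    ann = PhaseAnnotations.from_dict(d)
    r = np.asarray(d["r_samples"], dtype=int) if "r_samples" in d else None
    q = np.asarray(d["q_samples"], dtype=int) if "q_samples" in d else None
    return ann, r, q


def write_sidecar(
    path,
    annotations: PhaseAnnotations,
    r_samples=None,
    q_samples=None,
) -> None:
    d = annotations.to_dict()
    if r_samples is not None:
        d["r_samples"] = [int(x) for x in r_samples]
    if q_samples is not None:
        d["q_samples"] = [int(x) for x in q_samples]
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)
        fh.write("\n")
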