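"""Trace and trial-set serialization.

Traces travel as raw little-endian float64 binary plus a JSON metadata
sidecar (``<stem>.json`` next to the binary) carrying at least the
sampling rate, or as one-column delimited text. Phase trial sets are
one-column CSV of degrees.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .circstats import wrap_angle
from .synthgen import SyntheticTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_trace_text",
    "read_trace_text",
    "write_phase_trials",
    "read_phase_trials",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: SyntheticTrace, path) -> None:
    """Write samples as little-endian float64 plus a JSON sidecar."""
    path = Path(path)
    trace.samples.astype("<f8").tofile(path)
    meta = {"fs": trace.fs, "n_samples": len(trace.samples), "seed": trace.seed}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trace(path) -> SyntheticTrace:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    samples = np.fromfile(path, dtype="<f8")
    if len(samples) != meta["n_samples"]:
        raise ValueError(
            f"{path}: expected {meta['n_samples']} samples, found {len(samples)}")
    return SyntheticTrace(samples=samples, fs=float(meta["fs"]),
                          seed=meta.get("seed"))


def write_trace_text(trace: SyntheticTrace, path) -> None:
    """One sample per line; the sampling rate rides in a header comment."""
    np.savetxt(path, trace.samples, header=f"fs={trace.fs}")


def read_trace_text(path, fs: Optional[float] = None) -> SyntheticTrace:
    path = Path(path)
    if fs is None:
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("fs=")[1])
        else:
            raise ValueError(f"{path}: no fs header; pass fs explicitly")
    return SyntheticTrace(samples=np.loadtxt(path), fs=fs)


def write_phase_trials(angles_deg, path) -> None:
    np.savetxt(path, wrap_angle(np.asarray(angles_deg, dtype=float)),
               header="phase_deg")


def read_phase_trials(path) -> np.ndarray:
    return wrap_angle(np.atleast_1d(np.loadtxt(path)))
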