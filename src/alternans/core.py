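"""Core containers and file I/O for single-lead ECG tracings.

Amplitudes are microvolts (µV) everywhere in memory and in files; time is
seconds; sample indices are 0-based integers.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EcgTracing",
    "Fiducials",
    "read_tracing_csv",
    "write_tracing_csv",
    "read_sidecar",
    "write_sidecar",
    "read_wfdb_record",
]


@dataclass(frozen=True)
class EcgTracing:
    """A uniformly sampled single-lead voltage series.

    Parameters
    ----------
    samples
        Voltage series in µV.
    fs
        Sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ValueError("tracing must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("tracing contains non-finite samples")

    @property
    def length_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.length_samples / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.length_samples) / self.fs


@dataclass(frozen=True)
class Fiducials:
    """Per-beat QRS reference sample indices and RR intervals.

    ``rr_ms[i]`` is the interval from beat ``i`` to beat ``i+1``; the last
    beat inherits the preceding interval so every beat has an RR value.
    """

    qrs_sample: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        qrs = np.asarray(self.qrs_sample, dtype=int)
        rr = np.asarray(self.rr_ms, dtype=float)
        object.__setattr__(self, "qrs_sample", qrs)
        object.__setattr__(self, "rr_ms", rr)
        if qrs.size != rr.size:
            raise ValueError("qrs_sample and rr_ms must have equal length")
        if qrs.size > 1 and not np.all(np.diff(qrs) > 0):
            raise ValueError("qrs_sample must be strictly increasing")
        if np.any(rr <= 0):
            raise ValueError("rr_ms must be positive")

    @property
    def n_beats(self) -> int:
        return int(self.qrs_sample.size)

    @classmethod
    def from_samples(cls, qrs_sample: np.ndarray, fs: float) -> "Fiducials":
        """Build fiducials from QRS sample indices, deriving RR intervals."""
        qrs = np.asarray(qrs_sample, dtype=int)
        if qrs.size < 2:
            raise ValueError("at least two beats are required to derive RR")
        rr = np.diff(qrs) / fs * 1000.0
        rr = np.append(rr, rr[-1])
        return cls(qrs, rr)


# ---------------------------------------------------------------------------
# CSV tracing files: comma-separated, header ``time_s,amplitude_uv``, '.'
# decimal, UTF-8.  A JSON sidecar carries the sampling rate, ground-truth
# fiducials and (for simulated tracings) the true alternans sequence.
# ---------------------------------------------------------------------------

def write_tracing_csv(path: str | Path, tracing: EcgTracing) -> None:
    df = pd.DataFrame({"time_s": tracing.time_s, "amplitude_uv": tracing.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_tracing_csv(path: str | Path, fs: float | None = None) -> EcgTracing:
    """Read a ``time_s,amplitude_uv`` CSV.

    The sampling rate is taken from ``fs`` if given, otherwise inferred from
    the median time step of the file.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude_uv"):
        if col not in df.columns:
            raise ValueError(f"tracing CSV must have a '{col}' column")
    if fs is None:
        dt = np.median(np.diff(df["time_s"].to_numpy()))
        if not dt > 0:
            raise ValueError("cannot infer sampling rate from time column")
        fs = float(round(1.0 / dt))
    return EcgTracing(df["amplitude_uv"].to_numpy(dtype=float), fs)


def write_sidecar(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=1, default=_default))


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_wfdb_record(path: str | Path, lead: str | int = 0) -> EcgTracing:
    """Optional PhysioNet-format reader hook (requires the ``wfdb`` package).

    ``lead`` selects a signal by name or index.  Amplitudes are converted
    from the record's physical units (assumed mV) to µV.
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - exercised only without wfdb
        raise RuntimeError(
            "reading PhysioNet records requires the optional 'wfdb' package"
        ) from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover
    names = list(rec.sig_name)  # pragma: no cover
    idx = names.index(lead) if isinstance(lead, str) else int(lead)  # pragma: no cover
    return EcgTracing(rec.p_signal[:, idx] * 1000.0, float(rec.fs))  # pragma: no cover
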