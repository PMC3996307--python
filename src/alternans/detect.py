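"""Qualitative TWA detection via the alternans correlation index (ACI).

Each aligned T wave is compared to the median template with a normalized
dot product:

    ACI_i = Σ_j T_i(j)·T_m(j) / Σ_j T_m(j)²

An identical wave scores exactly 1; a wave scaled by c scores c.  TWA shows
up as a strict beat-to-beat oscillation of the ACI series (not necessarily
around 1).  An alternans episode is a maximal run of beats whose successive
ACI differences strictly alternate in sign and all exceed a magnitude
threshold, lasting at least ``min_run_beats`` beats.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TWaveMatrix

__all__ = ["AciSeries", "DetectionConfig", "AlternansEpisode", "compute_aci",
           "detect_episodes"]


@dataclass(frozen=True)
class AciSeries:
    """Per-beat alternans correlation indices (dimensionless)."""

    values: np.ndarray
    beat_index: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "beat_index", np.asarray(self.beat_index, dtype=int))
        if not np.all(np.isfinite(v)):
            raise ValueError("ACI series contains non-finite values")

    @property
    def n_beats(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class DetectionConfig:
    """Episode detection thresholds.

    ``th_aci`` is the local threshold of the underlying correlation method;
    ``alternation_min`` (its published value is 2·th_aci = 0.12) is the
    minimum magnitude every successive ACI difference inside an episode must
    exceed; ``min_run_beats`` is the minimum episode length.
    """

    th_aci: float = 0.06
    alternation_min: float = 0.12
    min_run_beats: int = 7

    def __post_init__(self) -> None:
        if self.th_aci < 0 or self.alternation_min < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_run_beats < 2:
            raise ValueError("min_run_beats must be at least 2")


@dataclass(frozen=True)
class AlternansEpisode:
    """A detected alternating run, as inclusive row indices into the
    ACI series / T-wave matrix.  The first beat defines the odd (A) phase."""

    start_beat: int
    end_beat: int

    def __post_init__(self) -> None:
        if self.end_beat < self.start_beat:
            raise ValueError("end_beat must be >= start_beat")

    @property
    def n_beats(self) -> int:
        return self.end_beat - self.start_beat + 1


def compute_aci(matrix: TWaveMatrix) -> AciSeries:
    """ACI of every aligned wave against the median template."""
    tm = matrix.template
    if tm is None:
        from .preprocess import median_template

        tm = median_template(matrix.waves)
    denom = float(np.dot(tm, tm))
    if denom == 0.0:
        raise ValueError("median template is identically zero")
    return AciSeries(matrix.waves @ tm / denom, matrix.beat_index)


def detect_episodes(aci: AciSeries, cfg: DetectionConfig | None = None) -> list[AlternansEpisode]:
    """Maximal strictly-alternating runs of the ACI series.

    A run covers beats whose successive differences alternate in sign with
    every ``|ΔACI| > alternation_min``; runs shorter than ``min_run_beats``
    are discarded.  When alternation breaks on a non-zero difference, that
    difference may seed the next run; returned episodes are nevertheless
    disjoint (an overlapping start is trimmed forward by one beat) and
    sorted.
    """
    cfg = cfg or DetectionConfig()
    v = aci.values
    n = v.size
    if n < cfg.min_run_beats:
        return []
    runs: list[tuple[int, int]] = []
    rs, prev_sign = 0, 0
    for k in range(1, n):
        d = v[k] - v[k - 1]
        sg = 0 if abs(d) <= cfg.alternation_min else (1 if d > 0 else -1)
        if sg != 0 and (prev_sign == 0 or sg == -prev_sign):
            prev_sign = sg
            continue
        runs.append((rs, k - 1))
        if sg != 0:  # this difference can start the next run
            rs, prev_sign = k - 1, sg
        else:
            rs, prev_sign = k, 0
    runs.append((rs, n - 1))

    episodes: list[AlternansEpisode] = []
    prev_end = -1
    for s, e in runs:
        s = max(s, prev_end + 1)
        if e - s + 1 >= cfg.min_run_beats:
            episodes.append(AlternansEpisode(s, e))
            prev_end = e
    return episodes
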