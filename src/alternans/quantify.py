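"""Quantitative TWA estimation from detected episodes.

The beats of an episode are split by parity into odd (A) and even (B)
T-wave matrices.  Each column (sample position) of each matrix is screened
for outlying beats: the column is cut into 7-beat epochs, a least-squares
line in the beat index is fitted per epoch, and while the largest absolute
deviation θ is at least 3·θ̄ (and at least 2 µV) the offending point is
replaced by the column mean and the epoch refitted.  Local TWA for beat
pair k is the maximum absolute sample difference between the corrected odd
and even waves; the segment TWA is the mean of its local TWAs and the
global TWA the mean over segments.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig, logger
from .detect import AlternansEpisode
from .preprocess import TWaveMatrix

__all__ = [
    "OddEvenMatrices",
    "EpochFit",
    "CorrectionState",
    "TwaEstimate",
    "split_odd_even",
    "fit_epoch",
    "correct_column",
    "correct_matrix",
    "local_twa",
    "aggregate",
    "quantify_episodes",
]


@dataclass(frozen=True)
class OddEvenMatrices:
    """Odd (A) and even (B) T-wave matrices of one episode, in µV."""

    ta: np.ndarray
    tb: np.ndarray

    def __post_init__(self) -> None:
        if abs(self.ta.shape[0] - self.tb.shape[0]) > 1:
            raise ValueError("odd/even row counts may differ by at most 1")
        if self.ta.shape[1] != self.tb.shape[1]:
            raise ValueError("odd/even matrices must have equal column counts")

    @property
    def m(self) -> int:
        """Paired-beat count."""
        return min(self.ta.shape[0], self.tb.shape[0])

    @property
    def n(self) -> int:
        return int(self.ta.shape[1])


@dataclass(frozen=True)
class EpochFit:
    """First-degree polynomial fit of one epoch of a column."""

    a: float              # slope, µV per beat index
    b: float              # intercept, µV (0-based index)
    theta: np.ndarray     # per-point absolute deviations, µV
    theta_bar: float      # mean deviation, µV


@dataclass(frozen=True)
class CorrectionState:
    column_mean: np.ndarray | float
    replaced_count: int
    iterations: int
    capped: bool = False


@dataclass(frozen=True)
class TwaEstimate:
    """Local / segment / global TWA amplitudes (µV, all non-negative)."""

    episodes: tuple
    local_twa: tuple            # one array of TWA(k) per episode
    segment_twa: np.ndarray     # per-episode mean
    global_twa: float
    detected: bool
    beat_index: np.ndarray | None = None
    replaced_count: int = 0


def split_odd_even(matrix: TWaveMatrix, episode: AlternansEpisode) -> OddEvenMatrices:
    """Label episode beats alternately A (odd position) and B (even).

    Positions are relative to the episode: its first beat is odd/A.
    """
    if episode.n_beats < 2:
        raise ValueError("episode must span at least 2 beats")
    if episode.end_beat >= matrix.n_beats:
        raise ValueError("episode extends past the T-wave matrix")
    rows = matrix.waves[episode.start_beat : episode.end_beat + 1]
    return OddEvenMatrices(ta=rows[0::2], tb=rows[1::2])


def fit_epoch(values: np.ndarray) -> EpochFit:
    """Ordinary least-squares line of epoch values against beat index.

    A 2-point epoch fits exactly (θ = 0).
    """
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("epoch needs at least 2 points")
    x = np.arange(y.size, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    a = float(np.sum((x - xm) * (y - ym)) / sxx)
    b = float(ym - a * xm)
    theta = np.abs(y - (a * x + b))
    return EpochFit(a, b, theta, float(theta.mean()))


def _epoch_slices(m: int, epoch_len: int, min_remainder: int) -> list[slice]:
    """Cut ``m`` beats into epochs of ``epoch_len``.

    A final short block of fewer than ``min_remainder`` points is merged
    into the previous epoch (tiny epochs fit exactly and would disable the
    outlier rule); a remainder of at least ``min_remainder`` stands alone.
    """
    bounds = list(range(0, m, epoch_len)) + [m]
    sl = [[bounds[i], bounds[i + 1]] for i in range(len(bounds) - 1)]
    if len(sl) > 1 and sl[-1][1] - sl[-1][0] < min_remainder:
        sl[-2][1] = sl[-1][1]
        sl.pop()
    return [slice(a, b) for a, b in sl]


def correct_column(
    column: np.ndarray,
    column_mean: float | None = None,
    floor_uv: float = PipelineConfig.theta_floor_uv,
    factor: float = PipelineConfig.theta_factor,
    epoch_len: int = PipelineConfig.epoch_len,
    min_remainder: int = PipelineConfig.min_epoch_remainder,
    cap: int = PipelineConfig.correction_cap,
) -> tuple[np.ndarray, CorrectionState]:
    """Epoch-wise outlier replacement for one column of an odd/even matrix.

    In every pass each epoch whose maximum deviation satisfies both
    ``max θ ≥ factor·θ̄`` and ``max θ ≥ floor_uv`` has that point replaced
    by the column mean T̄(k); passes repeat until no epoch triggers or
    ``cap`` passes have run (hitting the cap is reported in the state, not
    fatal).  T̄(k) is re-evaluated from the current column at the start of
    every pass — with a frozen mean the stop rule need not converge, since
    a gross outlier inflates the very mean meant to replace it.
    ``column_mean`` optionally overrides T̄(k) for the first pass.
    """
    col = np.asarray(column, dtype=float).copy()
    if col.size < 2:
        raise ValueError("column needs at least 2 points")
    slices = _epoch_slices(col.size, epoch_len, min_remainder)
    replaced = 0
    it = 0
    capped = False
    cmean = float(col.mean()) if column_mean is None else float(column_mean)
    while True:
        if it >= cap:
            capped = True
            logger.warning("correction iteration cap (%d) reached", cap)
            break
        if it > 0:
            cmean = float(col.mean())
        it += 1
        fired = False
        for sl in slices:
            fit = fit_epoch(col[sl])
            mx = fit.theta.max()
            if mx >= factor * fit.theta_bar and mx >= floor_uv:
                col[sl.start + int(np.argmax(fit.theta))] = cmean
                replaced += 1
                fired = True
        if not fired:
            break
    return col, CorrectionState(cmean, replaced, it, capped)


def correct_matrix(
    mat: np.ndarray,
    floor_uv: float = PipelineConfig.theta_floor_uv,
    factor: float = PipelineConfig.theta_factor,
    epoch_len: int = PipelineConfig.epoch_len,
    min_remainder: int = PipelineConfig.min_epoch_remainder,
    cap: int = PipelineConfig.correction_cap,
) -> tuple[np.ndarray, CorrectionState]:
    """Apply :func:`correct_column` to every column independently.

    Vectorized across columns; the result is identical to looping
    :func:`correct_column` over columns with the original column means.
    """
    M = np.asarray(mat, dtype=float).copy()
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("matrix needs at least 2 rows")
    m, _ = M.shape
    slices = _epoch_slices(m, epoch_len, min_remainder)
    xs = {sl.start: np.arange(sl.stop - sl.start, dtype=float) for sl in slices}
    replaced = 0
    it = 0
    capped = False
    cmean = M.mean(axis=0)
    active = np.ones(M.shape[1], dtype=bool)  # columns that may still fire
    while active.any():
        if it >= cap:
            capped = True
            logger.warning("correction iteration cap (%d) reached", cap)
            break
        it += 1
        cmean = M.mean(axis=0)  # T̄(k) re-evaluated each pass
        fired = np.zeros(M.shape[1], dtype=bool)
        for sl in slices:
            Y = M[sl, :]
            x = xs[sl.start]
            xm = x.mean()
            sxx = np.sum((x - xm) ** 2)
            ym = Y.mean(axis=0)
            a = (x - xm) @ (Y - ym) / sxx
            theta = np.abs(Y - (np.outer(x, a) + (ym - a * xm)))
            mx = theta.max(axis=0)
            tb = theta.mean(axis=0)
            hit = active & (mx >= factor * tb) & (mx >= floor_uv)
            if hit.any():
                rows = np.argmax(theta[:, hit], axis=0)
                M[sl.start + rows, np.nonzero(hit)[0]] = cmean[hit]
                replaced += int(hit.sum())
                fired |= hit
        active &= fired
    return M, CorrectionState(cmean, replaced, it, capped)


def local_twa(
    ta_row: np.ndarray,
    tb_row: np.ndarray,
    t_onset_idx: int | None = None,
    t_offset_idx: int | None = None,
) -> float:
    """Maximum absolute sample difference between a corrected A/B wave pair
    over ``[t_onset_idx, t_offset_idx]`` (inclusive; defaults to the full
    window)."""
    ta = np.asarray(ta_row, dtype=float)
    tb = np.asarray(tb_row, dtype=float)
    if ta.shape != tb.shape:
        raise ValueError("A and B rows must have the same length")
    lo = 0 if t_onset_idx is None else int(t_onset_idx)
    hi = ta.size - 1 if t_offset_idx is None else int(t_offset_idx)
    if hi < lo or lo < 0 or hi >= ta.size:
        raise ValueError(f"empty or out-of-range [{lo}, {hi}]")
    return float(np.max(np.abs(ta[lo : hi + 1] - tb[lo : hi + 1])))


def aggregate(
    local_twas: list[np.ndarray],
    episodes: list[AlternansEpisode],
    beat_index: np.ndarray | None = None,
    replaced_count: int = 0,
) -> TwaEstimate:
    """Segment TWA per episode (mean of local TWAs), global TWA (mean over
    segments; 0 with an explicit not-detected flag when there is none)."""
    seg = np.array([np.mean(lt) for lt in local_twas], dtype=float)
    detected = len(local_twas) > 0
    return TwaEstimate(
        episodes=tuple(episodes),
        local_twa=tuple(np.asarray(lt, dtype=float) for lt in local_twas),
        segment_twa=seg,
        global_twa=float(seg.mean()) if detected else 0.0,
        detected=detected,
        beat_index=beat_index,
        replaced_count=replaced_count,
    )


def quantify_episodes(
    matrix: TWaveMatrix,
    episodes: list[AlternansEpisode],
    cfg: PipelineConfig | None = None,
) -> TwaEstimate:
    """Correction + local/segment/global TWA for every detected episode."""
    cfg = cfg or PipelineConfig()
    locals_: list[np.ndarray] = []
    kept: list[AlternansEpisode] = []
    replaced = 0
    for ep in episodes:
        oe = split_odd_even(matrix, ep)
        m = oe.m
        if m < 1:
            continue
        ca, sa = correct_matrix(oe.ta[:m], cfg.theta_floor_uv, cfg.theta_factor,
                                cfg.epoch_len, cfg.min_epoch_remainder,
                                cfg.correction_cap)
        cb, sb = correct_matrix(oe.tb[:m], cfg.theta_floor_uv, cfg.theta_factor,
                                cfg.epoch_len, cfg.min_epoch_remainder,
                                cfg.correction_cap)
        replaced += sa.replaced_count + sb.replaced_count
        tw = np.array([
            local_twa(ca[k], cb[k], cfg.t_onset_idx, cfg.t_offset_idx)
            for k in range(m)
        ])
        locals_.append(tw)
        kept.append(ep)
    return aggregate(locals_, kept, beat_index=matrix.beat_index,
                     replaced_count=replaced)
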