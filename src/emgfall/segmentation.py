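"""Active-segment extraction by mean short-term energy thresholding.

The detection statistic is the mean short-term energy of disjoint n-point
windows, E_k = (1/n) * sum(x_i^2). Static onset/offset thresholds (STS, STE)
are calibrated from manually segmented intervals: the mean ratio between the
energy at the annotated boundary and the interval's peak energy, scaled by
the peak energy observed on held-out ("rest") data.

A segment opens at window k when

* E_k > STS,
* the mean of the preceding ``l`` energies is below E_k (rising edge), and
* the mean of the following ``m`` energies exceeds STS (sustained activity),

and closes at the first later window with E_k < STE whose following ``l``
energies average below E_k (decaying edge). The look-back/look-ahead counts
derive from the sampling rate and window size: l = fs/(2n) rounded
half-to-even, and m the rounded midpoint of the open interval
(fs/(2n), fs/n). At fs = 1500 Hz and n = 100 this gives l = 8, m = 11.

Multichannel recordings are reduced to one decision signal by the
root-sum-of-squares across channels, so the combined energy is the sum of
per-channel energies and no per-channel conflict resolution is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ActiveSegment, EmgRecording

__all__ = [
    "EnergySeries",
    "ThresholdCalibration",
    "SegmentationParams",
    "short_term_energy",
    "combine_channels",
    "calibrate_thresholds",
    "calibrate_dataset",
    "segmentation_params",
    "detect_segments",
]


@dataclass(frozen=True)
class EnergySeries:
    """Mean short-term energy per window, with the window grid that produced it."""

    values: np.ndarray  # E_k >= 0, one per window
    window_size: int  # n samples per window
    hop: int  # samples between window starts

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("energies must be non-negative")

    def window_start(self, k: int) -> int:
        return k * self.hop

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ThresholdCalibration:
    """Static thresholds and the ratios/peak they were built from."""

    sts: float
    ste: float
    ratio_start: float
    ratio_end: float
    ek_max: float


@dataclass(frozen=True)
class SegmentationParams:
    """Look-back count l, look-ahead count m, and the window grid."""

    l: int
    m: int
    n: int
    fs_hz: float


def short_term_energy(signal: np.ndarray, n: int = 100, hop: int | None = None) -> EnergySeries:
    """Mean of squared samples over n-point windows spaced ``hop`` apart.

    The default hop equals ``n`` (disjoint blocks). A trailing partial
    window is dropped.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("short_term_energy expects a single-channel signal")
    if n < 1:
        raise ValueError("window size n must be >= 1")
    if len(signal) < n:
        raise ValueError(f"signal length {len(signal)} shorter than window n={n}")
    hop = n if hop is None else hop
    if hop < 1:
        raise ValueError("hop must be >= 1")
    n_windows = (len(signal) - n) // hop + 1
    starts = np.arange(n_windows) * hop
    idx = starts[:, None] + np.arange(n)[None, :]
    values = np.mean(signal[idx] ** 2, axis=1)
    return EnergySeries(values=values, window_size=n, hop=hop)


def combine_channels(rec: EmgRecording) -> np.ndarray:
    """Root-sum-of-squares across channels, one value per sample."""
    return np.sqrt(np.sum(rec.samples**2, axis=1))


def calibrate_thresholds(
    calibration: list[tuple[EnergySeries, int, int]],
    holdout_ek_max: float,
) -> ThresholdCalibration:
    """Derive STS/STE from annotated intervals plus a held-out energy peak.

    Parameters
    ----------
    calibration : list of (EnergySeries, start_window, end_window)
        Each entry is the energy series of one manually segmented recording
        together with the window indices of the annotated onset and offset.
        The peak used in each ratio is the maximum energy inside
        ``[start_window, end_window]``.
    holdout_ek_max : float
        Maximum mean short-term energy over the rest of the cohort's data.
    """
    if not calibration:
        raise ValueError("calibration set is empty")
    start_ratios, end_ratios = [], []
    for series, k_start, k_end in calibration:
        vals = np.asarray(series.values)
        if not (0 <= k_start <= k_end < len(vals)):
            raise ValueError("annotated windows outside energy series")
        peak = float(np.max(vals[k_start : k_end + 1]))
        if peak <= 0:
            raise ValueError("calibration interval has zero peak energy")
        start_ratios.append(vals[k_start] / peak)
        end_ratios.append(vals[k_end] / peak)
    ratio_start = float(np.mean(start_ratios))
    ratio_end = float(np.mean(end_ratios))
    return ThresholdCalibration(
        sts=ratio_start * holdout_ek_max,
        ste=ratio_end * holdout_ek_max,
        ratio_start=ratio_start,
        ratio_end=ratio_end,
        ek_max=float(holdout_ek_max),
    )


def segmentation_params(fs_hz: float, n: int = 100) -> SegmentationParams:
    """Derive l and m from the sampling rate and energy-window size.

    l = fs/(2n) rounded half-to-even; m = rounded midpoint 3fs/(4n) of the
    open interval (fs/(2n), fs/n), nudged inside it if rounding lands on a
    boundary.
    """
    if fs_hz <= 0 or n <= 0:
        raise ValueError("fs_hz and n must be positive")
    lo, hi = fs_hz / (2 * n), fs_hz / n
    if hi - lo < 2:
        raise ValueError(f"degenerate look-ahead interval ({lo}, {hi}): need fs/(2n) span >= 2")
    l = int(np.round(fs_hz / (2 * n)))  # numpy rounds half to even
    m = int(np.round(3 * fs_hz / (4 * n)))
    if m <= lo:
        m = int(np.floor(lo)) + 1
    if m >= hi:
        m = int(np.ceil(hi)) - 1
    return SegmentationParams(l=l, m=m, n=n, fs_hz=fs_hz)


def calibrate_dataset(
    recordings,
    n: int = 100,
    hop: int | None = None,
    calibration_fraction: float = 0.2,
) -> tuple[ThresholdCalibration, dict[str, EnergySeries]]:
    """Calibrate pooled thresholds from a cohort with burst annotations.

    Emulates the manual-segmentation protocol: within each subject, the
    first ``calibration_fraction`` of recordings (by id) supply annotated
    onset/offset windows and peak energies for the ratio means; the peak
    energy of every remaining ("rest") recording supplies Ek_max. Returns
    the calibration plus each recording's energy series keyed by rec_id.
    """
    by_subject: dict[int, list] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    entries: list[tuple[EnergySeries, int, int]] = []
    series_by_rec: dict[str, EnergySeries] = {}
    rest_max = 0.0
    for _sid, group in sorted(by_subject.items()):
        group.sort(key=lambda r: r.rec_id)
        n_cal = max(1, int(np.ceil(calibration_fraction * len(group))))
        for i, rec in enumerate(group):
            series = short_term_energy(combine_channels(rec), n, hop)
            series_by_rec[rec.rec_id] = series
            if i < n_cal and rec.bursts:
                for s, e in rec.bursts:
                    k_start = s // series.hop
                    k_end = min((e - 1) // series.hop, len(series) - 1)
                    entries.append((series, k_start, k_end))
            else:
                rest_max = max(rest_max, float(np.max(series.values)))
    if rest_max == 0.0:  # tiny cohorts: every recording served as calibration
        rest_max = max(float(np.max(s.values)) for s, _, _ in entries)
    return calibrate_thresholds(entries, rest_max), series_by_rec


def detect_segments(
    energy: EnergySeries,
    calib: ThresholdCalibration,
    params: SegmentationParams,
    *,
    lookahead_mode: str = "mean",
    min_duration_s: float = 0.3,
) -> list[ActiveSegment]:
    """Scan the energy series for onset/offset pairs under the static thresholds.

    ``lookahead_mode`` selects how the m-window onset look-ahead is judged:
    ``"mean"`` (default) requires the mean of the next m energies to exceed
    STS; ``"per_window"`` requires every one of them to. Segments shorter
    than ``min_duration_s`` are discarded (they cannot fill a feature
    window). Quiet input returns an empty list.
    """
    if lookahead_mode not in ("mean", "per_window"):
        raise ValueError("lookahead_mode must be 'mean' or 'per_window'")
    e = np.asarray(energy.values, dtype=float)
    l, m = params.l, params.m
    if len(e) <= l + m:
        warnings.warn("energy series shorter than l+m windows; no segments detectable")
        return []
    min_samples = int(round(min_duration_s * params.fs_hz))

    segments: list[ActiveSegment] = []
    k = l  # need a full look-back
    n_win = len(e)
    while k < n_win - m:
        # ---- onset rule ----
        ahead = e[k + 1 : k + 1 + m]
        ahead_ok = np.mean(ahead) > calib.sts if lookahead_mode == "mean" else np.all(ahead > calib.sts)
        if e[k] > calib.sts and np.mean(e[k - l : k]) < e[k] and ahead_ok:
            start_k = k
            # ---- offset rule: first later window decaying below STE ----
            end_k = None
            j = k + 1
            while j < n_win:
                after = e[j + 1 : j + 1 + l]
                if e[j] < calib.ste and len(after) > 0 and np.mean(after) < e[j]:
                    end_k = j
                    break
                j += 1
            if end_k is None:
                end_k = n_win - 1
            start = energy.window_start(start_k)
            end = min(energy.window_start(end_k) + energy.window_size, energy.window_start(n_win - 1) + energy.window_size)
            if end - start >= min_samples:
                segments.append(ActiveSegment(start_sample=start, end_sample=end))
            k = end_k + 1
        else:
            k += 1
    return segments
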