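"""Feature construction: sliding-window spectrograms with PCA reduction, and
the six classical myoelectric time-domain features.

Spectrograms (SPM)
------------------
Each active segment is framed into 200 ms windows with a 100 ms step
(300/150 samples at 1500 Hz), each frame Hamming-weighted
(W(n) = (1-a) - a*cos(2*pi*n/(N-1)), a = 0.46) and Fourier-transformed with
zero-padding to the next power of two. Bins outside the informative
10-500 Hz band are discarded, and each segment-channel spectrogram is
min-max normalised to [0, 1] (channels have incomparable gains).
PCA, fitted on training-fold frames only, reduces the frequency axis to
k = 8 components; the reduced frames of the four channels stack into the
[n_frames x k x 4] tensor the classifier consumes.

Time-domain features
--------------------
Per window and channel: mean absolute value (MAV), population variance
(VAR), waveform length (WL), root mean square (RMS), zero crossings (ZC,
with dead-band epsilon), and slope-sign-change rate (SSC, mean of the
change indicator over interior points). The ZC dead-band defaults to
0.01 x window RMS so the count is amplitude-scale invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .types import ActiveSegment, EmgRecording

__all__ = [
    "WindowingConfig",
    "HammingSpec",
    "Spectrogram",
    "PcaModel",
    "ReducedSpectrogram",
    "TimeDomainFeatures",
    "hamming_window",
    "frame_windows",
    "compute_spectrogram",
    "fit_pca",
    "apply_pca",
    "time_domain_features",
    "time_domain_feature_table",
    "build_feature_tensor",
    "sidelobe_attenuation_db",
]

TD_FEATURE_NAMES = ("MAV", "VAR", "WL", "RMS", "ZC", "SSC")


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding analysis window: 200 ms frames, 100 ms step at 1500 Hz."""

    window_samples: int = 300
    step_samples: int = 150
    fs_hz: float = 1500.0

    def __post_init__(self) -> None:
        if not (1 <= self.step_samples <= self.window_samples):
            raise ValueError("require 1 <= step <= window")


@dataclass(frozen=True)
class HammingSpec:
    """Hamming taper parameters: length N and cosine coefficient a (0.46)."""

    N: int = 300
    a: float = 0.46

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("window length N must be >= 2")
        if not (0 < self.a < 1):
            raise ValueError("coefficient a must lie in (0, 1)")


@dataclass
class Spectrogram:
    """Band-limited, min-max normalised magnitude spectrogram of one channel."""

    magnitudes: np.ndarray  # (n_frames, n_bins), in [0, 1] unless degenerate
    frame_times_s: np.ndarray
    freq_bins_hz: np.ndarray  # strictly increasing, within [10, 500]
    norm_min: float
    norm_max: float
    degenerate: bool = False  # all-zero input: normalisation skipped

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]


@dataclass
class PcaModel:
    """Frequency-direction PCA: mean spectrum, loadings, variance report."""

    mean: np.ndarray  # (n_bins,)
    loadings: np.ndarray  # (n_bins, k), orthonormal columns
    explained_variance_ratio: np.ndarray  # (k,), non-increasing

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_bins(self) -> int:
        return self.loadings.shape[0]

    def variance_table(self) -> list[dict]:
        """Per-component and cumulative variance contribution rates (percent)."""
        cum = np.cumsum(self.explained_variance_ratio) * 100.0
        return [
            {
                "component": i + 1,
                "variance_pct": float(self.explained_variance_ratio[i] * 100.0),
                "cumulative_pct": float(cum[i]),
            }
            for i in range(self.k)
        ]


@dataclass
class ReducedSpectrogram:
    """PCA scores per frame, stacked over channels: (n_frames, k, n_channels)."""

    scores: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class TimeDomainFeatures:
    """The six classical features of one analysis window of one channel."""

    mav: float
    var: float
    wl: float
    rms: float
    zc: int
    ssc: float
    zc_threshold: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mav, self.var, self.wl, self.rms, self.zc, self.ssc])


def hamming_window(N: int, a: float = 0.46) -> np.ndarray:
    """Hamming taper W(n) = (1-a) - a*cos(2*pi*n/(N-1)), n = 0..N-1."""
    if N < 2:
        raise ValueError("window length N must be >= 2")
    n = np.arange(N)
    return (1 - a) - a * np.cos(2 * np.pi * n / (N - 1))


def sidelobe_attenuation_db(N: int = 300, a: float = 0.46, *, pad_factor: int = 16) -> float:
    """Main-lobe-peak to first-side-lobe-peak attenuation of the Hamming taper.

    Computed on a zero-padded magnitude spectrum (default 16x, rounded up to
    a power of two). The first side lobe is the first local maximum beyond
    the main lobe's first null.
    """
    w = hamming_window(N, a)
    nfft = 1 << int(np.ceil(np.log2(pad_factor * N)))
    mag = np.abs(np.fft.rfft(w, nfft))
    main = mag[0]
    # walk down from the main-lobe peak to the first null, then to the next peak
    i = 1
    while i < len(mag) - 1 and mag[i + 1] <= mag[i]:
        i += 1
    j = i
    while j < len(mag) - 1 and mag[j + 1] >= mag[j]:
        j += 1
    return float(20 * np.log10(main / mag[j]))


def frame_windows(signal: np.ndarray, cfg: WindowingConfig) -> np.ndarray:
    """Slice a 1-D signal into overlapping frames; (n_frames, window) array.

    A signal shorter than one window yields an empty (0, window) array with
    a warning rather than an error.
    """
    signal = np.asarray(signal, dtype=float)
    w, s = cfg.window_samples, cfg.step_samples
    if len(signal) < w:
        warnings.warn(f"signal of {len(signal)} samples shorter than one {w}-sample window")
        return np.empty((0, w))
    n_frames = (len(signal) - w) // s + 1
    idx = (np.arange(n_frames) * s)[:, None] + np.arange(w)[None, :]
    return signal[idx]


def compute_spectrogram(
    segment: np.ndarray,
    fs_hz: float,
    cfg: WindowingConfig | None = None,
    ham: HammingSpec | None = None,
    *,
    band_hz: tuple[float, float] = (10.0, 500.0),
    log_magnitude: bool = False,
) -> Spectrogram:
    """Hamming-windowed magnitude spectrogram, band-limited and normalised.

    FFT length is the next power of two >= the frame length (zero-padded).
    The whole spectrogram is min-max scaled to [0, 1]; an all-zero segment
    is passed through unscaled and flagged ``degenerate``.
    """
    cfg = cfg or WindowingConfig(fs_hz=fs_hz)
    ham = ham or HammingSpec(N=cfg.window_samples)
    if ham.N != cfg.window_samples:
        raise ValueError("Hamming length must match the framing window")
    frames = frame_windows(segment, cfg)
    if frames.shape[0] == 0:
        raise ValueError("segment spans less than one analysis window")
    nfft = 1 << int(np.ceil(np.log2(cfg.window_samples)))
    w = hamming_window(ham.N, ham.a)
    spec = np.abs(np.fft.rfft(frames * w, nfft, axis=1))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    spec = spec[:, keep]
    freqs = freqs[keep]
    if log_magnitude:
        spec = np.log1p(spec)
    lo, hi = float(spec.min()), float(spec.max())
    degenerate = hi <= lo
    if not degenerate:
        spec = (spec - lo) / (hi - lo)
    times = (np.arange(frames.shape[0]) * cfg.step_samples + cfg.window_samples / 2) / fs_hz
    return Spectrogram(
        magnitudes=spec,
        frame_times_s=times,
        freq_bins_hz=freqs,
        norm_min=lo,
        norm_max=hi,
        degenerate=degenerate,
    )


def fit_pca(training_frames: np.ndarray, k: int = 8) -> PcaModel:
    """Fit frequency-direction PCA on (n_frames, n_bins) training frames.

    Must be fitted on training-fold frames only; applying the model to its
    fold's test frames is the caller's contract.
    """
    X = np.asarray(training_frames, dtype=float)
    if X.ndim != 2:
        raise ValueError("training_frames must be 2-D (frames x bins)")
    if k < 1 or k > X.shape[1]:
        raise ValueError(f"k={k} must lie in [1, n_bins={X.shape[1]}]")
    if X.shape[0] < k:
        raise ValueError("need at least k training frames")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    return PcaModel(
        mean=pca.mean_.copy(),
        loadings=pca.components_.T.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def apply_pca(spec: Spectrogram, model: PcaModel) -> ReducedSpectrogram:
    """Project each frame onto the loadings after centring with the training mean."""
    if spec.magnitudes.shape[1] != model.n_bins:
        raise ValueError(
            f"spectrogram has {spec.magnitudes.shape[1]} bins, model expects {model.n_bins}"
        )
    scores = (spec.magnitudes - model.mean) @ model.loadings
    return ReducedSpectrogram(scores=scores, degenerate=spec.degenerate)


def time_domain_features(window: np.ndarray, eps: float | None = None) -> TimeDomainFeatures:
    """Evaluate MAV, VAR, WL, RMS, ZC, SSC on one window of one channel.

    ``eps`` is the zero-crossing dead-band; ``None`` selects 0.01 x the
    window's RMS (amplitude-scale invariant). Needs at least 3 samples
    (SSC is defined on interior points).
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("window must be 1-D with at least 3 samples")
    n = len(x)
    mav = float(np.mean(np.abs(x)))
    var = float(np.mean((x - np.mean(x)) ** 2))
    wl = float(np.sum(np.abs(np.diff(x))))
    rms = float(np.sqrt(np.mean(x**2)))
    if eps is None:
        eps = 0.01 * rms
    if eps < 0:
        raise ValueError("eps must be non-negative")
    sign_change = x[:-1] * x[1:] < 0
    big_enough = np.abs(x[:-1] - x[1:]) >= eps
    zc = int(np.sum(sign_change & big_enough))
    slope_prod = (x[1:-1] - x[:-2]) * (x[2:] - x[1:-1])
    ssc = float(np.mean(slope_prod < 0))
    return TimeDomainFeatures(mav=mav, var=var, wl=wl, rms=rms, zc=zc, ssc=ssc, zc_threshold=float(eps))


def time_domain_feature_table(
    segment: np.ndarray, cfg: WindowingConfig, eps: float | None = None
) -> np.ndarray:
    """All six features per sliding window per channel.

    ``segment`` is (n_samples, n_channels); returns
    (n_frames, 6, n_channels) ordered as :data:`TD_FEATURE_NAMES`.
    """
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    if seg.shape[0] < seg.shape[1]:
        raise ValueError("segment must be (n_samples, n_channels)")
    n_ch = seg.shape[1]
    per_ch = []
    for ch in range(n_ch):
        frames = frame_windows(seg[:, ch], cfg)
        feats = np.array([time_domain_features(f, eps).as_array() for f in frames])
        per_ch.append(feats)
    return np.stack(per_ch, axis=-1)  # (n_frames, 6, n_ch)


def build_feature_tensor(
    rec: EmgRecording,
    segments: list[ActiveSegment],
    model: PcaModel,
    cfg: WindowingConfig | None = None,
    ham: HammingSpec | None = None,
) -> list[dict]:
    """Per-segment feature bundles for a recording.

    For each usable segment returns a dict with

    * ``spm``: reduced spectrogram tensor (n_frames, k, n_channels),
    * ``td``: time-domain feature table (n_frames, 6, n_channels),
    * ``segment``: the source :class:`ActiveSegment`,
    * ``degenerate``: True when every channel was all-zero.

    Segments shorter than one analysis window are skipped with a warning.
    """
    cfg = cfg or WindowingConfig(fs_hz=rec.fs_hz)
    ham = ham or HammingSpec(N=cfg.window_samples)
    out = []
    for seg in segments:
        sl = rec.samples[seg.start_sample : seg.end_sample]
        if sl.shape[0] < cfg.window_samples:
            warnings.warn(f"segment {seg} shorter than one analysis window; skipped")
            continue
        per_ch, degenerate = [], True
        for ch in range(rec.n_channels):
            spec = compute_spectrogram(sl[:, ch], rec.fs_hz, cfg, ham)
            degenerate = degenerate and spec.degenerate
            per_ch.append(apply_pca(spec, model).scores)
        spm = np.stack(per_ch, axis=-1)  # (n_frames, k, n_ch)
        td = time_domain_feature_table(sl, cfg)
        assert spm.shape[0] == td.shape[0]
        out.append({"spm": spm, "td": td, "segment": seg, "degenerate": degenerate})
    return out
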