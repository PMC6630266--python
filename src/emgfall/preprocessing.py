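"""Band-pass denoising of raw sEMG.

The useful sEMG band is roughly 10-500 Hz. Denoising is a cascade of a
third-order Butterworth high-pass at 10 Hz and a third-order Butterworth
low-pass at 500 Hz (18 dB/octave roll-off per stage). No notch filter is
applied: the emulated acquisition hardware shields power-line interference,
and removing 50 Hz would cut into the signal band.

Discretisation uses the bilinear transform with frequency pre-warping
(scipy's default), which keeps the -3 dB points at the printed cutoffs.
Application is causal single-pass by default, preserving the real-time
framing of an alarm system; zero-phase forward-backward filtering is
available but doubles the effective order and attenuation slope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .types import EmgRecording

__all__ = ["FilterSpec", "design_bandpass", "apply_filter", "frequency_response"]

# renamed in newer scipy; keep both spellings working
_freqz_sos = getattr(sps, "freqz_sos", None) or sps.sosfreqz


@dataclass(frozen=True)
class FilterSpec:
    """Realised band-pass cascade: HP stage SOS followed by LP stage SOS."""

    fs_hz: float
    hp_cutoff_hz: float = 10.0
    lp_cutoff_hz: float = 500.0
    hp_order: int = 3
    lp_order: int = 3
    hp_sos: np.ndarray | None = None
    lp_sos: np.ndarray | None = None

    @property
    def sos(self) -> np.ndarray:
        """Full cascade as a single second-order-sections array."""
        return np.vstack([self.hp_sos, self.lp_sos])

    def is_stable(self) -> bool:
        """All poles of the realised cascade strictly inside the unit circle."""
        _, poles, _ = sps.sos2zpk(self.sos)
        return bool(np.all(np.abs(poles) < 1.0))


def design_bandpass(
    fs_hz: float,
    *,
    hp_cutoff_hz: float = 10.0,
    lp_cutoff_hz: float = 500.0,
    hp_order: int = 3,
    lp_order: int = 3,
) -> FilterSpec:
    """Design the cascaded HP(3rd, 10 Hz) + LP(3rd, 500 Hz) band-pass.

    Raises
    ------
    ValueError
        If ``fs_hz`` is too low to place the low-pass cutoff below Nyquist
        (requires fs > 1000 Hz at the default cutoffs).
    """
    if fs_hz <= 2 * lp_cutoff_hz:
        raise ValueError(
            f"fs_hz={fs_hz} too low: low-pass cutoff {lp_cutoff_hz} Hz must lie below Nyquist"
        )
    if not (0 < hp_cutoff_hz < lp_cutoff_hz):
        raise ValueError("cutoffs must satisfy 0 < hp_cutoff < lp_cutoff")
    hp_sos = sps.butter(hp_order, hp_cutoff_hz, btype="highpass", fs=fs_hz, output="sos")
    lp_sos = sps.butter(lp_order, lp_cutoff_hz, btype="lowpass", fs=fs_hz, output="sos")
    spec = FilterSpec(fs_hz, hp_cutoff_hz, lp_cutoff_hz, hp_order, lp_order, hp_sos, lp_sos)
    assert spec.is_stable()
    return spec


def apply_filter(rec: EmgRecording, spec: FilterSpec, *, zero_phase: bool = False) -> EmgRecording:
    """Band-pass every channel independently; shape and metadata preserved.

    ``zero_phase=True`` uses forward-backward filtering (no phase lag, but
    squared magnitude response, so twice the stop-band slope).
    """
    if abs(rec.fs_hz - spec.fs_hz) > 1e-9:
        raise ValueError(f"recording rate {rec.fs_hz} != filter design rate {spec.fs_hz}")
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("input contains non-finite samples")
    filt = sps.sosfiltfilt if zero_phase else sps.sosfilt
    out = np.column_stack([filt(spec.sos, rec.samples[:, ch]) for ch in range(rec.n_channels)])
    return replace(rec, samples=out)


def frequency_response(spec: FilterSpec, freqs_hz) -> np.ndarray:
    """Cascade magnitude in dB at the requested frequencies.

    Zero magnitude (e.g. at DC, which the high-pass blocks exactly) is
    reported as ``-inf``. Frequencies at or above Nyquist raise.
    """
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(freqs < 0) or np.any(freqs >= spec.fs_hz / 2):
        raise ValueError("frequencies must lie in [0, fs/2)")
    _, h = _freqz_sos(spec.sos, worN=2 * np.pi * freqs / spec.fs_hz)
    mag = np.abs(h)
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(mag)
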