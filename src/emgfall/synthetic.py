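"""Synthetic surface-EMG generator.

Real sEMG is a stochastic interference pattern: during a contraction the
electrode sees band-limited noise whose envelope tracks muscle activation.
The generator emulates this with band-pass-filtered Gaussian noise multiplied
by a trapezoidal activation envelope, embedded in zero-mean baseline noise,
without modelling individual motor units.

Gesture identity is encoded in the carrier band and the 4-channel amplitude
pattern of the burst; falls produce broad-band, near-simultaneous bursts on
all channels (co-contraction), daily activities narrower bands with uneven
channel loading. Combined-channel burst energy is kept comparable across
classes so that a single pair of static energy thresholds can serve all
gestures of a cohort, which also mirrors the fact that gross amplitude is a
poor class discriminator on real electrodes.

The default dataset mirrors the emulated study: 10 subjects x 4 gestures x
10 repetitions = 400 recordings (100 falls), 4 channels at 1500 Hz,
recordings 3-5 s long with one annotated activity burst each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import CHANNEL_NAMES, DEFAULT_FS_HZ, GESTURES, EmgRecording

__all__ = [
    "SubjectProfile",
    "BurstTemplate",
    "NoiseSetting",
    "make_profiles",
    "generate_recording",
    "generate_dataset",
]


#: Carrier band (Hz) per gesture. Bands are disjoint-ish and all within the
#: 10-500 Hz sEMG range; falling is broad-band and high-frequency.
CLASS_BANDS: dict[str, tuple[float, float]] = {
    "walking": (25.0, 130.0),
    "squatting": (70.0, 190.0),
    "sitting": (150.0, 290.0),
    "falling": (200.0, 470.0),
}

#: Relative per-channel loading of the burst per gesture (rectus femoris,
#: vastus medialis, tibialis anterior, gastrocnemius). Each row is
#: normalised to unit RMS across channels so classes share combined energy.
CLASS_CHANNEL_PATTERNS: dict[str, tuple[float, float, float, float]] = {
    "walking": (1.2, 0.8, 1.0, 1.0),
    "squatting": (1.4, 1.2, 0.7, 0.7),
    "sitting": (0.7, 0.7, 1.2, 1.3),
    "falling": (1.0, 1.0, 1.0, 1.0),
}

#: Overall burst-to-noise scale per gesture (falls co-contract slightly harder).
CLASS_AMPLITUDE_FACTORS: dict[str, float] = {
    "walking": 1.0,
    "squatting": 1.0,
    "sitting": 1.0,
    "falling": 1.1,
}


@dataclass(frozen=True)
class NoiseSetting:
    """Difficulty knob: burst RMS per channel relative to baseline noise SD.

    ``easy`` (snr_scale 6) gives clearly separable classes and reliable
    energy-threshold segmentation; ``hard`` (snr_scale 1.5) buries bursts
    close to the noise floor.
    """

    name: str
    snr_scale: float

    @staticmethod
    def easy() -> "NoiseSetting":
        return NoiseSetting("easy", 6.0)

    @staticmethod
    def hard() -> "NoiseSetting":
        return NoiseSetting("hard", 1.5)

    @staticmethod
    def from_name(name: str) -> "NoiseSetting":
        if name == "easy":
            return NoiseSetting.easy()
        if name == "hard":
            return NoiseSetting.hard()
        raise ValueError(f"unknown noise setting {name!r}; expected 'easy' or 'hard'")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject gains and noise level (inter-subject variability).

    Gains are mild lognormal perturbations around 1 so that pooled static
    thresholds calibrated on other subjects remain usable.
    """

    subject_id: int
    channel_gains: tuple[float, ...]
    baseline_noise_sd: float = 1.0
    burst_amplitude: float = 1.0  # multiplicative; 0 produces burst-free controls

    def __post_init__(self) -> None:
        if self.subject_id < 1:
            raise ValueError("subject_id must be >= 1")
        if any(g <= 0 for g in self.channel_gains):
            raise ValueError("channel gains must be strictly positive")
        if self.baseline_noise_sd <= 0:
            raise ValueError("baseline_noise_sd must be strictly positive")
        if self.burst_amplitude < 0:
            raise ValueError("burst_amplitude must be non-negative")


@dataclass(frozen=True)
class BurstTemplate:
    """Trapezoidal activation burst: rise / plateau / fall, with a carrier band."""

    onset_s: float
    rise_s: float
    plateau_s: float
    fall_s: float
    carrier_band: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.carrier_band
        if not (10.0 <= lo < hi <= 500.0):
            raise ValueError("carrier band must satisfy 10 <= low < high <= 500 Hz")
        if self.onset_s < 0 or min(self.rise_s, self.plateau_s, self.fall_s) < 0:
            raise ValueError("burst timing parameters must be non-negative")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.rise_s + self.plateau_s + self.fall_s

    def envelope(self, n_samples: int, fs_hz: float) -> np.ndarray:
        t = np.arange(n_samples) / fs_hz
        env = np.zeros(n_samples)
        r0, r1 = self.onset_s, self.onset_s + self.rise_s
        p1 = r1 + self.plateau_s
        f1 = p1 + self.fall_s
        if self.rise_s > 0:
            rising = (t >= r0) & (t < r1)
            env[rising] = (t[rising] - r0) / self.rise_s
        env[(t >= r1) & (t < p1)] = 1.0
        if self.fall_s > 0:
            falling = (t >= p1) & (t < f1)
            env[falling] = 1.0 - (t[falling] - p1) / self.fall_s
        return env


def make_profiles(n_subjects: int, seed: int, *, burst_amplitude: float = 1.0) -> list[SubjectProfile]:
    """Deterministic subject profiles; gain jitter lognormal(sd=0.05)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    profiles = []
    for sid in range(1, n_subjects + 1):
        gains = tuple(np.exp(rng.normal(0.0, 0.04, size=4)))
        profiles.append(
            SubjectProfile(
                subject_id=sid,
                channel_gains=gains,
                baseline_noise_sd=1.0,
                burst_amplitude=burst_amplitude,
            )
        )
    return profiles


def _bandlimited_noise(n: int, band: tuple[float, float], fs_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to ``band`` (4th-order Butterworth)."""
    white = rng.standard_normal(n + 600)  # pad to absorb the filter transient
    sos = sps.butter(4, band, btype="bandpass", fs=fs_hz, output="sos")
    x = sps.sosfilt(sos, white)[600:]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_recording(
    gesture: str,
    profile: SubjectProfile,
    duration_s: float,
    seed: int,
    *,
    fs_hz: float = DEFAULT_FS_HZ,
    noise: NoiseSetting | None = None,
    mains_hz: float | None = None,
    mains_amplitude: float = 0.0,
    rec_id: str = "",
) -> EmgRecording:
    """Synthesise one labelled 4-channel recording with one annotated burst.

    Parameters
    ----------
    gesture : str
        One of walking / squatting / sitting / falling; fixes the carrier
        band, channel pattern and envelope timing of the burst.
    profile : SubjectProfile
        Subject gains and noise level. ``burst_amplitude = 0`` yields a
        burst-free control whose annotation list is empty.
    duration_s : float
        Recording length in seconds (> 0).
    seed : int
        Fully determines the output (bit-identical arrays on repeat calls).
    mains_hz, mains_amplitude
        Optional power-line interference tone (off by default: the emulated
        acquisition hardware shields it). Useful for filter tests.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if gesture not in GESTURES:
        raise ValueError(f"unknown gesture {gesture!r}")
    noise = noise or NoiseSetting.easy()
    n = int(round(duration_s * fs_hz))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), profile.subject_id, GESTURES.index(gesture)]))

    samples = np.empty((n, 4))
    for ch in range(4):
        samples[:, ch] = rng.normal(0.0, profile.baseline_noise_sd, size=n)

    bursts: list[tuple[int, int]] = []
    amp = profile.burst_amplitude * CLASS_AMPLITUDE_FACTORS[gesture] * noise.snr_scale
    if amp > 0:
        rise, fall = 0.06, 0.30  # activation fast, relaxation slower
        plateau = float(rng.uniform(0.9, 1.6))
        # the acquisition protocol rests the subject before each repetition:
        # keep >= 0.9 s of baseline ahead of the burst and >= 0.25 s after
        lead, tail = 0.9, 0.25
        plateau = min(plateau, max(0.9, duration_s - rise - fall - lead - tail))
        burst_len = rise + plateau + fall
        latest = max(lead, duration_s - burst_len - tail)
        onset = float(rng.uniform(lead, latest))
        tpl = BurstTemplate(onset, rise, plateau, fall, CLASS_BANDS[gesture])
        env = tpl.envelope(n, fs_hz)
        pattern = np.asarray(CLASS_CHANNEL_PATTERNS[gesture], dtype=float)
        pattern = pattern / np.sqrt(np.mean(pattern**2))  # unit RMS over channels
        rep_jitter = float(np.exp(rng.normal(0.0, 0.03)))
        for ch in range(4):
            carrier = _bandlimited_noise(n, tpl.carrier_band, fs_hz, rng)
            gain = profile.channel_gains[ch] * rep_jitter
            samples[:, ch] += amp * pattern[ch] * gain * env * carrier
        # annotation convention mirrors manual marking on an energy trace:
        # onsets are sharp, so the start sits at the foot of the rise; decay
        # is gradual, so the end sits at the half-maximum of the fall ramp
        start = int(round(onset * fs_hz))
        end = min(n, int(round((tpl.offset_s - fall / 2) * fs_hz)))
        bursts.append((start, end))

    if mains_hz is not None and mains_amplitude > 0:
        t = np.arange(n) / fs_hz
        tone = mains_amplitude * np.sin(2 * np.pi * mains_hz * t)
        samples += tone[:, None]

    return EmgRecording(
        samples=samples,
        fs_hz=fs_hz,
        subject_id=profile.subject_id,
        gesture=gesture,
        channel_names=CHANNEL_NAMES,
        bursts=bursts,
        rec_id=rec_id or f"s{profile.subject_id:02d}_{gesture}_seed{seed}",
    )


def generate_dataset(
    n_subjects: int = 10,
    reps_per_gesture: int = 10,
    seed: int = 0,
    *,
    noise: NoiseSetting | str = "easy",
    fs_hz: float = DEFAULT_FS_HZ,
    burst_amplitude: float = 1.0,
) -> list[EmgRecording]:
    """Generate the full labelled cohort: ``n_subjects x 4 gestures x reps``.

    Defaults (10 subjects, 10 reps) reproduce the emulated study scale of
    400 recordings, 100 of them falls. Recording durations are uniform on
    3-5 s. Every recording carries its subject id (for LOSO splitting) and
    ground-truth burst annotations.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (LOSO needs at least two subjects)")
    if reps_per_gesture < 1:
        raise ValueError("reps_per_gesture must be >= 1")
    if isinstance(noise, str):
        noise = NoiseSetting.from_name(noise)
    profiles = make_profiles(n_subjects, seed, burst_amplitude=burst_amplitude)
    master = np.random.SeedSequence([int(seed), 0xDA7A])
    # one child seed per (subject, gesture, rep), spawned in a fixed order
    children = master.generate_state(n_subjects * 4 * reps_per_gesture * 2).reshape(-1, 2)
    dur_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD0]))

    recs: list[EmgRecording] = []
    idx = 0
    for profile in profiles:
        for gesture in GESTURES:
            for rep in range(reps_per_gesture):
                duration = float(dur_rng.uniform(3.0, 5.0))
                rec_seed = int(children[idx, 0] % (2**31 - 1))
                idx += 1
                rec = generate_recording(
                    gesture,
                    profile,
                    duration,
                    rec_seed,
                    fs_hz=fs_hz,
                    noise=noise,
                    rec_id=f"s{profile.subject_id:02d}_{gesture}_r{rep:02d}",
                )
                recs.append(rec)
    return recs
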