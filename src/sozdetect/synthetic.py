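"""Synthetic EEG generation with ground truth.

The clinical recordings this pipeline targets are private, so this module
emulates the statistical contrast the classifier relies on:

* background -- 1/f-shaped ("pink") noise plus a ~10 Hz alpha rhythm, the
  standard surrogate for resting scalp EEG;
* ictal activity -- rhythmic ~3 Hz spike-and-wave: a fundamental sinusoid
  with 2nd/3rd harmonics and one sharp transient per cycle, at several
  times the background amplitude.

Everything is driven by a single seed: identical (seed, spec, schedule)
reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .montage import CANONICAL_SITES
from .io_formats import LabeledWindowSet, MultiChannelRecording, write_uci_table

__all__ = [
    "SyntheticSpec",
    "PropagationSchedule",
    "gen_background",
    "gen_seizure",
    "gen_uci_like",
    "gen_multichannel",
    "default_schedule",
    "BACKGROUND_SCALE_UV",
]

#: Amplitude scale applied to unit-variance background to mimic scalp uV.
BACKGROUND_SCALE_UV = 40.0

#: Canonical row length of the labelled-window table.
WINDOW_LENGTH = 178


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic EEG generator.

    ``ictal_amplitude_gain`` is the guaranteed RMS ratio of ictal windows to
    background windows (> 1); ``noise_exponent`` is the 1/f spectral slope
    of the background noise.
    """

    sampling_rate: float = 256.0
    window_seconds: float = 1.0
    spike_wave_freq: float = 3.0
    ictal_amplitude_gain: float = 4.0
    background_alpha_freq: float = 10.0
    noise_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.window_seconds <= 0:
            raise ValueError("sampling_rate and window_seconds must be positive")
        if self.ictal_amplitude_gain <= 1:
            raise ValueError("ictal_amplitude_gain must exceed 1")
        highest = max(3 * self.spike_wave_freq, self.background_alpha_freq)
        if self.sampling_rate <= 2 * highest:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz violates Nyquist for "
                f"content up to {highest} Hz"
            )


@dataclass(frozen=True)
class PropagationSchedule:
    """Which sites seize, when each starts and stops, and the total duration.

    ``intervals`` maps a 10-20 site name to its (onset latency, offset) in
    seconds from the start of the recording; unlisted sites never seize.
    """

    intervals: dict[str, tuple[float, float]]
    total_duration_s: float

    def __post_init__(self) -> None:
        if self.total_duration_s <= 0:
            raise ValueError("total duration must be positive")
        for site, (lat, off) in self.intervals.items():
            if site not in CANONICAL_SITES:
                raise ValueError(f"unknown 10-20 site {site!r} in schedule")
            if not (0 <= lat < self.total_duration_s):
                raise ValueError(
                    f"{site}: onset latency {lat} outside [0, total duration)"
                )
            if off <= lat:
                raise ValueError(f"{site}: offset {off} must exceed latency {lat}")

    @property
    def onset_sites(self) -> set[str]:
        first = min(lat for lat, _ in self.intervals.values())
        return {s for s, (lat, _) in self.intervals.items() if lat == first}


def _unit_normalize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_background(
    n_samples: int,
    spec: SyntheticSpec | None = None,
    rng: np.random.Generator | None = None,
    alpha_amplitude: float = 0.5,
) -> np.ndarray:
    """Zero-mean unit-variance background: 1/f noise + alpha rhythm."""
    spec = spec or SyntheticSpec()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    white = rng.standard_normal(n_samples)
    if n_samples >= 4:
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n_samples, d=1.0 / spec.sampling_rate)
        shaping = np.ones_like(freqs)
        nz = freqs > 0
        shaping[nz] = freqs[nz] ** (-spec.noise_exponent / 2.0)
        shaping[0] = 0.0
        noise = np.fft.irfft(spectrum * shaping, n=n_samples)
        noise = _unit_normalize(noise)
    else:
        noise = white
    t = np.arange(n_samples) / spec.sampling_rate
    phase = rng.uniform(0, 2 * np.pi)
    alpha = alpha_amplitude * np.sin(2 * np.pi * spec.background_alpha_freq * t + phase)
    return _unit_normalize(noise + alpha)


def gen_seizure(
    n_samples: int,
    spec: SyntheticSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rhythmic spike-and-wave ictal signal.

    The output RMS is fixed at 1.1 x ``ictal_amplitude_gain``, so against
    unit-RMS background every ictal window exceeds the configured gain.
    """
    spec = spec or SyntheticSpec()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    t = np.arange(n_samples) / spec.sampling_rate
    f0 = spec.spike_wave_freq
    phase = rng.uniform(0, 2 * np.pi)
    wave = (
        np.sin(2 * np.pi * f0 * t + phase)
        + 0.5 * np.sin(2 * np.pi * 2 * f0 * t + 2 * phase)
        + 0.25 * np.sin(2 * np.pi * 3 * f0 * t + 3 * phase)
    )
    # one sharp transient per spike-wave cycle (~20 ms wide)
    cycle_pos = ((t * f0 + phase / (2 * np.pi)) % 1.0) / f0  # s into the cycle
    wave = wave + 1.5 * np.exp(-0.5 * (cycle_pos / 0.02) ** 2)
    noise = rng.standard_normal(n_samples) * 0.3
    if n_samples == 1:
        return np.asarray([1.1 * spec.ictal_amplitude_gain])
    out = _unit_normalize(wave + noise)
    return out * (1.1 * spec.ictal_amplitude_gain)


def gen_uci_like(
    n_per_class: int,
    spec: SyntheticSpec | None = None,
    path: str | Path | None = None,
) -> LabeledWindowSet:
    """A labelled-window table in the 179-column layout, with ground truth.

    Class 1 rows are ictal spike-wave windows; classes 2-5 are background
    variants (2/3: altered variance scaling; 4/5: weak/strong alpha,
    mimicking eyes-open/eyes-closed rest).  Each row is an independent
    178-sample window, band-limited to 0.53-40 Hz like the source data it
    emulates; amplitudes are in uV.  If ``path`` is given the table is also
    written as CSV.
    """
    spec = spec or SyntheticSpec()
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    # windows are canonical 178-sample seconds: generate at 178 Hz
    row_spec = SyntheticSpec(
        sampling_rate=float(WINDOW_LENGTH),
        window_seconds=1.0,
        spike_wave_freq=spec.spike_wave_freq,
        ictal_amplitude_gain=spec.ictal_amplitude_gain,
        background_alpha_freq=spec.background_alpha_freq,
        noise_exponent=spec.noise_exponent,
        seed=spec.seed,
    )
    rng = np.random.default_rng(spec.seed)
    # the emulated source windows are 0.53-40 Hz band-limited
    sos = sps.butter(5, [0.53, 40.0], btype="bandpass", fs=float(WINDOW_LENGTH),
                     output="sos")
    rows, labels = [], []
    class_variants = {
        2: dict(scale=1.5, alpha=0.5),
        3: dict(scale=0.75, alpha=0.5),
        4: dict(scale=1.0, alpha=0.2),
        5: dict(scale=1.0, alpha=0.8),
    }
    for label in (1, 2, 3, 4, 5):
        for _ in range(n_per_class):
            if label == 1:
                row = gen_seizure(WINDOW_LENGTH, row_spec, rng)
            else:
                v = class_variants[label]
                row = v["scale"] * gen_background(
                    WINDOW_LENGTH, row_spec, rng, alpha_amplitude=v["alpha"]
                )
            rows.append(sps.sosfiltfilt(sos, row) * BACKGROUND_SCALE_UV)
            labels.append(label)
    ws = LabeledWindowSet(
        windows=np.asarray(rows), labels5=np.asarray(labels, dtype=np.int64)
    )
    if path is not None:
        write_uci_table(ws, path)
    return ws


def gen_multichannel(
    schedule: PropagationSchedule, spec: SyntheticSpec | None = None
):
    """A 21-channel recording plus its per-second ground-truth matrix.

    Every channel carries background; channels named in the schedule carry
    spike-wave activity exactly within their [latency, offset) interval.
    The ground-truth matrix marks each whole second fully covered by a
    channel's ictal interval (partial tail seconds are rounded down,
    matching 1-s non-overlapping windowing downstream).
    """
    from .detection import DetectionMatrix

    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    sr = spec.sampling_rate
    n_total = int(round(schedule.total_duration_s * sr))
    n_seconds = int(np.floor(schedule.total_duration_s))
    data = np.empty((len(CANONICAL_SITES), n_total))
    truth = np.zeros((len(CANONICAL_SITES), n_seconds), dtype=int)
    for i, site in enumerate(CANONICAL_SITES):
        channel = gen_background(n_total, spec, rng) * BACKGROUND_SCALE_UV
        if site in schedule.intervals:
            lat, off = schedule.intervals[site]
            off = min(off, schedule.total_duration_s)
            a, b = int(round(lat * sr)), int(round(off * sr))
            channel[a:b] = gen_seizure(b - a, spec, rng) * BACKGROUND_SCALE_UV
            for s in range(n_seconds):
                if lat <= s and (s + 1) <= off:
                    truth[i, s] = 1
        data[i] = channel
    recording = MultiChannelRecording(
        channel_names=list(CANONICAL_SITES),
        sampling_rate=sr,
        data=data,
        annotations=_truth_annotations(schedule),
    )
    matrix = DetectionMatrix(
        site_names=list(CANONICAL_SITES),
        verdicts=truth,
        probabilities=truth.astype(float),
    )
    return recording, matrix


def _truth_annotations(schedule: PropagationSchedule):
    return [
        (lat, min(off, schedule.total_duration_s), f"seizure:{site}")
        for site, (lat, off) in sorted(schedule.intervals.items())
    ]


def default_schedule(
    onset_sites: tuple[str, ...] = ("F8", "T4"),
    onset_second: float = 10.0,
    spread_delay_s: float = 6.0,
    spread_sites: tuple[str, ...] = ("F4", "C4", "P4", "T6", "F3", "C3", "T3", "P3"),
    offset_second: float = 25.0,
    total_duration_s: float = 35.0,
) -> PropagationSchedule:
    """A focal-onset scenario: seizure starts at a few sites, spreads, ends.

    The defaults emulate a right-frontotemporal onset that later spreads
    bilaterally; onset sites persist to the end of the seizure while spread
    sites stop a little earlier.
    """
    intervals = {s: (onset_second, offset_second) for s in onset_sites}
    for s in spread_sites:
        if s not in intervals:
            intervals[s] = (onset_second + spread_delay_s, offset_second - 2.0)
    return PropagationSchedule(intervals=intervals, total_duration_s=total_duration_s)
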