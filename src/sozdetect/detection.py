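"""Channel-wise per-second seizure-site detection.

A 21-channel scalp recording is split into its channels; each channel is
band-passed, cut into 1-s windows, resampled to 178 samples, z-scored and
classified by the single trained 1-D CNN.  The result is a 21 x seconds
grid of seizure verdicts and probabilities, one row per 10-20 site in
canonical order.  Replicating the classifier per channel would be a
presentation device only -- identical training on identical data yields
identical models -- so one weight set is applied to every channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import CANONICAL_SITES
from .io_formats import MultiChannelRecording
from .preprocess import PreprocessConfig, select_channels, windows_from_recording
from .cnn import ModelSpec, ModelWeights, forward

__all__ = ["DetectionMatrix", "detect_sites", "summarize_counts"]


@dataclass
class DetectionMatrix:
    """Per-site, per-second seizure verdicts and probabilities."""

    site_names: list[str]
    verdicts: np.ndarray
    probabilities: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.verdicts = np.atleast_2d(np.asarray(self.verdicts, dtype=int))
        self.probabilities = np.atleast_2d(np.asarray(self.probabilities, dtype=float))
        if self.verdicts.shape != self.probabilities.shape:
            raise ValueError("verdicts and probabilities must share a shape")
        if self.verdicts.shape[0] != len(self.site_names):
            raise ValueError("one row per site name required")
        if self.probabilities.size and (
            self.probabilities.min() < 0 or self.probabilities.max() > 1
        ):
            raise ValueError("probabilities outside [0, 1]")
        if not np.isin(self.verdicts, (0, 1)).all():
            raise ValueError("verdicts must be binary")

    @property
    def seconds(self) -> int:
        return self.verdicts.shape[1]


def detect_sites(
    recording: MultiChannelRecording,
    weights: ModelWeights,
    model_spec: ModelSpec | None = None,
    preprocess_config: PreprocessConfig | None = None,
) -> DetectionMatrix:
    """Run the single-channel pipeline over all 21 sites of a recording.

    The recording must contain the 21 canonical 10-20 channels (extras are
    dropped); output rows follow the canonical order regardless of input
    channel order.
    """
    model_spec = model_spec or ModelSpec()
    config = preprocess_config or PreprocessConfig()
    if recording.duration < config.window_seconds:
        raise ValueError("recording shorter than one analysis window")
    canonical = select_channels(recording)
    windows = windows_from_recording(canonical, config)  # (21, sec, 178)
    n_ch, n_sec, _ = windows.shape
    probs = forward(
        weights, windows.reshape(n_ch * n_sec, -1), spec=model_spec,
        training_mode=False,
    ).reshape(n_ch, n_sec)
    verdicts = (probs >= model_spec.threshold).astype(int)
    return DetectionMatrix(
        site_names=list(CANONICAL_SITES),
        verdicts=verdicts,
        probabilities=probs,
        threshold=model_spec.threshold,
    )


def summarize_counts(matrix: DetectionMatrix) -> dict[str, np.ndarray]:
    """Marginal flag counts: per second (across sites) and per site (across seconds)."""
    return {
        "per_second": matrix.verdicts.sum(axis=0),
        "per_site": matrix.verdicts.sum(axis=1),
    }
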