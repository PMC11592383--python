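"""Readers and writers for the pipeline's on-disk formats.

Covers the single-channel labelled-window CSV table (178 sample columns
plus a 5-class label column ``y``), multi-channel EDF recordings, detection
matrices (JSON), and model checkpoints (NumPy archive).  All readers reject
malformed input rather than silently coercing it.

EDF is read through :mod:`mne`; writing uses a minimal 16-bit EDF encoder
implemented here, cross-checked against the mne reader in the test suite.
"""

from __future__ import annotations

import datetime as _dt
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import normalize_channel_name

__all__ = [
    "LabeledWindowSet",
    "MultiChannelRecording",
    "read_uci_table",
    "write_uci_table",
    "read_edf",
    "write_edf",
    "write_detection_matrix",
    "read_detection_matrix",
    "save_checkpoint",
    "load_checkpoint",
]

WINDOW_LENGTH = 178


@dataclass
class LabeledWindowSet:
    """n windows x 178 samples with 5-class and (optionally) binary labels."""

    windows: np.ndarray
    labels5: np.ndarray
    labels_binary: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels5 = np.asarray(self.labels5)
        if self.windows.ndim != 2 or self.windows.shape[1] != WINDOW_LENGTH:
            raise ValueError(
                f"windows must be (n, {WINDOW_LENGTH}); got {self.windows.shape}"
            )
        if self.labels5.shape != (self.windows.shape[0],):
            raise ValueError("labels5 length must match window count")
        if self.labels5.size and (
            not np.issubdtype(self.labels5.dtype, np.integer)
            or self.labels5.min() < 1
            or self.labels5.max() > 5
        ):
            raise ValueError("labels5 must be integers in {1..5}")

    def __len__(self) -> int:
        return self.windows.shape[0]


@dataclass
class MultiChannelRecording:
    """Named channels x samples at a single sampling rate, amplitudes in uV."""

    channel_names: list[str]
    sampling_rate: float
    data: np.ndarray
    annotations: list[tuple[float, float, str]] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names but "
                f"{self.data.shape[0]} data rows"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


# ---------------------------------------------------------------------------
# Labelled-window CSV table
# ---------------------------------------------------------------------------

def read_uci_table(path: str | Path) -> LabeledWindowSet:
    """Read a labelled-window table: 178 sample columns + final label column.

    Tolerates the public mirror's unnamed leading row-ID column.  Any other
    column count, or a non-integer / out-of-range label, is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    first = str(df.columns[0])
    if df.shape[1] == WINDOW_LENGTH + 2 and (
        first.startswith("Unnamed") or first == ""
    ):
        df = df.iloc[:, 1:]  # unnamed row-ID column on the public mirror
    if df.shape[1] != WINDOW_LENGTH + 1:
        raise ValueError(
            f"{path.name}: expected {WINDOW_LENGTH + 1} data columns "
            f"(178 samples + label), found {df.shape[1]}"
        )
    y = df.iloc[:, -1]
    y_int = pd.to_numeric(y, errors="raise")
    if not np.all(y_int == np.floor(y_int)):
        raise ValueError("label column contains non-integer values")
    labels5 = y_int.to_numpy(dtype=np.int64)
    if labels5.min() < 1 or labels5.max() > 5:
        raise ValueError("labels outside {1..5}")
    return LabeledWindowSet(
        windows=df.iloc[:, :-1].to_numpy(dtype=float), labels5=labels5
    )


def write_uci_table(ws: LabeledWindowSet, path: str | Path) -> None:
    """Write the 179-column CSV layout (header row, label column ``y``)."""
    cols = [f"X{i}" for i in range(1, WINDOW_LENGTH + 1)]
    df = pd.DataFrame(ws.windows, columns=cols)
    df["y"] = ws.labels5
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _fmt_phys(v: float) -> str:
    """Format a physical bound into <=8 ASCII chars."""
    for fmt in ("%.6g", "%.5g", "%.4g", "%.3g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    return "%.2g" % v


def write_edf(recording: MultiChannelRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF (physical dimension uV).

    Uses 1-s data records when the sample count divides evenly, otherwise a
    single record spanning the file.  Per-channel physical min/max are taken
    from the data, so the quantization step is (max - min) / 65535.
    """
    if int(recording.sampling_rate) != recording.sampling_rate:
        raise ValueError("EDF writer requires an integer sampling rate")
    sr = int(recording.sampling_rate)
    n_samples = recording.n_samples
    if n_samples % sr == 0:
        n_records, record_dur, spr = n_samples // sr, 1, sr
    else:
        n_records, record_dur, spr = 1, n_samples / sr, n_samples

    ns = len(recording.channel_names)
    dig_min, dig_max = -32768, 32767
    phys_mins, phys_maxs, digital = [], [], []
    for ch in recording.data:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            hi = lo + 1.0
        # round-trip through the printed 8-char fields so that the scaling
        # we apply matches what any reader reconstructs from the header
        lo_s, hi_s = _fmt_phys(lo), _fmt_phys(hi)
        lo_p, hi_p = float(lo_s), float(hi_s)
        if hi_p <= lo_p:
            hi_p = lo_p + 1.0
            hi_s = _fmt_phys(hi_p)
        scale = (dig_max - dig_min) / (hi_p - lo_p)
        d = np.clip(np.round((ch - lo_p) * scale + dig_min), dig_min, dig_max)
        phys_mins.append(lo_s)
        phys_maxs.append(hi_s)
        digital.append(d.astype("<i2"))

    now = _dt.datetime(2000, 1, 1)
    header = io.BytesIO()
    header.write(_edf_field("0", 8))
    header.write(_edf_field("X X X X", 80))
    header.write(_edf_field("Startdate X X X X", 80))
    header.write(_edf_field(now.strftime("%d.%m.%y"), 8))
    header.write(_edf_field(now.strftime("%H.%M.%S"), 8))
    header.write(_edf_field(256 * (1 + ns), 8))
    header.write(_edf_field("", 44))
    header.write(_edf_field(n_records, 8))
    dur_s = str(record_dur) if record_dur != int(record_dur) else str(int(record_dur))
    if len(dur_s) > 8:
        dur_s = "%.6f" % record_dur
        dur_s = dur_s[:8]
    header.write(_edf_field(dur_s, 8))
    header.write(_edf_field(ns, 4))
    for name in recording.channel_names:
        header.write(_edf_field(name, 16))
    for _ in range(ns):
        header.write(_edf_field("", 80))      # transducer
    for _ in range(ns):
        header.write(_edf_field("uV", 8))     # physical dimension
    for s in phys_mins:
        header.write(_edf_field(s, 8))
    for s in phys_maxs:
        header.write(_edf_field(s, 8))
    for _ in range(ns):
        header.write(_edf_field(dig_min, 8))
    for _ in range(ns):
        header.write(_edf_field(dig_max, 8))
    for _ in range(ns):
        header.write(_edf_field("", 80))      # prefiltering
    for _ in range(ns):
        header.write(_edf_field(spr, 8))
    for _ in range(ns):
        header.write(_edf_field("", 32))

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for rec in range(n_records):
            sl = slice(rec * spr, (rec + 1) * spr)
            for d in digital:
                fh.write(d[sl].tobytes())


def read_edf(path: str | Path) -> MultiChannelRecording:
    """Read an EDF file into a recording in uV, channel names normalized.

    Rejects files whose channels carry inconsistent sampling rates.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size < 256:
        raise ValueError(f"{path.name}: truncated or empty EDF header")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed headers
        raise ValueError(f"{path.name}: not a readable EDF file ({exc})") from exc
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:
        raise ValueError("inconsistent per-channel sampling rates")
    names = [normalize_channel_name(n) for n in raw.ch_names]
    data_uv = raw.get_data() * 1e6  # mne scales EEG to volts
    annotations = None
    if len(raw.annotations):
        annotations = [
            (float(a["onset"]), float(a["onset"] + a["duration"]), str(a["description"]))
            for a in raw.annotations
        ]
    return MultiChannelRecording(
        channel_names=names,
        sampling_rate=float(raw.info["sfreq"]),
        data=data_uv,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Detection matrices (JSON)
# ---------------------------------------------------------------------------

def write_detection_matrix(matrix, path: str | Path) -> None:
    """Serialize a detection matrix (site verdicts + probabilities) to JSON."""
    probs = np.asarray(matrix.probabilities, dtype=float)
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValueError("probabilities outside [0, 1]")
    payload = {
        "site_names": list(matrix.site_names),
        "seconds": int(matrix.seconds),
        "threshold": float(matrix.threshold),
        "verdicts": np.asarray(matrix.verdicts, dtype=int).tolist(),
        "probabilities": probs.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_detection_matrix(path: str | Path):
    from .detection import DetectionMatrix

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = json.loads(path.read_text())
    return DetectionMatrix(
        site_names=list(payload["site_names"]),
        verdicts=np.asarray(payload["verdicts"], dtype=int),
        probabilities=np.asarray(payload["probabilities"], dtype=float),
        threshold=float(payload.get("threshold", 0.5)),
    )


# ---------------------------------------------------------------------------
# Model checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(weights, model_spec, preprocess_config, path: str | Path) -> None:
    """Archive layer weights, model shape parameters and preprocessing config.

    Detection must reproduce training-time preprocessing exactly, so the
    preprocessing settings travel with the weights in one ``.npz`` archive.
    """
    arrays = {}
    for i, (w, b) in enumerate(weights.conv):
        arrays[f"conv{i}_W"] = w
        arrays[f"conv{i}_b"] = b
    for i, (w, b) in enumerate(weights.dense):
        arrays[f"dense{i}_W"] = w
        arrays[f"dense{i}_b"] = b
    meta = {
        "model_spec": model_spec.to_dict(),
        "preprocess": preprocess_config.to_dict(),
        "n_conv": len(weights.conv),
        "n_dense": len(weights.dense),
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path):
    """Load a checkpoint -> (ModelWeights, ModelSpec, PreprocessConfig)."""
    from .cnn import ModelSpec, ModelWeights
    from .preprocess import PreprocessConfig

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode("utf-8"))
        conv = [
            (npz[f"conv{i}_W"], npz[f"conv{i}_b"]) for i in range(meta["n_conv"])
        ]
        dense = [
            (npz[f"dense{i}_W"], npz[f"dense{i}_b"]) for i in range(meta["n_dense"])
        ]
    spec = ModelSpec.from_dict(meta["model_spec"])
    config = PreprocessConfig.from_dict(meta["preprocess"])
    return ModelWeights(conv=conv, dense=dense), spec, config
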