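"""Seizure-onset-zone inference and 10-20 topographic rendering.

From the per-site, per-second detection grid this module extracts the
onset sites (first flagged second and the sites flagged shortly after),
the terminal sites (sites still flagged near the end of the seizure),
and applies the laterality rules:

* midline (z) electrodes never vote on laterality;
* if the lateralized onset sites span both hemispheres the SOZ verdict is
  "both hemispheres" and the seizure is generalized;
* otherwise the SOZ is the single hemisphere containing the lateralized
  onset sites (terminal sites refine but never override the onset), and
  the seizure is focal.

The ear electrodes A1/A2 carry left/right tags like scalp sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .montage import ElectrodeLayout, LEFT, RIGHT, standard_layout
from .detection import DetectionMatrix

__all__ = [
    "SozReport",
    "onset_sites",
    "terminal_sites",
    "classify_soz",
    "classify_seizure_type",
    "analyze_matrix",
    "render_state",
    "render_topomap",
    "LateralityError",
]

LEFT_HEMISPHERE = "left hemisphere"
RIGHT_HEMISPHERE = "right hemisphere"
BOTH_HEMISPHERES = "both hemispheres"
FOCAL = "focal"
GENERALIZED = "generalized"


class LateralityError(ValueError):
    """Laterality cannot be determined (e.g. midline-only onset)."""


@dataclass
class SozReport:
    onset_sites: set[str]
    terminal_sites: set[str]
    soz_verdict: str
    seizure_type: str
    onset_second: int

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["onset_sites"] = sorted(self.onset_sites)
        d["terminal_sites"] = sorted(self.terminal_sites)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def _require_flags(matrix: DetectionMatrix) -> None:
    if not matrix.verdicts.any():
        raise ValueError("no seizure detected: the matrix has no flagged cells")


def onset_sites(
    matrix: DetectionMatrix, onset_window_s: int = 5
) -> tuple[int, set[str]]:
    """First flagged second and the sites flagged within the onset window.

    The onset window spans [onset_second, onset_second + onset_window_s).
    """
    _require_flags(matrix)
    per_second = matrix.verdicts.any(axis=0)
    onset_second = int(np.argmax(per_second))
    window = matrix.verdicts[:, onset_second : onset_second + onset_window_s]
    sites = {
        matrix.site_names[i] for i in np.flatnonzero(window.any(axis=1))
    }
    return onset_second, sites


def terminal_sites(matrix: DetectionMatrix, terminal_window_s: int = 5) -> set[str]:
    """Sites flagged within the last ``terminal_window_s`` flagged seconds."""
    _require_flags(matrix)
    per_second = matrix.verdicts.any(axis=0)
    last = int(len(per_second) - 1 - np.argmax(per_second[::-1]))
    window = matrix.verdicts[:, max(0, last - terminal_window_s + 1) : last + 1]
    return {matrix.site_names[i] for i in np.flatnonzero(window.any(axis=1))}


def _hemispheres_of(sites: set[str], layout: ElectrodeLayout) -> set[str]:
    return {layout.hemisphere(s) for s in layout.lateralized(sites)}


def classify_soz(
    onset: set[str],
    terminal: set[str],
    layout: ElectrodeLayout | None = None,
) -> str:
    """Hemisphere-level SOZ verdict from onset and terminal site sets."""
    layout = layout or standard_layout()
    if not onset:
        raise ValueError("onset site set is empty")
    onset_hemis = _hemispheres_of(onset, layout)
    if not onset_hemis:
        raise LateralityError(
            "onset contains only midline sites; laterality indeterminate"
        )
    if onset_hemis == {LEFT, RIGHT}:
        return BOTH_HEMISPHERES
    return LEFT_HEMISPHERE if onset_hemis == {LEFT} else RIGHT_HEMISPHERE


def classify_seizure_type(
    onset: set[str], layout: ElectrodeLayout | None = None
) -> str:
    """Generalized iff lateralized onset sites occur in both hemispheres."""
    layout = layout or standard_layout()
    if not onset:
        raise ValueError("onset site set is empty")
    hemis = _hemispheres_of(onset, layout)
    if not hemis:
        raise LateralityError(
            "onset contains only midline sites; laterality indeterminate"
        )
    return GENERALIZED if hemis == {LEFT, RIGHT} else FOCAL


def analyze_matrix(
    matrix: DetectionMatrix,
    layout: ElectrodeLayout | None = None,
    onset_window_s: int = 5,
    terminal_window_s: int = 5,
) -> SozReport:
    """Full localization: onset/terminal extraction + verdicts."""
    layout = layout or standard_layout()
    onset_second, onset = onset_sites(matrix, onset_window_s)
    terminal = terminal_sites(matrix, terminal_window_s)
    return SozReport(
        onset_sites=onset,
        terminal_sites=terminal,
        soz_verdict=classify_soz(onset, terminal, layout),
        seizure_type=classify_seizure_type(onset, layout),
        onset_second=onset_second,
    )


def render_state(matrix: DetectionMatrix, second: int) -> dict[str, bool]:
    """Site -> flagged mapping at one second (what a panel colours red)."""
    if not 0 <= second < matrix.seconds:
        raise ValueError(f"second {second} outside [0, {matrix.seconds})")
    return {
        name: bool(matrix.verdicts[i, second])
        for i, name in enumerate(matrix.site_names)
    }


def _draw_head(ax, layout: ElectrodeLayout, flagged: set[str], second: int) -> None:
    import matplotlib.patches as mpatches

    ax.add_patch(mpatches.Circle((0, 0), 1.0, fill=False, lw=1.5))
    ax.add_patch(
        mpatches.Polygon([(-0.1, 0.995), (0, 1.12), (0.1, 0.995)], fill=False, lw=1.5)
    )
    for site, (x, y) in layout.coords.items():
        on = site in flagged
        ax.add_patch(
            mpatches.Circle(
                (x, y), 0.09,
                facecolor="red" if on else "white",
                edgecolor="black", lw=1.0, zorder=3,
            )
        )
        ax.text(x, y, site, ha="center", va="center", fontsize=6, zorder=4,
                color="white" if on else "black")
    ax.set_xlim(-1.35, 1.35)
    ax.set_ylim(-1.25, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"T = {second} s", fontsize=9)


def render_topomap(
    matrix: DetectionMatrix,
    seconds: list[int],
    layout: ElectrodeLayout | None = None,
    out_dir: str | Path = ".",
    prefix: str = "topomap",
) -> list[Path]:
    """Render head-disc panels: one PNG per requested second + a sequence sheet.

    Flagged sites are drawn red on the schematic 10-20 layout.  Returns the
    written file paths (per-second images first, sequence image last).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    layout = layout or standard_layout()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    states = []
    for second in seconds:
        state = render_state(matrix, second)
        states.append(state)
        flagged = {s for s, on in state.items() if on}
        fig, ax = plt.subplots(figsize=(3, 3))
        _draw_head(ax, layout, flagged, second)
        p = out_dir / f"{prefix}_t{second:04d}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    fig, axes = plt.subplots(1, len(seconds), figsize=(3 * len(seconds), 3))
    axes = np.atleast_1d(axes)
    for ax, second, state in zip(axes, seconds, states):
        _draw_head(ax, layout, {s for s, on in state.items() if on}, second)
    p = out_dir / f"{prefix}_sequence.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(p)
    return paths
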