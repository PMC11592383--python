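"""International 10-20 scalp montage: the 21 canonical sites.

The 21 electrodes (19 scalp sites plus the two ear references A1/A2) cover
the whole scalp in the clinical routine montage.  Site names follow the
10-20 convention: odd indices lie over the left hemisphere, even indices
over the right, and a trailing "z" marks the midline.

Coordinates are schematic positions on the unit head disc (nose up), used
only for topographic rendering -- they are not digitized electrode
locations.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical channel order used everywhere in this package.
CANONICAL_SITES: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "A1", "A2", "Fz", "Cz", "Pz",
)

LEFT = "left"
RIGHT = "right"
MIDLINE = "midline"

# Schematic unit-disc positions (x: left-negative, y: nose-positive).
_COORDS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.29, 0.90), "Fp2": (0.29, 0.90),
    "F7": (-0.76, 0.56), "F3": (-0.45, 0.50), "Fz": (0.00, 0.45),
    "F4": (0.45, 0.50), "F8": (0.76, 0.56),
    "A1": (-1.12, -0.08), "T3": (-0.95, 0.00), "C3": (-0.45, 0.00),
    "Cz": (0.00, 0.00), "C4": (0.45, 0.00), "T4": (0.95, 0.00),
    "A2": (1.12, -0.08),
    "T5": (-0.76, -0.56), "P3": (-0.45, -0.50), "Pz": (0.00, -0.45),
    "P4": (0.45, -0.50), "T6": (0.76, -0.56),
    "O1": (-0.29, -0.90), "O2": (0.29, -0.90),
}


def normalize_channel_name(label: str) -> str:
    """Map an EDF channel label dialect onto a bare 10-20 site name.

    Strips an ``"EEG "`` prefix and ``-Ref``/``-REF``/``-LE`` reference
    suffixes, then matches case-insensitively against the canonical names.
    Labels that match no canonical site are returned stripped but otherwise
    unchanged (e.g. ``"ECG"``).
    """
    name = label.strip()
    if name.upper().startswith("EEG "):
        name = name[4:].strip()
    for suffix in ("-Ref", "-REF", "-ref", "-LE", "-le"):
        if name.endswith(suffix):
            name = name[: -len(suffix)].strip()
            break
    for site in CANONICAL_SITES:
        if name.lower() == site.lower():
            return site
    return name


def hemisphere_of(site: str) -> str:
    """Hemisphere tag of a 10-20 site name (odd=left, even=right, z=midline)."""
    if site not in CANONICAL_SITES:
        raise ValueError(f"unknown 10-20 site: {site!r}")
    tail = site[-1]
    if tail in ("z", "Z"):
        return MIDLINE
    return LEFT if int(tail) % 2 == 1 else RIGHT


@dataclass(frozen=True)
class ElectrodeLayout:
    """Site name -> schematic (x, y) on the unit head disc, with hemisphere tags."""

    coords: dict[str, tuple[float, float]]
    hemispheres: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(CANONICAL_SITES) - set(self.coords)
        if missing:
            raise ValueError(f"layout missing sites: {sorted(missing)}")

    def hemisphere(self, site: str) -> str:
        return self.hemispheres[site]

    def lateralized(self, sites: set[str]) -> set[str]:
        """Subset of ``sites`` lying off the midline."""
        return {s for s in sites if self.hemispheres[s] != MIDLINE}

    def mirror_site(self, site: str) -> str:
        """Left/right mirror image of a site (midline sites map to themselves)."""
        if self.hemispheres[site] == MIDLINE:
            return site
        base, idx = site[:-1], int(site[-1])
        return f"{base}{idx - 1 if idx % 2 == 0 else idx + 1}"


def standard_layout() -> ElectrodeLayout:
    """The built-in schematic 10-20 layout for the 21 canonical sites."""
    return ElectrodeLayout(
        coords=dict(_COORDS),
        hemispheres={s: hemisphere_of(s) for s in CANONICAL_SITES},
    )
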