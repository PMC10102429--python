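"""Band registry for the MicaSense RedEdge-MX Dual ten-band camera.

Bands are identified by center wavelength (nm) throughout the package, never
by positional index, so five-band and ten-band stacks can share code paths.
Feature-table columns follow the ``b<wavelength>`` convention (``b650`` is
the mean reflectance of the 650 nm band over a plot).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class Band:
    name: str
    center: int  # nm
    bandwidth: int  # nm

    @property
    def column(self) -> str:
        return f"b{self.center}"


#: The RedEdge-MX Dual band set, in sensor order.
REDEDGE_MX_DUAL: tuple[Band, ...] = (
    Band("coastal_blue", 444, 28),
    Band("blue", 475, 32),
    Band("green_531", 531, 14),
    Band("green", 560, 27),
    Band("red_650", 650, 16),
    Band("red", 668, 14),
    Band("red_edge_705", 705, 10),
    Band("red_edge_717", 717, 12),
    Band("red_edge_740", 740, 18),
    Band("near_infrared", 842, 57),
)

#: Wavelengths used for texture extraction: red, red edge, NIR.
TEXTURE_BANDS: tuple[int, ...] = (650, 705, 842)

#: Wavelengths any vegetation-index computation may require.
VI_BANDS: tuple[int, ...] = (475, 650, 705, 842)


def band_index(registry: Sequence[Band], center: int) -> int:
    """Position of the band with the given center wavelength in *registry*."""
    for i, b in enumerate(registry):
        if b.center == center:
            return i
    from .errors import MissingBandError

    raise MissingBandError(center)


def registry_from_names(names: Sequence[str]) -> tuple[Band, ...]:
    """Rebuild a registry from ``name:center:bandwidth`` strings (TIFF metadata)."""
    out = []
    for s in names:
        name, center, bw = s.rsplit(":", 2)
        out.append(Band(name, int(center), int(bw)))
    return tuple(out)


def registry_to_names(registry: Sequence[Band]) -> list[str]:
    return [f"{b.name}:{b.center}:{b.bandwidth}" for b in registry]
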