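"""BSI aggregation from classified hotspots.

A bone scan hotspot classified as metastatic occupies some area of one of
twelve anatomical regions. Its contribution to the Bone Scan Index is the
fraction of the region's area it covers, weighted by the region's share of
total skeletal mass, expressed in percent. The regional BSI is the sum of
the contributions of the region's metastatic hotspots, and the total BSI is
the sum over regions.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

#: The twelve skeletal regions, in canonical (reporting) order.
REGIONS: tuple[str, ...] = (
    "C_Spine",
    "Clavicle",
    "Costae",
    "Femur",
    "Humerus",
    "L_Spine",
    "Pelvis",
    "Sacrum",
    "Scapula",
    "Skull",
    "Th_Spine",
    "Sternum",
)


@dataclass(frozen=True)
class RegionGeometry:
    """Area and skeletal-mass share of one anatomical region.

    Parameters
    ----------
    region:
        Region label, one of :data:`REGIONS`.
    region_area:
        Projected area of the region in the scan, arbitrary units, > 0.
    mass_fraction:
        Fraction of total skeletal mass in this region, in [0, 1].
    """

    region: str
    region_area: float
    mass_fraction: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region label {self.region!r}")
        if not self.region_area > 0:
            raise ValueError("region_area must be > 0")
        if not 0.0 <= self.mass_fraction <= 1.0:
            raise ValueError("mass_fraction must be in [0, 1]")


@dataclass(frozen=True)
class Hotspot:
    """A detected hotspot: its region, area, and metastasis classification."""

    region: str
    area: float
    is_metastasis: bool

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("hotspot area must be >= 0")


def _check_geometry(geometry: Mapping[str, RegionGeometry]) -> None:
    total_mass = sum(g.mass_fraction for g in geometry.values())
    if total_mass > 1.0 + 1e-9:
        raise ValueError(f"region mass fractions sum to {total_mass:.4f} > 1")


def regional_bsi(
    hotspots: Iterable[Hotspot],
    geometry: Mapping[str, RegionGeometry],
) -> dict[str, float]:
    """Aggregate hotspots into per-region BSI percentages.

    Each metastatic hotspot contributes
    ``(hotspot_area / region_area) * mass_fraction * 100``;
    non-metastatic hotspots contribute nothing. Regions absent from
    ``geometry`` simply report 0 as long as no hotspot falls in them.

    Returns a dict over all twelve regions (zeros included).
    """
    _check_geometry(geometry)
    values = {r: 0.0 for r in REGIONS}
    area_used: dict[str, float] = {}
    for h in hotspots:
        if h.region not in geometry:
            raise KeyError(f"no geometry for region {h.region!r}")
        geo = geometry[h.region]
        used = area_used.get(h.region, 0.0) + h.area
        if used > geo.region_area * (1 + 1e-9):
            raise ValueError(
                f"hotspot areas in {h.region} ({used:g}) exceed region area "
                f"({geo.region_area:g})"
            )
        area_used[h.region] = used
        if h.is_metastasis:
            values[h.region] += h.area / geo.region_area * geo.mass_fraction * 100.0
    return values


def total_bsi(regional: Mapping[str, float] | Sequence[float]) -> float:
    """Sum regional BSI values into the total BSI (percent).

    Accepts either a mapping over region labels or a length-12 sequence in
    :data:`REGIONS` order. Negative inputs are rejected.
    """
    if isinstance(regional, Mapping):
        vals = np.array([regional[r] for r in REGIONS], dtype=float)
    else:
        vals = np.asarray(regional, dtype=float)
        if vals.shape != (len(REGIONS),):
            raise ValueError(f"expected {len(REGIONS)} regional values, got {vals.shape}")
    if np.any(vals < 0):
        raise ValueError("regional BSI values must be non-negative")
    return float(vals.sum())
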