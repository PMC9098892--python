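"""Closed-form histomorphometry.

Lesion volume by the Cavalieri rule over serial section areas, cortical
thickness as the mean of three medio-lateral measurements, cell density as
count over area, and excitatory/inhibitory synaptic-pair density along
outlined dendritic segments. All quantities carry explicit units in their
names (mm², mm³, µm) and inputs are validated rather than silently cast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SectionAreaSeries",
    "DendriteSynapseCounts",
    "lesion_volume",
    "cortical_thickness",
    "cell_density",
    "synaptic_pair_density",
]


@dataclass(frozen=True)
class SectionAreaSeries:
    """Outlined lesion areas (mm²) on serial sections at fixed spacing (mm)."""

    brain_id: str
    areas_mm2: tuple[float, ...]
    section_spacing_mm: float = 0.05  # 50 µm sections

    def __post_init__(self) -> None:
        if len(self.areas_mm2) < 1:
            raise ValueError("at least one section area is required")
        if any(a < 0 for a in self.areas_mm2):
            raise ValueError("section areas must be >= 0")
        if self.section_spacing_mm <= 0:
            raise ValueError("section spacing must be > 0")


@dataclass(frozen=True)
class DendriteSynapseCounts:
    dendrite_id: str
    perimeter_length_um: float
    excitatory_pairs: int
    inhibitory_pairs: int

    def __post_init__(self) -> None:
        if self.perimeter_length_um <= 0:
            raise ValueError("perimeter length must be > 0")
        if self.excitatory_pairs < 0 or self.inhibitory_pairs < 0:
            raise ValueError("pair counts must be >= 0")


def lesion_volume(series: SectionAreaSeries) -> float:
    """Cavalieri estimate: sum of section areas times the spacing (mm³)."""
    return float(np.sum(series.areas_mm2) * series.section_spacing_mm)


def cortical_thickness(measurements_mm) -> float:
    """Mean of the three medio-lateral thickness measurements (mm)."""
    vals = np.asarray(list(measurements_mm), dtype=float)
    if vals.shape != (3,):
        raise ValueError(f"exactly three measurements expected, got {vals.size}")
    if np.any(vals <= 0):
        raise ValueError("thickness measurements must be > 0")
    return float(vals.mean())


def cell_density(count: int, area_mm2: float) -> float:
    """Cells per mm²."""
    if count < 0:
        raise ValueError("cell count must be >= 0")
    if area_mm2 <= 0:
        raise ValueError("area must be > 0")
    return count / area_mm2


def synaptic_pair_density(counts: DendriteSynapseCounts) -> tuple[float, float]:
    """(excitatory, inhibitory) synaptic pairs per µm of dendrite."""
    L = counts.perimeter_length_um
    return counts.excitatory_pairs / L, counts.inhibitory_pairs / L
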