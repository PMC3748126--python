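"""Per-well aggregation: morphometry means, counts and the fusion index.

The myogenic fusion index (MFI) is the percentage of detected nuclei that
reside inside marker-positive myotube outlines — the standard readout of
fusion efficiency.  Morphometry means are computed over non-border myotubes
only (border-clipped shapes bias length/breadth downward and the fields are
non-overlapping, so clipped objects cannot be stitched); counts and the MFI
use all objects.  Empty wells propagate missing values (NaN), never zeros,
so downstream ANOVA is not biased by failed wells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PlateLayout
from .morphometry import CellRecord, MyotubeRecord

__all__ = [
    "WellSummary",
    "myogenic_fusion_index",
    "summarize_well",
    "summaries_to_frame",
]


def myogenic_fusion_index(assigned: int, total: int) -> float:
    """Percent of nuclei inside myotube outlines: 100·assigned/total.

    Undefined (NaN) when no nuclei were detected at all.
    """
    if assigned < 0 or total < 0 or assigned > total:
        raise ValueError("need 0 <= assigned <= total")
    if total == 0:
        return float("nan")
    return 100.0 * assigned / total


@dataclass
class WellSummary:
    """Per-well aggregates over all fields of one well."""

    well: str
    ethanol: bool | None
    gsi: bool | None
    treatment: str | None
    replicate: int | None
    myotube_count: int
    mean_length: float
    mean_breadth: float
    mean_area: float
    mean_perimeter: float
    mean_integrated_intensity: float
    mean_nuclei_per_myotube: float
    mean_myonuclear_area: float
    mean_cell_nuclear_area: float
    undifferentiated_count: int
    total_nuclei: int
    mfi: float


def _mean(values: list[float]) -> float:
    return float(np.mean(values)) if values else float("nan")


def summarize_well(
    myotubes: list[MyotubeRecord],
    cells: list[CellRecord],
    well: str,
    layout: PlateLayout | None = None,
) -> WellSummary:
    """Collapse object records of one well into a :class:`WellSummary`.

    ``cells`` must contain every detected nucleus of the well (assigned and
    unassigned); the MFI denominator is the total nucleus count.
    """
    myotubes = [m for m in myotubes if m.well == well]
    cells = [c for c in cells if c.well == well]
    factors: dict = {"ethanol": None, "gsi": None, "treatment": None, "replicate": None}
    if layout is not None:
        factors.update({
            k: v for k, v in layout.factors(well).items() if k in factors
        })

    interior = [m for m in myotubes if not m.border]
    assigned = sum(1 for c in cells if c.assigned_object is not None)
    unassigned = [c for c in cells if c.assigned_object is None]
    myonuclear: list[float] = [a for m in myotubes for a in m.myonuclear_areas]

    return WellSummary(
        well=well,
        ethanol=factors["ethanol"],
        gsi=factors["gsi"],
        treatment=factors["treatment"],
        replicate=factors["replicate"],
        myotube_count=len(myotubes),
        mean_length=_mean([m.length for m in interior]),
        mean_breadth=_mean([m.breadth for m in interior]),
        mean_area=_mean([m.area for m in interior]),
        mean_perimeter=_mean([m.perimeter for m in interior]),
        mean_integrated_intensity=_mean([m.integrated_intensity for m in interior]),
        mean_nuclei_per_myotube=_mean([float(m.nuclei_count) for m in interior]),
        mean_myonuclear_area=_mean(myonuclear),
        mean_cell_nuclear_area=_mean([c.nuclear_area for c in unassigned]),
        undifferentiated_count=len(unassigned),
        total_nuclei=len(cells),
        mfi=myogenic_fusion_index(assigned, len(cells)),
    )


def summaries_to_frame(summaries: list[WellSummary]) -> pd.DataFrame:
    cols = [
        "well", "ethanol", "gsi", "treatment", "replicate",
        "myotube_count", "mean_length", "mean_breadth", "mean_area",
        "mean_perimeter", "mean_integrated_intensity",
        "mean_nuclei_per_myotube", "mean_myonuclear_area",
        "mean_cell_nuclear_area", "undifferentiated_count",
        "total_nuclei", "mfi",
    ]
    return pd.DataFrame([s.__dict__ for s in summaries], columns=cols)
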