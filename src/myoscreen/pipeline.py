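"""End-to-end orchestration: field images → object tables → well summaries.

Glue around the segmentation, morphometry and aggregation stages so that a
plate can be processed in one call, either from in-memory
:class:`~myoscreen.io.FieldImage` objects or from a directory of TIFFs
written by the generator or an acquisition export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aggregation import WellSummary, summaries_to_frame, summarize_well
from .io import MARKER, NUCLEAR, FieldImage, PlateLayout, load_field
from .morphometry import (
    CellRecord,
    MyotubeRecord,
    assign_nuclei,
    cells_to_frame,
    filter_myotubes,
    measure_myotubes,
    myotubes_to_frame,
)
from .segmentation import SegmentationParams, detect_nuclei, segment_myotubes

__all__ = [
    "PlateResult",
    "analyze_field",
    "analyze_fields",
    "find_fields",
    "analyze_plate_dir",
    "match_objects",
]

_FIELD_RE = re.compile(
    r"^(?P<plate>.+)_(?P<well>[A-H]\d{2})_s(?P<site>\d+)_(?P<channel>marker|nuclear)\.tif$"
)


@dataclass
class PlateResult:
    """Object- and well-level outputs of a plate analysis."""

    myotubes: pd.DataFrame
    cells: pd.DataFrame
    wells: pd.DataFrame

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.myotubes.to_csv(directory / "myotubes.csv", index=False)
        self.cells.to_csv(directory / "cells.csv", index=False)
        self.wells.to_csv(directory / "well_summaries.csv", index=False)


def analyze_field(
    field: FieldImage,
    params: SegmentationParams | None = None,
    *,
    min_nuclei: int = 1,
) -> tuple[list[MyotubeRecord], list[CellRecord]]:
    """Segment, measure and assign one field; returns object records.

    Marker-positive regions with fewer than ``min_nuclei`` assigned nuclei
    are dropped from the myotube list (their nuclei stay assigned for the
    fusion-index bookkeeping only if the region survives; otherwise the
    nuclei count as undifferentiated).
    """
    params = params or SegmentationParams()
    mask = segment_myotubes(field.marker, params, field.pixel_size)
    nuc_mask, nuc_table = detect_nuclei(field.nuclear, params, field.pixel_size)
    records = measure_myotubes(
        mask, field.marker, field.pixel_size, well=field.well, site=field.site
    )
    cells = assign_nuclei(
        mask, nuc_mask, nuc_table, records, well=field.well, site=field.site
    )
    kept = filter_myotubes(records, min_nuclei=min_nuclei)
    kept_ids = {r.object_id for r in kept}
    for c in cells:
        if c.assigned_object is not None and c.assigned_object not in kept_ids:
            c.assigned_object = None
    return kept, cells


def analyze_fields(
    fields: Iterable[FieldImage],
    params: SegmentationParams | None = None,
    layout: PlateLayout | None = None,
    *,
    min_nuclei: int = 1,
) -> PlateResult:
    """Analyze a collection of fields and summarize per well."""
    all_myo: list[MyotubeRecord] = []
    all_cells: list[CellRecord] = []
    wells_seen: list[str] = []
    for field in fields:
        myo, cells = analyze_field(field, params, min_nuclei=min_nuclei)
        all_myo.extend(myo)
        all_cells.extend(cells)
        if field.well not in wells_seen:
            wells_seen.append(field.well)
    summaries: list[WellSummary] = [
        summarize_well(all_myo, all_cells, well, layout) for well in wells_seen
    ]
    return PlateResult(
        myotubes=myotubes_to_frame(all_myo),
        cells=cells_to_frame(all_cells),
        wells=summaries_to_frame(summaries),
    )


def find_fields(directory: str | Path) -> list[tuple[Path, Path]]:
    """Pair marker/nuclear TIFFs in a directory by (plate, well, site)."""
    directory = Path(directory)
    found: dict[tuple, dict] = {}
    for path in sorted(directory.glob("*.tif")):
        m = _FIELD_RE.match(path.name)
        if not m:
            continue
        key = (m["plate"], m["well"], int(m["site"]))
        found.setdefault(key, {})[m["channel"]] = path
    pairs = []
    for key in sorted(found):
        chans = found[key]
        if MARKER in chans and NUCLEAR in chans:
            pairs.append((chans[MARKER], chans[NUCLEAR]))
    return pairs


def analyze_plate_dir(
    directory: str | Path,
    params: SegmentationParams | None = None,
    layout: PlateLayout | None = None,
    *,
    min_nuclei: int = 1,
    pixel_size: float | None = None,
) -> PlateResult:
    """Analyze every field found in a directory of per-channel TIFFs."""
    pairs = find_fields(directory)
    fields = (
        load_field(mp, npth, pixel_size=pixel_size) for mp, npth in pairs
    )
    return analyze_fields(fields, params, layout, min_nuclei=min_nuclei)


def match_objects(
    measured: pd.DataFrame,
    truth: pd.DataFrame,
    *,
    max_dist_px: float = 25.0,
) -> pd.DataFrame:
    """Greedy nearest-centroid match of measured objects to truth objects.

    Both frames need ``well, site`` and centroid columns (``centroid_row/
    centroid_col`` for measurements, ``center_row_px/center_col_px`` for
    truth).  Returns the inner join of matched rows with ``_meas``/``_true``
    suffixes; used by the recovery benchmarks to compare per-object
    measurements against the generator's analytic values.
    """
    out = []
    for (well, site), tgrp in truth.groupby(["well", "site"], sort=True):
        mgrp = measured[(measured["well"] == well) & (measured["site"] == site)]
        if mgrp.empty:
            continue
        mpos = mgrp[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
        taken: set[int] = set()
        for _, trow in tgrp.iterrows():
            d = np.hypot(
                mpos[:, 0] - trow["center_row_px"],
                mpos[:, 1] - trow["center_col_px"],
            )
            order = np.argsort(d)
            for idx in order:
                if d[idx] > max_dist_px:
                    break
                if idx in taken:
                    continue
                taken.add(int(idx))
                mrow = mgrp.iloc[idx]
                out.append({
                    "well": well, "site": site,
                    "length_meas": mrow["length"], "length_true": trow["length_um"],
                    "breadth_meas": mrow["breadth"], "breadth_true": trow["breadth_um"],
                    "area_meas": mrow["area"], "area_true": trow["area_um2"],
                    "perimeter_meas": mrow["perimeter"],
                    "perimeter_true": trow["perimeter_um"],
                    "nuclei_meas": mrow["nuclei_count"], "nuclei_true": trow["n_nuclei"],
                    "clipped": bool(trow.get("clipped", False)),
                })
                break
    return pd.DataFrame(out)
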