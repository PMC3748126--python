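"""Field-image and plate-layout I/O.

Images are plain single-channel grayscale TIFFs, one file per field per
channel; acquisition metadata (plate, well, site, pixel size) travels in the
TIFF ImageDescription tag as JSON so that a write/read round trip preserves
both raster and metadata exactly.  The plate layout — which wells received
which treatments — is a sidecar YAML or CSV, never parsed from filenames.

Conventions: pixel coordinates are 0-based, row-major, origin top-left;
physical measurements are always in µm / µm² via ``pixel_size`` (µm per
pixel).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "FieldImage",
    "PlateLayout",
    "validate_well",
    "load_field",
    "save_field",
    "load_layout",
    "field_filename",
]

_WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")

#: channel-role suffixes used in filenames
MARKER = "marker"
NUCLEAR = "nuclear"


def validate_well(well: str) -> str:
    """Validate a 96-well identifier (A01–H12); returns it unchanged."""
    if not isinstance(well, str) or not _WELL_RE.match(well):
        raise ValueError(f"invalid 96-well identifier: {well!r} (expected A01–H12)")
    return well


@dataclass
class FieldImage:
    """One acquisition site: two co-registered single-channel rasters.

    ``marker`` is the myotube-marker channel (FITC-like), ``nuclear`` the
    nuclear stain (DAPI-like).  ``pixel_size`` is µm per pixel.
    """

    plate: str
    well: str
    site: int
    marker: np.ndarray
    nuclear: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        validate_well(self.well)
        self.marker = np.asarray(self.marker)
        self.nuclear = np.asarray(self.nuclear)
        if self.marker.ndim != 2 or self.nuclear.ndim != 2:
            raise ValueError("channel rasters must be 2-D")
        if self.marker.shape != self.nuclear.shape:
            raise ValueError(
                f"channel shape mismatch: marker {self.marker.shape} vs "
                f"nuclear {self.nuclear.shape}"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.site < 1:
            raise ValueError("site must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.marker.shape


def field_filename(plate: str, well: str, site: int, channel: str) -> str:
    return f"{plate}_{well}_s{site:02d}_{channel}.tif"


def save_field(img: FieldImage, directory: str | Path) -> tuple[Path, Path]:
    """Write both channels as 16-bit grayscale TIFFs with JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for channel, raster in ((MARKER, img.marker), (NUCLEAR, img.nuclear)):
        meta = {
            "plate": img.plate,
            "well": img.well,
            "site": img.site,
            "channel": channel,
            "pixel_size_um": img.pixel_size,
        }
        path = directory / field_filename(img.plate, img.well, img.site, channel)
        tifffile.imwrite(path, np.asarray(raster), description=json.dumps(meta))
        paths.append(path)
    return paths[0], paths[1]


def _read_channel(path: str | Path) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        raster = page.asarray()
        meta: dict = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    return raster, meta


def load_field(
    marker_path: str | Path,
    nuclear_path: str | Path,
    *,
    plate: str | None = None,
    well: str | None = None,
    site: int | None = None,
    pixel_size: float | None = None,
) -> FieldImage:
    """Read a two-channel field from per-channel TIFFs.

    Metadata embedded at save time is used unless overridden; a field
    missing from both the file and the call is an error (images without a
    spatial calibration cannot be measured in physical units).
    """
    marker, m_meta = _read_channel(marker_path)
    nuclear, n_meta = _read_channel(nuclear_path)
    if marker.ndim != 2 or nuclear.ndim != 2:
        raise ValueError("field channels must decode to 2-D rasters")
    if marker.shape != nuclear.shape:
        raise ValueError(
            f"channel shape mismatch: {marker.shape} vs {nuclear.shape}"
        )
    meta = {**n_meta, **m_meta}
    plate = plate if plate is not None else meta.get("plate", "plate")
    well = well if well is not None else meta.get("well")
    site = site if site is not None else meta.get("site", 1)
    pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if well is None:
        raise ValueError("well id missing from metadata and not provided")
    if pixel_size is None:
        raise ValueError(
            "pixel_size missing from metadata and not provided; spatial "
            "calibration is required"
        )
    return FieldImage(
        plate=plate, well=well, site=int(site),
        marker=marker, nuclear=nuclear, pixel_size=float(pixel_size),
    )


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

_LAYOUT_COLUMNS = ["well", "ethanol", "gsi", "treatment", "replicate"]


@dataclass
class PlateLayout:
    """Maps wells to treatment factors (2×2 ethanol × GSI plus free labels).

    Backed by a DataFrame with columns ``well, ethanol, gsi, treatment,
    replicate``; ``ethanol`` and ``gsi`` are booleans, ``treatment`` an
    optional label for non-factorial arms (e.g. rapamycin).
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_LAYOUT_COLUMNS))

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.empty and df.shape[1] == 0:
            df = pd.DataFrame(columns=_LAYOUT_COLUMNS)
        for col in _LAYOUT_COLUMNS:
            if col not in df.columns:
                if col == "treatment":
                    df[col] = None
                elif col == "replicate":
                    df[col] = 1
                else:
                    raise ValueError(f"layout missing required column {col!r}")
        df = df[_LAYOUT_COLUMNS]
        for well in df["well"]:
            validate_well(well)
        dup = df["well"][df["well"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate wells in layout: {sorted(set(dup))}")
        for col in ("ethanol", "gsi"):
            bad = ~df[col].isin([True, False, 0, 1])
            if bad.any():
                raise ValueError(
                    f"column {col!r} must be boolean; offending values: "
                    f"{df.loc[bad, col].unique().tolist()}"
                )
            df[col] = df[col].astype(bool)
        df["replicate"] = df["replicate"].astype(int)
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def wells(self) -> list[str]:
        return self.table["well"].tolist()

    def factors(self, well: str) -> dict:
        row = self.table[self.table["well"] == well]
        if row.empty:
            raise KeyError(f"well {well} not in layout")
        return row.iloc[0].to_dict()


def load_layout(source: str | Path | dict | pd.DataFrame) -> PlateLayout:
    """Load a plate layout from YAML (``wells:`` list), CSV, dict or frame."""
    if isinstance(source, PlateLayout):
        return source
    if isinstance(source, pd.DataFrame):
        return PlateLayout(source)
    if isinstance(source, dict):
        return PlateLayout(pd.DataFrame(source.get("wells", source)))
    path = Path(source)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        rows = data.get("wells", [])
        return PlateLayout(pd.DataFrame(rows, columns=None))
    if path.suffix.lower() in {".csv", ".tsv"}:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        return PlateLayout(pd.read_csv(path, sep=sep))
    raise ValueError(f"unsupported layout format: {path.suffix}")
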