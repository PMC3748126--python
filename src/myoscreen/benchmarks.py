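"""Reproducible benchmark studies at the assay's published scale.

Each function regenerates its inputs with the synthetic renderer (or a
closed-form simulator for the statistics calibrations), runs the pipeline
and returns summary numbers.  They are what the acceptance machinery and
the examples call; problem sizes are chosen so a full run completes in a
few minutes on one core (rationale in the methods note).

Conditions simulated throughout: vehicle, ethanol (100 mM) and rapamycin
(100 nM) morphology presets, and the 2×2 ethanol × gamma-secretase-
inhibitor factorial for the fusion-index statistics.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import myogenic_fusion_index
from .morphometry import _pixel_corners, measure_region
from .pipeline import analyze_fields, match_objects
from .plate_stats import twoway_anova
from .synthetic import (
    Capsule,
    ConditionPreset,
    PlateSpec,
    capsule_area,
    capsule_perimeter,
    condition_preset,
    generate_plate,
)

__all__ = [
    "stub_acquisition_preset",
    "acquisition_image_count",
    "morphometry_oracle_suite",
    "three_condition_spec",
    "ordering_benchmark",
    "recovery_benchmark",
    "fusion_index_fixtures",
    "interaction_null_calibration",
    "rescue_interaction_power",
    "balanced_f_discrepancy",
]

#: 2×2 fusion-index cell means used by the statistics calibrations:
#: control and ethanol from the published per-condition values; the
#: GSI arm elevates the index and fully rescues the ethanol deficit.
MFI_CELLS = {
    (False, False): 14.9,
    (True, False): 13.5,
    (False, True): 16.9,
    (True, True): 16.9,
}
#: per-cell SDs: 1.26 (no ethanol) and 2.12 (ethanol), the published scale
MFI_SDS = {
    (False, False): 1.26,
    (True, False): 2.12,
    (False, True): 1.26,
    (True, True): 2.12,
}


def stub_acquisition_preset() -> ConditionPreset:
    """Miniature condition for acquisition-arithmetic runs on stub fields."""
    return ConditionPreset(
        name="stub",
        mean_length=24.0, sd_length=2.0,
        mean_breadth=8.0, sd_breadth=0.5,
        mean_nuclei_per_myotube=1.0, sd_nuclei=0.0,
        myotube_density=1, background_cell_density=2,
        marker_intensity_mean=300.0,
        myonucleus_area_mean=12.0, myonucleus_area_sd=1.0,
        cell_nucleus_area_mean=12.0, cell_nucleus_area_sd=1.0,
    )


def acquisition_image_count(
    seed: int, outdir: str | Path | None = None, field_px: int = 64
) -> dict:
    """Render a full 96-well plate at 36 fields/well; count images written.

    Uses stub fields so the arithmetic (96 × 36 = 3,456 images per channel)
    is exercised at full plate scale in seconds.
    """
    wells = [
        (f"{r}{c:02d}", stub_acquisition_preset())
        for r in "ABCDEFGH" for c in range(1, 13)
    ]
    spec = PlateSpec(
        wells=wells, fields_per_well=36, field_shape=(field_px, field_px),
        pixel_size=1.0, noise_sd=5.0, blur_sigma=0.5, rng_seed=seed,
    )
    if outdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return _count_plate_images(spec, tmp)
    return _count_plate_images(spec, outdir)


def _count_plate_images(spec: PlateSpec, outdir: str | Path) -> dict:
    fields, _ = generate_plate(spec, outdir)
    out = Path(outdir)
    return {
        "fields_rendered": len(fields),
        "marker_images": len(list(out.glob("*_marker.tif"))),
        "nuclear_images": len(list(out.glob("*_nuclear.tif"))),
    }


def _projection_feret(points: np.ndarray, n_angles: int = 720) -> tuple[float, float]:
    theta = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    proj = np.asarray(points, float) @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.max()), float(widths.min())


def morphometry_oracle_suite(seed: int) -> dict:
    """Measure rasterized rectangles and capsules against analytic geometry.

    Returns worst-case relative errors (percent): area and perimeter against
    the closed forms, length/breadth against a 720-angle brute-force
    projection sweep over the same pixel-corner cloud.
    """
    rng = np.random.default_rng(seed)
    area_err, perim_err, feret_err = [], [], []

    # axis-aligned rectangles: exact closed forms
    for h, w in ((10, 40), (7, 23), (15, 60)):
        labels = np.zeros((h + 10, w + 10), dtype=int)
        labels[5:5 + h, 5:5 + w] = 1
        rec = measure_region(labels, 1, np.zeros(labels.shape), 1.0)
        area_err.append(abs(rec.area - h * w) / (h * w) * 100)
        perim_err.append(abs(rec.perimeter - 2 * (h + w)) / (2 * (h + w)) * 100)
        corners = _pixel_corners(np.argwhere(labels == 1).astype(float))
        o_max, o_min = _projection_feret(corners)
        feret_err.append(abs(rec.length - o_max) / o_max * 100)
        feret_err.append(abs(rec.breadth - o_min) / o_min * 100)

    # randomly oriented capsules: closed-form area/perimeter
    for _ in range(12):
        length = float(rng.uniform(80, 180))
        breadth = float(rng.uniform(24, min(52, length - 10)))
        cap = Capsule(
            center=(128.0, 128.0), orientation=float(rng.uniform(0, math.pi)),
            length=length, breadth=breadth,
        )
        g = np.arange(256) + 0.5
        grid = np.stack(np.meshgrid(g, g, indexing="ij"), -1).reshape(-1, 2)
        labels = cap.contains(grid).reshape(256, 256).astype(int)
        rec = measure_region(labels, 1, np.zeros(labels.shape), 1.0)
        true_area = capsule_area(length, breadth)
        true_perim = capsule_perimeter(length, breadth)
        area_err.append(abs(rec.area - true_area) / true_area * 100)
        perim_err.append(abs(rec.perimeter - true_perim) / true_perim * 100)
        corners = _pixel_corners(np.argwhere(labels == 1).astype(float))
        o_max, o_min = _projection_feret(corners)
        feret_err.append(abs(rec.length - o_max) / o_max * 100)
        feret_err.append(abs(rec.breadth - o_min) / o_min * 100)

    return {
        "max_area_error_pct": float(max(area_err)),
        "max_perimeter_error_pct": float(max(perim_err)),
        "max_feret_vs_oracle_pct": float(max(feret_err)),
    }


CONDITION_ROWS = {"A": "vehicle", "B": "ethanol", "C": "rapamycin"}


def three_condition_spec(
    seed: int,
    wells_per_condition: int,
    fields_per_well: int,
    field_px: int,
    pixel_size: float,
    **spec_kwargs,
) -> PlateSpec:
    """Plate spec with rows A/B/C holding vehicle/ethanol/rapamycin wells."""
    wells = []
    for row, name in zip("ABC", ("vehicle", "ethanol", "rapamycin")):
        preset = condition_preset(name)
        for j in range(wells_per_condition):
            wells.append((f"{row}{j + 1:02d}", preset))
    return PlateSpec(
        wells=wells, fields_per_well=fields_per_well,
        field_shape=(field_px, field_px), pixel_size=pixel_size,
        rng_seed=seed, **spec_kwargs,
    )


def ordering_benchmark(
    seed: int, wells_per_condition: int = 8, fields_per_well: int = 4
) -> dict:
    """End-to-end condition ordering on a plate under default blur/noise.

    Returns per-condition means of the measured well summaries, the count
    recovery relative to ground truth, and whether the strict ordering
    vehicle > ethanol > rapamycin holds for length, breadth, area,
    perimeter and the fusion index.
    """
    spec = three_condition_spec(
        seed, wells_per_condition, fields_per_well, field_px=512, pixel_size=1.0
    )
    fields, truth = generate_plate(spec)
    result = analyze_fields(fields)
    wells = result.wells.copy()
    wells["condition"] = [CONDITION_ROWS[w[0]] for w in wells["well"]]
    means = wells.groupby("condition")[
        ["mean_length", "mean_breadth", "mean_area", "mean_perimeter", "mfi",
         "mean_nuclei_per_myotube", "mean_integrated_intensity"]
    ].mean()
    ordered = all(
        means.loc["vehicle", col] > means.loc["ethanol", col] > means.loc["rapamycin", col]
        for col in ("mean_length", "mean_breadth", "mean_area", "mean_perimeter", "mfi")
    )
    true_myotubes = int((truth.objects["object_class"] == "myotube").sum())
    true_nuclei = int(len(truth.nuclei))
    return {
        "condition_means": means,
        "wells": wells,
        "n_fields": len(fields),
        "strictly_ordered": bool(ordered),
        "myotube_count_error_pct": abs(len(result.myotubes) - true_myotubes)
        / true_myotubes * 100,
        "nucleus_count_error_pct": abs(len(result.cells) - true_nuclei)
        / true_nuclei * 100,
        "conservation_holds": _nuclei_conserved(result),
    }


def _nuclei_conserved(result) -> bool:
    """Per well: assigned nuclei + undifferentiated count = total detected."""
    assigned = (
        result.cells[result.cells["assigned_object"].notna()]
        .groupby("well").size()
    )
    for row in result.wells.itertuples(index=False):
        n_assigned = int(assigned.get(row.well, 0))
        if n_assigned + row.undifferentiated_count != row.total_nuclei:
            return False
    return True


def recovery_benchmark(
    seed: int, wells_per_condition: int = 4, fields_per_well: int = 2
) -> dict:
    """Per-object morphometry recovery on noise-free plates.

    Fields are rendered at 0.5 µm/px (768×768 px) without camera noise;
    measured length/breadth/area of every unclipped myotube is compared
    with the generator's analytic truth.  Returns the fraction of objects
    with all three measurements within 3%.
    """
    spec = three_condition_spec(
        seed, wells_per_condition, fields_per_well, field_px=768,
        pixel_size=0.5, noise_sd=0.0,
    )
    fields, truth = generate_plate(spec)
    result = analyze_fields(fields)
    matched = match_objects(
        result.myotubes, truth.objects[truth.objects["object_class"] == "myotube"],
        max_dist_px=40.0,
    )
    unclipped = matched[~matched["clipped"]]
    ok = np.ones(len(unclipped), dtype=bool)
    for f in ("length", "breadth", "area"):
        rel = (unclipped[f + "_meas"] - unclipped[f + "_true"]).abs() / unclipped[f + "_true"]
        ok &= (rel <= 0.03).to_numpy()
    return {
        "n_unclipped": int(len(unclipped)),
        "fraction_within_3pct": float(ok.mean()) if len(unclipped) else float("nan"),
        "matched": matched,
    }


def fusion_index_fixtures() -> dict:
    """Exact fusion-index values on constructed counts."""
    return {
        "mfi_3_of_20": myogenic_fusion_index(3, 20),
        "mfi_0_of_20": myogenic_fusion_index(0, 20),
        "mfi_50_of_50": myogenic_fusion_index(50, 50),
    }


def _simulate_factorial(
    rng: np.random.Generator, cells: dict, sds: dict, n: int
) -> pd.DataFrame:
    rows = []
    for (a, b), mu in cells.items():
        for y in rng.normal(mu, sds[(a, b)], n):
            rows.append({"y": y, "ethanol": a, "gsi": b})
    return pd.DataFrame(rows)


def interaction_null_calibration(
    seed: int, n_sims: int = 1000, n_per_cell: int = 24, alpha: float = 0.05
) -> dict:
    """Type-I error of the interaction test under an additive null.

    Cell means carry the ethanol and GSI main effects but no interaction;
    per-cell SDs are the published fusion-index scale.  Returns the
    fraction of simulations rejecting the (true) null at ``alpha``.
    """
    null_cells = {
        (False, False): 14.9,
        (True, False): 13.5,
        (False, True): 16.9,
        (True, True): 15.5,   # 14.9 − 1.4 + 2.0: additive, no interaction
    }
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        df = _simulate_factorial(rng, null_cells, MFI_SDS, n_per_cell)
        hits += twoway_anova(df, "y").interaction_p < alpha
    return {"n_sims": n_sims, "type_i_error": hits / n_sims}


def rescue_interaction_power(
    seed: int, n_sims: int = 300, n_per_cell: int = 24, alpha: float = 0.001
) -> dict:
    """Power to detect the programmed complete-rescue interaction.

    The ethanol deficit (14.9 → 13.5) is abolished in the GSI arm; per-cell
    SDs are the published scale.  Returns the fraction of simulations with
    interaction p below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        df = _simulate_factorial(rng, MFI_CELLS, MFI_SDS, n_per_cell)
        hits += twoway_anova(df, "y").interaction_p < alpha
    return {"n_sims": n_sims, "power": hits / n_sims}


def balanced_f_discrepancy(seed: int, n_designs: int = 10) -> dict:
    """Max relative gap between module F statistics and closed-form SS.

    Random balanced 2×2 designs; the reference recomputes the three F
    ratios directly from cell means and residual sums of squares.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_designs):
        n = int(rng.integers(4, 25))
        cells = {
            (a, b): rng.normal(rng.uniform(5, 20), rng.uniform(0.5, 3.0), n)
            for a in (False, True) for b in (False, True)
        }
        rows = [
            {"y": y, "ethanol": a, "gsi": b}
            for (a, b), v in cells.items() for y in v
        ]
        df = pd.DataFrame(rows)
        res = twoway_anova(df, "y")
        m = {k: v.mean() for k, v in cells.items()}
        grand = float(df["y"].mean())
        a_means = {a: np.mean([m[(a, b)] for b in (False, True)]) for a in (False, True)}
        b_means = {b: np.mean([m[(a, b)] for a in (False, True)]) for b in (False, True)}
        ss_a = 2 * n * sum((a_means[a] - grand) ** 2 for a in (False, True))
        ss_b = 2 * n * sum((b_means[b] - grand) ** 2 for b in (False, True))
        ss_ab = n * sum(
            (m[(a, b)] - a_means[a] - b_means[b] + grand) ** 2
            for a in (False, True) for b in (False, True)
        )
        mse = sum(((v - m[k]) ** 2).sum() for k, v in cells.items()) / (4 * (n - 1))
        for term, ss in (("ethanol", ss_a), ("gsi", ss_b), ("interaction", ss_ab)):
            f_ref = ss / mse
            f_mod = float(res.anova.loc[term, "F"])
            worst = max(worst, abs(f_mod - f_ref) / f_ref)
    return {"max_relative_f_gap": worst}
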