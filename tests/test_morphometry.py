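"""Morphometry tests: Feret calipers vs projection oracle, analytic shapes,
calibration linearity, nucleus assignment bookkeeping."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from myoscreen import (
    LabelMask,
    assign_nuclei,
    feret_diameters,
    filter_myotubes,
    measure_region,
)
from myoscreen.morphometry import MyotubeRecord, _pixel_corners
from myoscreen.synthetic import Capsule, capsule_area


def projection_feret(points: np.ndarray, n_angles: int = 720) -> tuple[float, float]:
    """Brute-force caliper oracle: directional widths over an angle sweep."""
    theta = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    proj = np.asarray(points, float) @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.max()), float(widths.min())


def rasterize_capsule(length, breadth, orientation, shape=(256, 256)):
    c = Capsule(
        center=(shape[0] / 2, shape[1] / 2), orientation=orientation,
        length=length, breadth=breadth,
    )
    g = np.arange(shape[0]) + 0.5
    h = np.arange(shape[1]) + 0.5
    grid = np.stack(np.meshgrid(g, h, indexing="ij"), -1).reshape(-1, 2)
    return c.contains(grid).reshape(shape)


def _rect_labels(h=10, w=40, pad=5):
    labels = np.zeros((h + 2 * pad, w + 2 * pad), dtype=int)
    labels[pad:pad + h, pad:pad + w] = 1
    return labels


class TestMeasureRegion:
    def test_rectangle_geometry(self):
        """40×10 px rectangle at 1 µm/px: analytic area/Feret/perimeter."""
        labels = _rect_labels()
        marker = np.zeros(labels.shape)
        rec = measure_region(labels, 1, marker, 1.0)
        assert rec.area == 400.0
        assert rec.breadth == pytest.approx(10.0)
        assert rec.length == pytest.approx(math.hypot(40, 10), rel=1e-9)
        assert rec.perimeter == pytest.approx(100.0, rel=0.05)
        assert not rec.border

    def test_integrated_intensity(self):
        labels = _rect_labels()
        marker = np.where(labels > 0, 200.0, 7.0)
        rec = measure_region(labels, 1, marker, 1.0)
        assert rec.integrated_intensity == 400 * 200.0

    def test_capsule_at_table_scale(self):
        """Rasterized 178×46 px capsule recovers its analytic morphometry."""
        mask = rasterize_capsule(178.0, 46.0, 0.3)
        rec = measure_region(mask.astype(int), 1, np.zeros(mask.shape), 1.0)
        assert abs(rec.length - 178.0) <= 2.0
        assert abs(rec.breadth - 46.0) <= 2.0
        assert abs(rec.area - capsule_area(178.0, 46.0)) / capsule_area(178.0, 46.0) < 0.02

    def test_single_pixel_convention(self):
        labels = np.zeros((9, 9), dtype=int)
        labels[4, 4] = 1
        rec = measure_region(labels, 1, np.zeros((9, 9)), 0.65)
        assert rec.length == rec.breadth == 0.65
        assert rec.perimeter == pytest.approx(4 * 0.65)
        assert rec.area == pytest.approx(0.65**2)

    def test_missing_label_raises(self):
        with pytest.raises(ValueError, match="not present"):
            measure_region(np.zeros((5, 5), int), 3, np.zeros((5, 5)), 1.0)

    def test_border_flag(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[0:5, 0:5] = 1
        rec = measure_region(labels, 1, np.zeros((20, 20)), 1.0)
        assert rec.border

    @pytest.mark.parametrize(
        "length,breadth,orientation",
        [(120.0, 30.0, 0.0), (150.0, 40.0, 0.7), (90.0, 25.0, 1.2),
         (178.0, 46.0, 2.4), (60.0, 50.0, 0.35)],
    )
    def test_calipers_match_projection_oracle(self, length, breadth, orientation):
        """Hull calipers agree with a 720-angle projection sweep to <1%."""
        mask = rasterize_capsule(length, breadth, orientation)
        corners = _pixel_corners(np.argwhere(mask).astype(float))
        max_f, min_f = feret_diameters(corners)
        o_max, o_min = projection_feret(corners)
        assert abs(max_f - o_max) / o_max < 0.01
        assert abs(min_f - o_min) / o_min < 0.01

    def test_calibration_linearity(self):
        """Doubling pixel_size doubles lengths and quadruples area exactly."""
        mask = rasterize_capsule(100.0, 30.0, 0.5).astype(int)
        marker = np.zeros(mask.shape)
        r1 = measure_region(mask, 1, marker, 1.0)
        r2 = measure_region(mask, 1, marker, 2.0)
        assert r2.length == pytest.approx(2 * r1.length, rel=1e-12)
        assert r2.breadth == pytest.approx(2 * r1.breadth, rel=1e-12)
        assert r2.perimeter == pytest.approx(2 * r1.perimeter, rel=1e-12)
        assert r2.area == pytest.approx(4 * r1.area, rel=1e-12)

    def test_shape_invariants(self):
        """Isoperimetric inequality and area ≤ length·breadth (2% slack)."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            L = rng.uniform(60, 170)
            B = rng.uniform(20, min(50, L - 5))
            mask = rasterize_capsule(L, B, rng.uniform(0, np.pi)).astype(int)
            rec = measure_region(mask, 1, np.zeros(mask.shape), 1.0)
            assert 4 * math.pi * rec.area <= rec.perimeter**2 * 1.02
            assert rec.area <= rec.length * rec.breadth * 1.02


def _square_nucleus_mask(shape, top_left, size, label=1):
    m = np.zeros(shape, dtype=int)
    r, c = top_left
    m[r:r + size, c:c + size] = label
    return m


class TestAssignNuclei:
    def _table(self, entries):
        return pd.DataFrame(
            [
                {"nucleus_id": i + 1, "centroid_row": r, "centroid_col": c,
                 "area_um2": a}
                for i, (r, c, a) in enumerate(entries)
            ]
        )

    def _myotube_mask(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[5:25, 5:20] = 1
        return LabelMask(labels=labels, role="marker", n_objects=1)

    def test_inside_nucleus_assigned(self):
        myo = self._myotube_mask()
        nuc = LabelMask(
            labels=_square_nucleus_mask((40, 40), (10, 10), 4),
            role="nuclear", n_objects=1,
        )
        rec = MyotubeRecord(
            object_id=1, well="A01", site=1, area=300.0, perimeter=70.0,
            length=20.0, breadth=15.0, integrated_intensity=0.0,
            centroid_row=15.0, centroid_col=12.0, border=False,
        )
        cells = assign_nuclei(myo, nuc, self._table([(11.5, 11.5, 28.0)]), [rec])
        assert cells[0].assigned_object == 1
        assert rec.nuclei_count == 1
        assert rec.myonuclear_areas == [28.0]

    def test_centroid_outside_is_unassigned(self):
        """A nucleus overlapping the outline but centred outside stays out."""
        myo = self._myotube_mask()            # region cols 5..19
        yy, xx = np.mgrid[0:40, 0:40]
        disc = ((yy - 15) ** 2 + (xx - 21) ** 2 <= 9).astype(int)  # ~40% inside
        nuc = LabelMask(labels=disc, role="nuclear", n_objects=1)
        cells = assign_nuclei(myo, nuc, self._table([(15.0, 21.0, 28.0)]))
        assert cells[0].assigned_object is None

    def test_bookkeeping_three_in_two_out(self):
        myo = self._myotube_mask()
        labels = np.zeros((40, 40), dtype=int)
        for i, (r, c) in enumerate([(8, 8), (14, 12), (20, 10), (8, 30), (30, 30)], 1):
            labels[r:r + 2, c:c + 2] = i
        nuc = LabelMask(labels=labels, role="nuclear", n_objects=5)
        rec = MyotubeRecord(
            object_id=1, well="A01", site=1, area=300.0, perimeter=70.0,
            length=20.0, breadth=15.0, integrated_intensity=0.0,
            centroid_row=15.0, centroid_col=12.0, border=False,
        )
        table = self._table([
            (8.5, 8.5, 20.0), (14.5, 12.5, 21.0), (20.5, 10.5, 22.0),
            (8.5, 30.5, 23.0), (30.5, 30.5, 24.0),
        ])
        cells = assign_nuclei(myo, nuc, table, [rec])
        assert rec.nuclei_count == 3
        unassigned = [c for c in cells if c.assigned_object is None]
        assert len(unassigned) == 2
        # conservation: every nucleus appears exactly once
        assert len(cells) == 5

    def test_dimension_mismatch(self):
        myo = self._myotube_mask()
        nuc = LabelMask(labels=np.zeros((20, 20), int), role="nuclear", n_objects=0)
        with pytest.raises(ValueError, match="dimensions"):
            assign_nuclei(myo, nuc, self._table([]))


class TestFilterMyotubes:
    def _records(self, counts):
        recs = []
        for i, n in enumerate(counts, 1):
            r = MyotubeRecord(
                object_id=i, well="A01", site=1, area=100.0, perimeter=40.0,
                length=20.0, breadth=6.0, integrated_intensity=0.0,
                centroid_row=0.0, centroid_col=0.0, border=False,
            )
            r.nuclei_count = n
            recs.append(r)
        return recs

    @pytest.mark.parametrize("min_nuclei,expected", [(0, 3), (1, 2), (2, 1)])
    def test_min_nuclei_gate(self, min_nuclei, expected):
        recs = self._records([0, 1, 3])
        assert len(filter_myotubes(recs, min_nuclei)) == expected
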