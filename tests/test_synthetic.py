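"""Generator tests: sampling distributions, rendering, plate determinism."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from myoscreen import (
    PlacementError,
    PlateSpec,
    capsule_area,
    capsule_perimeter,
    condition_preset,
    generate_plate,
    render_field,
    sample_myotube,
)
from myoscreen.synthetic import Capsule, FieldSample, MyotubeSample, Nucleus

from conftest import stub_preset


class TestSampleMyotube:
    def test_vehicle_means_recovered(self):
        """10,000 vehicle draws recover the preset morphology means."""
        rng = np.random.default_rng(0)
        preset = condition_preset("vehicle")
        draws = [sample_myotube(preset, rng) for _ in range(10_000)]
        lengths = np.array([d.capsule.length for d in draws])
        breadths = np.array([d.capsule.breadth for d in draws])
        nuclei = np.array([len(d.nuclei) for d in draws], dtype=float)
        assert abs(lengths.mean() - 178.0) / 178.0 < 0.02
        assert abs(breadths.mean() - 46.2) / 46.2 < 0.02
        # distributional fidelity: sample means within 2 standard errors
        for sample, mean in ((lengths, 178.0), (breadths, 46.2), (nuclei, 6.0)):
            se = sample.std(ddof=1) / math.sqrt(sample.size)
            assert abs(sample.mean() - mean) < 2 * se

    def test_ethanol_nuclei_mean(self):
        """Ethanol draws average ~4 nuclei per myotube."""
        rng = np.random.default_rng(1)
        preset = condition_preset("ethanol")
        counts = [len(sample_myotube(preset, rng).nuclei) for _ in range(10_000)]
        assert abs(np.mean(counts) - 4.0) / 4.0 < 0.05

    def test_zero_sd_is_degenerate(self, rng):
        preset = condition_preset("vehicle")
        preset = replace(preset, sd_length=0.0, sd_breadth=0.0, sd_nuclei=0.0)
        for _ in range(20):
            d = sample_myotube(preset, rng)
            assert d.capsule.length == 178.0
            assert d.capsule.breadth == 46.2
            assert len(d.nuclei) == 6

    def test_postconditions(self, rng):
        """Dimensions positive, ≥1 nucleus, all nucleus centres in capsule."""
        preset = condition_preset("rapamycin")
        for _ in range(50):
            d = sample_myotube(preset, rng)
            assert d.capsule.length > 0 and d.capsule.breadth > 0
            assert d.capsule.breadth < d.capsule.length
            assert len(d.nuclei) >= 1
            centers = np.array([n.center for n in d.nuclei])
            assert d.capsule.contains(centers).all()

    def test_overcrowded_capsule_raises(self, rng):
        """A capsule that cannot hold its nuclei is an explicit error."""
        preset = stub_preset(
            mean_length=16.0, sd_length=0.0, mean_breadth=7.0, sd_breadth=0.0,
            mean_nuclei_per_myotube=40.0, sd_nuclei=0.0,
            myonucleus_area_mean=9.0, myonucleus_area_sd=0.0,
        )
        with pytest.raises(PlacementError):
            for _ in range(20):
                sample_myotube(preset, rng)

    def test_preset_ordering_by_construction(self):
        """True mean length/breadth/area order vehicle > ethanol > rapamycin."""
        means = {}
        for name in ("vehicle", "ethanol", "rapamycin"):
            p = condition_preset(name)
            rng = np.random.default_rng(5)
            dims = [sample_myotube(p, rng).capsule for _ in range(2000)]
            means[name] = (
                np.mean([c.length for c in dims]),
                np.mean([c.breadth for c in dims]),
                np.mean([c.area for c in dims]),
            )
        for i in range(3):
            assert means["vehicle"][i] > means["ethanol"][i] > means["rapamycin"][i]


class TestRenderField:
    def _spec(self, **kw):
        defaults = dict(
            wells=[("A01", stub_preset())], field_shape=(100, 100),
            pixel_size=1.0, noise_sd=0.0, blur_sigma=0.0,
            background_level=0.0, rng_seed=0,
        )
        defaults.update(kw)
        return PlateSpec(**defaults)

    def test_empty_field_is_background(self, rng):
        spec = self._spec(background_level=100.0)
        img, truth = render_field(FieldSample([], []), spec, rng)
        assert (img.marker == 100).all() and (img.nuclear == 100).all()
        assert len(truth.objects) == 0 and len(truth.nuclei) == 0

    def test_capsule_pixel_count_matches_analytic_area(self, rng):
        """A 40×10 µm capsule covers ≈ L·B − B² + π(B/2)² = 378.5 px at 1 µm/px."""
        spec = self._spec()
        cap = Capsule(center=(50.0, 50.0), orientation=0.4, length=40.0, breadth=10.0)
        sample = FieldSample(
            [MyotubeSample(capsule=cap, nuclei=[], marker_intensity=500.0)], []
        )
        img, truth = render_field(sample, spec, rng)
        analytic = capsule_area(40.0, 10.0)
        assert abs(int((img.marker > 0).sum()) - analytic) / analytic < 0.02
        assert truth.objects.loc[0, "area_um2"] == pytest.approx(analytic)
        assert truth.objects.loc[0, "perimeter_um"] == pytest.approx(
            capsule_perimeter(40.0, 10.0)
        )

    def test_background_cell_only(self, rng):
        """Marker channel stays blank; nuclear channel has one component."""
        from scipy import ndimage as ndi

        spec = self._spec()
        sample = FieldSample([], [Nucleus(center=(30.0, 60.0), area=120.0)])
        img, truth = render_field(sample, spec, rng)
        assert (img.marker == 0).all()
        _, n = ndi.label(img.nuclear > 0)
        assert n == 1
        assert truth.objects["object_class"].tolist() == ["cell"]

    def test_nucleus_membership_is_unique(self, clean_field):
        """Every ground-truth nucleus belongs to exactly one object."""
        _, truth, _ = clean_field
        assert truth.nuclei["nucleus_id"].is_unique
        per_object = truth.nuclei.groupby("object_id").size()
        expected = truth.objects.set_index("object_id")["n_nuclei"]
        assert per_object.reindex(expected.index, fill_value=0).equals(
            expected.astype(per_object.dtype)
        )


class TestGeneratePlate:
    def test_single_well_single_field(self, tmp_path):
        spec = PlateSpec(
            wells=[("H12", stub_preset())], fields_per_well=1,
            field_shape=(64, 64), pixel_size=1.0, rng_seed=3,
        )
        fields, truth = generate_plate(spec, tmp_path)
        assert len(fields) == 1
        assert len(list(tmp_path.glob("*_marker.tif"))) == 1
        assert len(list(tmp_path.glob("*_nuclear.tif"))) == 1

    def test_seeded_determinism(self, tmp_path):
        """Same seed → byte-identical outputs; different seed → different truth."""
        spec = PlateSpec(
            wells=[("A01", stub_preset()), ("B02", stub_preset())],
            fields_per_well=2, field_shape=(96, 96), pixel_size=1.0, rng_seed=42,
        )
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        _, t1 = generate_plate(spec, d1)
        _, t2 = generate_plate(spec, d2)
        for p1 in sorted(d1.glob("*.tif")):
            p2 = d2 / p1.name
            assert p1.read_bytes() == p2.read_bytes()
        assert t1.objects.equals(t2.objects) and t1.nuclei.equals(t2.nuclei)

        spec_b = replace(spec, rng_seed=43)
        _, t3 = generate_plate(spec_b)
        assert not t1.objects["length_um"].equals(t3.objects["length_um"])

    def test_nucleus_conservation_per_field(self, clean_field):
        """Total nuclei = myotube nuclei + background-cell nuclei."""
        _, truth, _ = clean_field
        obj = truth.objects
        n_myo = obj.loc[obj.object_class == "myotube", "n_nuclei"].sum()
        n_cell = obj.loc[obj.object_class == "cell", "n_nuclei"].sum()
        assert len(truth.nuclei) == n_myo + n_cell

    def test_duplicate_well_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PlateSpec(wells=[("A01", stub_preset()), ("A01", stub_preset())])

    def test_invalid_well_rejected(self):
        with pytest.raises(ValueError, match="well"):
            PlateSpec(wells=[("Q99", stub_preset())])
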