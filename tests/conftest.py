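"""Shared fixtures: small synthetic fields and plates with ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from myoscreen import (
    ConditionPreset,
    PlateSpec,
    analyze_fields,
    condition_preset,
    generate_plate,
)
from myoscreen.synthetic import simulate_field


def stub_preset(**overrides) -> ConditionPreset:
    """A miniature condition for fast plates: tiny capsules, few objects."""
    base = dict(
        name="stub",
        mean_length=24.0, sd_length=2.0,
        mean_breadth=8.0, sd_breadth=0.5,
        mean_nuclei_per_myotube=1.0, sd_nuclei=0.0,
        myotube_density=1, background_cell_density=2,
        marker_intensity_mean=300.0, marker_intensity_sd=0.0,
        myonucleus_area_mean=12.0, myonucleus_area_sd=1.0,
        cell_nucleus_area_mean=12.0, cell_nucleus_area_sd=1.0,
    )
    base.update(overrides)
    return ConditionPreset(**base)


def three_condition_wells(wells_per_condition: int) -> list[tuple[str, ConditionPreset]]:
    """Wells A* = vehicle, B* = ethanol, C* = rapamycin."""
    wells = []
    for row, name in zip("ABC", ("vehicle", "ethanol", "rapamycin")):
        preset = condition_preset(name)
        for j in range(wells_per_condition):
            wells.append((f"{row}{j + 1:02d}", preset))
    return wells


CONDITION_OF_ROW = {"A": "vehicle", "B": "ethanol", "C": "rapamycin"}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_field():
    """One noise-free, blur-free rapamycin field with ground truth."""
    preset = condition_preset("rapamycin")
    spec = PlateSpec(
        wells=[("A01", preset)], field_shape=(384, 384), pixel_size=1.0,
        noise_sd=0.0, blur_sigma=0.0, rng_seed=7, interior_only=True,
    )
    field_rng = np.random.default_rng(7)
    img, truth = simulate_field(preset, spec, field_rng)
    return img, truth, spec


@pytest.fixture(scope="session")
def ordering_plate():
    """24-well plate (8 wells/condition × 4 fields) under default noise/blur.

    This is the end-to-end benchmark scale: 512×512 px fields at 1.0 µm/px,
    three condition presets, with both ground truth and analysis results.
    """
    spec = PlateSpec(
        wells=three_condition_wells(8), fields_per_well=4,
        field_shape=(512, 512), pixel_size=1.0, rng_seed=11,
    )
    fields, truth = generate_plate(spec)
    result = analyze_fields(fields)
    return fields, truth, result
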