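"""Generator determinism, composition fidelity, presets and core layout."""

import numpy as np
import pytest

from lungplex import synthgen
from lungplex.panel import CELL_TYPES


def test_bit_identical_determinism():
    params = synthgen.normal_core_params(seed=5, n_cells=60, field_shape=(300, 300))
    s1, g1 = synthgen.generate_section(params)
    s2, g2 = synthgen.generate_section(params)
    assert set(s1.images) == set(s2.images)
    for key in s1.images:
        assert np.array_equal(s1.images[key], s2.images[key])
    assert g1.cells.equals(g2.cells)


def test_zero_cells_background_only():
    params = synthgen.normal_core_params(seed=1, n_cells=0, field_shape=(260, 260))
    stack, gt = synthgen.generate_section(params)
    assert gt.n_cells == 0
    # no nuclei: DAPI stays at background + read noise
    assert stack.get(1, "DAPI").max() < params.background + 6 * params.read_noise_sd
    # far red carries no autofluorescence either
    far_red = stack.get(3, "FARRED")
    assert far_red.mean() < params.background + 5


def test_single_type_composition():
    params = synthgen.normal_core_params(
        seed=3, n_cells=100, field_shape=(420, 420), composition={"AT1": 1.0}
    )
    stack, gt = synthgen.generate_section(params)
    assert (gt.cells["true_type"] == "AT1").all() and gt.n_cells == 100
    # AQP5 is painted for AT1, CD3 stays at noise level
    aqp5 = stack.marker_image(synthgen.default_panel(), "AQP5")
    cd3 = stack.marker_image(synthgen.default_panel(), "CD3")
    assert aqp5.max() > 100
    assert cd3.max() < 60


def test_normal_preset_at1_fraction_within_binomial_noise():
    p0 = 0.22 / sum(v for v in synthgen._NORMAL_LUNG_PCT.values()) * 100
    n = 6000
    params = synthgen.normal_core_params(seed=7, n_cells=n)
    gt = synthgen.generate_ground_truth(params)
    frac = (gt.cells["true_type"] == "AT1").mean()
    se = np.sqrt(p0 * (1 - p0) / n)
    assert abs(frac - p0) <= 3 * se


def test_signal_fidelity_pos_vs_neg(small_section):
    """POS (type, marker) pixels clear the background; NEG ones do not."""
    params, stack, gt = small_section
    panel = synthgen.default_panel()
    at1 = gt.cells[gt.cells["true_type"] == "AT1"]
    img_pos = stack.marker_image(panel, "AQP5").astype(float)
    img_neg = stack.marker_image(panel, "CD3").astype(float)
    xs = at1["x_px"].round().astype(int)
    ys = at1["y_px"].round().astype(int)
    pos_vals = img_pos[ys, xs]
    neg_vals = img_neg[ys, xs]
    assert pos_vals.mean() > params.background + 50
    assert neg_vals.mean() < params.background + 30
    assert pos_vals.mean() > neg_vals.mean() + 50


def test_overcrowded_field_raises():
    params = synthgen.normal_core_params(seed=0, n_cells=2000, field_shape=(260, 260))
    with pytest.raises(ValueError, match="overcrowded"):
        synthgen.generate_ground_truth(params)


def test_composition_must_sum_to_one():
    with pytest.raises(ValueError, match="sum"):
        synthgen.TissueParams(composition={"AT1": 0.5})


class TestTreatmentPresets:
    def test_saline_multipliers_all_one(self):
        eff = synthgen.treatment_preset("saline")
        assert all(m == 1.0 for m in eff.pgp_multiplier.values())

    def test_unknown_timepoint(self):
        with pytest.raises(ValueError, match="unknown timepoint"):
            synthgen.treatment_preset("d35")

    def test_stromal_rise_and_bronchial_pgp_flat(self):
        saline = synthgen.treatment_preset("saline")
        d21 = synthgen.treatment_preset("d21")
        assert (
            d21.composition_override["stromal"] > saline.composition_override["stromal"]
        )
        for tp in synthgen.TIMEPOINTS:
            assert synthgen.treatment_preset(tp).pgp_multiplier["bronchial_goblet"] == 1.0

    def test_course_shapes(self):
        comp = {tp: synthgen.treatment_preset(tp).composition_override
                for tp in synthgen.TIMEPOINTS}
        # monotone stromal rise d7 -> d21
        assert comp["d7"]["stromal"] < comp["d14"]["stromal"] < comp["d21"]["stromal"]
        # progressive AT2 + transitional decline d7 -> d21
        at2t = {tp: c["AT2"] + c["transitional_AT"] for tp, c in comp.items()}
        assert at2t["saline"] > at2t["d7"] > at2t["d14"] > at2t["d21"]
        # day 28 closer to saline (L1) than day 14
        def l1(a, b):
            return sum(abs(a[t] - b[t]) for t in a)
        assert l1(comp["d28"], comp["saline"]) < l1(comp["d14"], comp["saline"])
        # delayed stromal P-gP onset
        d7 = synthgen.treatment_preset("d7").pgp_multiplier
        assert d7["stromal"] == 1.0 and d7["macrophage"] > 1.0

    def test_every_type_probability_normalized(self):
        for tp in synthgen.TIMEPOINTS:
            eff = synthgen.treatment_preset(tp)
            assert abs(sum(eff.composition_override.values()) - 1.0) < 1e-9
            assert set(eff.composition_override) <= set(CELL_TYPES)


def test_jitter_composition_normalized():
    rng = np.random.default_rng(0)
    comp = synthgen.normal_lung_composition()
    j = synthgen.jitter_composition(comp, rng)
    assert abs(sum(j.values()) - 1.0) < 1e-9
    assert set(j) == set(comp)


class TestCoreLayout:
    def test_unit_conversion(self):
        params = synthgen.whole_section_params(seed=0, width_mm=3.0)
        layout = synthgen.plant_core_layout(params, [2.0])
        assert layout[0]["radius_px"] == 1000.0

    def test_four_plus_four_disjoint(self):
        params = synthgen.whole_section_params(seed=0)
        layout = synthgen.plant_core_layout(params, [2, 2, 2, 2, 1, 1, 1, 1])
        assert len(layout) == 8
        for i, a in enumerate(layout):
            for b in layout[i + 1 :]:
                d = np.hypot(a["x"] - b["x"], a["y"] - b["y"])
                assert d >= a["radius_px"] + b["radius_px"] - 1e-6

    def test_core_too_large(self):
        params = synthgen.whole_section_params(seed=0, width_mm=1.0)
        with pytest.raises(ValueError, match="does not fit"):
            synthgen.plant_core_layout(params, [2.0])
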