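"""Feature extraction correctness and cell-table CSV round trips."""

import numpy as np
import pandas as pd
import pytest

import lungplex as lp
from lungplex.features import read_cell_table, table_columns, write_cell_table
from lungplex.panel import MarkerPanel, MarkerSpec
from lungplex.segmentation import LabelMask, match_to_ground_truth
from lungplex.stack import ImageStack


@pytest.fixture()
def tiny_panel():
    return MarkerPanel(
        [
            MarkerSpec("CD3", 1, "TRITC", targets=("T_cell",)),
            MarkerSpec("CD206", 1, "FITC", targets=("macrophage",)),
        ]
    )


def _mask_two_blobs(shape=(20, 20)):
    labels = np.zeros(shape, dtype=np.int32)
    labels[2:6, 2:6] = 1
    labels[10:16, 10:14] = 2
    table = pd.DataFrame(
        {"label": [1, 2], "x": [3.5, 11.5], "y": [3.5, 12.5], "area": [16, 24]}
    )
    return LabelMask(labels, table)


def _stack_with(values: dict, shape=(20, 20)):
    images = {(1, "DAPI"): np.full(shape, 50, np.uint8)}
    for ch, v in values.items():
        images[(1, ch)] = np.full(shape, v, np.uint8)
    return ImageStack(images, microns_per_pixel=0.5)


def test_uniform_image_exact_means(tiny_panel):
    stack = _stack_with({"TRITC": 80, "FITC": 10})
    mask = _mask_two_blobs()
    table = lp.extract_features(stack, mask, mask, tiny_panel)
    assert (table["CD3_raw"] == 80).all()
    assert (table["CD3_scaled"] == 80 / 255).all()
    assert (table["CD206_raw"] == 10).all()
    # um coordinates respect the pixel scale
    assert (table["x_um"] == table["x_px"] * 0.5).all()


def test_zero_cells_empty_with_header(tiny_panel):
    stack = _stack_with({"TRITC": 80, "FITC": 10})
    empty = LabelMask(
        np.zeros((20, 20), np.int32),
        pd.DataFrame(columns=["label", "x", "y", "area"]),
    )
    table = lp.extract_features(stack, empty, empty, tiny_panel)
    assert len(table) == 0
    assert list(table.columns) == table_columns(tiny_panel)


def test_missing_marker_image_rejected(tiny_panel):
    stack = _stack_with({"TRITC": 80})  # no FITC image -> CD206 missing
    mask = _mask_two_blobs()
    with pytest.raises(KeyError, match="CD206"):
        lp.extract_features(stack, mask, mask, tiny_panel)


def test_roi_mean_equals_bruteforce_pixel_loop(tiny_panel):
    rng = np.random.default_rng(1)
    img = rng.integers(0, 255, (20, 20)).astype(np.uint8)
    stack = _stack_with({"FITC": 10})
    stack.images[(1, "TRITC")] = img
    mask = _mask_two_blobs()
    table = lp.extract_features(stack, mask, mask, tiny_panel)
    for label in (1, 2):
        acc, cnt = 0.0, 0
        for y in range(20):
            for x in range(20):
                if mask.labels[y, x] == label:
                    acc += float(img[y, x])
                    cnt += 1
        assert table.loc[table["cell_id"] == label, "CD3_raw"].iloc[0] == acc / cnt


def test_mean_over_expanded_roi_but_nuclear_centroid(tiny_panel):
    """Centroids come from the nuclei, means from the expanded regions."""
    nuclei = _mask_two_blobs()
    grown = lp.expand_to_cells(nuclei, 2)
    img = np.zeros((20, 20), np.uint8)
    img[grown.labels == 1] = 100
    img[nuclei.labels == 1] = 200  # nucleus brighter than rim
    stack = _stack_with({"FITC": 10})
    stack.images[(1, "TRITC")] = img
    table = lp.extract_features(stack, nuclei, grown, tiny_panel)
    row = table[table["cell_id"] == 1].iloc[0]
    assert row["x_px"] == nuclei.table["x"].iloc[0]
    expected = img[grown.labels == 1].mean()
    assert row["CD3_raw"] == pytest.approx(expected, abs=1e-12)
    assert 100 < row["CD3_raw"] < 200  # rim dilutes the nuclear value


class TestCsvRoundTrip:
    def test_lossless_to_six_digits(self, tmp_path, tiny_panel):
        stack = _stack_with({"TRITC": 80, "FITC": 10})
        mask = _mask_two_blobs()
        table = lp.extract_features(stack, mask, mask, tiny_panel)
        path = tmp_path / "cells.csv"
        write_cell_table(table, path)
        back = read_cell_table(path, tiny_panel)
        assert len(back) == len(table)
        for c in table.columns:
            if table[c].dtype.kind == "f":
                np.testing.assert_allclose(back[c], table[c], rtol=1e-5)
            else:
                assert (back[c] == table[c]).all()

    def test_missing_column_named_in_error(self, tmp_path, tiny_panel):
        path = tmp_path / "cells.csv"
        df = pd.DataFrame({c: [0.0] for c in table_columns(tiny_panel)})
        df.drop(columns=["CD206_raw"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="CD206_raw"):
            read_cell_table(path, tiny_panel)

    def test_core_sized_table_roundtrips(self, tmp_path, tiny_panel):
        # a table at the average cells-per-core scale survives the trip
        rng = np.random.default_rng(0)
        n = 6029
        table = pd.DataFrame({c: rng.uniform(0, 255, n) for c in table_columns(tiny_panel)[:-1]})
        table["sample_id"] = "core1"
        path = tmp_path / "big.csv"
        write_cell_table(table, path)
        assert len(read_cell_table(path, tiny_panel)) == n


def test_synthetic_section_marker_recovery(small_registered):
    """Measured AT1 AQP5 means track the generative per-cell values within 5%."""
    gt = small_registered["gt"]
    nuclei = small_registered["nuclei"]
    table = small_registered["table"]
    matched = match_to_ground_truth(nuclei.table, gt.cells)
    sel = matched["true_index"] >= 0
    truth_idx = matched["true_index"].to_numpy()[sel.to_numpy()]
    is_at1 = gt.cells["true_type"].to_numpy()[truth_idx] == "AT1"
    measured = table["AQP5_raw"].to_numpy()[sel.to_numpy()][is_at1]
    true = gt.cells["true_AQP5"].to_numpy()[truth_idx][is_at1]
    assert np.median(measured / true) == pytest.approx(1.0, abs=0.05)
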