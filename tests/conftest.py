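import numpy as np
import pandas as pd
import pytest

import lungplex as lp
from lungplex import synthgen


@pytest.fixture(scope="session")
def panel():
    return lp.default_panel()


@pytest.fixture(scope="session")
def signature(panel):
    return lp.build_signature_matrix(panel)


@pytest.fixture(scope="session")
def small_section():
    """One small rendered core (400 cells, 600 px) shared across modules."""
    params = synthgen.normal_core_params(seed=2, n_cells=400, field_shape=(600, 600))
    stack, gt = synthgen.generate_section(params)
    return params, stack, gt


@pytest.fixture(scope="session")
def small_registered(small_section, panel):
    """The small core taken through registration, segmentation and features."""
    _, stack, gt = small_section
    aligned, transforms = lp.register_stack(stack)
    nuclei = lp.segment_nuclei(aligned.get(1, "DAPI"))
    cells = lp.expand_to_cells(nuclei, ring_px=2)
    table = lp.extract_features(aligned, nuclei, cells, panel)
    return {
        "gt": gt,
        "aligned": aligned,
        "transforms": transforms,
        "nuclei": nuclei,
        "cells": cells,
        "table": table,
    }


@pytest.fixture(scope="session")
def tabular_section(panel):
    """Medium tabular sample (no rendering) for clustering-level tests."""
    params = synthgen.normal_core_params(seed=9, n_cells=1500, field_shape=(1120, 1120))
    gt = synthgen.generate_ground_truth(params, panel=panel)
    table = synthgen.cell_table_from_truth(gt, panel, sample_id="tab9")
    return gt, table


def draw_disks(shape, centers, radius, value=200, background=8):
    """Plain disk image for segmentation unit tests."""
    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cx, cy in centers:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2] = value
    return img.astype(np.uint8)
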