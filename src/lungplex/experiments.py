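"""Study-level experiments built from the pipeline stages.

Three reusable protocols:

* ``normal_core_recovery`` — the full image pipeline on one synthetic
  2 mm normal-lung core; reports the recovered composition against the
  generative (printed) percentages.
* ``core_size_validation`` — whole-section phenotyping plus 4 + 4
  virtual cores of 1 and 2 mm, re-clustered independently; reports
  per-core adequacy (tabular generator path: cell placement and
  intensity statistics, pixel fidelity validated separately).
* ``timecourse`` — saline + Bleomycin days 7/14/21/28, several animals
  per group, jointly clustered then per-animal composition and per-type
  P-gP statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import synthgen
from .features import extract_features
from .panel import default_panel
from .phenotyping import PhenotypingConfig, phenotype_cells
from .pipeline import subseeds
from .quantify import composition, composition_distance, group_composition, marker_by_type
from .registration import register_stack
from .segmentation import expand_to_cells, segment_nuclei
from .tma import adequacy_test, majority_verdict, sample_core


def normal_core_recovery(seed: int = 0, n_cells: int = 6100,
                         config: PhenotypingConfig | None = None) -> dict:
    """Full pipeline (render -> register -> segment -> extract -> cluster ->
    classify -> quantify) on one 2 mm synthetic normal-lung core."""
    panel = default_panel()
    s = subseeds(seed, 3)
    params = synthgen.normal_core_params(seed=s[0], n_cells=n_cells)
    stack, gt = synthgen.generate_section(params, panel=panel)
    aligned, _ = register_stack(stack)
    nuclei = segment_nuclei(aligned.get(1, "DAPI"))
    cells_mask = expand_to_cells(nuclei, ring_px=params.ring_px)
    table = extract_features(aligned, nuclei, cells_mask, panel, sample_id=f"core{seed}")
    result = phenotype_cells(table, panel, seed=s[1], config=config)
    comp = composition(result.table).iloc[0]
    sub = composition(result.table, level="cell_type").iloc[0]
    return {
        "ground_truth": gt,
        "table": table,
        "phenotyping": result,
        "composition_major": comp,
        "composition_sub": sub,
        "n_segmented": len(table),
        "n_classified": int(comp["n_classified"]),
    }


def core_size_validation(
    seed: int = 0,
    diameters: tuple[float, ...] = (2.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0),
    config: PhenotypingConfig | None = None,
    min_cells: int = 20,
    min_purity: float = 0.6,
) -> dict:
    """Whole-section clustering vs independently re-clustered virtual cores."""
    panel = default_panel()
    s = subseeds(seed, 4)
    params = synthgen.whole_section_params(seed=s[0])
    gt = synthgen.generate_ground_truth(params, panel=panel)
    table = synthgen.cell_table_from_truth(gt, panel, sample_id=f"whole{seed}")
    whole = phenotype_cells(table, panel, seed=s[1], config=config)
    layout = synthgen.plant_core_layout(params, list(diameters))
    mpp = params.microns_per_pixel
    h, w = params.field_shape
    cores = [
        (c["diameter_mm"],
         sample_core(table, (c["x"] * mpp, c["y"] * mpp), c["diameter_mm"],
                     field_um=(w * mpp, h * mpp)))
        for c in layout
    ]
    reports = adequacy_test(whole, cores, panel, config=config, seed=s[2],
                            min_cells=min_cells, min_purity=min_purity)
    return {
        "whole": whole,
        "reports": reports,
        "majority": majority_verdict(reports),
        "layout": layout,
    }


def timecourse(
    seed: int = 0,
    mice_per_group: int = 3,
    n_cells: int = 2500,
    config: PhenotypingConfig | None = None,
    concentration: float = 60.0,
) -> dict:
    """Bleomycin time course: joint clustering, per-animal composition,
    per-type P-gP summaries (tabular generator path)."""
    panel = default_panel()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    s = subseeds(seed, 2 + len(synthgen.TIMEPOINTS) * mice_per_group)
    tables = []
    groups = {}
    i = 2
    for tp in synthgen.TIMEPOINTS:
        preset = synthgen.treatment_preset(tp)
        for m in range(mice_per_group):
            comp = synthgen.jitter_composition(
                preset.composition_override, rng, concentration=concentration
            )
            effect = synthgen.TreatmentEffect(tp, comp, preset.pgp_multiplier)
            params = synthgen.normal_core_params(
                seed=s[i], n_cells=n_cells, field_shape=(1420, 1420)
            )
            gt = synthgen.generate_ground_truth(params, effect, panel)
            sample = f"{tp}_m{m}"
            t = synthgen.cell_table_from_truth(gt, panel, sample_id=sample)
            t["timepoint"] = tp
            tables.append(t)
            groups[sample] = tp
            i += 1
    combined = pd.concat(tables, ignore_index=True)
    result = phenotype_cells(combined, panel, seed=s[1], config=config)
    comp = composition(result.table)
    group_series = pd.Series(groups)
    agg = group_composition(comp, group_series)
    pgp = marker_by_type(result.table, "P-gP", group_col="timepoint")

    means = {tp: comp.loc[group_series[group_series == tp].index,
                          [c for c in comp.columns if c not in ("n_classified", "n_discarded")]
                          ].mean() for tp in synthgen.TIMEPOINTS}
    distances = {tp: composition_distance(means[tp], means["saline"])
                 for tp in synthgen.TIMEPOINTS if tp != "saline"}
    return {
        "phenotyping": result,
        "composition": comp,
        "groups": group_series,
        "group_stats": agg,
        "group_means": means,
        "pgp": pgp,
        "l1_to_saline": distances,
    }
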