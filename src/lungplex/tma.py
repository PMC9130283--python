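"""Virtual tissue-microarray core sampling and core-size adequacy.

A core diameter is adequate when every main cell population discovered
on the whole section is rediscovered by independently re-clustering and
re-classifying only the cells inside the core.  "Rediscovered" is
operationalized as: some core cluster is assigned that population with
at least `min_cells` members and a per-cell signature purity of at
least `min_purity` (the published criterion was visual embedding
inspection; the thresholds here are configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import DISCARD, nearest_template_types
from .panel import MAJOR_TYPE, MarkerPanel, build_signature_matrix, default_panel
from .phenotyping import PhenotypingConfig, PhenotypingResult, phenotype_cells


def sample_core(
    table: pd.DataFrame,
    center_um: tuple[float, float],
    diameter_mm: float,
    field_um: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Rows whose centroid lies strictly inside the circular core.

    `field_um` is the (width, height) of the section in um; inferred
    from the data extent when omitted.  A circle that does not fit
    inside the section raises.
    """
    cx, cy = center_um
    r = diameter_mm * 1000.0 / 2.0
    if field_um is None:
        field_um = (float(table["x_um"].max()) if len(table) else 0.0,
                    float(table["y_um"].max()) if len(table) else 0.0)
    w, h = field_um
    if cx - r < 0 or cy - r < 0 or cx + r > w or cy + r > h:
        raise ValueError(
            f"core (center ({cx}, {cy}) um, diameter {diameter_mm} mm) "
            f"falls outside the {w} x {h} um section"
        )
    d2 = (table["x_um"] - cx) ** 2 + (table["y_um"] - cy) ** 2
    return table[d2 < r * r].copy()


def identifiable_populations(
    result: PhenotypingResult,
    panel: MarkerPanel | None = None,
    min_cells: int = 20,
    min_purity: float = 0.6,
) -> set[str]:
    """Major-type populations with an identifiable cluster in `result`."""
    panel = panel or default_panel()
    signature = build_signature_matrix(panel)
    table = result.table
    cell_major = pd.Series(
        [MAJOR_TYPE[t] for t in nearest_template_types(table, signature)],
        index=table.index,
    )
    found: set[str] = set()
    for cluster, sub in result.assignment.assigned.items():
        if sub == DISCARD:
            continue
        members = table.index[table["cluster"] == cluster]
        if len(members) < min_cells:
            continue
        major = MAJOR_TYPE[sub]
        purity = float((cell_major.loc[members] == major).mean())
        if purity >= min_purity:
            found.add(major)
    return found


def population_identifiable(
    result: PhenotypingResult,
    population: str,
    panel: MarkerPanel | None = None,
    min_cells: int = 20,
    min_purity: float = 0.6,
) -> bool:
    """True iff `population` (major type) is rediscovered in this clustering."""
    return population in identifiable_populations(
        result, panel, min_cells=min_cells, min_purity=min_purity
    )


@dataclass
class AdequacyReport:
    """Verdict for one virtual core."""

    diameter_mm: float
    n_cells: int
    populations_expected: set[str]
    populations_recovered: set[str]
    missing: set[str]
    adequate: bool
    note: str = ""

    def __post_init__(self):
        assert self.populations_recovered <= self.populations_expected

    def to_dict(self) -> dict:
        return {
            "diameter_mm": self.diameter_mm,
            "n_cells": self.n_cells,
            "populations_expected": sorted(self.populations_expected),
            "populations_recovered": sorted(self.populations_recovered),
            "missing": sorted(self.missing),
            "adequate": self.adequate,
            "note": self.note,
        }


def adequacy_test(
    whole_result: PhenotypingResult,
    core_tables: list[tuple[float, pd.DataFrame]],
    panel: MarkerPanel | None = None,
    config: PhenotypingConfig | None = None,
    seed: int = 0,
    min_cells: int = 20,
    min_purity: float = 0.6,
) -> list[AdequacyReport]:
    """Re-cluster and re-classify every core with the whole-section config.

    `core_tables` is a list of (diameter_mm, cell table).  The expected
    population set is what the whole-section analysis identified; each
    core's verdict is adequate iff nothing is missing.
    """
    panel = panel or default_panel()
    config = config or PhenotypingConfig()
    expected = identifiable_populations(
        whole_result, panel, min_cells=min_cells, min_purity=min_purity
    )
    reports = []
    for diameter, core in core_tables:
        if len(core) < config.k + 1:
            reports.append(AdequacyReport(
                diameter, len(core), expected, set(), set(expected), False,
                "insufficient cells",
            ))
            continue
        res = phenotype_cells(core.reset_index(drop=True), panel, seed=seed, config=config)
        recovered = identifiable_populations(
            res, panel, min_cells=min_cells, min_purity=min_purity
        ) & expected
        missing = expected - recovered
        reports.append(AdequacyReport(
            diameter, len(core), expected, recovered, missing, not missing
        ))
    return reports


def majority_verdict(reports: list[AdequacyReport]) -> dict[float, bool]:
    """Adequate-in-the-majority verdict per core diameter."""
    out: dict[float, bool] = {}
    for d in sorted({r.diameter_mm for r in reports}):
        votes = [r.adequate for r in reports if r.diameter_mm == d]
        out[d] = sum(votes) > len(votes) / 2
    return out
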