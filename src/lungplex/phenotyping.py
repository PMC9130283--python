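"""One-call phenotyping: cluster a cell table and classify the clusters.

Shared by the pipeline driver, the virtual-TMA adequacy test and the
time-course experiments so that every context runs the identical
configuration (k, seed, positivity rule, scoring penalty).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classification import (
    CellTypeAssignment,
    assign_cluster_types,
    call_marker_positivity,
    label_cells,
)
from .clustering import DEFAULT_K, ClusterResult, PhenoGraphClusterer
from .features import scaled_matrix
from .panel import MarkerPanel, build_signature_matrix, classification_markers, default_panel


@dataclass
class PhenotypingConfig:
    """Knobs of the cluster-then-classify stage."""

    k: int = DEFAULT_K
    positivity_method: str = "kmeans"
    positivity_z: float = 1.0
    min_contrast: float = 0.08
    penalty: float = 1.0
    classify_with: list[str] | None = None  # default: panel classify flags


@dataclass
class PhenotypingResult:
    table: pd.DataFrame  # cell table + cluster / cell_type / major_type
    clusters: ClusterResult
    assignment: CellTypeAssignment


def phenotype_cells(
    table: pd.DataFrame,
    panel: MarkerPanel | None = None,
    seed: int = 0,
    config: PhenotypingConfig | None = None,
) -> PhenotypingResult:
    """Cluster the table on the classification markers and type the clusters."""
    panel = panel or default_panel()
    config = config or PhenotypingConfig()
    markers = config.classify_with or classification_markers(panel)
    signature = build_signature_matrix(panel)

    X = scaled_matrix(table, markers)
    clusterer = PhenoGraphClusterer(k=config.k, seed=seed).fit(X)
    result = clusterer.result(table, markers)
    positivity = call_marker_positivity(
        result.cluster_means,
        method=config.positivity_method,
        z=config.positivity_z,
        min_contrast=config.min_contrast,
    )
    assignment = assign_cluster_types(positivity, signature, penalty=config.penalty)
    typed = label_cells(table, result.labels, assignment)
    return PhenotypingResult(typed, result, assignment)
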