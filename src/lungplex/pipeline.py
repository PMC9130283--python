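"""End-to-end pipeline driver: one config, one seed, one run directory.

Stage order: synthesize (or load) images -> rigid inter-round
registration + autofluorescence subtraction -> DAPI nuclear
segmentation -> pseudo-cell expansion -> feature extraction ->
phenoclustering -> signature classification -> composition statistics.
Every stochastic stage consumes a sub-seed derived deterministically
from the master seed; outputs carry the config hash and seed, so
identical config + seed reproduces identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import synthgen
from .features import extract_features, write_cell_table
from .panel import MarkerPanel, default_panel, load_panel
from .phenotyping import PhenotypingConfig, PhenotypingResult, phenotype_cells
from .quantify import composition
from .registration import register_stack
from .segmentation import expand_to_cells, segment_nuclei
from .stack import ImageStack


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Single-document configuration of a full run."""

    seed: int = 0
    out_dir: str = "run"
    panel_path: str | None = None  # None -> packaged default panel
    # synthesis
    n_cells: int = 6100
    field_px: int = 2200
    microns_per_pixel: float = 1.0
    timepoint: str = "saline"
    tissue: str = "circle"
    # segmentation
    threshold: str = "isodata"
    min_area_px: int = 20
    ring_px: int = 2
    # phenotyping
    k: int = 30
    positivity_method: str = "kmeans"
    positivity_z: float = 1.0
    penalty: float = 1.0
    # registration
    max_rotation_deg: float = 3.0
    # outputs
    save_images: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError("config", f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def phenotyping(self) -> PhenotypingConfig:
        return PhenotypingConfig(
            k=self.k,
            positivity_method=self.positivity_method,
            positivity_z=self.positivity_z,
            penalty=self.penalty,
        )


def subseeds(master: int, n: int) -> list[int]:
    """Deterministic per-stage sub-seeds (kept below 2**31)."""
    ss = np.random.SeedSequence(master)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def run_pipeline(config: RunConfig, panel: MarkerPanel | None = None) -> dict:
    """Execute all stages; returns a dict of in-memory results and writes
    the stage outputs (CSV + JSON provenance) to the run directory."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(config), "config_hash": config.digest(),
                 "seed": config.seed, "stages": {}}
    seeds = subseeds(config.seed, 4)

    def stage(name):
        log["stages"][name] = {"t_start": round(time.time() - t0, 2)}
        return time.time()

    # -- panel
    try:
        panel = panel or (load_panel(config.panel_path) if config.panel_path else default_panel())
    except FileNotFoundError as e:
        raise PipelineError("panel", f"panel file not found: {e}") from e

    # -- synthesize
    stage("simulate")
    effect = synthgen.treatment_preset(config.timepoint)
    params = dataclasses.replace(
        synthgen.TissueParams(seed=seeds[0]),
        field_shape=(config.field_px, config.field_px),
        microns_per_pixel=config.microns_per_pixel,
        n_cells=config.n_cells,
        tissue=config.tissue,
        ring_px=config.ring_px,
    )
    stack, gt = synthgen.generate_section(params, effect, panel)
    gt.cells.to_csv(out / "ground_truth.csv", index=False)
    if config.save_images:
        stack.write_tiff(out / "stack.tiff")
    log["stages"]["simulate"]["n_cells"] = gt.n_cells

    # -- register
    stage("register")
    aligned, transforms = register_stack(stack, max_rotation=config.max_rotation_deg)
    with open(out / "transforms.json", "w") as fh:
        json.dump(aligned.metadata["transforms"], fh, indent=1)

    # -- segment
    stage("segment")
    nuclei = segment_nuclei(
        aligned.get(1, "DAPI"), min_area_px=config.min_area_px, threshold=config.threshold
    )
    cells_mask = expand_to_cells(nuclei, ring_px=config.ring_px)
    log["stages"]["segment"]["n_nuclei"] = nuclei.n_labels

    # -- features
    stage("features")
    table = extract_features(aligned, nuclei, cells_mask, panel, sample_id=f"seed{config.seed}")
    write_cell_table(table, out / "cell_table.csv")

    # -- phenotype
    stage("phenotype")
    result: PhenotypingResult = phenotype_cells(
        table, panel, seed=seeds[1], config=config.phenotyping()
    )
    result.table.to_csv(out / "typed_cells.csv", index=False)
    result.clusters.cluster_means.to_csv(out / "cluster_means.csv")
    result.assignment.df.to_csv(out / "assignment.csv")
    log["stages"]["phenotype"].update(
        n_clusters=result.clusters.n_clusters,
        n_discarded_clusters=int((result.assignment.assigned == "DISCARD").sum()),
        k=result.clusters.k_neighbors,
    )

    # -- quantify
    stage("quantify")
    comp = composition(result.table)
    comp.to_csv(out / "composition.csv")

    log["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "run.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return {
        "ground_truth": gt,
        "stack": aligned,
        "nuclei": nuclei,
        "cell_table": table,
        "phenotyping": result,
        "composition": comp,
        "log": log,
    }
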