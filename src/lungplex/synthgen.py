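"""Synthetic multi-round multiplexed lung images with per-cell ground truth.

The generator emulates the statistical structure a mouse-lung
multiplex-immunofluorescence analysis has to cope with:

* nuclei placed at realistic density (~1,900 cells/mm^2, i.e. ~6,000
  cells in a 2 mm core) with a hard-core minimum spacing plus a
  controlled fraction of deliberately touching pairs;
* per-type marker expression following the packaged panel's signature
  matrix (truncated-normal intensities on the 0-255 scale, a per-cell
  multiplicative staining factor shared across markers);
* spatially structured cell types — vasculature and myofibroblasts on
  random Bezier tubes, bronchial/goblet cells lining larger tubes —
  versus diffusely scattered alveolar and hematopoietic cells;
* elongated (3:1) nuclei for stromal and myofibroblast cells, which
  makes them deliberately hard for nucleus-based segmentation;
* low-frequency autofluorescence texture in the FITC and TRITC
  channels (FITC > TRITC, none in far red) plus a blank reference
  round;
* a small rigid misalignment (translation + rotation) per staining
  round;
* Bleomycin treatment presets (days 7/14/21/28) encoding the fibrosis
  time course: composition shifts and per-type multipliers on the
  constitutive P-gP drug-transporter signal.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .panel import AF_CHANNELS, CELL_TYPES, MarkerPanel, SignatureMatrix, \
    build_signature_matrix, default_panel
from .registration import RigidTransform
from .stack import AF_ROUND, ImageStack

TIMEPOINTS = ("saline", "d7", "d14", "d21", "d28")

ELONGATED_TYPES = ("stromal", "myofibroblast_smc")
TUBE_TYPES = ("vasculature", "myofibroblast_smc", "bronchial_goblet")

#: printed normal-lung composition (percent); normalized to fractions at use
_NORMAL_LUNG_PCT = {
    "AT1": 22.0,
    "AT2": 14.0,
    "transitional_AT": 32.0,
    "bronchial_goblet": 7.0,
    "vasculature": 3.0,
    "myofibroblast_smc": 2.0,
    "stromal": 0.7,
    "T_cell": 7.0,
    "B_cell": 3.0,
    "macrophage": 4.0,
    "neutrophil": 1.0,
}

#: qualitative fibrosis time course as composition weights (normalized at use):
#: transient AT1 dip, progressive AT2 + transitional decline to day 21, monotone
#: stromal rise with a late myofibroblast component, late drop of macrophages /
#: neutrophils / B cells, near-recovery at day 28
_TREATMENT_WEIGHTS = {
    "saline": _NORMAL_LUNG_PCT,
    "d7": {
        "AT1": 15.0, "AT2": 12.0, "transitional_AT": 27.0, "bronchial_goblet": 7.0,
        "vasculature": 3.0, "myofibroblast_smc": 2.0, "stromal": 3.0,
        "T_cell": 9.0, "B_cell": 3.5, "macrophage": 5.0, "neutrophil": 2.0,
    },
    "d14": {
        "AT1": 16.0, "AT2": 9.0, "transitional_AT": 21.0, "bronchial_goblet": 7.0,
        "vasculature": 3.0, "myofibroblast_smc": 2.5, "stromal": 6.0,
        "T_cell": 10.0, "B_cell": 3.5, "macrophage": 5.0, "neutrophil": 2.0,
    },
    "d21": {
        "AT1": 19.0, "AT2": 7.0, "transitional_AT": 17.0, "bronchial_goblet": 7.0,
        "vasculature": 3.0, "myofibroblast_smc": 5.0, "stromal": 9.0,
        "T_cell": 9.0, "B_cell": 2.0, "macrophage": 3.0, "neutrophil": 0.7,
    },
    "d28": {
        "AT1": 21.0, "AT2": 12.0, "transitional_AT": 29.0, "bronchial_goblet": 7.0,
        "vasculature": 3.0, "myofibroblast_smc": 3.0, "stromal": 2.5,
        "T_cell": 8.0, "B_cell": 2.5, "macrophage": 3.5, "neutrophil": 0.8,
    },
}

#: P-gP intensity multipliers: rises in every type after treatment except
#: bronchial/goblet; onset delayed by one week in the stromal (mesenchymal)
#: compartment, i.e. both the stromal and the myofibroblast/SMC subtype that
#: are merged into the major "stromal" class
_PGP_COURSE = {"saline": 1.0, "d7": 1.35, "d14": 1.65, "d21": 1.8, "d28": 1.25}
_PGP_STROMAL = {"saline": 1.0, "d7": 1.0, "d14": 1.5, "d21": 1.75, "d28": 1.2}


def _normalize(weights: dict[str, float]) -> dict[str, float]:
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("composition weights must have a positive sum")
    return {k: v / total for k, v in weights.items()}


def normal_lung_composition() -> dict[str, float]:
    """Normal-lung composition preset, normalized to sum exactly 1."""
    return _normalize(_NORMAL_LUNG_PCT)


@dataclass(frozen=True)
class TreatmentEffect:
    """Composition override and per-type P-gP multipliers for one time point."""

    timepoint: str
    composition_override: dict[str, float]
    pgp_multiplier: dict[str, float]

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}")
        s = sum(self.composition_override.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"composition_override sums to {s}, expected 1")
        for t, m in self.pgp_multiplier.items():
            if m < 0:
                raise ValueError(f"pgp_multiplier[{t}] < 0")


def treatment_preset(timepoint: str) -> TreatmentEffect:
    """Packaged Bleomycin-course preset for one of saline/d7/d14/d21/d28."""
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}")
    comp = _normalize(_TREATMENT_WEIGHTS[timepoint])
    mult = {}
    for ct in CELL_TYPES:
        if ct == "bronchial_goblet":
            mult[ct] = 1.0
        elif ct in ("stromal", "myofibroblast_smc"):
            mult[ct] = _PGP_STROMAL[timepoint]
        else:
            mult[ct] = _PGP_COURSE[timepoint]
    return TreatmentEffect(timepoint, comp, mult)


def jitter_composition(
    composition: dict[str, float], rng: np.random.Generator, concentration: float = 60.0
) -> dict[str, float]:
    """Per-animal compositional variation: one Dirichlet draw around the preset.

    concentration ~60 gives a between-animal SD of roughly 3-5 percentage
    points for a 20-30% population, matching the spread printed for
    individual mice.
    """
    keys = list(composition)
    alpha = np.array([max(composition[k], 1e-6) for k in keys]) * concentration
    draw = rng.dirichlet(alpha)
    return dict(zip(keys, draw))


# ---------------------------------------------------------------------------
# parameters


@dataclass
class TissueParams:
    """Generative parameters for one synthetic tissue field."""

    field_shape: tuple[int, int] = (2200, 2200)  # (H, W) px
    microns_per_pixel: float = 1.0
    n_cells: int = 6100
    composition: dict[str, float] = field(default_factory=normal_lung_composition)
    tissue: str = "circle"  # "circle" (core) or "rect" (whole section)
    tissue_margin_px: int = 24
    nucleus_radius_um: tuple[float, float] = (3.5, 0.45)  # mean, SD
    min_spacing_um: float = 9.0
    touching_fraction: float = 0.05
    # intensity model (8-bit scale)
    pos_mean: float = 140.0
    pos_sd: float = 45.0
    neg_mean: float = 12.0
    neg_sd: float = 8.0
    dapi_mean: float = 185.0
    dapi_sd: float = 25.0
    pgp_mean: float = 60.0
    pgp_sd: float = 20.0
    transitional_factor: float = 0.7
    staining_cv: float = 0.12
    background: float = 8.0
    read_noise_sd: float = 3.0
    ring_px: int = 2  # painted perinuclear ring for marker signal
    intensity_overrides: dict = field(default_factory=dict)  # (type, marker) -> (mean, sd)
    # autofluorescence: (constant, texture amplitude); far red has none
    af_fitc: tuple[float, float] = (26.0, 12.0)
    af_tritc: tuple[float, float] = (14.0, 7.0)
    # per-round rigid misalignment bounds
    max_translation_px: float = 10.0
    max_rotation_deg: float = 2.0
    seed: int = 0

    def __post_init__(self):
        s = sum(self.composition.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {s}, expected 1 +- 1e-9")
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("composition fractions must be >= 0")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")

    @property
    def min_spacing_px(self) -> float:
        return self.min_spacing_um / self.microns_per_pixel


@dataclass
class GroundTruth:
    """Oracle record: per-cell placement, type and true marker means."""

    cells: pd.DataFrame
    transforms: dict[int, RigidTransform]
    params: TissueParams
    timepoint: str = "saline"

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def composition(self) -> pd.Series:
        """True type fractions among generated cells."""
        return self.cells["true_type"].value_counts(normalize=True)


def normal_core_params(seed: int = 0, n_cells: int = 6100, **overrides) -> TissueParams:
    """Default 2 mm-core preset: ~6,000 segmentable cells at 1 um/px."""
    return replace(TissueParams(seed=seed, n_cells=n_cells), **overrides)


def whole_section_params(
    seed: int = 0, width_mm: float = 5.2, cells_per_mm2: float = 1919.0, **overrides
) -> TissueParams:
    """Rectangular whole-section preset at the same areal cell density."""
    mpp = overrides.pop("microns_per_pixel", 1.0)
    side = int(round(width_mm * 1000.0 / mpp))
    n = int(round(cells_per_mm2 * width_mm * width_mm))
    return replace(
        TissueParams(
            field_shape=(side, side), microns_per_pixel=mpp, n_cells=n,
            tissue="rect", seed=seed,
        ),
        **overrides,
    )


# ---------------------------------------------------------------------------
# placement


class _SpacingGrid:
    """Occupancy grid for hard-core (minimum-distance) dart throwing."""

    def __init__(self, spacing: float):
        self.spacing = spacing
        self.cell = max(spacing, 1.0)
        self.grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def ok(self, x: float, y: float) -> bool:
        gx, gy = int(x // self.cell), int(y // self.cell)
        r2 = self.spacing * self.spacing
        for ix in (gx - 1, gx, gx + 1):
            for iy in (gy - 1, gy, gy + 1):
                for px, py in self.grid.get((ix, iy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < r2:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        self.grid.setdefault((int(x // self.cell), int(y // self.cell)), []).append((x, y))


def _inside_tissue(x: float, y: float, params: TissueParams) -> bool:
    h, w = params.field_shape
    m = params.tissue_margin_px
    if not (m <= x < w - m and m <= y < h - m):
        return False
    if params.tissue == "circle":
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        r = min(h, w) / 2.0 - m
        return (x - cx) ** 2 + (y - cy) ** 2 <= r * r
    return True


def _bezier(p0, p1, p2, t):
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def _make_tubes(params: TissueParams, rng: np.random.Generator, per_mm2: float,
                n_min: int = 1) -> list[np.ndarray]:
    """Random quadratic Bezier centerlines, sampled at ~2 px arc spacing."""
    h, w = params.field_shape
    area_mm2 = (h * params.microns_per_pixel / 1000.0) * (w * params.microns_per_pixel / 1000.0)
    n_tubes = max(n_min, int(round(per_mm2 * area_mm2)))
    tubes = []
    for _ in range(n_tubes):
        p0 = rng.uniform([0, 0], [w, h])
        p2 = rng.uniform([0, 0], [w, h])
        mid = (p0 + p2) / 2
        norm = np.array([-(p2 - p0)[1], (p2 - p0)[0]])
        nlen = np.linalg.norm(norm) + 1e-9
        p1 = mid + norm / nlen * rng.uniform(-0.25, 0.25) * nlen
        length = np.linalg.norm(p2 - p0) * 1.2 + 1
        t = np.linspace(0, 1, max(int(length / 2), 8))
        tubes.append(_bezier(p0, p1, p2, t))
    return tubes


def _tube_point(tubes, rng, offset_mean, offset_sd, two_sided=True):
    tube = tubes[rng.integers(len(tubes))]
    i = rng.integers(1, len(tube))
    p = tube[i]
    tangent = tube[i] - tube[i - 1]
    tangent = tangent / (np.linalg.norm(tangent) + 1e-9)
    normal = np.array([-tangent[1], tangent[0]])
    off = rng.normal(offset_mean, offset_sd)
    if two_sided and rng.random() < 0.5:
        off = -off
    q = p + normal * off + tangent * rng.normal(0, 1.0)
    angle = math.degrees(math.atan2(tangent[1], tangent[0]))
    return q[0], q[1], angle


def _place_cells(types: np.ndarray, params: TissueParams,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Place one nucleus per requested type; hard-core spacing plus a
    deliberate touching fraction.  Raises on an overcrowded field."""
    n = len(types)
    h, w = params.field_shape
    mpp = params.microns_per_pixel
    grid = _SpacingGrid(params.min_spacing_px)
    vessel_tubes = _make_tubes(params, rng, per_mm2=2.5)
    bronchi_tubes = _make_tubes(params, rng, per_mm2=0.6)

    r_mean, r_sd = params.nucleus_radius_um
    radii = np.clip(rng.normal(r_mean, r_sd, n), 1.8, None) / mpp
    n_touch = int(params.touching_fraction * n / 2)

    xs = np.empty(n)
    ys = np.empty(n)
    angles = np.zeros(n)
    aspects = np.ones(n)
    order = rng.permutation(n)
    placed: list[int] = []

    for rank, i in enumerate(order):
        ct = types[i]
        aspects[i] = 3.0 if ct in ELONGATED_TYPES else 1.0
        touching = rank >= n - n_touch and placed
        ok = False
        for attempt in range(300):
            if touching:
                j = placed[rng.integers(len(placed))]
                theta = rng.uniform(0, 2 * np.pi)
                d = 0.9 * (radii[i] + radii[j])
                x, y = xs[j] + d * np.cos(theta), ys[j] + d * np.sin(theta)
                ang = math.degrees(theta) + 90
                if _inside_tissue(x, y, params):
                    ok = True
                    break
                continue
            use_tube = ct in TUBE_TYPES and attempt < 150
            if use_tube:
                if ct == "vasculature":
                    x, y, ang = _tube_point(vessel_tubes, rng, 0.0, 1.5)
                elif ct == "myofibroblast_smc":
                    x, y, ang = _tube_point(vessel_tubes, rng, 5.0 / mpp, 1.2)
                else:  # bronchial_goblet lining
                    x, y, ang = _tube_point(bronchi_tubes, rng, 9.0 / mpp, 1.5)
            else:
                x, y = rng.uniform(0, w), rng.uniform(0, h)
                ang = rng.uniform(0, 180)
            if _inside_tissue(x, y, params) and grid.ok(x, y):
                ok = True
                break
        if not ok:
            raise ValueError(
                f"overcrowded field: cannot place {n} cells at "
                f"{params.min_spacing_um} um minimum spacing"
            )
        xs[i], ys[i] = x, y
        if aspects[i] == 1.0 and types[i] not in TUBE_TYPES:
            angles[i] = rng.uniform(0, 180)
        else:
            angles[i] = ang
        if not touching:
            grid.add(x, y)
        placed.append(i)

    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "true_type": types,
            "x_px": xs,
            "y_px": ys,
            "radius_px": radii,
            "aspect": aspects,
            "angle_deg": angles,
        }
    )


# ---------------------------------------------------------------------------
# intensity model


def intensity_table(
    params: TissueParams,
    signature: SignatureMatrix,
    effect: TreatmentEffect | None = None,
    markers: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(mean, sd) per (cell type, marker) on the 0-255 scale.

    POS entries get the positive-staining level (transitional AT at a
    reduced 0.7x level on the alveolar marker sets), NEG entries the
    background level; the measured-only P-gP transporter is painted
    constitutively in every type, scaled by the treatment multiplier.
    """
    at_set = set(signature.pos_markers("AT1")) | set(signature.pos_markers("AT2"))
    at_set -= set(signature.pos_markers("bronchial_goblet"))  # keep pan-epithelial full
    mult = effect.pgp_multiplier if effect is not None else {}
    if markers is None:
        markers = signature.markers
    means = pd.DataFrame(index=list(CELL_TYPES), columns=markers, dtype=float)
    sds = means.copy()
    for ct in CELL_TYPES:
        for m in markers:
            # markers outside the signature (measured-only, e.g. BCRP) are ANY
            entry = signature.df.loc[ct, m] if m in signature.markers else SignatureMatrix.ANY
            if entry == SignatureMatrix.POS:
                f = params.transitional_factor if (ct == "transitional_AT" and m in at_set) else 1.0
                mean, sd = params.pos_mean * f, params.pos_sd * f
            elif m == "P-gP":
                mean, sd = params.pgp_mean * mult.get(ct, 1.0), params.pgp_sd
            else:
                mean, sd = params.neg_mean, params.neg_sd
            if (ct, m) in params.intensity_overrides:
                mean, sd = params.intensity_overrides[(ct, m)]
            means.loc[ct, m], sds.loc[ct, m] = mean, sd
    return means, sds


def _draw_intensities(cells: pd.DataFrame, means: pd.DataFrame, sds: pd.DataFrame,
                      params: TissueParams, rng: np.random.Generator) -> pd.DataFrame:
    n = len(cells)
    markers = list(means.columns)
    if n == 0:
        for m in markers:
            cells[f"true_{m}"] = pd.Series(dtype=float)
        cells["true_DAPI"] = pd.Series(dtype=float)
        return cells
    factor = np.exp(rng.normal(0.0, params.staining_cv, n))
    mu = means.loc[cells["true_type"]].to_numpy(dtype=float) * factor[:, None]
    sd = sds.loc[cells["true_type"]].to_numpy(dtype=float)
    vals = np.clip(rng.normal(mu, sd), 0.0, 255.0)
    for j, m in enumerate(markers):
        cells[f"true_{m}"] = vals[:, j]
    cells["true_DAPI"] = np.clip(rng.normal(params.dapi_mean, params.dapi_sd, n), 40.0, 255.0)
    return cells


# ---------------------------------------------------------------------------
# rendering


def _paint_ellipse(canvas: np.ndarray, x: float, y: float, a: float, b: float,
                   angle_deg: float, value: float) -> None:
    """Max-composite one anti-aliased filled ellipse onto the canvas."""
    h, w = canvas.shape
    ext = int(math.ceil(max(a, b))) + 2
    x0, x1 = max(int(x) - ext, 0), min(int(x) + ext + 1, w)
    y0, y1 = max(int(y) - ext, 0), min(int(y) + ext + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - x, yy - y
    th = math.radians(angle_deg)
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    e = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    r_eff = math.sqrt(a * b)
    cov = np.clip((1.0 - e) * r_eff + 0.5, 0.0, 1.0)
    region = canvas[y0:y1, x0:x1]
    np.maximum(region, (value * cov).astype(np.float32), out=region)


def _marker_canvas(cells: pd.DataFrame, marker: str, params: TissueParams,
                   paint_threshold: float, shape: tuple[int, int]) -> np.ndarray:
    canvas = np.zeros(shape, dtype=np.float32)
    col = cells[f"true_{marker}"].to_numpy()
    ring = params.ring_px
    for x, y, r, asp, ang, val in zip(
        cells["x_px"], cells["y_px"], cells["radius_px"],
        cells["aspect"], cells["angle_deg"], col,
    ):
        if val < paint_threshold:
            continue
        a = r * math.sqrt(asp) + ring
        b = r / math.sqrt(asp) + ring
        _paint_ellipse(canvas, x, y, a, b, ang, val)
    return canvas


def _dapi_canvas(cells: pd.DataFrame, shape: tuple[int, int]) -> np.ndarray:
    canvas = np.zeros(shape, dtype=np.float32)
    for x, y, r, asp, ang, val in zip(
        cells["x_px"], cells["y_px"], cells["radius_px"],
        cells["aspect"], cells["angle_deg"], cells["true_DAPI"],
    ):
        _paint_ellipse(canvas, x, y, r * math.sqrt(asp), r / math.sqrt(asp), ang, val)
    return canvas


def _af_texture(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Low-frequency, unit-variance autofluorescence texture field."""
    coarse = rng.normal(size=(12, 12))
    tex = ndi.zoom(coarse, (shape[0] / 12, shape[1] / 12), order=3)[: shape[0], : shape[1]]
    pad = np.zeros(shape, dtype=np.float64)
    pad[: tex.shape[0], : tex.shape[1]] = tex
    pad = ndi.gaussian_filter(pad, sigma=min(shape) / 40.0)
    pad -= pad.mean()
    sd = pad.std() or 1.0
    return (pad / sd).astype(np.float32)


def generate_ground_truth(
    params: TissueParams,
    effect: TreatmentEffect | None = None,
    panel: MarkerPanel | None = None,
) -> GroundTruth:
    """Placement + true intensities + per-round misalignment (no rendering)."""
    panel = panel or default_panel()
    signature = build_signature_matrix(panel)
    rng = np.random.default_rng(params.seed)
    composition = effect.composition_override if effect is not None else params.composition
    missing = [t for t in composition if t not in CELL_TYPES]
    if missing:
        raise ValueError(f"composition references unknown cell type(s) {missing}")
    keys = [t for t in CELL_TYPES if composition.get(t, 0) > 0]
    probs = np.array([composition[t] for t in keys], dtype=float)
    probs /= probs.sum()
    if params.n_cells > 0:
        types = rng.choice(np.array(keys, dtype=object), size=params.n_cells, p=probs)
        cells = _place_cells(types.astype(str), params, rng)
    else:
        cells = pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in [
                ("cell_id", int), ("true_type", str), ("x_px", float), ("y_px", float),
                ("radius_px", float), ("aspect", float), ("angle_deg", float)]}
        )
    means, sds = intensity_table(params, signature, effect, markers=panel.marker_names)
    cells = _draw_intensities(cells, means, sds, params, rng)

    transforms: dict[int, RigidTransform] = {}
    for rnd in [AF_ROUND] + list(range(1, panel.n_rounds + 1)):
        if rnd == 1:
            transforms[rnd] = RigidTransform()
        else:
            transforms[rnd] = RigidTransform(
                rotation=float(rng.uniform(-params.max_rotation_deg, params.max_rotation_deg)),
                translation=(
                    float(rng.uniform(-params.max_translation_px, params.max_translation_px)),
                    float(rng.uniform(-params.max_translation_px, params.max_translation_px)),
                ),
            )
    return GroundTruth(cells, transforms,
                       params, effect.timepoint if effect else "saline")


def render_stack(gt: GroundTruth, panel: MarkerPanel | None = None) -> ImageStack:
    """Render the multi-round image set for a ground-truth section."""
    panel = panel or default_panel()
    params = gt.params
    shape = params.field_shape
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    paint_threshold = params.neg_mean + 3.0 * params.neg_sd

    tex = _af_texture(shape, rng)
    af = {
        "FITC": np.clip(params.af_fitc[0] + params.af_fitc[1] * tex, 0, None),
        "TRITC": np.clip(params.af_tritc[0] + params.af_tritc[1] * tex, 0, None),
    }
    dapi = _dapi_canvas(gt.cells, shape)

    images: dict[tuple[int, str], np.ndarray] = {}

    def acquire(rnd: int, channel: str, canvas: np.ndarray | None):
        img = np.full(shape, params.background, dtype=np.float32)
        if canvas is not None:
            np.maximum(img, canvas + params.background, out=img)
        if channel in AF_CHANNELS:
            img += af[channel]
        t = gt.transforms[rnd]
        if not t.is_identity:
            img = t.apply(img)
        img = img + rng.normal(0.0, params.read_noise_sd, shape).astype(np.float32)
        images[(rnd, channel)] = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    # blank autofluorescence reference round (DAPI restained for registration)
    acquire(AF_ROUND, "DAPI", dapi)
    for ch in AF_CHANNELS:
        acquire(AF_ROUND, ch, None)
    for rnd in range(1, panel.n_rounds + 1):
        acquire(rnd, "DAPI", dapi)
        for m in panel.markers:
            if m.staining_round != rnd:
                continue
            canvas = _marker_canvas(gt.cells, m.short_name, params, paint_threshold, shape)
            acquire(rnd, m.channel, canvas)
    return ImageStack(images, params.microns_per_pixel,
                      {"seed": params.seed, "timepoint": gt.timepoint})


def generate_section(
    params: TissueParams,
    effect: TreatmentEffect | None = None,
    panel: MarkerPanel | None = None,
) -> tuple[ImageStack, GroundTruth]:
    """One synthetic specimen: rendered image stack plus its ground truth."""
    panel = panel or default_panel()
    gt = generate_ground_truth(params, effect, panel)
    return render_stack(gt, panel), gt


# ---------------------------------------------------------------------------
# fast tabular path


def cell_table_from_truth(
    gt: GroundTruth,
    panel: MarkerPanel | None = None,
    sample_id: str = "S1",
    dilution: float = 0.88,
    noise_sd: float = 2.5,
) -> pd.DataFrame:
    """Emulated single-cell feature table straight from ground truth.

    Models the measurement chain (ROI dilution toward background plus a
    small read-noise term) without rendering pixels; used for the large
    sampling experiments where pixel-level fidelity is validated
    separately.
    """
    panel = panel or default_panel()
    params = gt.params
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 11]))
    cells = gt.cells
    mpp = params.microns_per_pixel
    out = pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy(),
        "x_px": cells["x_px"].round(3),
        "y_px": cells["y_px"].round(3),
        "x_um": (cells["x_px"] * mpp).round(3),
        "y_um": (cells["y_px"] * mpp).round(3),
        "area_px": (np.pi * cells["radius_px"] ** 2).round(1),
    })
    for m in panel.marker_names:
        true = cells[f"true_{m}"].to_numpy(dtype=float) if len(cells) else np.array([])
        raw = dilution * true + (1 - dilution) * params.background
        raw = np.clip(raw + rng.normal(0, noise_sd, len(out)), 0, 255)
        out[f"{m}_raw"] = raw
    for m in panel.marker_names:
        out[f"{m}_scaled"] = out[f"{m}_raw"] / 255.0
    out["sample_id"] = sample_id
    return out


# ---------------------------------------------------------------------------
# virtual cores


def plant_core_layout(params: TissueParams, diameters_mm: list[float]) -> list[dict]:
    """Pack non-overlapping virtual circular cores into the field.

    Largest cores first, greedy placement on a coarse lattice; raises if
    the requested circles cannot be packed.  Returns pixel-coordinate
    circles ``{x, y, radius_px, diameter_mm}``.
    """
    h, w = params.field_shape
    mpp = params.microns_per_pixel
    radii = [d * 1000.0 / 2.0 / mpp for d in diameters_mm]
    for d, r in zip(diameters_mm, radii):
        if 2 * r > min(h, w):
            raise ValueError(f"{d} mm core does not fit in the field")
    order = np.argsort(radii)[::-1]
    placed: list[dict] = []
    step = max(min(radii) / 2.0, 8.0)
    for idx in order:
        r = radii[idx]
        found = False
        y = r
        while y <= h - r and not found:
            x = r
            while x <= w - r:
                if all((c["x"] - x) ** 2 + (c["y"] - y) ** 2 >= (c["radius_px"] + r) ** 2
                       for c in placed):
                    placed.append({"x": float(x), "y": float(y), "radius_px": float(r),
                                   "diameter_mm": float(diameters_mm[idx])})
                    found = True
                    break
                x += step
            y += step
        if not found:
            raise ValueError(
                f"cannot pack {len(diameters_mm)} cores of {sorted(set(diameters_mm))} mm "
                f"into a {h}x{w} px field"
            )
    # restore request order
    placed_sorted = []
    used = [False] * len(placed)
    for d in diameters_mm:
        for i, c in enumerate(placed):
            if not used[i] and c["diameter_mm"] == float(d):
                placed_sorted.append(c)
                used[i] = True
                break
    return placed_sorted
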