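"""Marker panel and cell-type signature matrix.

The panel is the machine-readable staining design of a cyclic
(stain / image / strip) multiplex immunofluorescence experiment: which
antibody is applied in which round, revealed in which fluorescence
channel, and which cell types it marks.  A nuclear DAPI counterstain is
acquired in every round and is implicit — panel entries describe the
primary antibodies only.

The signature matrix derived from the panel drives cluster phenotyping:
entry (cell type, marker) is POS when the marker labels that type, ANY
when the marker carries no lineage information (measured-only markers
such as the P-gP drug transporter), NEG otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

CHANNELS = ("FITC", "TRITC", "FARRED", "DAPI")
#: channels that receive autofluorescence subtraction
AF_CHANNELS = ("FITC", "TRITC")

#: fixed cell-type vocabulary: the 8 major types plus the 3 alveolar subtypes
CELL_TYPES = (
    "AT1",
    "AT2",
    "transitional_AT",
    "bronchial_goblet",
    "vasculature",
    "myofibroblast_smc",
    "stromal",
    "T_cell",
    "B_cell",
    "macrophage",
    "neutrophil",
)

#: sub-type -> major type (8 major classes; alveolar subtypes keep a sub-label)
MAJOR_TYPE = {
    "AT1": "alveolar",
    "AT2": "alveolar",
    "transitional_AT": "alveolar",
    "bronchial_goblet": "bronchial_goblet",
    "vasculature": "vasculature",
    "myofibroblast_smc": "stromal",
    "stromal": "stromal",
    "T_cell": "T_cell",
    "B_cell": "B_cell",
    "macrophage": "macrophage",
    "neutrophil": "neutrophil",
}

#: mutually exclusive lineage compartments used by the hybrid-artifact rule
LINEAGE_OF_TYPE = {
    "AT1": "epithelial",
    "AT2": "epithelial",
    "transitional_AT": "epithelial",
    "bronchial_goblet": "epithelial",
    "vasculature": "vascular",
    "myofibroblast_smc": "stromal",
    "stromal": "stromal",
    "T_cell": "hematopoietic",
    "B_cell": "hematopoietic",
    "macrophage": "hematopoietic",
    "neutrophil": "hematopoietic",
}

MAX_MARKERS_PER_ROUND = 3  # 3 fluor channels + DAPI


class PanelError(ValueError):
    """Raised when a panel file violates the panel invariants."""


@dataclass(frozen=True)
class MarkerSpec:
    """One primary antibody: name, staining round, channel, host, targets."""

    short_name: str
    staining_round: int
    channel: str
    host: str = ""
    targets: tuple[str, ...] = ()
    classify: bool = True

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise PanelError(
                f"unknown channel {self.channel!r} for marker {self.short_name!r}; "
                f"expected one of {CHANNELS}"
            )
        if self.channel == "DAPI":
            raise PanelError("DAPI is the implicit counterstain, not a panel marker")
        if self.staining_round < 1:
            raise PanelError(f"staining_round must be >= 1 (marker {self.short_name!r})")
        for t in self.targets:
            if t not in CELL_TYPES:
                raise PanelError(
                    f"marker {self.short_name!r} targets unknown cell type {t!r}"
                )


@dataclass
class MarkerPanel:
    """A validated staining design (list of markers over n_rounds rounds)."""

    markers: list[MarkerSpec]
    name: str = "panel"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if not self.markers:
            raise PanelError("panel has no markers")
        names = [m.short_name for m in self.markers]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise PanelError(f"duplicate marker short_name(s): {sorted(dupes)}")
        per_round: dict[int, list[MarkerSpec]] = {}
        for m in self.markers:
            per_round.setdefault(m.staining_round, []).append(m)
        for r, ms in per_round.items():
            if len(ms) > MAX_MARKERS_PER_ROUND:
                raise PanelError(
                    f"round {r} has {len(ms)} markers; at most "
                    f"{MAX_MARKERS_PER_ROUND} non-DAPI markers per round"
                )
            chans = [m.channel for m in ms]
            if len(set(chans)) != len(chans):
                raise PanelError(f"round {r} assigns one channel to two markers")
        for r in range(1, self.n_rounds + 1):
            if r not in per_round:
                raise PanelError(f"round {r} has no markers")

    # -- derived views -------------------------------------------------
    @property
    def n_rounds(self) -> int:
        return max(m.staining_round for m in self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [m.short_name for m in self.markers]

    def marker(self, short_name: str) -> MarkerSpec:
        for m in self.markers:
            if m.short_name == short_name:
                return m
        raise KeyError(short_name)

    def round_channel(self, short_name: str) -> tuple[int, str]:
        m = self.marker(short_name)
        return m.staining_round, m.channel


class SignatureMatrix:
    """Cell-type x marker matrix with entries POS / NEG / ANY."""

    POS, NEG, ANY = "POS", "NEG", "ANY"

    def __init__(self, df: pd.DataFrame):
        self.df = df
        for ct in df.index:
            if not (df.loc[ct] == self.POS).any():
                raise PanelError(f"cell type {ct!r} has no POS marker")

    @property
    def cell_types(self) -> list[str]:
        return list(self.df.index)

    @property
    def markers(self) -> list[str]:
        return list(self.df.columns)

    def pos_markers(self, cell_type: str) -> list[str]:
        row = self.df.loc[cell_type]
        return list(row.index[row == self.POS])

    def neg_markers(self, cell_type: str) -> list[str]:
        row = self.df.loc[cell_type]
        return list(row.index[row == self.NEG])

    def exclusive_markers(self, cell_type: str, versus: str) -> list[str]:
        """POS markers of `cell_type` that are not POS for `versus`."""
        return [
            m for m in self.pos_markers(cell_type) if m not in self.pos_markers(versus)
        ]

    def lineage_of_marker(self, marker: str) -> set[str]:
        col = self.df[marker]
        return {LINEAGE_OF_TYPE[ct] for ct in col.index[col == self.POS]}


# ---------------------------------------------------------------------------
# loading / writing


def _panel_from_dict(doc: dict) -> MarkerPanel:
    if not isinstance(doc, dict) or "markers" not in doc:
        raise PanelError("panel file must be a mapping with a 'markers' list")
    entries = doc["markers"] or []
    markers = []
    for e in entries:
        try:
            markers.append(
                MarkerSpec(
                    short_name=str(e["short_name"]),
                    staining_round=int(e["round"]),
                    channel=str(e["channel"]),
                    host=str(e.get("host", "")),
                    targets=tuple(e.get("targets") or ()),
                    classify=bool(e.get("classify", True)),
                )
            )
        except KeyError as k:
            raise PanelError(f"panel entry missing required key {k}") from None
    meta = {k: v for k, v in doc.items() if k not in ("markers", "name")}
    return MarkerPanel(markers, name=str(doc.get("name", "panel")), metadata=meta)


def load_panel(path: str | Path) -> MarkerPanel:
    """Load and validate a panel from a YAML (or JSON) file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _panel_from_dict(doc)


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    doc = {
        "name": panel.name,
        **panel.metadata,
        "markers": [
            {
                "short_name": m.short_name,
                "round": m.staining_round,
                "channel": m.channel,
                "host": m.host,
                "targets": list(m.targets),
                "classify": m.classify,
            }
            for m in panel.markers
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_panel() -> MarkerPanel:
    """The packaged 24-antibody, 11-round mouse-lung panel."""
    ref = resources.files("lungplex.data").joinpath("table1_panel.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _panel_from_dict(doc)


def classification_markers(panel: MarkerPanel) -> list[str]:
    """Markers used for clustering/classification (non-DAPI, classify flag set)."""
    return [m.short_name for m in panel.markers if m.classify]


def build_signature_matrix(panel: MarkerPanel) -> SignatureMatrix:
    """Derive the POS/NEG/ANY matrix from the panel's target lists.

    A marker with an empty target list is measured-only and contributes
    ANY to every row; otherwise it is POS for its targets and NEG for
    every other type.
    """
    markers = classification_markers(panel)
    data = {}
    for name in markers:
        m = panel.marker(name)
        if not m.targets:
            data[name] = {ct: SignatureMatrix.ANY for ct in CELL_TYPES}
        else:
            data[name] = {
                ct: SignatureMatrix.POS if ct in m.targets else SignatureMatrix.NEG
                for ct in CELL_TYPES
            }
    df = pd.DataFrame(data, index=list(CELL_TYPES), columns=markers)
    sig = SignatureMatrix(df)
    if "transitional_AT" in df.index and {"AT1", "AT2"} <= set(df.index):
        at1_only = set(sig.exclusive_markers("AT1", "AT2"))
        at2_only = set(sig.exclusive_markers("AT2", "AT1"))
        tr = set(sig.pos_markers("transitional_AT"))
        if not (tr & at1_only and tr & at2_only):
            raise PanelError(
                "transitional_AT must be POS for markers from both the AT1 and "
                "the AT2 marker sets"
            )
    return sig
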