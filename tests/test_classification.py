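"""Positivity calling, signature scoring, artifact discard, major-type merge."""

import numpy as np
import pandas as pd
import pytest

import lungplex as lp
from lungplex.classification import (
    DISCARD,
    CellTypeAssignment,
    assign_cluster_types,
    call_marker_positivity,
    label_cells,
    merge_major_types,
)


def _means(rows: dict[int, dict[str, float]], markers) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=markers, fill_value=0.0
    )


class TestPositivityZRule:
    def test_single_high_cluster_called(self):
        cm = pd.DataFrame({"m": [0.9] + [0.05] * 9})
        # by hand: mean 0.135, sd 0.255 -> cutoff 0.39: only cluster 0 exceeds
        pos = call_marker_positivity(cm, method="z", z=1.0)
        assert pos["m"].tolist() == [True] + [False] * 9

    def test_zero_everywhere_negative(self):
        cm = pd.DataFrame({"m": [0.0] * 5, "other": [0.5, 0.1, 0.1, 0.1, 0.1]})
        pos = call_marker_positivity(cm, method="z")
        assert not pos["m"].any()

    def test_all_equal_all_negative(self):
        cm = pd.DataFrame({"m": [0.4] * 6})
        pos = call_marker_positivity(cm, method="z")
        assert not pos["m"].any()

    def test_single_cluster_falls_back_to_fixed(self):
        cm = pd.DataFrame({"hi": [0.5], "lo": [0.1]})
        pos = call_marker_positivity(cm, method="z", fixed_cutoff=0.2)
        assert pos.loc[0, "hi"] and not pos.loc[0, "lo"]


class TestPositivityTwoMeans:
    def test_bimodal_split(self):
        cm = pd.DataFrame({"m": [0.5, 0.45, 0.35, 0.05, 0.06, 0.04]})
        pos = call_marker_positivity(cm, method="kmeans")
        assert pos["m"].tolist() == [True, True, True, False, False, False]

    def test_contrast_guard_blocks_flat_marker(self):
        cm = pd.DataFrame({"m": [0.050, 0.052, 0.055, 0.048, 0.051]})
        pos = call_marker_positivity(cm, method="kmeans", min_contrast=0.08)
        assert not pos["m"].any()

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown positivity method"):
            call_marker_positivity(pd.DataFrame({"m": [0.1, 0.2]}), method="median")


@pytest.fixture()
def positivity_frame(signature):
    def make(pos_markers_by_cluster: dict[int, list[str]]) -> pd.DataFrame:
        df = pd.DataFrame(
            False, index=sorted(pos_markers_by_cluster), columns=signature.markers
        )
        for c, ms in pos_markers_by_cluster.items():
            df.loc[c, ms] = True
        return df

    return make


class TestAssignment:
    def test_at1_signature(self, signature, positivity_frame):
        pos = positivity_frame({0: ["AQP5", "PDPN", "RAGE", "HOP"]})
        out = assign_cluster_types(pos, signature)
        assert out.assigned[0] == "AT1"

    def test_coexpression_is_transitional(self, signature, positivity_frame):
        pos = positivity_frame({0: ["SPD", "NKX2-1", "ABCA3", "AQP5", "HOP"]})
        out = assign_cluster_types(pos, signature)
        assert out.assigned[0] == "transitional_AT"

    def test_epithelial_plus_macrophage_discarded(self, signature, positivity_frame):
        pos = positivity_frame({0: ["PanCK", "CD206"]})
        out = assign_cluster_types(pos, signature)
        assert out.assigned[0] == DISCARD
        assert "hybrid lineage" in out.df.loc[0, "reason"]

    def test_no_positive_marker_discarded(self, signature, positivity_frame):
        pos = positivity_frame({0: [], 1: ["P-gP"]})  # P-gP carries no lineage
        out = assign_cluster_types(pos, signature)
        assert (out.assigned == DISCARD).all()
        assert (out.df["reason"] == "null phenotype").all()

    def test_score_formula_bruteforce(self, signature, positivity_frame):
        called = ["CD206", "OPN", "CD3"]
        pos = positivity_frame({0: called})
        out = assign_cluster_types(pos, signature, penalty=1.0)
        for ct in ["macrophage", "T_cell", "neutrophil"]:
            p = set(signature.pos_markers(ct))
            n = set(signature.neg_markers(ct))
            expect = (
                len(set(called) & p) - len(p - set(called)) - len(set(called) & n)
            )
            assert out.scores.loc[0, ct] == expect

    def test_every_cluster_gets_exactly_one_outcome(self, signature, positivity_frame):
        pos = positivity_frame(
            {0: ["CD3"], 1: ["PanCK", "MUC5b"], 2: [], 3: ["vWF"], 4: ["MPO", "OPN"]}
        )
        out = assign_cluster_types(pos, signature)
        assert len(out.df) == 5
        assert out.df["assigned"].notna().all()


class TestMajorTypes:
    def test_alveolar_subtypes_merge(self, signature, positivity_frame):
        pos = positivity_frame(
            {0: ["AQP5", "PDPN", "RAGE", "HOP"], 1: ["SPD", "NKX2-1", "ABCA3"]}
        )
        out = assign_cluster_types(pos, signature)
        major = merge_major_types(out)
        assert major == {0: "alveolar", 1: "alveolar"}

    def test_mesenchymal_groupable_but_sub_labels_kept(self, signature, positivity_frame):
        pos = positivity_frame({0: ["COLL1", "VIM", "FGF10"], 1: ["aSMA", "SM22", "DESM"]})
        out = assign_cluster_types(pos, signature)
        assert out.assigned[0] == "stromal"
        assert out.assigned[1] == "myofibroblast_smc"
        major = merge_major_types(out)
        assert major == {0: "stromal", 1: "stromal"}

    def test_discard_excluded_from_merge(self, signature, positivity_frame):
        pos = positivity_frame({0: ["PanCK", "CD206"], 1: ["CD3"]})
        major = merge_major_types(assign_cluster_types(pos, signature))
        assert major == {1: "T_cell"}

    def test_empty_assignment_empty_mapping(self, signature):
        empty = assign_cluster_types(
            pd.DataFrame(columns=signature.markers, dtype=bool), signature
        )
        assert merge_major_types(empty) == {}


def test_label_cells_counts_conserved(signature, positivity_frame):
    pos = positivity_frame({0: ["CD3"], 1: ["PanCK", "CD206"]})
    out = assign_cluster_types(pos, signature)
    table = pd.DataFrame({"cell_id": range(6), "sample_id": "s"})
    labels = np.array([0, 0, 1, 1, 1, 5])  # 5: cluster without an assignment
    typed = label_cells(table, labels, out)
    assert len(typed) == 6
    counts = typed["major_type"].value_counts()
    assert counts.get("T_cell", 0) == 2
    assert counts.get(DISCARD, 0) == 3
    assert counts.get("UNMATCHED", 0) == 1
    assert counts.sum() == 6
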