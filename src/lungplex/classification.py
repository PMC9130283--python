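"""Signature-driven phenocluster classification.

Replaces the manual reading of cluster-mean heatmaps with a
reproducible rule: (1) call each marker positive or negative per
cluster from the across-cluster distribution of cluster means;
(2) score every candidate cell type against the signature matrix
(matched positives minus missed positives minus a penalty per violated
negative); (3) discard artifact clusters whose positive markers span
two mutually exclusive lineage compartments (the hybrid signatures
produced by juxtaposed elongated cells) and clusters with no positive
lineage marker at all; (4) merge the surviving clusters into the 8
major types, keeping the three alveolar subtypes as sub-labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import CELL_TYPES, MAJOR_TYPE, SignatureMatrix

DISCARD = "DISCARD"
UNMATCHED = "UNMATCHED"


def _two_means_split(values: np.ndarray) -> float | None:
    """Exact 1-D 2-means: boundary minimizing within-class SSE, or None."""
    v = np.sort(values)
    n = len(v)
    if n < 2 or v[0] == v[-1]:
        return None
    csum = np.cumsum(v)
    csq = np.cumsum(v * v)
    best, best_i = np.inf, None
    for i in range(1, n):  # lower class = v[:i]
        s1, q1 = csum[i - 1], csq[i - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        sse = (q1 - s1 * s1 / i) + (q2 - s2 * s2 / (n - i))
        if sse < best - 1e-15:
            best, best_i = sse, i
    return float((v[best_i - 1] + v[best_i]) / 2.0)


def call_marker_positivity(
    cluster_means: pd.DataFrame,
    method: str = "z",
    z: float = 1.0,
    min_contrast: float = 0.08,
    fixed_cutoff: float = 0.2,
) -> pd.DataFrame:
    """Boolean cluster x marker positivity matrix.

    ``z``        : positive where the cluster mean exceeds the across-cluster
                   mean + z*SD for that marker (all negative at zero variance).
    ``kmeans``   : 1-D two-means split of the cluster means; the upper class is
                   positive provided the class means differ by >= min_contrast.
    ``fixed``    : absolute cutoff on the rescaled mean.

    A single-cluster input falls back to the fixed cutoff (there is no
    across-cluster distribution to threshold against).
    """
    cm = cluster_means
    if len(cm) < 2 or method == "fixed":
        return cm > fixed_cutoff
    if method == "z":
        cut = cm.mean(axis=0) + z * cm.std(axis=0, ddof=0)
        return cm.gt(cut, axis=1)
    if method == "kmeans":
        out = pd.DataFrame(False, index=cm.index, columns=cm.columns)
        for m in cm.columns:
            vals = cm[m].to_numpy(dtype=float)
            cut = _two_means_split(vals)
            if cut is None:
                continue
            hi, lo = vals[vals > cut], vals[vals <= cut]
            if hi.size and lo.size and hi.mean() - lo.mean() >= min_contrast:
                out[m] = cm[m] > cut
        return out
    raise ValueError(f"unknown positivity method {method!r}")


@dataclass
class CellTypeAssignment:
    """Per-cluster assigned type (or DISCARD with a reason) plus scores."""

    df: pd.DataFrame  # index: cluster; columns: assigned, reason, score
    scores: pd.DataFrame  # cluster x cell type
    positivity: pd.DataFrame

    @property
    def assigned(self) -> pd.Series:
        return self.df["assigned"]

    def kept_clusters(self) -> list:
        return list(self.df.index[self.df["assigned"] != DISCARD])


def at_marker_sets(signature: SignatureMatrix) -> tuple[set, set]:
    """AT1-only and AT2-only marker sets (pan-epithelial markers excluded)."""
    at1 = set(signature.exclusive_markers("AT1", "AT2"))
    at2 = set(signature.exclusive_markers("AT2", "AT1"))
    return at1, at2


def assign_cluster_types(
    positivity: pd.DataFrame,
    signature: SignatureMatrix,
    penalty: float = 1.0,
) -> CellTypeAssignment:
    """Score positivity patterns against the signature matrix.

    score(type) = #POS matched - #POS missed - penalty * #NEG violated;
    the argmax wins, ties broken by the fixed type priority order.  A
    cluster positive for markers of both the AT1-only and AT2-only sets
    is the transitional AT phenotype.  Discards: positives spanning >= 2
    exclusive lineage compartments ("hybrid lineage") and clusters with
    no positive lineage marker ("null phenotype").
    """
    unknown = [m for m in positivity.columns if m not in signature.markers]
    if unknown:
        raise ValueError(f"positivity has marker(s) absent from the signature: {unknown}")
    at1_only, at2_only = at_marker_sets(signature)
    types = [ct for ct in CELL_TYPES if ct in signature.cell_types]
    pos_of = {ct: set(signature.pos_markers(ct)) for ct in types}
    neg_of = {ct: set(signature.neg_markers(ct)) for ct in types}

    rows, score_rows = [], []
    for cluster in positivity.index:
        called = set(positivity.columns[positivity.loc[cluster]])
        lineage_pos = {m for m in called if signature.lineage_of_marker(m)}
        scores = {
            ct: len(called & pos_of[ct])
            - len(pos_of[ct] - called)
            - penalty * len(called & neg_of[ct])
            for ct in types
        }
        score_rows.append(scores)
        if not lineage_pos:
            rows.append((cluster, DISCARD, "null phenotype", np.nan))
            continue
        lineages = set()
        for m in lineage_pos:
            lineages |= signature.lineage_of_marker(m)
        if len(lineages) >= 2:
            rows.append(
                (cluster, DISCARD, "hybrid lineage: " + "+".join(sorted(lineages)), np.nan)
            )
            continue
        if called & at1_only and called & at2_only:
            assigned = "transitional_AT"
        else:
            best = max(scores.values())
            assigned = next(ct for ct in types if scores[ct] == best)
        rows.append((cluster, assigned, "", float(scores[assigned])))

    df = pd.DataFrame(rows, columns=["cluster", "assigned", "reason", "score"]).set_index("cluster")
    scores_df = pd.DataFrame(score_rows, index=positivity.index, columns=types)
    return CellTypeAssignment(df, scores_df, positivity)


def merge_major_types(assignment: CellTypeAssignment) -> dict:
    """Cluster -> major type (8 classes); DISCARD clusters are excluded."""
    return {
        cluster: MAJOR_TYPE[sub]
        for cluster, sub in assignment.assigned.items()
        if sub != DISCARD
    }


def label_cells(
    table: pd.DataFrame, labels: np.ndarray, assignment: CellTypeAssignment
) -> pd.DataFrame:
    """Append cluster / cell_type / major_type columns to a cell table."""
    out = table.copy()
    out["cluster"] = labels
    sub = assignment.assigned.to_dict()
    major = merge_major_types(assignment)
    out["cell_type"] = [sub.get(c, UNMATCHED) for c in labels]
    out["major_type"] = [major.get(c, DISCARD if sub.get(c) == DISCARD else UNMATCHED)
                         for c in labels]
    return out


def nearest_template_types(
    table: pd.DataFrame, signature: SignatureMatrix
) -> np.ndarray:
    """Per-cell nearest signature template by cosine similarity.

    Templates are POS=1 / otherwise 0 over the lineage-bearing markers.
    Cluster-free and used only as a purity diagnostic (core-adequacy
    testing), never as the classifier.
    """
    markers = [m for m in signature.markers if signature.lineage_of_marker(m)]
    X = table[[f"{m}_scaled" for m in markers]].to_numpy(dtype=float)
    types = [ct for ct in CELL_TYPES if ct in signature.cell_types]
    T = np.array(
        [[1.0 if m in set(signature.pos_markers(ct)) else 0.0 for m in markers] for ct in types]
    )
    Xn = X / (np.linalg.norm(X, axis=1, keepdims=True) + 1e-12)
    Tn = T / (np.linalg.norm(T, axis=1, keepdims=True) + 1e-12)
    sim = Xn @ Tn.T
    return np.array(types, dtype=object)[np.argmax(sim, axis=1)].astype(str)
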