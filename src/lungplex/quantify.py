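"""Composition and per-type intensity statistics.

Percentages are computed over classified cells only (artifact clusters
are excluded from every denominator, mirroring the removal of hybrid
clusters before composition figures).  Group statistics are unweighted
mean +- SD across samples; transporter intensities are summarized as
Tukey boxplot statistics (1.5 x IQR whiskers) on the rescaled 0-1
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import DISCARD, UNMATCHED


def composition(table: pd.DataFrame, level: str = "major_type") -> pd.DataFrame:
    """Per-sample cell-type percentages over classified cells.

    Returns one row per sample_id with a column per type (percent, rows
    sum to 100), plus ``n_classified`` and ``n_discarded``.
    """
    if level not in table.columns:
        raise ValueError(f"cell table has no {level!r} column")
    rows = {}
    for sample, grp in table.groupby("sample_id", sort=True):
        keep = grp[~grp[level].isin([DISCARD, UNMATCHED])]
        if not len(keep):
            raise ValueError(f"sample {sample!r} has zero classified cells")
        pct = keep[level].value_counts(normalize=True) * 100.0
        row = pct.to_dict()
        row["n_classified"] = len(keep)
        row["n_discarded"] = int((grp[level] == DISCARD).sum())
        rows[sample] = row
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    out.index.name = "sample_id"
    type_cols = [c for c in out.columns if c not in ("n_classified", "n_discarded")]
    return out[sorted(type_cols) + ["n_classified", "n_discarded"]]


def group_composition(comp: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Unweighted mean +- SD per treatment group across samples.

    `groups` maps sample_id -> group label.  SD is the sample SD
    (ddof=1; 0 for singleton groups).
    """
    type_cols = [c for c in comp.columns if c not in ("n_classified", "n_discarded")]
    df = comp[type_cols].copy()
    df["group"] = groups.reindex(comp.index)
    agg = df.groupby("group").agg(["mean", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0])
    agg.columns = [f"{t}_{'sd' if stat == '<lambda_0>' else stat}" for t, stat in agg.columns]
    return agg


@dataclass
class IntensitySummary:
    """Tukey boxplot statistics of one marker per (type, group)."""

    stats: pd.DataFrame  # index (type, group); median, q1, q3, lo, hi, n_outliers, n

    def median(self, cell_type: str, group) -> float:
        return float(self.stats.loc[(cell_type, group), "median"])


def _tukey(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    in_lo = values[values >= q1 - 1.5 * iqr]
    in_hi = values[values <= q3 + 1.5 * iqr]
    lo = in_lo.min() if in_lo.size else q1
    hi = in_hi.max() if in_hi.size else q3
    n_out = int(((values < lo) | (values > hi)).sum())
    return {"median": med, "q1": q1, "q3": q3, "lo": lo, "hi": hi,
            "n_outliers": n_out, "n": int(values.size)}


def marker_by_type(
    table: pd.DataFrame,
    marker: str = "P-gP",
    level: str = "major_type",
    group_col: str | None = None,
) -> IntensitySummary:
    """Rescaled-intensity boxplot statistics of `marker` per cell type.

    With `group_col` (e.g. a treatment day column) statistics are per
    (type, group); otherwise per type.
    """
    col = f"{marker}_scaled"
    if col not in table.columns:
        raise ValueError(f"unknown marker {marker!r}: no column {col}")
    keep = table[~table[level].isin([DISCARD, UNMATCHED])]
    keys = [level] + ([group_col] if group_col else [])
    rows = {}
    for key, grp in keep.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        k = key if group_col else (key[0], "all")
        rows[k] = _tukey(grp[col].to_numpy(dtype=float))
    stats = pd.DataFrame.from_dict(rows, orient="index")
    stats.index = pd.MultiIndex.from_tuples(stats.index, names=[level, group_col or "group"])
    return IntensitySummary(stats)


def composition_distance(a: pd.Series, b: pd.Series) -> float:
    """L1 distance between two composition vectors (percent units)."""
    keys = sorted(set(a.index) | set(b.index))
    return float(sum(abs(a.get(k, 0.0) - b.get(k, 0.0)) for k in keys))


def timecourse_report(
    comp: pd.DataFrame, groups: pd.Series, order: list[str] | None = None
) -> pd.DataFrame:
    """Type-fraction trajectories: group mean and SD per type per time point."""
    if groups.reindex(comp.index).nunique() < 2:
        raise ValueError("timecourse needs at least 2 time points")
    agg = group_composition(comp, groups)
    if order:
        agg = agg.reindex([g for g in order if g in agg.index])
    return agg


def sd_two_pass(values) -> float:
    """Brute-force two-pass sample SD (oracle for the SD computations)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return 0.0
    m = v.sum() / len(v)
    return float(np.sqrt(((v - m) ** 2).sum() / (len(v) - 1)))


# -- optional plotting ------------------------------------------------------


def plot_composition(agg: pd.DataFrame, order: list[str], path=None):
    """Bar chart of group mean +- SD per type (composition figure layout)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    types = sorted({c[:-5] for c in agg.columns if c.endswith("_mean")})
    fig, ax = plt.subplots(figsize=(10, 4))
    width = 0.8 / len(order)
    xs = np.arange(len(types))
    for i, g in enumerate(order):
        m = [agg.loc[g, f"{t}_mean"] for t in types]
        s = [agg.loc[g, f"{t}_sd"] for t in types]
        ax.bar(xs + i * width, m, width=width, yerr=s, capsize=2, label=str(g))
    ax.set_xticks(xs + 0.4, types, rotation=45, ha="right")
    ax.set_ylabel("% of classified cells")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_marker_boxes(summary: IntensitySummary, path=None):
    """Boxplot-style rendering of an IntensitySummary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    st = summary.stats
    fig, ax = plt.subplots(figsize=(10, 4))
    labels = [f"{t}\n{g}" for t, g in st.index]
    for i, (_, row) in enumerate(st.iterrows()):
        ax.vlines(i, row["lo"], row["hi"], color="k", lw=0.8)
        ax.add_patch(plt.Rectangle((i - 0.3, row["q1"]), 0.6, row["q3"] - row["q1"],
                                   fill=False))
        ax.hlines(row["median"], i - 0.3, i + 0.3, color="tab:red")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_ylabel("rescaled intensity (0-1)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
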