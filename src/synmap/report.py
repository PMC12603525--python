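"""Derived tables and clustered heatmaps.

Two reporting products: (1) *fraction tables* comparing the density of a
reference marker (SV2A) against the summed density of a panel of other
markers, per region and overall — the arithmetic behind the "SV2A is
present in only a subset of synapses" conclusion; (2) row-normalised
marker × region heatmaps with rows/columns ordered by agglomerative
hierarchical clustering (average linkage on Euclidean distances of the
normalised rows), the standard "clustered by similarity" display.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .quantify import round_half_away

__all__ = [
    "marker_fraction",
    "build_fraction_table",
    "round_fraction_table",
    "row_normalize",
    "cluster_order",
    "clustered_heatmap",
]


def marker_fraction(rho_ref: float, rho_others) -> float:
    """Reference density as a percentage of the summed comparison densities.

    ``100 * rho_ref / sum(rho_others)``, full precision (round for display
    with :func:`synmap.quantify.round_half_away`).
    """
    denom = float(np.sum(rho_others))
    if denom <= 0:
        raise ValueError("summed comparison density must be positive")
    return 100.0 * float(rho_ref) / denom


def build_fraction_table(
    density: pd.DataFrame,
    ref_marker: str,
    denom_markers: list[str],
    add_mean_column: bool = False,
) -> pd.DataFrame:
    """Three-row fraction table: reference density, summed denominator, percent.

    ``density`` is a marker × region table of density means (per 100 µm²);
    every named marker must be present for every column.  Columns pass
    through as given — include a precomputed ``Mean`` column to reproduce
    printed layouts, or set ``add_mean_column`` to append one from the
    row means of the regional columns.  Values are full precision;
    ``round_fraction_table`` matches the printed integer layout.
    """
    missing = [m for m in [ref_marker, *denom_markers] if m not in density.index]
    if missing:
        raise ValueError(f"density table is missing markers {missing}")
    if density.loc[[ref_marker, *denom_markers]].isna().any().any():
        na_cols = density.columns[
            density.loc[[ref_marker, *denom_markers]].isna().any()
        ].tolist()
        raise ValueError(f"missing density values in columns {na_cols}")
    table = density.loc[[ref_marker]].astype(float).copy()
    denom_label = " + ".join(denom_markers)
    table.loc[denom_label] = density.loc[denom_markers].astype(float).sum(axis=0)
    if add_mean_column:
        table["Mean"] = table.mean(axis=1)
    table.loc[f"% {ref_marker}"] = (
        100.0 * table.loc[ref_marker] / table.loc[denom_label]
    )
    table.index.name = "marker"
    return table


def round_fraction_table(table: pd.DataFrame) -> pd.DataFrame:
    """Integer display form (half-away-from-zero) of a fraction table."""
    return table.map(lambda v: round_half_away(v, 0)).astype(int)


def row_normalize(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Min-max normalise each row to [0, 1].

    Each row maps through ``(x - min) / (max - min)`` so its smallest cell
    becomes 0 and its largest 1.  Constant rows carry no contrast; they map
    to 0.5 everywhere and a warning is raised.  Idempotent.
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 1:
        raise ValueError("matrix must be 2-D with at least one column")
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s) normalised to 0.5 (no contrast)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span == 0, 0.5, (values - lo) / np.where(span == 0, 1, span))
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def cluster_order(
    matrix: pd.DataFrame | np.ndarray,
    axis: str = "rows",
    method: str = "average",
    metric: str = "euclidean",
) -> np.ndarray:
    """Deterministic dendrogram leaf order from hierarchical clustering.

    Average-linkage agglomeration on Euclidean distances by default
    (pass the row-normalised matrix to cluster on display values).  A
    single item returns the identity permutation.
    """
    values = np.asarray(matrix, dtype=float)
    if axis == "cols":
        values = values.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    n = values.shape[0]
    if n < 1:
        raise ValueError("nothing to cluster")
    if n == 1:
        return np.array([0])
    z = linkage(pdist(values, metric=metric), method=method)
    return leaves_list(z)


def clustered_heatmap(
    matrix: pd.DataFrame,
    out_path=None,
    cluster_rows: bool = True,
    cluster_cols: bool = False,
    cmap: str = "viridis",
    title: str | None = None,
):
    """Row-normalised heatmap with cluster-ordered rows (and optionally cols).

    Returns (figure, normalised-and-reordered DataFrame); saves to
    ``out_path`` when given.  Normalisation is per row, so colours compare
    regions within a marker, not markers against each other.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = row_normalize(matrix)
    if cluster_rows and len(norm) > 1:
        norm = norm.iloc[cluster_order(norm, "rows")]
    if cluster_cols and norm.shape[1] > 1:
        norm = norm.iloc[:, cluster_order(norm, "cols")]
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * norm.shape[1], 1.0 + 0.5 * norm.shape[0])
    )
    sns.heatmap(norm, cmap=cmap, vmin=0.0, vmax=1.0, ax=ax,
                cbar_kws={"label": "row-normalised value"})
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig, norm
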