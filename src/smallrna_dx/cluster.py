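"""Pairwise differential matrix and hierarchical clustering for heat maps.

Each column of the matrix is one disease/control sample pair; each row one
miRNA; each cell the pair's log2 fold change, or missing when the miRNA is
unexpressed in at least one member of the pair (the heat map's gray cells).
Distances between rows/columns are computed pairwise-complete over shared
non-missing cells, then fed to standard agglomerative linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Literal, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .diffexp import DERecord

Distance = Literal["euclidean", "correlation"]
Linkage = Literal["average", "complete"]


@dataclass
class ClusterResult:
    row_order: List[str]
    col_order: List[str]
    row_tree: np.ndarray  # scipy linkage matrix
    col_tree: np.ndarray


def build_pair_matrix(pairs: Mapping[str, Sequence[DERecord]]) -> pd.DataFrame:
    """Assemble the miRNA x sample-pair fold-change matrix.

    A cell is NaN (missing) iff the miRNA's normalized expression was
    floored — i.e. effectively absent — in at least one member of that
    pair, or the miRNA is absent from the pair's record list entirely.
    Row/column order is sorted and stable.  Duplicate pair labels raise.
    """
    labels = list(pairs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample-pair labels")
    if not labels:
        raise ValueError("at least one sample pair is required")
    columns: Dict[str, Dict[str, float]] = {}
    for label, records in pairs.items():
        col: Dict[str, float] = {}
        for rec in records:
            if rec.mirna in col:
                raise ValueError(f"pair {label!r}: duplicate miRNA {rec.mirna!r}")
            col[rec.mirna] = rec.fold_change if rec.expressed_both else np.nan
        columns[label] = col
    matrix = pd.DataFrame(columns).sort_index()
    matrix = matrix[sorted(matrix.columns)]
    matrix.index.name = "mirna"
    return matrix


def _pairwise_complete_distance(
    data: np.ndarray, labels: Sequence[str], metric: Distance
) -> np.ndarray:
    """Condensed distance vector over rows of ``data``, ignoring NaN cells.

    Raises when two rows share no observed cell (distance undefined).
    """
    n = data.shape[0]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    for i, j in combinations(range(n), 2):
        mask = ~np.isnan(data[i]) & ~np.isnan(data[j])
        if not mask.any():
            raise ValueError(
                f"no shared non-missing entries between {labels[i]!r} and {labels[j]!r}"
            )
        a, b = data[i][mask], data[j][mask]
        if metric == "euclidean":
            out[k] = float(np.sqrt(np.sum((a - b) ** 2)))
        else:  # correlation distance 1 - r
            if a.std() == 0 or b.std() == 0:
                # degenerate: constant vector(s); identical constants -> 0
                out[k] = 0.0 if np.array_equal(a, b) else 1.0
            else:
                out[k] = float(1.0 - np.corrcoef(a, b)[0, 1])
        k += 1
    return out


def cluster(
    matrix: pd.DataFrame,
    distance: Distance = "euclidean",
    linkage_method: Linkage = "average",
) -> ClusterResult:
    """Agglomerative clustering of rows and columns with missing-aware distances.

    Requires at least 2 rows and 2 columns.  Merge heights are
    non-decreasing for the supported linkages; leaf orders are the
    deterministic scipy dendrogram orders.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 matrix to cluster")
    if linkage_method not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported distance {distance!r}")
    rows = list(matrix.index.astype(str))
    cols = list(matrix.columns.astype(str))
    row_d = _pairwise_complete_distance(matrix.to_numpy(float), rows, distance)
    col_d = _pairwise_complete_distance(matrix.to_numpy(float).T, cols, distance)
    row_tree = linkage(row_d, method=linkage_method)
    col_tree = linkage(col_d, method=linkage_method)
    return ClusterResult(
        row_order=[rows[i] for i in leaves_list(row_tree)],
        col_order=[cols[i] for i in leaves_list(col_tree)],
        row_tree=row_tree,
        col_tree=col_tree,
    )


def write_heatmap_tsv(
    matrix: pd.DataFrame, result: ClusterResult, path: str | Path
) -> None:
    """Clustered matrix as TSV with tri-state semantics.

    Cells carry the log2 value (up > 0, down < 0) or the literal ``NA``
    missing marker, so heat-map colors (red/green/gray) are reproducible
    from the table alone.
    """
    ordered = matrix.loc[result.row_order, result.col_order]
    ordered.to_csv(path, sep="\t", na_rep="NA", float_format="%.6f")


def plot_heatmap(
    matrix: pd.DataFrame, result: ClusterResult, path: str | Path
) -> None:
    """Optional image export (red = up, green = down, gray = missing)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    ordered = matrix.loc[result.row_order, result.col_order]
    cmap = LinearSegmentedColormap.from_list("updown", ["green", "black", "red"])
    cmap.set_bad("gray")
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * ordered.shape[1]), max(4, 0.12 * ordered.shape[0]))
    )
    vmax = float(np.nanmax(np.abs(ordered.to_numpy(float)))) or 1.0
    ax.imshow(ordered.to_numpy(float), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("sample pair")
    ax.set_ylabel("miRNA")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
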