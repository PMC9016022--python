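"""Phenotype expression array: logit transform + complete-linkage clustering.

A diseases x 17-feature matrix of presence proportions is transformed with
a truncated logit — proportions clamped to [eps, 1 - eps] (eps = 0.01,
"truncated at 1%") before ``ln(q / (1 - q))`` — and both rows (diseases)
and columns (features) are clustered agglomeratively with complete linkage
on Euclidean distances. The truncation keeps frequencies of 0% and 100%,
which are common in small case series, at finite coordinates while the
logit spreads the informative mid-range.

The clustered heatmap (red = high frequency, blue = low) with marginal
dendrograms mirrors the array-style view used for cohort phenotype
comparison; dendrograms can be exported as Newick trees with merge heights
as node depths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .kaleidoscope import AXIS_LABELS, N_AXES, CohortProfile

__all__ = [
    "PhenotypeMatrix",
    "ClusteringResult",
    "logit_truncate",
    "cluster_phenotypes",
    "cut_rows",
    "linkage_to_newick",
    "render_heatmap",
]

DEFAULT_EPS = 0.01


def logit_truncate(p, eps: float = DEFAULT_EPS):
    """Truncated logit: clamp ``p`` to ``[eps, 1 - eps]``, then ``ln(q/(1-q))``.

    Accepts scalars or arrays of proportions in [0, 1]. Antisymmetric about
    0.5 and strictly monotone on the un-clamped interval; with the default
    eps = 0.01 the range is about [-4.595, +4.595].
    """
    if not 0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps!r}")
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    q = np.clip(arr, eps, 1.0 - eps)
    out = np.log(q / (1.0 - q))
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


@dataclass(frozen=True)
class PhenotypeMatrix:
    """Diseases x features matrix of presence proportions in [0, 1]."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if vals.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.row_labels)} rows x {len(self.col_labels)} cols"
            )
        if np.any(np.isnan(vals)) or np.any((vals < 0) | (vals > 1)):
            raise ValueError("matrix values must be proportions in [0, 1]")

    @classmethod
    def from_profiles(
        cls,
        profiles: Sequence[CohortProfile],
        impute: float = DEFAULT_EPS,
        label_with_n: bool = True,
    ) -> "PhenotypeMatrix":
        """Stack cohort profiles into a matrix of proportions.

        Axes a cohort never had assessed (denominator 0) are imputed at the
        truncation floor (default 0.01) with a warning — the clamp value is
        the least-informative finite coordinate, so the imputation cannot
        dominate a distance.
        """
        rows = []
        labels = []
        for prof in profiles:
            row = []
            for i, f in enumerate(prof.frequencies):
                if f is None:
                    warnings.warn(
                        f"cohort {prof.label!r}: axis {i + 1} unavailable, "
                        f"imputing at {impute}",
                        stacklevel=2,
                    )
                    row.append(impute)
                else:
                    row.append(f / 100.0)
            rows.append(row)
            labels.append(
                f"{prof.label} (n={prof.n_patients})" if label_with_n else prof.label
            )
        return cls(
            row_labels=tuple(labels),
            col_labels=AXIS_LABELS,
            values=np.array(rows, dtype=float),
        )


@dataclass(frozen=True)
class ClusteringResult:
    """Row and column dendrograms over the logit-transformed matrix.

    ``row_linkage`` / ``col_linkage`` are SciPy linkage matrices (each row:
    merged cluster ids, merge height, new size); complete linkage
    guarantees non-decreasing merge heights. ``transformed`` is the matrix
    actually clustered.
    """

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: tuple[int, ...]
    col_order: tuple[int, ...]
    transformed: np.ndarray


def _zscore(a: np.ndarray, axis: int) -> np.ndarray:
    mu = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, ddof=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mu) / sd


def cluster_phenotypes(
    matrix: PhenotypeMatrix,
    eps: float = DEFAULT_EPS,
    scale: str = "none",
) -> ClusteringResult:
    """Cluster rows and columns of a phenotype matrix.

    The matrix of proportions is passed through :func:`logit_truncate`,
    optionally z-scored along ``scale`` (``"rows"``, ``"cols"`` or
    ``"none"``, the default), then rows and columns are clustered
    independently: agglomerative, complete linkage, Euclidean distances.
    Deterministic for a given input; exact distance ties are resolved by
    SciPy's ordering.
    """
    if matrix.values.shape[0] < 2 or matrix.values.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    if scale not in {"none", "rows", "cols"}:
        raise ValueError(f"scale must be 'none', 'rows' or 'cols', got {scale!r}")
    t = logit_truncate(matrix.values, eps=eps)
    if scale == "rows":
        t = _zscore(t, axis=1)
    elif scale == "cols":
        t = _zscore(t, axis=0)
    row_Z = hierarchy.linkage(t, method="complete", metric="euclidean")
    col_Z = hierarchy.linkage(t.T, method="complete", metric="euclidean")
    return ClusteringResult(
        row_linkage=row_Z,
        col_linkage=col_Z,
        row_order=tuple(int(i) for i in hierarchy.leaves_list(row_Z)),
        col_order=tuple(int(i) for i in hierarchy.leaves_list(col_Z)),
        transformed=t,
    )


def cut_rows(result: ClusteringResult, k: int) -> np.ndarray:
    """Cut the row dendrogram into ``k`` flat clusters (labels 1..k)."""
    return hierarchy.fcluster(result.row_linkage, t=k, criterion="maxclust")


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a linkage matrix as a Newick tree.

    Branch lengths are differences of merge heights (so the root-to-leaf
    path length of a leaf equals the final merge height); complete
    linkage's monotone heights keep all branch lengths non-negative.
    """
    tree = hierarchy.to_tree(Z)

    def escape(label: str) -> str:
        if any(c in label for c in " (),:;'\t\n"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{escape(labels[node.id])}:{length:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"


def render_heatmap(
    matrix: PhenotypeMatrix,
    result: ClusteringResult,
    out_path,
    annotate_percent: bool = False,
):
    """Draw the clustered heatmap with marginal dendrograms.

    Rows and columns are permuted to the dendrogram leaf orders; cells show
    the logit-transformed values on a diverging palette, red for high
    frequency and blue for low. Row labels carry the cohort size when the
    matrix was built with ``label_with_n=True``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd
    import seaborn as sns

    frame = pd.DataFrame(
        result.transformed, index=matrix.row_labels, columns=matrix.col_labels
    )
    grid = sns.clustermap(
        frame,
        row_linkage=result.row_linkage,
        col_linkage=result.col_linkage,
        cmap="RdBu_r",
        center=0.0,
        figsize=(10, max(4, 0.45 * len(matrix.row_labels) + 3)),
        annot=(matrix.values * 100).round(0).astype(int) if annotate_percent else None,
        fmt="d" if annotate_percent else "",
        xticklabels=True,
        yticklabels=True,
        cbar_kws={"label": "logit(frequency), truncated at 1%"},
    )
    grid.ax_heatmap.set_xticklabels(
        grid.ax_heatmap.get_xticklabels(), rotation=60, ha="right", fontsize=7
    )
    grid.ax_heatmap.set_yticklabels(
        grid.ax_heatmap.get_yticklabels(), fontsize=7
    )
    grid.savefig(out_path)
    plt.close(grid.figure)
    return out_path
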