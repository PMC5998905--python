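"""Comparative flux statistics across tissue-specific models.

Three statistics quantify how a reaction's steady-state flux shifts across
tissues and developmental stages:

* **total variation** of an ordered flux series f_1..f_k,
  TV = sum_i |f_i - f_{i-1}| (k values give k-1 consecutive differences);
  the larger the TV, the more the reaction fluctuates across the series;
* the **FVA-normalized flux-change ratio** between two tissues,
  ratio = (|flux2| - |flux1|) / (maxflux - minflux), where the denominator
  is the reaction's flux variability range; ratio > 0.5 calls the reaction
  up-regulated, ratio < -0.5 down-regulated (fold change is unusable here
  because fluxes can be negative);
* **hierarchical clustering** of the reactions x tissues flux matrix to
  expose tissues with similar flux patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "total_variation",
    "rank_fluctuating_reactions",
    "FluxChange",
    "flux_change",
    "compare_fluxes",
    "significantly_active",
    "ClusteringResult",
    "cluster_patterns",
]


def total_variation(series: Sequence[float]) -> float:
    """Sum of absolute consecutive differences of an ordered flux series."""
    values = np.asarray(series, dtype=float)
    if values.size < 2:
        raise ValueError("total variation needs at least two flux values")
    return float(np.abs(np.diff(values)).sum())


def rank_fluctuating_reactions(
    flux_matrix: pd.DataFrame, order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Rank reactions by total variation across an ordered tissue series.

    ``flux_matrix`` is reactions x tissues; ``order`` selects and orders
    the tissue columns (defaults to the matrix's column order).  Returns a
    frame with columns ``reaction_id``, ``total_variation``, ``rank``
    sorted descending by TV, ties broken by reaction id.
    """
    cols = list(order) if order is not None else list(flux_matrix.columns)
    missing = set(cols) - set(flux_matrix.columns)
    if missing:
        raise KeyError(f"unknown tissues in order: {sorted(missing)}")
    if len(cols) < 2:
        raise ValueError("total variation needs at least two tissues")
    sub = flux_matrix[cols]
    tv = np.abs(np.diff(sub.to_numpy(dtype=float), axis=1)).sum(axis=1)
    out = pd.DataFrame(
        {"reaction_id": sub.index.astype(str), "total_variation": tv}
    ).sort_values(
        ["total_variation", "reaction_id"], ascending=[False, True], kind="mergesort"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class FluxChange:
    """One reaction's FVA-normalized flux change between two tissues."""

    reaction_id: str
    flux1: float
    flux2: float
    minflux: float
    maxflux: float
    ratio: float  # NaN when the FVA range is degenerate
    call: str  # "up" | "down" | "unchanged" | "undefined"


def flux_change(
    flux1: float,
    flux2: float,
    fva_range: tuple[float, float],
    reaction_id: str = "",
    up_threshold: float = 0.5,
    down_threshold: float = -0.5,
) -> FluxChange:
    """ratio = (|flux2| - |flux1|) / (maxflux - minflux) with the ±0.5 rule.

    A degenerate variability range (maxflux == minflux, i.e. the flux is
    pinned) makes the ratio undefined; that is reported as a value
    (call ``"undefined"``, ratio NaN), never as a division error.
    """
    minflux, maxflux = fva_range
    span = maxflux - minflux
    if span <= 0:
        return FluxChange(
            reaction_id, flux1, flux2, minflux, maxflux, math.nan, "undefined"
        )
    ratio = (abs(flux2) - abs(flux1)) / span
    if ratio > up_threshold:
        call = "up"
    elif ratio < down_threshold:
        call = "down"
    else:
        call = "unchanged"
    return FluxChange(reaction_id, flux1, flux2, minflux, maxflux, float(ratio), call)


def compare_fluxes(
    flux_matrix: pd.DataFrame,
    tissue1: str,
    tissue2: str,
    fva_ranges: Mapping[str, tuple[float, float]],
    up_threshold: float = 0.5,
    down_threshold: float = -0.5,
) -> pd.DataFrame:
    """Per-reaction flux-change table for one tissue pair.

    Reactions absent from a tissue model carry flux 0 there (they are
    inactive); reactions with no FVA entry are treated as degenerate.
    """
    for tissue in (tissue1, tissue2):
        if tissue not in flux_matrix.columns:
            raise KeyError(f"unknown tissue {tissue!r}")
    rows = []
    for rid in flux_matrix.index:
        change = flux_change(
            float(flux_matrix.at[rid, tissue1]),
            float(flux_matrix.at[rid, tissue2]),
            fva_ranges.get(rid, (0.0, 0.0)),
            reaction_id=str(rid),
            up_threshold=up_threshold,
            down_threshold=down_threshold,
        )
        rows.append(change)
    return pd.DataFrame(
        {
            "reaction_id": [c.reaction_id for c in rows],
            "flux1": [c.flux1 for c in rows],
            "flux2": [c.flux2 for c in rows],
            "minflux": [c.minflux for c in rows],
            "maxflux": [c.maxflux for c in rows],
            "ratio": [c.ratio for c in rows],
            "call": [c.call for c in rows],
        }
    )


def significantly_active(
    fluxes: Mapping[str, float], magnitude_quantile: float = 0.75
) -> set[str]:
    """Reactions in the top |flux| quantile of one tissue (default top 25%).

    "Significantly active" has no canonical threshold; this interprets it
    as a within-tissue flux-magnitude quantile over the reactions carrying
    any flux, configurable via ``magnitude_quantile``.
    """
    if not 0 < magnitude_quantile < 1:
        raise ValueError("magnitude_quantile must be in (0, 1)")
    nonzero = {r: abs(v) for r, v in fluxes.items() if abs(v) > 0}
    if not nonzero:
        return set()
    cutoff = float(np.quantile(list(nonzero.values()), magnitude_quantile))
    return {r for r, mag in nonzero.items() if mag >= cutoff}


@dataclass
class ClusteringResult:
    """Agglomerative clustering of flux (or expression) patterns."""

    labels: list[str]  # input labels, clustering order
    leaves: list[str]  # labels in dendrogram leaf order
    linkage_matrix: np.ndarray  # scipy linkage encoding of the merge tree
    metric: str
    method: str

    def to_newick(self) -> str:
        """Merge tree as a Newick string with heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.9g}"
            children = ",".join(render(c, node.dist) for c in (node.left, node.right))
            return f"({children}):{length:.9g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"

    def heights_frame(self) -> pd.DataFrame:
        Z = self.linkage_matrix
        return pd.DataFrame(
            {
                "merge": np.arange(1, Z.shape[0] + 1),
                "left": Z[:, 0].astype(int),
                "right": Z[:, 1].astype(int),
                "height": Z[:, 2],
                "size": Z[:, 3].astype(int),
            }
        )


def cluster_patterns(
    matrix: pd.DataFrame,
    axis: str = "columns",
    metric: str = "euclidean",
    method: str = "average",
) -> ClusteringResult:
    """Hierarchical clustering of rows or columns of a labeled matrix.

    Deterministic given its inputs: equal-distance merges follow the input
    label order (scipy's tie behavior with a stable observation order).
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = matrix.T if axis == "columns" else matrix
    labels = [str(x) for x in data.index]
    if len(labels) < 2:
        raise ValueError("need at least two labels to cluster")
    if data.isna().to_numpy().any():
        raise ValueError("matrix contains missing values")
    distances = pdist(data.to_numpy(dtype=float), metric=metric)
    Z = hierarchy.linkage(distances, method=method)
    leaves = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusteringResult(
        labels=labels, leaves=leaves, linkage_matrix=Z, metric=metric, method=method
    )
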