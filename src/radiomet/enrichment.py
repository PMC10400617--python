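"""Downstream characterization of selected metabolites.

Two standard steps: hypergeometric over-representation analysis (ORA) of the
selected metabolite set against a GMT pathway map, and agglomerative
hierarchical clustering of samples on the selected features (Euclidean
distance, Ward linkage by default), mirroring heatmap-style sample grouping.

ORA tests, per pathway, the upper tail P(X >= k) of a hypergeometric
distribution with universe size N, pathway size K (after intersecting with the
universe), selection size n and overlap k; p-values are Benjamini-Hochberg
adjusted across pathways, and the enrichment ratio is (k/n) / (K/N).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import false_discovery_control, hypergeom

from .io import OmicsBlock, PathwayMap


def hypergeometric_ora(
    selected: set[str],
    universe: set[str],
    pathway_map: PathwayMap,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Pathway over-representation of *selected* within *universe*.

    Returns a DataFrame sorted by p-value with columns ``pathway``, ``name``,
    ``k`` (overlap), ``K`` (pathway size in universe), ``n`` (selection size),
    ``N`` (universe size), ``p_value``, ``adjusted_p``, ``enrichment_ratio``.
    """
    selected = set(selected)
    universe = set(universe)
    if not selected:
        raise ValueError("selected metabolite set is empty")
    if not selected <= universe:
        raise ValueError("selected metabolites must be a subset of the universe")
    restricted = pathway_map.restrict(universe)
    if not restricted.members:
        raise ValueError("no pathway overlaps the universe")

    N, n = len(universe), len(selected)
    rows = []
    for pid, members in restricted.members.items():
        K = len(members)
        k = len(selected & members)
        p = float(hypergeom.sf(k - 1, N, K, n))  # upper tail P(X >= k)
        ratio = (k / n) / (K / N)
        rows.append(
            {"pathway": pid, "name": restricted.names[pid], "k": k, "K": K,
             "n": n, "N": N, "p_value": min(p, 1.0), "enrichment_ratio": ratio}
        )
    out = pd.DataFrame(rows)
    if fdr_method != "bh":
        raise ValueError(f"unsupported fdr_method {fdr_method!r}")
    out["adjusted_p"] = false_discovery_control(out["p_value"].to_numpy(), method="bh")
    out = out.sort_values(["p_value", "pathway"], kind="mergesort").reset_index(drop=True)
    return out[
        ["pathway", "name", "k", "K", "n", "N", "p_value", "adjusted_p", "enrichment_ratio"]
    ]


def hierarchical_cluster(
    block: OmicsBlock, k_clusters: int, linkage: str = "ward"
) -> tuple[pd.Series, np.ndarray]:
    """Cluster samples on the block's features (Euclidean distance).

    Returns the sample -> cluster-id assignment (ids 1..k, renumbered in order
    of first appearance along the sample-id axis) and the scipy linkage matrix.
    """
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    if k_clusters > block.n_samples:
        raise ValueError(
            f"k_clusters={k_clusters} exceeds number of samples {block.n_samples}"
        )
    if linkage not in {"ward", "complete", "average", "single"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    Z = hierarchy.linkage(block.values, method=linkage, metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k_clusters, criterion="maxclust")
    # renumber deterministically by first appearance in sample order
    remap: dict[int, int] = {}
    ids = []
    for c in raw:
        if c not in remap:
            remap[c] = len(remap) + 1
        ids.append(remap[c])
    assignment = pd.Series(ids, index=block.data.index, name="cluster")
    return assignment, Z
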