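"""Sparse-PLS association networks and delta-centrality node selection.

This is the core of the package. Two z-scored blocks measured on the same
samples are related by a canonical-mode sparse PLS: each component is the
dominant singular pair of the current cross-covariance matrix, soft-thresholded
so that at most ``keep_x`` / ``keep_y`` loading entries stay nonzero, iterated
to convergence and followed by canonical deflation of both blocks. From the
fitted components an association matrix

    M = sum_h c_h * u_h v_h^T            (clipped to [-1, 1])

is reconstructed, where ``c_h`` is the Pearson correlation of the paired
component scores. Thresholding ``|M|`` yields a bipartite radiomics-metabolite
association network per condition. Node importance is eigenvector centrality
(power iteration on the absolute-weight adjacency of the largest connected
component, max-normalized to 1; nodes outside that component score 0), and the
per-node difference between the benign-condition and malignant-condition
centralities (delta centrality, DC) flags condition-discriminative features:
nodes with DC beyond a threshold (default 0.1) are selected.

Note on scales: because the loading vectors have unit L2 norm, an association
score for a factor spread over ``s`` features in each block has magnitude of
order ``c_h / s``, not of order of a feature-feature correlation. The default
edge threshold used by :func:`build_network` callers should be chosen with
this in mind (the pipeline default is 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import METABOLITE, RADIOMICS, OmicsBlock, check_aligned

DEFAULT_TAU_DC = 0.1


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, n_iter: int):
        super().__init__(f"{msg} (after {n_iter} iterations)")
        self.n_iter = n_iter


# --------------------------------------------------------------------------- #
# sparse PLS
# --------------------------------------------------------------------------- #

@dataclass
class SplsModel:
    """Fitted canonical-mode sparse PLS.

    ``x_loadings`` (p x H) and ``y_loadings`` (q x H) columns have unit L2 norm
    with at most ``keep_x`` / ``keep_y`` nonzeros; ``component_correlations``
    holds the Pearson correlation of each pair of component scores.
    """

    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    component_correlations: np.ndarray
    x_feature_ids: list[str]
    y_feature_ids: list[str]
    keep_x: int
    keep_y: int

    @property
    def n_components(self) -> int:
        return self.x_loadings.shape[1]


def _soft_threshold_to_k(w: np.ndarray, k: int) -> np.ndarray:
    """Soft-threshold *w* so at most *k* entries remain nonzero."""
    if k >= w.size:
        return w
    lam = np.sort(np.abs(w))[::-1][k]
    out = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
    return out


def _iterate_component(
    M: np.ndarray, v0: np.ndarray, keep_x: int, keep_y: int, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholded power iteration from one initial right vector."""
    v = v0 / np.linalg.norm(v0)
    u = M @ v
    nrm = np.linalg.norm(u)
    if nrm <= 1e-15:
        raise ConvergenceError("initial loading vector is degenerate", 0)
    u /= nrm
    for it in range(1, max_iter + 1):
        u_new = _soft_threshold_to_k(M @ v, keep_x)
        nrm = np.linalg.norm(u_new)
        if nrm <= 1e-15:
            raise ConvergenceError("loading vector collapsed to zero", it)
        u_new /= nrm
        v_new = _soft_threshold_to_k(M.T @ u_new, keep_y)
        nrm = np.linalg.norm(v_new)
        if nrm <= 1e-15:
            raise ConvergenceError("loading vector collapsed to zero", it)
        v_new /= nrm
        s = 1.0 if float(u_new @ u) >= 0 else -1.0  # sign-aligned change
        delta = max(np.abs(s * u_new - u).max(), np.abs(s * v_new - v).max())
        u, v = u_new, v_new
        if delta < tol:
            return u, v
    raise ConvergenceError("sparse PLS component did not converge", max_iter)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa <= 0 or sb <= 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_spls(
    X: OmicsBlock,
    Y: OmicsBlock,
    n_components: int = 3,
    keep_x: int | None = None,
    keep_y: int | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
    n_starts: int = 8,
) -> SplsModel:
    """Fit a canonical-mode sparse PLS relating two row-aligned blocks.

    Parameters
    ----------
    n_components:
        Number of latent components H; must satisfy H <= min(p, q, n-1).
    keep_x, keep_y:
        Maximum nonzero loadings per component (``None`` = no sparsity).
    n_starts:
        Number of initializations per component. The thresholded power
        iteration maximizes ``u' M v`` under the sparsity constraint, a
        non-convex problem with local optima; each start initializes ``v``
        from one of the leading right singular vectors of the current
        cross-covariance and the converged pair with the largest objective
        is kept. With no sparsity every start converges to the dominant
        singular pair, so ``n_starts`` only matters for sparse fits.
    """
    check_aligned(X, Y)
    x = np.asarray(X.values, dtype=float)
    y = np.asarray(Y.values, dtype=float)
    n, p = x.shape
    q = y.shape[1]
    if n < 3:
        raise ValueError("sparse PLS needs at least 3 samples")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(p, q, n - 1):
        raise ValueError(
            f"n_components={n_components} exceeds min(p, q, n-1)={min(p, q, n - 1)}"
        )
    keep_x = p if keep_x is None else int(keep_x)
    keep_y = q if keep_y is None else int(keep_y)
    if not 1 <= keep_x <= p:
        raise ValueError(f"keep_x must be in [1, {p}]")
    if not 1 <= keep_y <= q:
        raise ValueError(f"keep_y must be in [1, {q}]")

    # center defensively; inputs are normally z-scored already
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)

    U = np.zeros((p, n_components))
    V = np.zeros((q, n_components))
    Xi = np.zeros((n, n_components))
    Om = np.zeros((n, n_components))
    cors = np.zeros(n_components)

    for h in range(n_components):
        M = x.T @ y
        _, sv, vt = np.linalg.svd(M, full_matrices=False)
        if sv[0] <= 1e-15:
            # nothing left to extract: zero cross-covariance
            u = np.zeros(p)
            v = np.zeros(q)
        else:
            sparse = keep_x < p or keep_y < q
            starts = 1 if not sparse else min(max(1, n_starts), (sv > 1e-12 * sv[0]).sum())
            best_obj, best_uv = -np.inf, None
            for s0 in range(starts):
                u, v = _iterate_component(
                    M, vt[s0], keep_x, keep_y, tol, max_iter
                )
                obj = abs(float(u @ M @ v))
                if obj > best_obj + 1e-12:
                    best_obj, best_uv = obj, (u, v)
            u, v = best_uv
            # deterministic sign: largest-|u| entry positive (flip the pair)
            imax = int(np.argmax(np.abs(u)))
            if u[imax] < 0:
                u, v = -u, -v

        xi = x @ u
        om = y @ v
        U[:, h], V[:, h] = u, v
        Xi[:, h], Om[:, h] = xi, om
        cors[h] = _corr(xi, om)

        # canonical deflation of both blocks on their own scores
        d = float(xi @ xi)
        if d > 0:
            x = x - np.outer(xi, (xi @ x) / d)
        d = float(om @ om)
        if d > 0:
            y = y - np.outer(om, (om @ y) / d)

    return SplsModel(
        x_loadings=U,
        y_loadings=V,
        x_scores=Xi,
        y_scores=Om,
        component_correlations=cors,
        x_feature_ids=X.feature_ids,
        y_feature_ids=Y.feature_ids,
        keep_x=keep_x,
        keep_y=keep_y,
    )


# --------------------------------------------------------------------------- #
# association matrix and network
# --------------------------------------------------------------------------- #

@dataclass
class AssociationMatrix:
    """Cross-block association scores reconstructed from sPLS components."""

    scores: pd.DataFrame  # rows: radiomics ids, columns: metabolite ids

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.scores.index]

    @property
    def col_ids(self) -> list[str]:
        return [str(c) for c in self.scores.columns]


def association_matrix(model: SplsModel) -> AssociationMatrix:
    """Reconstruct M = sum_h c_h u_h v_h^T, clipped to [-1, 1]."""
    M = np.zeros((len(model.x_feature_ids), len(model.y_feature_ids)))
    for h in range(model.n_components):
        M += model.component_correlations[h] * np.outer(
            model.x_loadings[:, h], model.y_loadings[:, h]
        )
    M = np.clip(M, -1.0, 1.0)
    return AssociationMatrix(
        pd.DataFrame(M, index=model.x_feature_ids, columns=model.y_feature_ids)
    )


@dataclass
class AssociationNetwork:
    """Thresholded bipartite graph over radiomics and metabolite nodes.

    Edges keep their signed weight as attribute ``weight`` and its absolute
    value as ``abs_weight``; node attribute ``block`` records the block kind.
    Features whose every association fell below the threshold are not in the
    graph but are listed in ``isolated``.
    """

    graph: nx.Graph
    tau_assoc: float
    isolated: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edgelist(self, path, sep: str = "\t") -> None:
        rows = [
            {"radiomics": u if self.graph.nodes[u]["block"] == RADIOMICS else v,
             "metabolite": v if self.graph.nodes[v]["block"] == METABOLITE else u,
             "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["radiomics", "metabolite", "weight"]).to_csv(
            path, sep=sep, index=False
        )


def build_network(assoc: AssociationMatrix, tau_assoc: float) -> AssociationNetwork:
    """Keep edges with ``|M_ij| >= tau_assoc``; drop (but report) isolated nodes."""
    if not 0.0 <= tau_assoc <= 1.0:
        raise ValueError("tau_assoc must lie in [0, 1]")
    M = assoc.scores.to_numpy()
    g = nx.Graph()
    rows, cols = np.nonzero(np.abs(M) >= tau_assoc)
    # a zero entry never makes an edge, even at tau=0
    keep = M[rows, cols] != 0
    rows, cols = rows[keep], cols[keep]
    row_ids, col_ids = assoc.row_ids, assoc.col_ids
    for i, j in zip(rows, cols):
        w = float(M[i, j])
        g.add_node(row_ids[i], block=RADIOMICS)
        g.add_node(col_ids[j], block=METABOLITE)
        g.add_edge(row_ids[i], col_ids[j], weight=w, abs_weight=abs(w))
    isolated = {
        RADIOMICS: [f for f in row_ids if f not in g],
        METABOLITE: [f for f in col_ids if f not in g],
    }
    return AssociationNetwork(graph=g, tau_assoc=tau_assoc, isolated=isolated)


# --------------------------------------------------------------------------- #
# communities and centrality
# --------------------------------------------------------------------------- #

@dataclass
class CommunityPartition:
    membership: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))


def detect_communities(
    net: AssociationNetwork, resolution: float = 1.0, seed: int = 0
) -> CommunityPartition:
    """Louvain-style modularity maximization on absolute edge weights."""
    if net.n_edges == 0:
        raise ValueError("cannot detect communities in an empty network")
    comms = nx.community.louvain_communities(
        net.graph, weight="abs_weight", resolution=resolution, seed=int(seed)
    )
    q = nx.community.modularity(
        net.graph, comms, weight="abs_weight", resolution=resolution
    )
    membership = {}
    # deterministic community numbering by smallest member id
    for cid, nodes in enumerate(sorted(comms, key=lambda s: sorted(s)[0])):
        for node in nodes:
            membership[node] = cid
    return CommunityPartition(membership=membership, modularity=float(q))


def eigenvector_centrality(
    net: AssociationNetwork, tol: float = 1e-10, max_iter: int = 10_000
) -> dict[str, float]:
    """Eigenvector centrality on the largest connected component.

    Power iteration on the absolute-weight adjacency matrix; the result is
    max-normalized so the most central node scores 1. Nodes outside the largest
    component (including isolated features) score 0. The largest component is
    chosen by node count, ties broken by smallest node id.
    """
    if net.n_edges == 0:
        raise ValueError("cannot compute centrality on an empty network")
    components = sorted(
        nx.connected_components(net.graph), key=lambda c: (-len(c), sorted(c)[0])
    )
    nodes = sorted(components[0])
    idx = {nd: i for i, nd in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v, d in net.graph.subgraph(nodes).edges(data=True):
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = abs(d["weight"])

    # power iteration on A + I: same Perron vector, but strictly dominant top
    # eigenvalue even on bipartite components (whose spectrum is symmetric)
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        x_new = A @ x + x
        norm = np.abs(x_new).max()
        if norm <= 0:
            raise ConvergenceError("adjacency annihilated the iterate", _ + 1)
        x_new /= norm
        if np.abs(x_new - x).max() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise ConvergenceError("power iteration did not converge", max_iter)

    x = np.abs(x)
    x /= x.max()
    ec = {nd: 0.0 for nd in net.graph.nodes}
    ec.update({nd: float(x[idx[nd]]) for nd in nodes})
    return ec


# --------------------------------------------------------------------------- #
# delta centrality and selection
# --------------------------------------------------------------------------- #

@dataclass
class CentralityTable:
    """Per-node centralities per condition, their difference, and selection."""

    table: pd.DataFrame  # index node; columns ec_benign, ec_malignant, dc, selected
    tau_dc: float
    mode: str

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def write(self, path, sep: str = "\t") -> None:
        out = self.table.reindex(
            self.table["dc"].abs().sort_values(ascending=False).index
        )
        out.to_csv(path, sep=sep, index_label="node")


def delta_centrality(
    ec_benign: dict[str, float],
    ec_malignant: dict[str, float],
    tau_dc: float = DEFAULT_TAU_DC,
    mode: str = "absolute",
) -> CentralityTable:
    """DC = EC_benign - EC_malignant per node; nodes missing in one condition
    network take EC = 0 there."""
    nodes = sorted(set(ec_benign) | set(ec_malignant))
    eb = np.array([ec_benign.get(n, 0.0) for n in nodes])
    em = np.array([ec_malignant.get(n, 0.0) for n in nodes])
    table = pd.DataFrame(
        {"ec_benign": eb, "ec_malignant": em, "dc": eb - em}, index=pd.Index(nodes, name="node")
    )
    table["selected"] = _select_mask(table["dc"].to_numpy(), tau_dc, mode)
    return CentralityTable(table=table, tau_dc=tau_dc, mode=mode)


def _select_mask(dc: np.ndarray, tau_dc: float, mode: str) -> np.ndarray:
    if mode == "absolute":
        return np.abs(dc) > tau_dc
    if mode == "signed":
        return dc > tau_dc
    raise ValueError(f"unknown selection mode {mode!r}")


def select_discriminative_nodes(
    table: CentralityTable, tau_dc: float = DEFAULT_TAU_DC, mode: str = "absolute"
) -> set[str]:
    """Nodes whose delta centrality exceeds ``tau_dc`` (strictly).

    ``absolute`` mode uses ``|DC| > tau_dc`` (discriminative for either
    condition); ``signed`` mode uses ``DC > tau_dc`` (benign-defining only).
    """
    dc = table.table["dc"].to_numpy()
    mask = _select_mask(dc, tau_dc, mode)
    return set(table.table.index[mask])
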