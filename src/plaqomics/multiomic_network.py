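"""Cross-block association networks and differential eigenvector centrality.

Pairs of omic blocks (mRNA, miRNA, cytokines) are related by a two-block
partial least squares with soft-thresholded (sparse) loadings.  Each block is
reconstructed from its own latent scores over the retained components, and
the association score between a feature of block A and a feature of block B
is the Pearson correlation of their reconstructions across samples.  Edge
significance comes from a seeded sample-permutation null.  Per-group edge
lists are merged into typed networks; communities are found by modularity
maximization and per-group eigenvector centralities are compared to rank
nodes by their change in importance between groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .omics_io import ExpressionMatrix, OmicsIOError

__all__ = [
    "AssociationNetwork",
    "pairwise_spls_associations",
    "merge_networks",
    "detect_communities",
    "differential_centrality",
    "eigenvector_centrality",
    "build_group_networks",
]


@dataclass
class AssociationNetwork:
    """Typed association graph for one sample group."""

    graph: nx.Graph
    group: str | None = None
    communities: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (
                u,
                v,
                self.graph.nodes[u].get("kind", ""),
                self.graph.nodes[v].get("kind", ""),
                d["weight"],
                d.get("p", np.nan),
            )
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["u", "v", "kind_u", "kind_v", "weight", "p"])


def _spls_reconstructions(
    X: np.ndarray, Y: np.ndarray, n_components: int, keep_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct both blocks from their own sparse PLS scores.

    X, Y are samples × features, column-centered by the caller.  Component
    weights come from the SVD of the cross-covariance, soft-thresholded to
    the top ``keep_fraction`` by absolute value; each block is deflated on
    its own score with regression loadings, so the reconstruction is the
    orthogonal projection of the block onto its retained score space.
    """
    n = X.shape[0]
    Xd, Yd = X.copy(), Y.copy()
    n_components = min(n_components, n - 1, X.shape[1], Y.shape[1])
    for _ in range(max(n_components, 1)):
        M = Xd.T @ Yd
        if not np.any(M):
            break
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        a, b = u[:, 0], vt[0]
        a = _soft_keep(a, keep_fraction)
        b = _soft_keep(b, keep_fraction)
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            break
        a, b = a / na, b / nb
        t = Xd @ a
        w = Yd @ b
        tt = t @ t
        ww = w @ w
        if tt > 0:
            Xd = Xd - np.outer(t, (Xd.T @ t) / tt)
        if ww > 0:
            Yd = Yd - np.outer(w, (Yd.T @ w) / ww)
        if tt == 0 or ww == 0:
            break
    return X - Xd, Y - Yd


def _soft_keep(v: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Zero all but the top ``keep_fraction`` entries of |v| (at least 1)."""
    if keep_fraction >= 1.0:
        return v
    k = max(1, int(np.ceil(keep_fraction * len(v))))
    if k >= len(v):
        return v
    thresh = np.sort(np.abs(v))[-k]
    out = v.copy()
    out[np.abs(v) < thresh] = 0.0
    return out


def _score_matrix(
    Xhat: np.ndarray, Yhat: np.ndarray, sd_x: np.ndarray, sd_y: np.ndarray
) -> np.ndarray:
    """Association of reconstructed features, on the original feature scales.

    ``score(i, j) = cov(Xhat_i, Yhat_j) / (sd(X_i) * sd(Y_j))`` — the
    correlation of the reconstructions, attenuated by the fraction of each
    feature's variance the retained components actually explain.  Because
    each reconstruction is an orthogonal projection, the score lies in
    [-1, 1] and equals the plain Pearson r whenever reconstruction is exact
    (e.g. univariate blocks with one component and no sparsity).
    """
    cov = Xhat.T @ Yhat / Xhat.shape[0]
    sx = np.where(sd_x > 0, sd_x, np.inf)
    sy = np.where(sd_y > 0, sd_y, np.inf)
    return np.clip(cov / np.outer(sx, sy), -1.0, 1.0)


def pairwise_spls_associations(
    block_a: ExpressionMatrix,
    block_b: ExpressionMatrix,
    n_components: int = 2,
    keep_fraction: float = 0.1,
    n_permutations: int = 200,
    seed: int = 0,
    kind_a: str = "gene",
    kind_b: str = "gene",
) -> pd.DataFrame:
    """Score every cross-block feature pair and attach permutation p-values.

    Returns a long DataFrame (u, v, kind_u, kind_v, score, p).  The
    permutation null shuffles block B's sample rows and recomputes the full
    score matrix; ``p = (1 + #extreme) / (1 + n_permutations)``.
    """
    common = [s for s in block_a.sample_ids if s in set(block_b.sample_ids)]
    if len(common) < 4:
        raise OmicsIOError("fewer than 4 shared samples between blocks")
    X = block_a.values[common].to_numpy(dtype=float).T
    Y = block_b.values[common].to_numpy(dtype=float).T
    X = X - X.mean(axis=0, keepdims=True)
    Y = Y - Y.mean(axis=0, keepdims=True)

    sd_x = X.std(axis=0)
    sd_y = Y.std(axis=0)
    Xhat, Yhat = _spls_reconstructions(X, Y, n_components, keep_fraction)
    score = _score_matrix(Xhat, Yhat, sd_x, sd_y)

    rng = np.random.default_rng(seed)
    extreme = np.ones_like(score)  # the observed ordering counts once
    for _ in range(n_permutations):
        perm = rng.permutation(len(common))
        Xp, Yp = _spls_reconstructions(X, Y[perm], n_components, keep_fraction)
        sp = _score_matrix(Xp, Yp, sd_x, sd_y)
        extreme += np.abs(sp) >= np.abs(score)
    p = extreme / (1.0 + n_permutations)

    feats_a = block_a.feature_ids
    feats_b = block_b.feature_ids
    rows = []
    for i, fa in enumerate(feats_a):
        for j, fb in enumerate(feats_b):
            rows.append((fa, fb, kind_a, kind_b, float(score[i, j]), float(p[i, j])))
    return pd.DataFrame(rows, columns=["u", "v", "kind_u", "kind_v", "score", "p"])


def merge_networks(
    edge_lists: list[pd.DataFrame],
    score_min: float = 0.4,
    p_max: float = 0.05,
    group: str | None = None,
) -> AssociationNetwork:
    """Filter edge lists by |score| and p, and union them into one graph.

    Duplicate edges keep the larger |score|; nodes with no surviving edge are
    dropped.
    """
    g = nx.Graph()
    for edges in edge_lists:
        keep = (edges["score"].abs() >= score_min) & (edges["p"] < p_max)
        for rec in edges.loc[keep].itertuples(index=False):
            if g.has_edge(rec.u, rec.v) and abs(g[rec.u][rec.v]["weight"]) >= abs(rec.score):
                continue
            g.add_node(rec.u, kind=rec.kind_u)
            g.add_node(rec.v, kind=rec.kind_v)
            g.add_edge(rec.u, rec.v, weight=float(rec.score), p=float(rec.p))
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return AssociationNetwork(graph=g, group=group)


def detect_communities(net: AssociationNetwork, seed: int = 0) -> dict[str, int]:
    """Modularity-maximizing partition on |weight| (seeded Louvain)."""
    if net.graph.number_of_nodes() == 0:
        raise OmicsIOError("cannot detect communities on an empty graph")
    absg = nx.Graph()
    absg.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        absg.add_edge(u, v, weight=abs(d["weight"]))
    parts = nx.community.louvain_communities(absg, weight="weight", seed=seed)
    labels = {}
    for cid, members in enumerate(sorted(parts, key=lambda s: sorted(s)[0])):
        for node in members:
            labels[node] = cid
    net.communities = labels
    nx.set_node_attributes(net.graph, labels, "community")
    return labels


def eigenvector_centrality(graph: nx.Graph) -> dict[str, float]:
    """Eigenvector centrality on |weight|, per connected component, globally
    max-normalized to 1.

    Within each component the Perron vector (unit max) is scaled by the
    component's leading eigenvalue before global rescaling, so nodes in
    strongly connected, heavy components rank above nodes in stray doublets;
    isolated nodes get 0.  A graph with no edges yields all zeros (with a
    warning).
    """
    cent = {n: 0.0 for n in graph.nodes}
    if graph.number_of_edges() == 0:
        if graph.number_of_nodes():
            warnings.warn("graph has no edges; all centralities set to 0")
        return cent
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) < 2:
            continue
        A = np.zeros((len(nodes), len(nodes)))
        idx = {n: i for i, n in enumerate(nodes)}
        for u, v, d in graph.subgraph(nodes).edges(data=True):
            w = abs(d["weight"])
            A[idx[u], idx[v]] = w
            A[idx[v], idx[u]] = w
        vals, vecs = np.linalg.eigh(A)
        lam = float(vals[-1])
        lead = np.abs(vecs[:, -1])
        peak = lead.max()
        if peak > 0 and lam > 0:
            lead = lead / peak * lam
        else:
            lead = np.zeros_like(lead)
        for n in nodes:
            cent[n] = float(lead[idx[n]])
    peak = max(cent.values())
    if peak > 0:
        cent = {n: c / peak for n, c in cent.items()}
    return cent


def differential_centrality(
    net_by_group: dict[str, AssociationNetwork], contrast: tuple[str, str]
) -> pd.DataFrame:
    """Per-node eigenvector centrality per group and their difference.

    ``delta = centrality[contrast[0]] - centrality[contrast[1]]`` over the
    union node set; nodes absent from a group's graph get centrality 0.
    Sorted by descending delta (ties by node ID).
    """
    g_a, g_b = contrast
    for g in contrast:
        if g not in net_by_group:
            raise OmicsIOError(f"no network for group {g!r}")
    union_nodes = sorted(set(net_by_group[g_a].nodes) | set(net_by_group[g_b].nodes))
    kinds = {}
    cents = {}
    for g in contrast:
        graph = net_by_group[g].graph
        c = eigenvector_centrality(graph)
        cents[g] = {n: c.get(n, 0.0) for n in union_nodes}
        for n in graph.nodes:
            kinds.setdefault(n, graph.nodes[n].get("kind", ""))
    rows = [
        (
            n,
            kinds.get(n, ""),
            cents[g_a][n],
            cents[g_b][n],
            cents[g_a][n] - cents[g_b][n],
        )
        for n in union_nodes
    ]
    df = pd.DataFrame(
        rows, columns=["node", "kind", f"centrality_{g_a}", f"centrality_{g_b}", "delta"]
    )
    return df.sort_values(["delta", "node"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )


def build_group_networks(
    blocks: dict[str, ExpressionMatrix],
    groups: list[str],
    n_components: int = 2,
    keep_fraction: float = 0.1,
    score_min: float = 0.4,
    p_max: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
    max_genes: int = 500,
) -> dict[str, AssociationNetwork]:
    """One association network per group from every pair of omic blocks.

    ``blocks`` maps a node kind (``gene``, ``mirna``, ``cytokine``) to its
    matrix.  The ``gene`` block is pre-filtered to the ``max_genes`` most
    variable features.  Each group's network uses only that group's samples.
    """
    nets: dict[str, AssociationNetwork] = {}
    kinds = sorted(blocks)
    for gi, group in enumerate(groups):
        per_group = {}
        for kind, mat in blocks.items():
            samples = [s for s in mat.sample_ids if mat.sample_group[s] == group]
            sub = mat.subset_samples(samples)
            if kind == "gene" and sub.n_features > max_genes:
                variances = sub.values.var(axis=1)
                top = variances.sort_values(ascending=False, kind="stable").index[:max_genes]
                sub = ExpressionMatrix(
                    sub.values.loc[sorted(top)], sub.sample_group, sub.kind
                )
            per_group[kind] = sub
        edge_lists = []
        for i in range(len(kinds)):
            for j in range(i + 1, len(kinds)):
                edge_lists.append(
                    pairwise_spls_associations(
                        per_group[kinds[i]],
                        per_group[kinds[j]],
                        n_components=n_components,
                        keep_fraction=keep_fraction,
                        n_permutations=n_permutations,
                        seed=seed + 1000 * gi + i * 10 + j,
                        kind_a=kinds[i],
                        kind_b=kinds[j],
                    )
                )
        nets[group] = merge_networks(edge_lists, score_min, p_max, group=group)
    return nets
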