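"""Weighted unsigned correlation networks, module detection, module eigenvalues,
and connectivity-SD pruning.

The network treats every molecular feature as a node and connects nodes i, j
with weight ``w_ij = |pearson(i, j)|**beta`` (unsigned: positively and
negatively co-varying features cluster together).  Modules are found by
average-linkage hierarchical clustering on a topological-overlap
dissimilarity; each module is summarized by its eigenvalue — the per-sample
first-principal-component score of the standardized member submatrix — which
downstream stages use as a derived trait.  Pruning retains only edges whose
weight exceeds ``mean + k*SD`` of all pairwise weights, the rule used to
report the condensed network at k = 1, 4 and 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .io import ScaledMatrix, autoscale

__all__ = [
    "CorrelationNetwork",
    "ModulePartition",
    "ModuleEigenvalues",
    "PrunedNetwork",
    "MODULE_COLORS",
    "build_network",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigenvalues",
    "prune_at_sd",
    "network_summary",
    "export_edges",
    "annotate_by_association",
]

# Size-ordered standard module palette (largest module = "turquoise").  The
# label "grey" is reserved for unassigned nodes.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1", "lightcyan1", "ivory", "floralwhite", "darkorange2",
    "brown4", "bisque4", "darkslateblue", "plum2", "thistle2", "thistle1",
    "salmon4", "palevioletred3", "navajowhite2", "maroon", "lightpink4",
    "lavenderblush3", "honeydew1", "darkseagreen4", "coral1",
]

UNASSIGNED = "grey"


@dataclass
class CorrelationNetwork:
    """Unsigned weighted adjacency ``w_ij = |r_ij|**beta`` over feature nodes."""

    node_ids: list[str]
    weights: np.ndarray  # dense symmetric, unit diagonal
    beta: float

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def offdiag_weights(self) -> np.ndarray:
        """Upper-triangle (i<j) weights; diagonal excluded from all statistics."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]


@dataclass
class ModulePartition:
    """Node -> module color labels, colors ordered by descending module size."""

    labels: pd.Series  # index node id, value color

    @property
    def modules(self) -> list[str]:
        """Assigned module colors in size order (excludes grey)."""
        sizes = self.sizes()
        return [c for c in sizes.index if c != UNASSIGNED]

    def sizes(self) -> pd.Series:
        counts = self.labels.value_counts()
        order = [c for c in MODULE_COLORS if c in counts.index]
        order += [c for c in counts.index if c not in order]
        return counts.reindex(order)

    def members(self, color: str) -> list[str]:
        return list(self.labels.index[self.labels == color])


@dataclass
class ModuleEigenvalues:
    """Per-module, per-sample first-PC scores (unit sample variance).

    Rows are modules, columns samples.  ``pve`` is the proportion of the
    member submatrix variance the first PC explains.  Sign is fixed so each
    eigenvalue correlates non-negatively with the mean standardized profile of
    its module's members.
    """

    scores: pd.DataFrame  # modules x samples
    pve: pd.Series

    def as_traits(self) -> pd.DataFrame:
        """Samples x modules orientation, ready to use as GWAS traits."""
        return self.scores.T


@dataclass
class PrunedNetwork:
    """Edges surviving the ``w > mean + k*SD`` connectivity rule."""

    edges: pd.DataFrame  # columns source, target, weight
    k: float
    threshold: float
    node_ids: list[str]  # nodes retained (non-isolated)
    n_components: int
    component_labels: pd.Series = field(default=None)  # type: ignore[assignment]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((s, t))) for s, t in
                zip(self.edges["source"], self.edges["target"])}


def build_network(sm: ScaledMatrix, beta: float) -> CorrelationNetwork:
    """Soft-threshold the absolute Pearson correlation matrix: ``|r|**beta``."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    X = sm.values.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to build a network")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(sm.values.columns[sd == 0])
        raise ValueError(f"zero-variance nodes must be dropped upstream: {bad[:5]}")
    r = np.corrcoef(X, rowvar=False)
    w = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(w, 1.0)
    w = (w + w.T) / 2.0
    return CorrelationNetwork(list(sm.values.columns), w, float(beta))


def pick_soft_threshold(sm: ScaledMatrix, candidate_betas=tuple(range(1, 21)),
                        r2_min: float = 0.8, fallback: float = 6,
                        n_bins: int = 10):
    """Choose the soft power by the scale-free-topology criterion.

    For each candidate beta the node connectivities ``k_i = sum_j w_ij`` are
    binned and ``log10 p(k)`` is regressed on ``log10 k``; the fit index is
    ``-sign(slope) * R^2``.  The smallest beta whose index reaches ``r2_min``
    is chosen, else ``fallback``.  Returns ``(beta, report)`` where the report
    tabulates (beta, fit index, mean connectivity).
    """
    X = sm.values.to_numpy(dtype=float)
    r = np.abs(np.clip(np.corrcoef(X, rowvar=False), -1.0, 1.0))
    np.fill_diagonal(r, 0.0)
    rows = []
    chosen = None
    for beta in candidate_betas:
        w = r ** beta
        k = w.sum(axis=1)
        rows.append((beta, _scale_free_fit(k, n_bins), float(k.mean())))
        if chosen is None and rows[-1][1] >= r2_min:
            chosen = float(beta)
    report = pd.DataFrame(rows, columns=["beta", "sft_r2", "mean_connectivity"])
    return (chosen if chosen is not None else float(fallback)), report


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return 0.0
    x = np.log10(centers[keep])
    y = np.log10(counts[keep] / counts.sum())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    return float(-np.sign(slope) * r2)


def tom_similarity(net: CorrelationNetwork) -> np.ndarray:
    """Topological overlap of the soft-thresholded adjacency.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` over u != i, j and ``k_i`` the node connectivity
    (diagonal excluded).  Unit diagonal.
    """
    a = net.weights.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(net: CorrelationNetwork, min_module_size: int = 10,
                   cut_height: float | None = None,
                   use_tom: bool = True) -> ModulePartition:
    """Cluster nodes into modules and label them with size-ordered colors.

    Average-linkage hierarchical clustering on dissimilarity ``1 - TOM`` (or
    ``1 - w`` when ``use_tom=False``) with a static cut; clusters smaller than
    ``min_module_size`` are left unassigned ("grey").  The default cut height
    (``cut_height=None``) is chosen from the dendrogram itself: the midpoint
    of the largest gap in the sorted merge heights, which separates the tight
    within-module joins from the near-ceiling background joins whatever the
    soft power compressed the dissimilarity scale to.  A numeric
    ``cut_height`` overrides this.  Ties in module size break on the
    lexicographically smallest member id, keeping labels deterministic.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    sim = tom_similarity(net) if use_tom else net.weights
    diss = 1.0 - sim
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = average(squareform(diss, checks=False))
    if cut_height is None:
        cut_height = _gap_cut(link[:, 2])
    raw = fcluster(link, t=cut_height, criterion="distance")
    ids = np.asarray(net.node_ids, dtype=object)
    clusters = []
    for c in np.unique(raw):
        members = ids[raw == c]
        if members.size >= min_module_size:
            clusters.append((members.size, str(min(members)), list(members)))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    labels = pd.Series(UNASSIGNED, index=list(ids), dtype=object)
    for rank, (_, _, members) in enumerate(clusters):
        color = (MODULE_COLORS[rank] if rank < len(MODULE_COLORS)
                 else f"module{rank + 1}")
        labels.loc[members] = color
    return ModulePartition(labels)


def _gap_cut(heights: np.ndarray) -> float:
    """Midpoint of the largest gap in the sorted dendrogram merge heights."""
    h = np.sort(np.asarray(heights, dtype=float))
    if h.size < 2:
        return float(h[-1]) if h.size else 1.0
    gaps = np.diff(h)
    i = int(np.argmax(gaps))
    return float(0.5 * (h[i] + h[i + 1]))


def module_eigenvalues(sm: ScaledMatrix, partition: ModulePartition) -> ModuleEigenvalues:
    """First-PC score per module per sample, unit variance, sign-aligned.

    Each module's standardized member submatrix is decomposed by SVD; the
    left singular vector of the leading component gives the per-sample score,
    rescaled to sample SD 1 and signed to correlate non-negatively with the
    module's mean member profile.  ``pve`` is the leading squared singular
    value over the total.
    """
    Z = sm.values
    scores, pve = {}, {}
    for color in partition.modules:
        members = [m for m in partition.members(color) if m in Z.columns]
        if not members:
            raise ValueError(f"module {color!r} has no members in the matrix")
        M = Z[members].to_numpy(dtype=float)
        M = M - M.mean(axis=0)
        u, s, _ = np.linalg.svd(M, full_matrices=False)
        score = u[:, 0]
        mean_profile = M.mean(axis=1)
        if score @ mean_profile < 0:
            score = -score
        sd = score.std(ddof=1)
        scores[color] = score / sd if sd > 0 else score
        pve[color] = float(s[0] ** 2 / np.sum(s**2))
    sdf = pd.DataFrame(scores, index=Z.index).T
    return ModuleEigenvalues(sdf, pd.Series(pve))


def prune_at_sd(net: CorrelationNetwork, k: float) -> PrunedNetwork:
    """Retain edges whose weight strictly exceeds mean + k*SD of all pairwise
    weights (population SD over the off-diagonal); drop isolated nodes and
    count connected components."""
    w = net.offdiag_weights()
    threshold = float(w.mean() + k * w.std(ddof=0))
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    keep = net.weights[iu, ju] > threshold
    ids = np.asarray(net.node_ids, dtype=object)
    edges = pd.DataFrame({
        "source": ids[iu[keep]],
        "target": ids[ju[keep]],
        "weight": net.weights[iu[keep], ju[keep]],
    })
    retained = sorted(set(edges["source"]) | set(edges["target"]),
                      key=list(ids).index)
    if retained:
        idx = {n: i for i, n in enumerate(retained)}
        g = coo_matrix(
            (np.ones(len(edges)),
             ([idx[s] for s in edges["source"]], [idx[t] for t in edges["target"]])),
            shape=(len(retained), len(retained)))
        ncomp, comp = connected_components(g, directed=False)
        comp_labels = pd.Series(comp, index=retained)
    else:
        ncomp, comp_labels = 0, pd.Series(dtype=int)
    return PrunedNetwork(edges, float(k), threshold, retained, int(ncomp), comp_labels)


def network_summary(partition: ModulePartition,
                    pruned: dict[float, PrunedNetwork]) -> pd.DataFrame:
    """Node/edge/module/component accounting per pruning level.

    ``pct_of_detected`` is retained nodes over all detected features, to one
    decimal (4,102 of 8,710 prints as 47.1).
    """
    total = len(partition.labels)
    rows = []
    for k in sorted(pruned, key=float):
        pn = pruned[k]
        kept = set(pn.node_ids)
        mods = {partition.labels[n] for n in kept} - {UNASSIGNED}
        rows.append({
            "k_sd": k,
            "nodes": pn.n_nodes,
            "pct_of_detected": round(100.0 * pn.n_nodes / total, 1),
            "edges": pn.n_edges,
            "modules": len(mods),
            "components": pn.n_components,
        })
    return pd.DataFrame(rows)


def export_edges(pruned: PrunedNetwork, prefix,
                 partition: ModulePartition | None = None) -> dict[str, str]:
    """Write Cytoscape-loadable files: ``<prefix>.sif`` (source cc target),
    ``<prefix>_edges.tsv`` (weights to 6 decimals) and ``<prefix>_nodes.tsv``
    (node attribute table with module color when a partition is given)."""
    prefix = str(prefix)
    sif_path, edge_path, node_path = (prefix + ".sif", prefix + "_edges.tsv",
                                      prefix + "_nodes.tsv")
    with open(sif_path, "w") as fh:
        for _, row in pruned.edges.iterrows():
            fh.write(f"{row['source']}\tcc\t{row['target']}\n")
    with open(edge_path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for _, row in pruned.edges.iterrows():
            fh.write(f"{row['source']}\t{row['target']}\t{row['weight']:.6f}\n")
    with open(node_path, "w") as fh:
        fh.write("node\tmodule\n")
        for n in pruned.node_ids:
            color = partition.labels.get(n, UNASSIGNED) if partition is not None else ""
            fh.write(f"{n}\t{color}\n")
    return {"sif": sif_path, "edges": edge_path, "nodes": node_path}


def annotate_by_association(partition: ModulePartition, pruned: PrunedNetwork,
                            known: dict[str, str]) -> pd.DataFrame:
    """Guilt-by-association annotation transfer within modules.

    Every unannotated node receives ``"<label>-associated"`` candidates from
    each annotated node sharing its module, scored by the retained edge weight
    between the pair (0 when pruning severed the connection).  Rows are sorted
    by node then descending score.
    """
    if not known:
        raise ValueError("need at least one annotated feature")
    wlookup: dict[tuple[str, str], float] = {}
    for _, row in pruned.edges.iterrows():
        key = tuple(sorted((row["source"], row["target"])))
        wlookup[key] = float(row["weight"])
    rows = []
    for node, color in partition.labels.items():
        if node in known or color == UNASSIGNED:
            continue
        for anno_node, label in known.items():
            if partition.labels.get(anno_node) != color:
                continue
            w = wlookup.get(tuple(sorted((node, anno_node))), 0.0)
            rows.append({"node": node, "annotation": f"{label}-associated",
                         "source_node": anno_node, "score": w})
    out = pd.DataFrame(rows, columns=["node", "annotation", "source_node", "score"])
    return out.sort_values(["node", "score"], ascending=[True, False],
                           kind="mergesort").reset_index(drop=True)
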