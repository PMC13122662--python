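"""Connectivity-based trajectory reconstruction.

For every clustering in the ensemble a minimum-spanning tree over
Mahalanobis-like inter-cluster distances is built; each cluster's
connectivity (MST degree divided by the number of clusters) is assigned to
its cells and averaged over the ensemble into a per-cell connectivity score.
Candidate clusterings are then ranked by the Calinski–Harabasz variance-ratio
criterion (VRC) on that one-dimensional score, the selected clustering gets a
fresh MST, a root (highest mean connectivity, optionally restricted to
marker-enriched clusters), root-to-leaf lineages, and arc-length pseudotime
along piecewise-linear centroid curves.  A barycentric interpolation of the
scores over the embedding gives the connectivity landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from scipy.spatial import QhullError

from .embed import ClusteringRun


@dataclass
class ClusterGraph:
    centroids: np.ndarray  # (k, 2)
    covariances: np.ndarray  # (k, 2, 2)
    distances: np.ndarray  # (k, k)
    mst_edges: list[tuple[int, int]]


@dataclass
class TrajectoryModel:
    run: ClusteringRun
    graph: ClusterGraph
    root: int
    lineages: list[list[int]]  # ordered cluster ids, root first
    cells: pd.DataFrame  # barcode(index), cluster, lineage, weight, pseudotime


def intercluster_distances(
    embedding: np.ndarray, labels: np.ndarray, ridge_scale: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mahalanobis-like distances between cluster centroids.

    ``d^2(i, j) = (mu_i - mu_j)^T [(S_i + S_j)/2 + eps I]^-1 (mu_i - mu_j)``
    with ``eps = ridge_scale *`` mean per-axis variance of the embedding;
    singleton clusters contribute ``eps I`` alone.  Returns (distances,
    centroids, covariances).
    """
    labels = np.asarray(labels)
    k = int(labels.max()) + 1
    d = embedding.shape[1]
    centroids = np.zeros((k, d))
    covs = np.zeros((k, d, d))
    eps = ridge_scale * float(embedding.var(axis=0).mean())
    for j in range(k):
        pts = embedding[labels == j]
        if len(pts) == 0:
            raise ValueError(f"cluster {j} is empty")
        centroids[j] = pts.mean(axis=0)
        if len(pts) > 1:
            covs[j] = np.cov(pts, rowvar=False, ddof=0)
    dist = np.zeros((k, k))
    eye = np.eye(d)
    for i in range(k):
        for j in range(i + 1, k):
            pooled = (covs[i] + covs[j]) / 2 + eps * eye
            delta = centroids[i] - centroids[j]
            d2 = float(delta @ np.linalg.solve(pooled, delta))
            dist[i, j] = dist[j, i] = np.sqrt(max(d2, 0.0))
    return dist, centroids, covs


def minimum_spanning_tree(distances: np.ndarray) -> list[tuple[int, int]]:
    """Prim's MST; ties broken by the lexicographically smallest (i, j) pair."""
    D = np.asarray(distances, dtype=float)
    k = D.shape[0]
    if k <= 1:
        return []
    in_tree = np.zeros(k, dtype=bool)
    in_tree[0] = True
    edges: list[tuple[int, int]] = []
    while len(edges) < k - 1:
        best = None
        for a in np.flatnonzero(in_tree):
            for b in np.flatnonzero(~in_tree):
                key = (D[a, b], min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, (min(a, b), max(a, b)), b)
        assert best is not None
        edges.append(best[1])
        in_tree[best[2]] = True
    return edges


def cluster_connectivity(mst_edges: list[tuple[int, int]], k: int) -> np.ndarray:
    """Connectivity of each cluster: MST degree / number of clusters."""
    degree = np.zeros(k)
    for a, b in mst_edges:
        degree[a] += 1
        degree[b] += 1
    return degree / k


def cluster_graph(embedding: np.ndarray, labels: np.ndarray) -> ClusterGraph:
    dist, centroids, covs = intercluster_distances(embedding, labels)
    return ClusterGraph(centroids, covs, dist, minimum_spanning_tree(dist))


def cell_connectivity(
    runs: list[ClusteringRun], graphs: list[ClusterGraph]
) -> np.ndarray:
    """Ensemble score: mean over runs of the cell's cluster connectivity."""
    if len(runs) == 0:
        raise ValueError("need at least one run")
    if len(runs) != len(graphs):
        raise ValueError(f"{len(runs)} runs but {len(graphs)} graphs")
    n = len(runs[0].labels)
    total = np.zeros(n)
    for run, graph in zip(runs, graphs):
        conn = cluster_connectivity(graph.mst_edges, run.k)
        total += conn[run.labels]
    return total / len(runs)


def ensemble_connectivity(
    embedding: np.ndarray, runs: list[ClusteringRun]
) -> np.ndarray:
    """Per-cell connectivity score averaged over per-run MSTs."""
    n = len(embedding)
    total = np.zeros(n)
    for run in runs:
        graph = cluster_graph(embedding, run.labels)
        conn = cluster_connectivity(graph.mst_edges, run.k)
        total += conn[run.labels]
    return total / len(runs)


def vrc(labels: np.ndarray, values: np.ndarray) -> float:
    """Calinski–Harabasz variance-ratio criterion on a 1-D value vector.

    Returns ``inf`` when the within-cluster variance is exactly zero while
    clusters differ (perfectly separated sentinel), so ranking still works.
    """
    labels = np.asarray(labels)
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    ids = np.unique(labels)
    k = len(ids)
    n = len(v)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    if n <= k:
        raise ValueError("need more points than clusters")
    grand = v.mean()
    ssb = 0.0
    ssw = 0.0
    for j in ids:
        grp = v[labels == j]
        ssb += len(grp) * (grp.mean() - grand) ** 2
        ssw += ((grp - grp.mean()) ** 2).sum()
    if ssw == 0.0:
        return float("inf") if ssb > 0 else 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


def rank_and_select(
    runs: list[ClusteringRun],
    cell_conn: np.ndarray,
    top_n: int = 20,
    pick: int | str = "best",
) -> tuple[ClusteringRun, pd.DataFrame]:
    """Rank the ensemble by VRC of the connectivity vector; select one run.

    Returns the selected run and the top-``top_n`` report (rank, run index,
    k, seed, VRC).  ``pick="best"`` takes the top-1; an integer picks that row
    of the report, mirroring a manual choice among the top candidates.
    """
    if not runs:
        raise ValueError("no runs to rank")
    scores = np.array([vrc(r.labels, cell_conn) for r in runs])
    order = np.argsort(-scores, kind="stable")
    top = order[: min(top_n, len(runs))]
    report = pd.DataFrame(
        {
            "rank": np.arange(len(top)),
            "run_index": top,
            "k": [runs[i].k for i in top],
            "seed": [runs[i].seed for i in top],
            "vrc": scores[top],
        }
    )
    if pick == "best":
        chosen = 0
    else:
        chosen = int(pick)
        if not 0 <= chosen < len(top):
            raise ValueError(f"pick = {chosen} outside the top-{len(top)} report")
    return runs[top[chosen]], report


def select_root(
    run: ClusteringRun,
    cell_conn: np.ndarray,
    marker_scores: np.ndarray | None = None,
) -> int:
    """Root cluster: highest mean connectivity, restricted (when marker
    scores are given) to clusters whose mean marker score is above the
    across-cluster median.  Ties go to the lowest cluster id."""
    k = run.k
    mean_conn = np.array(
        [cell_conn[run.labels == j].mean() for j in range(k)]
    )
    candidates = np.arange(k)
    if marker_scores is not None:
        marker_scores = np.asarray(marker_scores, dtype=float)
        mean_marker = np.array(
            [marker_scores[run.labels == j].mean() for j in range(k)]
        )
        enriched = mean_marker > np.median(mean_marker)
        if enriched.any():
            candidates = candidates[enriched]
    best = candidates[np.argmax(mean_conn[candidates])]
    return int(best)


def extract_lineages(
    mst_edges: list[tuple[int, int]], root: int, k: int
) -> list[list[int]]:
    """Root-to-leaf cluster paths of the final MST, in ascending leaf order."""
    if k == 1:
        return [[root]]
    adj: dict[int, list[int]] = {j: [] for j in range(k)}
    for a, b in mst_edges:
        adj[a].append(b)
        adj[b].append(a)
    parent = {root: None}
    stack = [root]
    while stack:
        node = stack.pop()
        for nb in sorted(adj[node]):
            if nb not in parent:
                parent[nb] = node
                stack.append(nb)
    if len(parent) != k:
        raise ValueError("MST does not span all clusters")
    leaves = sorted(j for j in range(k) if len(adj[j]) == 1 and j != root)
    lineages = []
    for leaf in leaves:
        path = [leaf]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])
        lineages.append(path[::-1])
    return lineages


def _project_polyline(points: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Arc-length of the nearest orthogonal projection onto a polyline."""
    seg_vec = np.diff(curve, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d2 = np.full(len(points), np.inf)
    best_s = np.zeros(len(points))
    for i, (a, v, L) in enumerate(zip(curve[:-1], seg_vec, seg_len)):
        if L == 0:
            t = np.zeros(len(points))
        else:
            t = np.clip((points - a) @ v / (L * L), 0.0, 1.0)
        proj = a + t[:, None] * v
        d2 = ((points - proj) ** 2).sum(axis=1)
        better = d2 < best_d2 - 1e-12
        best_d2[better] = d2[better]
        best_s[better] = cum[i] + t[better] * L
    return best_s


def pseudotime(
    embedding: np.ndarray,
    run: ClusteringRun,
    lineages: list[list[int]],
    barcodes: list[str],
    centroids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Arc-length pseudotime along piecewise-linear centroid curves.

    Each lineage's curve passes through its ordered cluster centroids.  A cell
    is assigned to every lineage containing its cluster, with weight
    1 / (number of such lineages); its pseudotime on a lineage is the
    arc-length of its orthogonal projection onto the curve.  Cells whose
    cluster is on no lineage get a single row with lineage ``"unassigned"``.
    """
    if centroids is None:
        centroids = np.vstack(
            [embedding[run.labels == j].mean(axis=0) for j in range(run.k)]
        )
    member_lineages: dict[int, list[int]] = {j: [] for j in range(run.k)}
    for li, path in enumerate(lineages):
        for j in path:
            member_lineages[j].append(li)
    rows = []
    for li, path in enumerate(lineages):
        curve = centroids[np.array(path)]
        mask = np.isin(run.labels, path)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        s = _project_polyline(embedding[idx], curve)
        for i, t in zip(idx, s):
            rows.append(
                {
                    "barcode": barcodes[i],
                    "cluster": int(run.labels[i]),
                    "lineage": li,
                    "weight": 1.0 / len(member_lineages[run.labels[i]]),
                    "pseudotime": float(t),
                }
            )
    orphan = [j for j, lins in member_lineages.items() if not lins]
    for i in np.flatnonzero(np.isin(run.labels, orphan)):
        rows.append(
            {
                "barcode": barcodes[i],
                "cluster": int(run.labels[i]),
                "lineage": "unassigned",
                "weight": 0.0,
                "pseudotime": np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("barcode")


def build_trajectory(
    embedding: np.ndarray,
    run: ClusteringRun,
    cell_conn: np.ndarray,
    barcodes: list[str],
    marker_scores: np.ndarray | None = None,
) -> TrajectoryModel:
    """Final MST, root, lineages and pseudotime for a selected clustering."""
    graph = cluster_graph(embedding, run.labels)
    root = select_root(run, cell_conn, marker_scores)
    lineages = extract_lineages(graph.mst_edges, root, run.k)
    cells = pseudotime(embedding, run, lineages, barcodes, graph.centroids)
    return TrajectoryModel(run, graph, root, lineages, cells)


def connectivity_landscape(
    embedding: np.ndarray,
    cell_conn: np.ndarray,
    grid_resolution: int = 100,
    margin: float = 0.05,
) -> pd.DataFrame:
    """Interpolated connectivity surface over the embedding bounding box.

    Linear barycentric interpolation inside the convex hull, nearest-neighbor
    fill outside; emits a long-format (x, y, connectivity) grid usable for
    contour or 3-D surface plots.
    """
    xy = np.asarray(embedding, dtype=float)
    z = np.asarray(cell_conn, dtype=float)
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    pad = (hi - lo) * margin
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_resolution)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_resolution)
    GX, GY = np.meshgrid(gx, gy)
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    try:
        grid = griddata(xy, z, pts, method="linear")
    except QhullError:
        warnings.warn("all cells collinear; using nearest-neighbor interpolation")
        grid = np.full(len(pts), np.nan)
    nearest = griddata(xy, z, pts, method="nearest")
    grid = np.where(np.isnan(grid), nearest, grid)
    return pd.DataFrame(
        {"x": pts[:, 0], "y": pts[:, 1], "connectivity": grid}
    )
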