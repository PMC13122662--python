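"""Preprocessing, classical MDS, and the CLARA/PAM k-medoids ensemble.

The trajectory workflow clusters a 2-D classical (Torgerson) MDS embedding of
the normalised, log-transformed, highly-variable-gene matrix with CLARA
k-medoids over a range of k, many times over, to build an ensemble of
candidate clusterings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg
from scipy.spatial.distance import cdist

from .io import CountMatrix


@dataclass
class PreprocessResult:
    matrix: np.ndarray  # cells x HVGs, log scale
    barcodes: list[str]
    genes: list[str]


@dataclass
class ClusteringRun:
    """One k-medoids solution over the full data set."""

    k: int
    labels: np.ndarray  # per-cell cluster id in [0, k)
    medoids: np.ndarray  # k cell indices into the clustered data
    seed: int | None
    cost: float


@dataclass
class EnsembleConfig:
    k_min: int = 3
    k_max: int = 20
    n_runs: int = 1000  # desk-scale default; the reference workflow used 10,000
    clara_sample_size: int | None = None  # None -> min(n, 40 + 2k)
    clara_n_samples: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.clara_n_samples < 1:
            raise ValueError("clara_n_samples must be >= 1")


def preprocess(
    counts: CountMatrix,
    min_counts_per_cell: int = 200,
    min_cells_per_gene: int = 3,
    n_hvg: int = 500,
) -> PreprocessResult:
    """Filter, normalise to the median cell total, log1p, keep top HVGs.

    Genes are ranked by the variance of their log-normalised values; ties are
    broken by gene order for determinism.
    """
    mat = counts.matrix.tocsc()
    cell_totals = np.asarray(mat.sum(axis=0)).ravel()
    keep_cells = np.flatnonzero(cell_totals >= min_counts_per_cell)
    if len(keep_cells) == 0:
        raise ValueError(
            f"no cells with >= {min_counts_per_cell} counts "
            f"(n cells in = {counts.n_cells})"
        )
    mat = mat[:, keep_cells]
    detected = np.asarray((mat > 0).sum(axis=1)).ravel()
    keep_genes = np.flatnonzero(detected >= min_cells_per_gene)
    if len(keep_genes) == 0:
        raise ValueError(
            f"no genes detected in >= {min_cells_per_gene} cells "
            f"after keeping {len(keep_cells)} cells"
        )
    mat = mat[keep_genes, :]

    totals = np.asarray(mat.sum(axis=0)).ravel().astype(float)
    target = float(np.median(totals))
    dense = np.asarray(mat.todense(), dtype=float)
    dense *= target / totals[None, :]
    logged = np.log1p(dense)

    variances = logged.var(axis=1)
    n_hvg = min(n_hvg, len(keep_genes))
    hvg = np.sort(np.argsort(-variances, kind="stable")[:n_hvg])
    return PreprocessResult(
        logged[hvg, :].T.copy(),
        [counts.barcodes[i] for i in keep_cells],
        [counts.genes[keep_genes[i]] for i in hvg],
    )


def classical_mds(dissimilarity: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson classical scaling of a symmetric dissimilarity matrix.

    Double-centers ``-D^2 / 2`` and returns the top eigenpairs scaled by the
    square roots of their (clamped non-negative) eigenvalues.  The sign of
    each axis is fixed so that its first non-negligible loading is positive.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("dissimilarity must be symmetric")
    if D.min() < 0:
        raise ValueError("dissimilarity must be non-negative")
    n = D.shape[0]
    B = -0.5 * D**2
    B -= B.mean(axis=0, keepdims=True)
    B -= B.mean(axis=1, keepdims=True)
    B = (B + B.T) / 2
    if n > 200:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = scipy.sparse.linalg.eigsh(B, k=n_components, which="LA", v0=v0)
        order = np.argsort(-vals)
        vals, vecs = vals[order], vecs[:, order]
    else:
        vals, vecs = np.linalg.eigh(B)
        vals, vecs = vals[::-1][:n_components], vecs[:, ::-1][:, :n_components]
    coords = vecs * np.sqrt(np.maximum(vals, 0.0))[None, :]
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            coords[:, j] = -col
    return coords


def mds_embedding(matrix: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical MDS of the Euclidean distances between rows of `matrix`."""
    D = cdist(matrix, matrix)
    D = (D + D.T) / 2
    return classical_mds(D, n_components=n_components)


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    dnear = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        j = int(np.argmax(gains))
        medoids.append(j)
        np.minimum(dnear, D[j], out=dnear)
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    n = D.shape[0]
    med = np.array(sorted(medoids))
    k = len(med)
    while True:
        dist = D[med]  # (k, n)
        order = np.argsort(dist, axis=0, kind="stable")
        cols = np.arange(n)
        nearest = order[0]
        d1 = dist[nearest, cols]
        cost = float(d1.sum())
        if k == 1:
            return med, cost
        d2 = dist[order[1], cols]
        in_med = np.zeros(n, dtype=bool)
        in_med[med] = True
        nonmed = np.flatnonzero(~in_med)
        best_delta = -1e-9
        best = None
        for mi in range(k):
            base = np.where(nearest == mi, d2, d1)
            newcosts = np.minimum(base[None, :], D[nonmed]).sum(axis=1)
            deltas = newcosts - cost
            j = int(np.argmin(deltas))
            if deltas[j] < best_delta:
                best_delta = float(deltas[j])
                best = (mi, int(nonmed[j]))
        if best is None:
            return med, cost
        med[best[0]] = best[1]
        med = np.sort(med)


def pam(
    dissimilarity: np.ndarray,
    k: int,
    seed: int | None = None,
    n_restarts: int = 4,
) -> ClusteringRun:
    """PAM (BUILD + SWAP) k-medoids on a precomputed dissimilarity matrix.

    Greedy BUILD followed by steepest-descent SWAP passes until no single
    swap lowers the cost, ties broken by lowest index throughout.  Because
    single-swap descent can stall in a local optimum, a few additional
    seeded random starts are swapped to convergence and the best solution is
    kept; the result is deterministic given `seed`.
    """
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be < n = {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    med, cost = _pam_swap(D, _pam_build(D, k))
    if n_restarts > 0 and k > 1:
        rng = np.random.default_rng(0 if seed is None else seed)
        for _ in range(n_restarts):
            start = list(rng.choice(n, size=k, replace=False))
            med2, cost2 = _pam_swap(D, start)
            if cost2 < cost - 1e-12:
                med, cost = med2, cost2
    labels = np.argmin(D[med], axis=0)
    return ClusteringRun(k, labels.astype(np.int32), med, seed, cost)


def clara(
    coords: np.ndarray,
    k: int,
    config: EnsembleConfig | None = None,
    seed: int = 0,
) -> ClusteringRun:
    """CLARA: PAM on random subsamples, full-data assignment, keep the best.

    Uses the classical defaults (5 subsamples of size ``40 + 2k``).  With a
    subsample as large as the data this reduces exactly to PAM.
    """
    config = config or EnsembleConfig()
    n = len(coords)
    if k >= n:
        raise ValueError(f"k = {k} must be < n = {n}")
    size = config.clara_sample_size or (40 + 2 * k)
    size = min(size, n)
    if size < k + 1:
        raise ValueError(f"clara sample size {size} too small for k = {k}")
    rng = np.random.default_rng(seed)
    best: ClusteringRun | None = None
    for _ in range(config.clara_n_samples):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        D = cdist(coords[idx], coords[idx])
        sub = pam(D, k)
        med_global = idx[sub.medoids]
        dist_all = cdist(coords, coords[med_global])
        labels = np.argmin(dist_all, axis=1).astype(np.int32)
        cost = float(dist_all[np.arange(n), labels].sum())
        if best is None or cost < best.cost:
            best = ClusteringRun(k, labels, med_global, seed, cost)
    assert best is not None
    return best


def ensemble_cluster(
    coords: np.ndarray, config: EnsembleConfig | None = None
) -> list[ClusteringRun]:
    """Run CLARA ``n_runs`` times, cycling k evenly over ``[k_min, k_max]``.

    Run ``r`` uses ``k = k_min + (r mod (k_max - k_min + 1))`` and seed
    ``base_seed + r``; all runs are retained.
    """
    config = config or EnsembleConfig()
    n = len(coords)
    if config.k_max >= n:
        raise ValueError("k_max must be < number of cells")
    span = config.k_max - config.k_min + 1
    runs = []
    for r in range(config.n_runs):
        k = config.k_min + (r % span)
        runs.append(clara(coords, k, config, seed=config.base_seed + r))
    return runs
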