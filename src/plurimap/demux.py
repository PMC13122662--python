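"""Cell-hashing demultiplexing and doublet handling.

Implements the tag-based sample assignment used for pooled single-cell runs:
cell calling from the barcode-rank knee, linear normalization of hashtag
libraries to the smallest library, sample assignment by the fold-change
between the first- and second-most counted hashtags, removal of a fixed
fraction of lowest-fold-change cells as doublets, and the Poisson estimate of
the doublet fraction from the cell load and number of capture wells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TagCountMatrix


@dataclass
class PoissonLoad:
    """Cell-loading description of a microwell capture run."""

    n_loaded: int
    n_wells: int

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.n_loaded < 1:
            raise ValueError("n_loaded must be >= 1")

    @property
    def lam(self) -> float:
        return self.n_loaded / self.n_wells


def barcode_rank_inflection(
    per_barcode_totals: np.ndarray, smooth_window: int = 5
) -> float:
    """Total-count threshold at the knee of the barcode-rank curve.

    The log10(total) vs log10(rank) curve is smoothed with a centered moving
    average; the threshold is placed at the steepest raw drop within the
    smoothing window around the steepest smoothed negative slope (geometric
    mean of the totals on either side).  Barcodes strictly below the returned
    threshold are empty.
    """
    totals = np.asarray(per_barcode_totals, dtype=float)
    totals = totals[totals > 0]
    if len(totals) < 10:
        raise ValueError(f"need >= 10 barcodes with positive totals, got {len(totals)}")
    order = np.sort(totals)[::-1]
    logt = np.log10(order)
    logr = np.log10(np.arange(1, len(order) + 1))

    w = max(1, int(smooth_window))
    kernel = np.ones(w) / w
    pad = w // 2
    padded = np.concatenate([np.full(pad, logt[0]), logt, np.full(pad, logt[-1])])
    smooth = np.convolve(padded, kernel, mode="valid")[: len(logt)]

    dr = np.diff(logr)
    dr[dr == 0] = np.finfo(float).tiny
    slopes = np.diff(smooth) / dr
    if slopes.min() >= 0:
        warnings.warn("barcode-rank curve has no negative slope; retaining all barcodes")
        return float(order[-1])
    center = int(np.argmin(slopes))
    lo = max(0, center - w)
    hi = min(len(logt) - 1, center + w)
    drops = logt[lo:hi] - logt[lo + 1 : hi + 1]
    i = lo + int(np.argmax(drops))
    return float(10 ** ((logt[i] + logt[i + 1]) / 2))


def call_cells(tags_or_totals, smooth_window: int = 5):
    """Indices of barcodes at/above the knee threshold (order preserved)."""
    totals = np.asarray(tags_or_totals, dtype=float)
    thr = barcode_rank_inflection(totals, smooth_window=smooth_window)
    return np.flatnonzero(totals >= thr), thr


def normalize_tags(tags: TagCountMatrix) -> TagCountMatrix:
    """Scale every hashtag library linearly to the smallest library total."""
    totals = tags.matrix.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(
            f"hashtag(s) with zero total reads: {[tags.hashtags[i] for i in zero]}"
        )
    scale = totals.min() / totals
    return TagCountMatrix(tags.matrix * scale[:, None], tags.hashtags, tags.barcodes)


def assign_tags(norm_tags: TagCountMatrix) -> pd.DataFrame:
    """Per-cell hashtag assignment by first/second fold-change.

    Returns a frame indexed by barcode with columns ``hashtag``, ``fc`` (the
    pseudocounted ratio ``(first + 1) / (second + 1)``) and ``status``
    (``singlet`` or ``ambiguous`` on an exact first/second tie).  With a
    single hashtag every cell is a singlet with infinite fold-change.
    """
    mat = norm_tags.matrix
    n = norm_tags.n_cells
    if norm_tags.n_tags == 1:
        return pd.DataFrame(
            {
                "hashtag": [norm_tags.hashtags[0]] * n,
                "fc": np.full(n, np.inf),
                "status": ["singlet"] * n,
            },
            index=pd.Index(norm_tags.barcodes, name="barcode"),
        )
    order = np.argsort(-mat, axis=0, kind="stable")
    first_idx = order[0]
    cols = np.arange(n)
    first = mat[first_idx, cols]
    second = mat[order[1], cols]
    fc = (first + 1.0) / (second + 1.0)
    tie = first == second
    status = np.where(tie, "ambiguous", "singlet")
    assigned = np.array(norm_tags.hashtags, dtype=object)[first_idx]
    return pd.DataFrame(
        {"hashtag": assigned, "fc": fc, "status": status},
        index=pd.Index(norm_tags.barcodes, name="barcode"),
    )


def filter_doublets(assignments: pd.DataFrame, remove_fraction: float) -> pd.DataFrame:
    """Relabel the ``floor(n * remove_fraction)`` lowest-fold-change cells as doublets.

    Cells are ordered ascending by fold-change (ties broken by barcode, so the
    cut is deterministic); the default removal fraction in the reference
    workflow is 0.0382.
    """
    if not 0 <= remove_fraction < 1:
        raise ValueError("remove_fraction must be in [0, 1)")
    out = assignments.copy()
    n_remove = int(math.floor(len(out) * remove_fraction))
    if n_remove == 0:
        return out
    order = out.assign(_bc=out.index).sort_values(["fc", "_bc"], kind="stable")
    flagged = order.index[:n_remove]
    out.loc[flagged, "status"] = "doublet"
    return out


def poisson_doublet_fraction(load: PoissonLoad) -> float:
    """Doublet fraction among occupied wells under Poisson loading.

    ``P(>= 2 cells | >= 1 cell) = (1 - e^-lam - lam e^-lam) / (1 - e^-lam)``
    with ``lam = n_loaded / n_wells``.
    """
    lam = load.lam
    if lam <= 0:
        raise ValueError("lambda must be positive")
    e = math.exp(-lam)
    return (1.0 - e - lam * e) / (1.0 - e)
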