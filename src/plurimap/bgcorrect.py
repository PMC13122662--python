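"""Distribution-based background correction of the expression matrix.

For each gene the positive ``log2(x+1)`` values are decomposed into two
equal-variance Gaussian components by EM.  When a gene passes three gates —
its maximum ``log2(x+1)`` exceeds ``min_gene_max``, the lower component's
mean is at most ``max_first_mean``, and the two component means are at least
``min_component_gap`` apart — the counts of cells belonging to the lower
(background) component are set to zero.  Defaults follow the gates of the
distribution-based error-correction step this reproduces: 8 / 5.5 / 5 on the
``log2(x+1)`` scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

_VAR_FLOOR = 1e-6


@dataclass
class CorrectionGates:
    min_gene_max: float = 8.0
    max_first_mean: float = 5.5
    min_component_gap: float = 5.0

    def __post_init__(self) -> None:
        for name in ("min_gene_max", "max_first_mean", "min_component_gap"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.min_component_gap <= 0:
            raise ValueError("min_component_gap must be positive")


@dataclass
class TwoComponentFit:
    mean1: float  # lower (background) component
    mean2: float
    responsibilities: np.ndarray  # P(component 2 | value), per input value
    converged: bool
    degenerate: bool  # single-component fallback


def fit_two_components(
    values: np.ndarray, max_iter: int = 100, tol: float = 1e-6
) -> TwoComponentFit:
    """Equal-variance two-component 1-D Gaussian mixture by EM.

    Means are initialized at the data minimum and maximum, weights at 1/2 and
    the shared variance at the sample variance; components are returned
    ordered by mean.  Fewer than 4 positive values, or a degenerate spread,
    yields a single-component fallback (no correction possible).
    """
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if len(v) < 4 or np.ptp(v) < 1e-12:
        m = float(v.mean()) if len(v) else 0.0
        return TwoComponentFit(m, m, np.zeros(len(v)), False, True)

    mu = np.array([v.min(), v.max()])
    var = max(v.var(), _VAR_FLOOR)
    w = np.array([0.5, 0.5])
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step (log-space for numerical safety)
        log_pdf = -0.5 * (v[:, None] - mu[None, :]) ** 2 / var - 0.5 * np.log(
            2 * np.pi * var
        )
        log_joint = np.log(w)[None, :] + log_pdf
        mx = log_joint.max(axis=1, keepdims=True)
        joint = np.exp(log_joint - mx)
        norm = joint.sum(axis=1, keepdims=True)
        resp = joint / norm
        ll = float((np.log(norm).ravel() + mx.ravel()).sum())
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = (resp * v[:, None]).sum(axis=0) / nk
        var = float(
            max((resp * (v[:, None] - mu[None, :]) ** 2).sum() / len(v), _VAR_FLOOR)
        )
        w = nk / len(v)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
    if mu[0] > mu[1]:
        mu = mu[::-1]
        resp = resp[:, ::-1]
    return TwoComponentFit(float(mu[0]), float(mu[1]), resp[:, 1], converged, False)


def correct_background(
    counts: CountMatrix, gates: CorrectionGates | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Zero background-component counts of every gene passing the gates.

    Returns the corrected matrix (integer, elementwise <= input) and a
    per-gene report with columns ``gated``, ``mean1``, ``mean2``,
    ``n_zeroed``.
    """
    gates = gates or CorrectionGates()
    csr = counts.matrix.tocsr()
    out = csr.copy().astype(csr.dtype)
    report = []
    for gi in range(counts.n_genes):
        start, end = csr.indptr[gi], csr.indptr[gi + 1]
        data = csr.data[start:end]
        rec = {"gene": counts.genes[gi], "gated": False,
               "mean1": np.nan, "mean2": np.nan, "n_zeroed": 0}
        if len(data):
            logv = np.log2(data.astype(float) + 1.0)
            if logv.max() > gates.min_gene_max:
                fit = fit_two_components(logv)
                rec["mean1"], rec["mean2"] = fit.mean1, fit.mean2
                if (
                    not fit.degenerate
                    and fit.mean1 <= gates.max_first_mean
                    and (fit.mean2 - fit.mean1) >= gates.min_component_gap
                ):
                    background = fit.responsibilities <= 0.5
                    out.data[start:end][background] = 0
                    rec["gated"] = True
                    rec["n_zeroed"] = int(background.sum())
        report.append(rec)
    out.eliminate_zeros()
    corrected = CountMatrix(out, counts.genes, counts.barcodes)
    return corrected, pd.DataFrame(report).set_index("gene")
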