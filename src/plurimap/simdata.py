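"""Synthetic branching pluripotency-state scRNA-seq data.

The generator emulates a naive-conversion experiment: ~3,000 cells spread
over seven states on a rooted tree of trajectories,

    primed -> bridge -> {intermediate_A -> naive, intermediate_B -> ectoderm}
    primed -> mesoderm

with negative-binomial counts driven by gene programs (pluripotency,
naive-related incl. metallothioneins, differentiation-suppressive, neural,
mesodermal, housekeeping), hashtag libraries of unequal depth with ambient
background reads, and cell doublets at a configurable rate.

Expression is controlled by per-program *activation* curves, piecewise linear
in the position along each trajectory, continuous across state boundaries:

* the primed population is a dense cloud (constant mid-level pluripotency),
* the bridge ramps pluripotency up (the Oct4+/Nanog+ bridge),
* the two intermediate subpopulations share that profile but diverge in a
  few programs only: A ramps the naive + metallothionein programs (with a
  transient differentiation-suppressive pulse), B ramps the neural program,
* the termini complete the ramps (naive, ectoderm) and the mesoderm
  offshoot leaves the primed cloud directly (pluripotency down, mesodermal
  program up).

Identical ``SimConfig`` (including ``seed``) gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io import CountMatrix, TagCountMatrix, write_mtx

STATES = [
    "primed",
    "bridge",
    "intermediate_A",
    "intermediate_B",
    "naive",
    "ectoderm",
    "mesoderm",
]

LINEAGES = {
    "naive": ["primed", "bridge", "intermediate_A", "naive"],
    "ectoderm": ["primed", "intermediate_B", "ectoderm"],
    "mesoderm": ["primed", "mesoderm"],
}

PROGRAMS = [
    "pluripotency",
    "naive",
    "diff_suppressive",
    "neural",
    "metallothionein",
    "mesoderm",
    "housekeeping",
]

#: states each lineage-agnostic program can appear in (documentation aid)
_DEF_SIZES = {
    "primed": 1000,
    "bridge": 150,
    "intermediate_A": 300,
    "intermediate_B": 300,
    "naive": 350,
    "ectoderm": 350,
    "mesoderm": 550,
}

_DEF_LOGFC = {
    "pluripotency": 3.0,
    "naive": 3.0,
    "diff_suppressive": 1.5,
    "neural": 3.0,
    "metallothionein": 1.5,
    "mesoderm": 3.0,
    "housekeeping": 2.0,
}

_DEF_DEPTHS = {"HT7": 500, "HT8": 1000, "HT9": 1500, "HT10": 2000}


@dataclass
class SimConfig:
    n_cells_per_state: dict[str, int] = field(default_factory=lambda: dict(_DEF_SIZES))
    n_genes: int = 2000
    program_sizes: dict[str, int] = field(
        default_factory=lambda: {p: 50 for p in PROGRAMS}
    )
    program_logfc: dict[str, float] = field(default_factory=lambda: dict(_DEF_LOGFC))
    nb_dispersion: float = 2.0
    base_mean: float = 0.5
    branch_noise_sd: float = 0.05
    primed_heterogeneity: float = 0.35
    discrete_states: bool = False  # flatten within-state gradients (separable blobs)
    doublet_rate: float = 0.05
    tag_depth: dict[str, int] = field(default_factory=lambda: dict(_DEF_DEPTHS))
    tag_background_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_cells_per_state) - set(STATES)
        if unknown:
            raise ValueError(f"unknown states in n_cells_per_state: {sorted(unknown)}")
        if any(n <= 0 for n in self.n_cells_per_state.values()):
            raise ValueError("cell counts per state must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        unknown = set(self.program_sizes) - set(PROGRAMS)
        if unknown:
            raise ValueError(f"unknown programs: {sorted(unknown)}")
        if any(s <= 0 for s in self.program_sizes.values()):
            raise ValueError("program sizes must be positive")
        if sum(self.program_sizes.values()) > self.n_genes:
            raise ValueError(
                f"program sizes sum to {sum(self.program_sizes.values())} "
                f"> n_genes = {self.n_genes}"
            )
        if any(f < 0 for f in self.program_logfc.values()):
            raise ValueError("program_logfc must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if self.branch_noise_sd < 0:
            raise ValueError("branch_noise_sd must be non-negative")
        if not 0 <= self.primed_heterogeneity <= 1:
            raise ValueError("primed_heterogeneity must be in [0, 1]")
        if not 0 <= self.doublet_rate <= 0.5:
            raise ValueError("doublet_rate must be in [0, 0.5]")
        if any(d <= 0 for d in self.tag_depth.values()):
            raise ValueError("tag depths must be positive")
        if not 0 <= self.tag_background_fraction <= 0.5:
            raise ValueError("tag_background_fraction must be in [0, 0.5]")

    @property
    def n_cells(self) -> int:
        return sum(self.n_cells_per_state.values())

    @property
    def hashtags(self) -> list[str]:
        return list(self.tag_depth)


@dataclass
class SimTruth:
    """Ground truth tables: one row per cell, one entry per gene."""

    cells: pd.DataFrame  # barcode(index), state, lineage, latent_time, is_doublet, hashtag
    gene_programs: pd.Series  # gene -> program name or "none"

    def __post_init__(self) -> None:
        required = {"state", "lineage", "latent_time", "is_doublet", "hashtag"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")


def _activation(
    program: str, state: str, u: np.ndarray, lineage: np.ndarray, het: float
) -> np.ndarray:
    """Program activation for cells of `state` at within-state progress u.

    ``het`` is the lineage-priming amplitude: primed cells ramp the leading
    program of their own fate up to ``het`` (naive-inducers for the naive and
    ectoderm routes, the mesodermal program for the offshoot), which spreads
    the primed cloud toward every arm and makes progress along the trajectory
    observable inside it.  Downstream states continue each ramp continuously.
    """
    z = np.zeros_like(u)
    if program == "housekeeping":
        return np.ones_like(u)
    if program == "pluripotency":
        # transient Oct4/Nanog peak: the bridge is a narrow spur off the
        # primed cloud; the naive-fated intermediate settles back quickly
        if state == "primed":
            return np.full_like(u, 0.6)
        if state == "bridge":
            return 0.6 + 0.4 * u
        if state == "intermediate_A":
            return 1.0 - 0.4 * np.minimum(u / 0.1, 1.0)  # sharp post-peak descent
        if state == "intermediate_B":
            return np.full_like(u, 0.6)
        if state == "naive":
            return 0.6 + 0.2 * u
        if state in ("ectoderm", "mesoderm"):
            return 0.6 * (1.0 - u)
    if program == "naive":
        # naive-inducer ramp shared by both intermediate subpopulations (the
        # hub is one corridor; its halves differ in a few late programs only)
        if state == "primed":
            return np.where(np.isin(lineage, ["naive", "ectoderm"]), het * u, 0.0)
        if state == "bridge":
            return np.full_like(u, het)
        if state in ("intermediate_A", "intermediate_B"):
            return het + (0.6 - het) * u
        if state == "naive":
            return 0.6 + 0.4 * u
        if state == "ectoderm":
            return 0.6 * (1.0 - u)
    if program == "metallothionein":
        if state == "intermediate_A":
            return 0.6 * np.maximum((u - 0.15) / 0.85, 0.0)  # naive-fated half
        if state == "naive":
            return 0.6 + 0.4 * u
    if program == "diff_suppressive":
        if state == "intermediate_A":
            return np.maximum(1.0 - np.abs(u - 0.55) / 0.45, 0.0)  # transient pulse
    if program == "neural":
        if state == "intermediate_B":
            return 0.6 * np.maximum((u - 0.15) / 0.85, 0.0)  # neural-fated half
        if state == "ectoderm":
            return 0.6 + 0.4 * u
    if program == "mesoderm":
        if state == "primed":
            return np.where(lineage == "mesoderm", het * u, 0.0)
        if state == "mesoderm":
            return het + (1.0 - het) * u
    return z


def _gene_programs(config: SimConfig) -> pd.Series:
    names = [f"G{i:05d}" for i in range(config.n_genes)]
    membership = np.array(["none"] * config.n_genes, dtype=object)
    start = 0
    for prog in PROGRAMS:
        size = config.program_sizes.get(prog, 0)
        membership[start : start + size] = prog
        start += size
    return pd.Series(membership, index=names, name="program")


def _sample_cells(config: SimConfig, rng: np.random.Generator, n_extra: int = 0):
    """Draw per-cell (state, lineage, latent_time, noisy position)."""
    states: list[str] = []
    for s in STATES:
        states.extend([s] * config.n_cells_per_state.get(s, 0))
    if n_extra:
        pool = list(config.n_cells_per_state)
        probs = np.array([config.n_cells_per_state[s] for s in pool], dtype=float)
        probs /= probs.sum()
        states.extend(rng.choice(pool, size=n_extra, p=probs))
    states_arr = np.array(states, dtype=object)
    n = len(states_arr)

    lineage = np.empty(n, dtype=object)
    latent = np.empty(n)
    u_noisy = np.empty(n)
    state_noisy = np.empty(n, dtype=object)
    for i, s in enumerate(states_arr):
        options = [name for name, path in LINEAGES.items() if s in path]
        lin = options[rng.integers(len(options))]
        path = LINEAGES[lin]
        pos = path.index(s)
        u = rng.uniform()
        t = (pos + u) / len(path)
        # jitter along the trajectory ("spread around the latent curve")
        t_noisy = t + rng.normal(0.0, config.branch_noise_sd)
        t_noisy = min(max(t_noisy, 0.0), 1.0 - 1e-9)
        s_idx = int(t_noisy * len(path))
        lineage[i] = lin
        latent[i] = t
        state_noisy[i] = path[s_idx]
        u_noisy[i] = t_noisy * len(path) - s_idx
    return states_arr, lineage, latent, state_noisy, u_noisy


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with mean `mean` and size `dispersion` (Poisson limit at inf)."""
    if np.isinf(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_counts(
    config: SimConfig, n_extra: int = 0
) -> tuple[CountMatrix, SimTruth]:
    """Draw the gene x cell count matrix and its truth table.

    ``n_extra`` appends extra singlet cells (states drawn proportionally to the
    configured sizes); :func:`simulate_dataset` uses it so that doublet
    injection preserves the configured cell total.
    """
    rng = np.random.default_rng(config.seed)
    programs = _gene_programs(config)
    states, lineage, latent, state_noisy, u_noisy = _sample_cells(config, rng, n_extra)
    if config.discrete_states:
        # plateau mode: every cell sits at its state's midpoint expression
        state_noisy = states.copy()
        u_noisy = np.full(len(states), 0.5)
    n = len(states)
    barcodes = [f"CELL{i:05d}" for i in range(n)]

    # per-cell activation of each program, from the jittered trajectory position
    act = np.zeros((len(PROGRAMS), n))
    for s in STATES:
        mask = state_noisy == s
        if not mask.any():
            continue
        u = u_noisy[mask]
        lin = lineage[mask]
        for pi, prog in enumerate(PROGRAMS):
            act[pi, mask] = _activation(
                prog, s, u, lin, config.primed_heterogeneity
            )

    # stochastic priming: beyond the fate-directed ramps, primed cells leak
    # low-level expression of programs off their own route, making the
    # starting population a broad heterogeneous cloud (its breadth is what
    # keeps it at the center of the inter-cluster distance structure)
    if config.primed_heterogeneity > 0:
        pmask = state_noisy == "primed"
        n_primed = int(pmask.sum())
        for prog in ("neural", "metallothionein", "diff_suppressive"):
            pi = PROGRAMS.index(prog)
            act[pi, pmask] = np.minimum(
                act[pi, pmask]
                + rng.uniform(0.0, config.primed_heterogeneity, n_primed),
                1.0,
            )

    log_mu = np.full((config.n_genes, n), np.log(config.base_mean))
    prog_codes = programs.to_numpy()
    for pi, prog in enumerate(PROGRAMS):
        gmask = prog_codes == prog
        if gmask.any():
            log_mu[gmask, :] += config.program_logfc.get(prog, 0.0) * act[pi][None, :]
    counts = _nb_sample(rng, np.exp(log_mu), config.nb_dispersion)

    hashtags = np.array(config.hashtags, dtype=object)
    tag_of_cell = hashtags[rng.integers(len(hashtags), size=n)]

    cells = pd.DataFrame(
        {
            "state": states,
            "lineage": lineage,
            "latent_time": latent,
            "is_doublet": np.zeros(n, dtype=bool),
            "hashtag": tag_of_cell,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    matrix = CountMatrix(sp.csr_matrix(counts), list(programs.index), barcodes)
    return matrix, SimTruth(cells, programs)


def inject_doublets(
    counts: CountMatrix, truth: SimTruth, rate: float, seed: int
) -> tuple[CountMatrix, SimTruth]:
    """Merge random cell pairs into synthetic doublets.

    ``floor(rate * n)`` pairs of distinct cells are summed gene-wise; each pair
    becomes one cell (the first member's barcode) flagged ``is_doublet`` with
    both hashtags recorded as ``"a|b"``.  The output therefore has
    ``n - floor(rate * n)`` cells; :func:`simulate_dataset` over-generates
    singlets first so the configured cell total is preserved end to end.
    """
    if not 0 <= rate <= 0.5:
        raise ValueError("doublet rate must be in [0, 0.5]")
    n = counts.n_cells
    n_d = int(np.floor(rate * n))
    if n_d == 0:
        return counts, truth
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=2 * n_d, replace=False)
    hosts, partners = chosen[:n_d], chosen[n_d:]
    return _merge_pairs(counts, truth, hosts, partners)


def _merge_pairs(
    counts: CountMatrix, truth: SimTruth, hosts: np.ndarray, partners: np.ndarray
) -> tuple[CountMatrix, SimTruth]:
    mat = np.asarray(counts.matrix.todense())
    mat[:, hosts] += mat[:, partners]
    keep = np.setdiff1d(np.arange(counts.n_cells), partners)
    cells = truth.cells.copy()
    host_tags = cells["hashtag"].to_numpy()
    merged_tags = [
        "|".join(sorted([host_tags[h], host_tags[p]]))
        for h, p in zip(hosts, partners)
    ]
    cells.iloc[hosts, cells.columns.get_loc("hashtag")] = merged_tags
    cells.iloc[hosts, cells.columns.get_loc("is_doublet")] = True
    new_counts = CountMatrix(
        sp.csr_matrix(mat[:, keep]),
        counts.genes,
        [counts.barcodes[i] for i in keep],
    )
    return new_counts, SimTruth(cells.iloc[keep], truth.gene_programs)


def simulate_tags(truth: SimTruth, config: SimConfig) -> TagCountMatrix:
    """Hashtag x cell read counts for the cells in `truth`.

    A singlet stained with hashtag ``h`` yields ``Poisson((1-b) * depth_h)``
    own-tag reads and background ``Poisson(b * depth_h / (T-1))`` reads spread
    uniformly over the other tags (``b`` = tag_background_fraction).  Doublets
    contribute half of each member tag's profile.  Library depths are
    deliberately unequal across hashtags to exercise the linear normalization.
    """
    tags = config.hashtags
    if len(tags) < 2 and config.doublet_rate > 0:
        raise ValueError("need >= 2 hashtags when doublet_rate > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = len(truth.cells)
    T = len(tags)
    tag_index = {t: i for i, t in enumerate(tags)}
    b = config.tag_background_fraction
    mean = np.zeros((T, n))
    for j, label in enumerate(truth.cells["hashtag"]):
        members = label.split("|")
        w = 1.0 / len(members)
        for m in members:
            depth = config.tag_depth[m]
            own = tag_index[m]
            mean[own, j] += w * (1.0 - b) * depth
            if T > 1:
                bg = w * b * depth / (T - 1)
                for other in range(T):
                    if other != own:
                        mean[other, j] += bg
    counts = rng.poisson(mean)
    return TagCountMatrix(counts, tags, list(truth.cells.index))


def inject_ambient_background(
    counts: CountMatrix,
    genes: Iterable[str],
    rate: float,
    level: float,
    seed: int,
) -> tuple[CountMatrix, sp.csr_matrix]:
    """Add spurious low counts to non-expressing cells of the given genes.

    Each zero-count (gene, cell) position of a target gene receives, with
    probability `rate`, ``1 + Poisson(level - 1)`` ambient counts.  Returns the
    contaminated matrix and a sparse mask of injected positions — the oracle
    for judging background-correction recall/specificity.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_idx = {g: i for i, g in enumerate(counts.genes)}
    mat = counts.matrix.tolil(copy=True)
    mask = sp.lil_matrix(counts.matrix.shape, dtype=bool)
    for g in genes:
        gi = gene_idx[g]
        row = counts.matrix.getrow(gi).toarray().ravel()
        zeros = np.flatnonzero(row == 0)
        hit = zeros[rng.random(len(zeros)) < rate]
        if len(hit) == 0:
            continue
        added = 1 + rng.poisson(max(level - 1.0, 0.0), size=len(hit))
        mat[gi, hit] = added
        mask[gi, hit] = True
    contaminated = CountMatrix(sp.csr_matrix(mat), counts.genes, counts.barcodes)
    return contaminated, sp.csr_matrix(mask)


def simulate_dataset(
    config: SimConfig,
) -> tuple[CountMatrix, TagCountMatrix, SimTruth]:
    """Full synthetic dataset: counts + hashtag reads + truth.

    Doublets are created by over-generating ``floor(rate * n)`` extra singlets
    and merging each into a resident cell, so the returned matrices have
    exactly the configured number of cells.
    """
    n_target = config.n_cells
    n_d = int(np.floor(config.doublet_rate * n_target))
    counts, truth = simulate_counts(config, n_extra=n_d)
    if n_d > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
        hosts = rng.choice(n_target, size=n_d, replace=False)
        partners = np.arange(n_target, n_target + n_d)
        counts, truth = _merge_pairs(counts, truth, hosts, partners)
    tags = simulate_tags(truth, config)
    return counts, tags, truth


def write_dataset(
    outdir: str | Path,
    counts: CountMatrix,
    tags: TagCountMatrix,
    truth: SimTruth,
    config: SimConfig,
) -> None:
    """Write counts/tags as MTX+TSV, truth as TSV, config echoed as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx(counts, outdir / "counts")
    write_mtx(tags, outdir / "tags")
    truth.cells.to_csv(outdir / "truth.tsv", sep="\t")
    truth.gene_programs.to_csv(outdir / "gene_programs.tsv", sep="\t")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
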