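"""Config-driven end-to-end pipeline.

A YAML run configuration (strictly validated, unknown keys rejected) drives
the stages simulate -> demultiplex -> background-correct -> preprocess/embed
-> ensemble -> connectivity/trajectory -> landscape.  Every run echoes its
fully-resolved configuration next to the outputs; a rerun against the same
directory with an identical configuration reuses intermediates on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import demux as dx
from .bgcorrect import CorrectionGates, correct_background
from .embed import ClusteringRun, EnsembleConfig, ensemble_cluster, mds_embedding, preprocess
from .io import CountMatrix, TagCountMatrix, read_mtx, write_mtx
from .simdata import SimConfig, simulate_dataset
from .trajectory import (
    build_trajectory,
    connectivity_landscape,
    ensemble_connectivity,
    rank_and_select,
)

log = logging.getLogger("plurimap")


@dataclass
class RunConfig:
    outdir: str = "plurimap_run"
    seed: int = 0
    counts_prefix: str | None = None  # load counts instead of simulating
    tags_prefix: str | None = None
    simulate: dict = field(default_factory=dict)
    demux: dict = field(default_factory=dict)
    correct: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    landscape: dict = field(default_factory=dict)
    log_level: str = "INFO"

    _KNOWN_SUB = {
        "demux": {"remove_fraction"},
        "correct": {"enabled", "min_gene_max", "max_first_mean", "min_component_gap"},
        "preprocess": {"min_counts_per_cell", "min_cells_per_gene", "n_hvg"},
        "trajectory": {"top_n", "pick"},
        "landscape": {"grid_resolution"},
    }

    def __post_init__(self) -> None:
        for name, allowed in self._KNOWN_SUB.items():
            unknown = set(getattr(self, name)) - allowed
            if unknown:
                raise ValueError(f"unknown keys in '{name}': {sorted(unknown)}")
        # delegate validation of the big blocks to their dataclasses
        self.sim_config = SimConfig(**{"seed": self.seed, **self.simulate})
        self.ens_config = EnsembleConfig(**{"base_seed": self.seed, **self.ensemble})
        self.gates = CorrectionGates(
            **{k: v for k, v in self.correct.items() if k != "enabled"}
        )
        frac = self.demux.get("remove_fraction", 0.0382)
        if not 0 <= frac < 1:
            raise ValueError("demux.remove_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "counts_prefix": self.counts_prefix,
            "tags_prefix": self.tags_prefix,
            "simulate": dataclasses.asdict(self.sim_config),
            "demux": {"remove_fraction": self.demux.get("remove_fraction", 0.0382)},
            "correct": {"enabled": self.correct.get("enabled", True),
                        **dataclasses.asdict(self.gates)},
            "preprocess": {
                "min_counts_per_cell": self.preprocess.get("min_counts_per_cell", 200),
                "min_cells_per_gene": self.preprocess.get("min_cells_per_gene", 3),
                "n_hvg": self.preprocess.get("n_hvg", 500),
            },
            "ensemble": dataclasses.asdict(self.ens_config),
            "trajectory": {"top_n": self.trajectory.get("top_n", 20),
                           "pick": self.trajectory.get("pick", "best")},
            "landscape": {"grid_resolution": self.landscape.get("grid_resolution", 100)},
        }


def _fresh(outdir: Path, resolved: dict) -> bool:
    """True when a previous run with the identical configuration exists."""
    echo = outdir / "config.yaml"
    if not echo.exists():
        return False
    with open(echo) as fh:
        return yaml.safe_load(fh) == json.loads(json.dumps(resolved))


def pipeline_run(config: RunConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    Stage outputs: ``counts.*``/``tags.*`` (MTX+TSV), ``assignments.tsv``,
    ``corrected.*``, ``embedding.tsv``, ``runs.tsv`` + ``labels.npz``,
    ``trajectory.tsv``, ``mst.tsv``, ``landscape.tsv``, ``config.yaml``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    resolved = config.resolved()
    resume = _fresh(outdir, resolved)
    if not resume:
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(resolved)), fh, sort_keys=False)

    # --- input counts and tags
    if config.counts_prefix:
        counts = read_mtx(config.counts_prefix)
        tags = read_mtx(config.tags_prefix, kind="tags") if config.tags_prefix else None
        log.info("loaded %d genes x %d cells", counts.n_genes, counts.n_cells)
    else:
        counts, tags, truth = simulate_dataset(config.sim_config)
        write_mtx(counts, outdir / "counts")
        write_mtx(tags, outdir / "tags")
        truth.cells.to_csv(outdir / "truth.tsv", sep="\t")
        log.info("simulated %d genes x %d cells (seed %d)",
                 counts.n_genes, counts.n_cells, config.seed)

    # --- demultiplex and drop doublets
    if tags is not None:
        assign = dx.assign_tags(dx.normalize_tags(tags))
        assign = dx.filter_doublets(
            assign, config.demux.get("remove_fraction", 0.0382)
        )
        assign.to_csv(outdir / "assignments.tsv", sep="\t")
        keep_bc = set(assign.index[assign["status"] == "singlet"])
        keep = [i for i, bc in enumerate(counts.barcodes) if bc in keep_bc]
        counts = counts.subset_cells(np.array(keep))
        log.info("demux kept %d singlet cells", counts.n_cells)

    # --- background correction
    if config.correct.get("enabled", True):
        counts, report = correct_background(counts, config.gates)
        report.to_csv(outdir / "correction_report.tsv", sep="\t")
        log.info("background correction gated %d genes", int(report["gated"].sum()))

    # --- preprocess and embed
    prep = preprocess(
        counts,
        min_counts_per_cell=config.preprocess.get("min_counts_per_cell", 200),
        min_cells_per_gene=config.preprocess.get("min_cells_per_gene", 3),
        n_hvg=config.preprocess.get("n_hvg", 500),
    )
    emb_path = outdir / "embedding.tsv"
    emb_bin = outdir / "embedding.npz"
    if resume and emb_bin.exists():
        embedding = np.load(emb_bin)["coords"]
        log.info("reusing embedding for %d cells", len(embedding))
    else:
        embedding = mds_embedding(prep.matrix)
        np.savez_compressed(emb_bin, coords=embedding)
        pd.DataFrame(
            {"x": embedding[:, 0], "y": embedding[:, 1]},
            index=pd.Index(prep.barcodes, name="barcode"),
        ).to_csv(emb_path, sep="\t")
        log.info("embedded %d cells (classical MDS, 2-D)", len(embedding))

    # --- ensemble clustering
    labels_path = outdir / "labels.npz"
    runs_path = outdir / "runs.tsv"
    if resume and labels_path.exists() and runs_path.exists():
        index = pd.read_csv(runs_path, sep="\t")
        archive = np.load(labels_path)
        runs = [
            ClusteringRun(
                k=int(row.k),
                labels=archive[f"run{int(row.run)}"],
                medoids=np.array([], dtype=int),
                seed=int(row.seed),
                cost=float(row.cost),
            )
            for row in index.itertuples()
        ]
        log.info("reusing %d clustering runs", len(runs))
    else:
        runs = ensemble_cluster(embedding, config.ens_config)
        np.savez_compressed(
            labels_path, **{f"run{i}": r.labels for i, r in enumerate(runs)}
        )
        pd.DataFrame(
            {
                "run": np.arange(len(runs)),
                "k": [r.k for r in runs],
                "seed": [r.seed for r in runs],
                "cost": [r.cost for r in runs],
            }
        ).to_csv(runs_path, sep="\t", index=False)
        log.info("ensemble: %d CLARA runs, k in [%d, %d]",
                 len(runs), config.ens_config.k_min, config.ens_config.k_max)

    # --- connectivity, selection, trajectory
    cell_conn = ensemble_connectivity(embedding, runs)
    selected, report = rank_and_select(
        runs, cell_conn,
        top_n=config.trajectory.get("top_n", 20),
        pick=config.trajectory.get("pick", "best"),
    )
    report.to_csv(outdir / "vrc_report.tsv", sep="\t", index=False)
    model = build_trajectory(embedding, selected, cell_conn, prep.barcodes)
    cells = model.cells.copy()
    cells["connectivity"] = cell_conn[
        [prep.barcodes.index(bc) for bc in cells.index]
    ]
    cells.to_csv(outdir / "trajectory.tsv", sep="\t")
    pd.DataFrame(
        [
            {"a": a, "b": b, "weight": model.graph.distances[a, b]}
            for a, b in model.graph.mst_edges
        ]
    ).to_csv(outdir / "mst.tsv", sep="\t", index=False)
    log.info("selected k = %d (VRC %.1f), root cluster %d, %d lineages",
             selected.k, report["vrc"].iloc[0], model.root, len(model.lineages))

    # --- connectivity landscape
    grid = connectivity_landscape(
        embedding, cell_conn,
        grid_resolution=config.landscape.get("grid_resolution", 100),
    )
    grid.to_csv(outdir / "landscape.tsv", sep="\t", index=False)
    log.info("pipeline complete: %s", outdir)
    return outdir
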