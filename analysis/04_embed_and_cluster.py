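"""Embed the demultiplexed cells and run the CLARA connectivity ensemble.

Reads results/data/ and results/assignments.tsv, preprocesses (filtering,
median normalization, log, 500 HVGs), embeds with classical MDS, runs a
300-run CLARA ensemble over k = 3-20, and writes the embedding and the
per-cell connectivity scores with per-state means.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from plurimap.embed import EnsembleConfig, ensemble_cluster, mds_embedding, preprocess
from plurimap.io import read_mtx
from plurimap.trajectory import ensemble_connectivity

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    counts = read_mtx(ROOT / "data" / "counts")
    assign = pd.read_csv(ROOT / "assignments.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(ROOT / "data" / "truth.tsv", sep="\t", index_col=0)
    keep = set(assign.index[assign["status"] == "singlet"])
    counts = counts.subset_cells(
        np.array([i for i, bc in enumerate(counts.barcodes) if bc in keep])
    )

    prep = preprocess(counts)
    embedding = mds_embedding(prep.matrix)
    pd.DataFrame(
        {"x": embedding[:, 0], "y": embedding[:, 1]},
        index=pd.Index(prep.barcodes, name="barcode"),
    ).to_csv(ROOT / "embedding.tsv", sep="\t")

    runs = ensemble_cluster(embedding, EnsembleConfig(n_runs=300, base_seed=1))
    conn = ensemble_connectivity(embedding, runs)
    np.savez_compressed(
        ROOT / "ensemble_labels.npz", **{f"run{i}": r.labels for i, r in enumerate(runs)}
    )
    pd.DataFrame(
        {"run": range(len(runs)), "k": [r.k for r in runs],
         "seed": [r.seed for r in runs], "cost": [r.cost for r in runs]}
    ).to_csv(ROOT / "ensemble_runs.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"connectivity": conn}, index=pd.Index(prep.barcodes, name="barcode")
    ).to_csv(ROOT / "connectivity.tsv", sep="\t")

    states = truth.loc[prep.barcodes, "state"]
    means = pd.Series(conn).groupby(states.to_numpy()).mean().sort_values(ascending=False)
    print(f"embedded {len(embedding)} cells; {len(runs)} CLARA runs")
    print("mean cell-connectivity by true state:")
    print(means.round(3).to_string())


if __name__ == "__main__":
    main()
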