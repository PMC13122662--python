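"""Generate the synthetic naive-conversion dataset used by the analyses.

Writes the default 3,000-cell, 2,000-gene branching dataset (counts +
hashtag reads + truth tables) to results/data/ and prints its composition.
"""

from pathlib import Path

from plurimap.simdata import SimConfig, simulate_dataset, write_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    config = SimConfig(seed=1)
    counts, tags, truth = simulate_dataset(config)
    write_dataset(OUT, counts, tags, truth, config)
    print(f"dataset: {counts.n_genes} genes x {counts.n_cells} cells -> {OUT}")
    print("state composition:")
    print(truth.cells["state"].value_counts().to_string())
    print(f"doublets: {int(truth.cells['is_doublet'].sum())}")
    print(f"hashtag depths: {config.tag_depth}")


if __name__ == "__main__":
    main()
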