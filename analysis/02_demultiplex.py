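"""Demultiplex the pooled run: hashtag normalization, fold-change
assignment, doublet removal, and the Poisson doublet estimate.

Reads results/data/ (from 01_simulate_dataset.py), writes
results/assignments.tsv and prints accuracy against the simulation truth.
"""

from pathlib import Path

import pandas as pd

from plurimap import demux as dx
from plurimap.io import read_mtx

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    tags = read_mtx(ROOT / "data" / "tags", kind="tags")
    truth = pd.read_csv(ROOT / "data" / "truth.tsv", sep="\t", index_col=0)

    assign = dx.assign_tags(dx.normalize_tags(tags))
    assign = dx.filter_doublets(assign, remove_fraction=0.05)
    assign.to_csv(ROOT / "assignments.tsv", sep="\t")

    singlets = assign["status"] == "singlet"
    truth_singlets = ~truth["is_doublet"]
    accuracy = (
        assign.loc[singlets & truth_singlets.to_numpy(), "hashtag"]
        == truth.loc[(singlets & truth_singlets.to_numpy()).to_numpy(), "hashtag"]
    ).mean()
    flagged = assign.index[assign["status"] == "doublet"]
    precision = truth.loc[flagged, "is_doublet"].mean()
    print(f"cells: {len(assign)}; flagged doublets: {len(flagged)}")
    print(f"singlet hashtag accuracy: {100 * accuracy:.2f}%")
    print(f"doublet-filter precision: {precision:.2f} "
          f"(base rate {truth['is_doublet'].mean():.2f})")

    frac = dx.poisson_doublet_fraction(dx.PoissonLoad(36_664, 200_000))
    print(f"Poisson doublet estimate at 36,664 cells / 200,000 wells: "
          f"{100 * frac:.2f}% of occupied wells")


if __name__ == "__main__":
    main()
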