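"""Distribution-based background correction on a contaminated dataset.

Builds a bimodal scenario (a strongly expressed naive program over a
near-silent baseline), injects ambient counts into non-expressing cells,
corrects with the gated two-component decomposition, and reports recall and
specificity.  Writes results/correction_report.tsv.
"""

from pathlib import Path

import numpy as np

from plurimap.bgcorrect import correct_background
from plurimap.simdata import SimConfig, inject_ambient_background, simulate_counts

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    config = SimConfig(
        seed=1,
        discrete_states=True,
        primed_heterogeneity=0.0,
        doublet_rate=0.0,
        base_mean=0.002,
        nb_dispersion=8.0,
        n_cells_per_state={"primed": 1500, "naive": 800, "mesoderm": 700},
        program_logfc={
            "pluripotency": 3.0, "naive": 15.0, "diff_suppressive": 1.0,
            "neural": 1.0, "metallothionein": 1.0, "mesoderm": 3.0,
            "housekeeping": 2.0,
        },
    )
    counts, truth = simulate_counts(config)
    targets = [g for g, p in truth.gene_programs.items() if p == "naive"]
    contaminated, mask = inject_ambient_background(
        counts, targets, rate=0.05, level=5.0, seed=2
    )
    corrected, report = correct_background(contaminated)
    report.to_csv(ROOT / "correction_report.tsv", sep="\t")

    inj = mask.toarray()
    before = np.asarray(contaminated.matrix.todense())
    after = np.asarray(corrected.matrix.todense())
    gated = np.array([report.loc[g, "gated"] for g in contaminated.genes])
    removed = (after == 0) & (before > 0)
    inj_gated = inj & gated[:, None]
    signal = (before > 0) & ~inj
    print(f"gated genes: {int(gated.sum())} "
          f"({sum(report.loc[g, 'gated'] for g in targets)} of 50 targets)")
    print(f"injected ambient counts removed: {100 * removed[inj_gated].mean():.1f}%")
    print(f"true-signal counts removed: {100 * removed[signal].mean():.2f}%")


if __name__ == "__main__":
    main()
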