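"""Interpolate the connectivity landscape over the embedding.

Writes the (x, y, connectivity) grid to results/landscape.tsv and, when
matplotlib is available, a contour figure to results/landscape_contours.png
(the grid equally supports a 3-D surface plot).
"""

from pathlib import Path

import pandas as pd

from plurimap.trajectory import connectivity_landscape

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    emb_df = pd.read_csv(ROOT / "embedding.tsv", sep="\t", index_col=0)
    conn = pd.read_csv(ROOT / "connectivity.tsv", sep="\t", index_col=0)
    cell_conn = conn.loc[emb_df.index, "connectivity"].to_numpy()
    grid = connectivity_landscape(
        emb_df[["x", "y"]].to_numpy(), cell_conn, grid_resolution=100
    )
    grid.to_csv(ROOT / "landscape.tsv", sep="\t", index=False)
    print(f"landscape grid: {len(grid)} points "
          f"(connectivity {grid['connectivity'].min():.3f}"
          f"-{grid['connectivity'].max():.3f})")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    n = int(len(grid) ** 0.5)
    X = grid["x"].to_numpy().reshape(n, n)
    Y = grid["y"].to_numpy().reshape(n, n)
    Z = grid["connectivity"].to_numpy().reshape(n, n)
    fig, ax = plt.subplots(figsize=(7, 6))
    cs = ax.contourf(X, Y, Z, levels=15, cmap="viridis")
    ax.scatter(emb_df["x"], emb_df["y"], s=1, c="black", alpha=0.2)
    fig.colorbar(cs, label="cell connectivity")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    fig.savefig(ROOT / "landscape_contours.png", dpi=120)
    print(f"contours -> {ROOT / 'landscape_contours.png'}")


if __name__ == "__main__":
    main()
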