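"""Best-effort diagnostic plots (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path


def plot_pipeline_result(result, out_dir: Path) -> list[Path]:
    """Growth-rate ranking, radius linearity proxy and D-by-line charts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    if not result.growth_fits.empty:
        fig, ax = plt.subplots(figsize=(7, 4))
        df = result.growth_fits.sort_values("alpha", ascending=False)
        ax.bar(df["cell_line"], df["alpha"])
        ax.set_ylabel(r"growth rate $\alpha$")
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        path = out_dir / "growth_alpha.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if not result.diffusion.empty:
        fig, ax = plt.subplots(figsize=(7, 4))
        df = result.diffusion.sort_values("D_bar", ascending=False)
        ax.bar(df["cell_line"], df["D_bar"])
        ax.set_yscale("log")
        ax.set_ylabel(r"$\bar{D}$ (mm$^2$/day)")
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        path = out_dir / "diffusion_dbar.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if not result.correlation.empty:
        fig, ax = plt.subplots(figsize=(5.5, 5))
        im = ax.imshow(result.correlation.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(result.correlation.columns)), result.correlation.columns,
                      rotation=90)
        ax.set_yticks(range(len(result.correlation.index)), result.correlation.index)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        path = out_dir / "correlation.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
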