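"""Summary plots: stacked class bars, micro/homology length histograms
(full range and zoomed), per-chromosome variant density."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_bundle(result, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    paths = {}

    fig, ax = plt.subplots(figsize=(4, 4))
    tallies = result.tallies
    bottom = 0
    for klass in ("INS", "DEL", "SUB", "REPEAT", "EXCEPTION"):
        n = tallies.get(klass, 0)
        ax.bar(["variants"], [n], bottom=bottom, label=f"{klass} ({n})")
        bottom += n
    ax.set_ylabel("count")
    ax.legend(fontsize=8)
    ax.set_title("variant classes")
    paths["plot_classes"] = outdir / "classes.png"
    fig.savefig(paths["plot_classes"], dpi=120, bbox_inches="tight")
    plt.close(fig)

    hist = np.asarray(result.summary.histogram)
    for name, upper in (("hom_hist_full", len(hist)), ("hom_hist_zoom", 61)):
        fig, ax = plt.subplots(figsize=(6, 3))
        upper = min(upper, len(hist))
        ax.bar(np.arange(upper), hist[:upper], width=1.0)
        ax.axvline(result.baseline + 0.5, color="red", ls=":",
                   label=f"baseline {result.baseline} bp")
        ax.set_xlabel("micro/homology length (bp)")
        ax.set_ylabel("variants")
        ax.legend(fontsize=8)
        paths[f"plot_{name}"] = outdir / f"{name}.png"
        fig.savefig(paths[f"plot_{name}"], dpi=120, bbox_inches="tight")
        plt.close(fig)

    density = result.summary.chrom_density
    if density:
        fig, axes = plt.subplots(len(density), 1,
                                 figsize=(6, 1.6 * len(density)), squeeze=False)
        for ax, (chrom, per_mech) in zip(axes.ravel(), sorted(density.items())):
            for mech, counts in sorted(per_mech.items()):
                ax.plot(np.arange(len(counts)), counts, label=mech, lw=1)
            ax.set_ylabel(chrom, fontsize=8)
            ax.legend(fontsize=6)
        axes.ravel()[-1].set_xlabel("window index")
        paths["plot_density"] = outdir / "chrom_density.png"
        fig.savefig(paths["plot_density"], dpi=120, bbox_inches="tight")
        plt.close(fig)
    return paths
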