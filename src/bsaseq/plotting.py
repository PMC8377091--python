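"""Static figures: per-site posterior population-difference densities.

One panel per locus, one density ridge per CpG site (labelled by its
TSS-relative position), with the part of the distribution outside the 95%
HDI shaded darker and a reference line at zero. Positive values mean the
focal population is hypermethylated at that site.
"""

from __future__ import annotations

import numpy as np

from .model import PosteriorDraws, hdi

__all__ = ["plot_contrast_densities"]


def plot_contrast_densities(
    draws: PosteriorDraws,
    loci: list[str] | None = None,
    mass: float = 0.95,
    out_path: str | None = None,
):
    """Density ridges of the per-site contrast, HDI-shaded; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sites = draws.spec.site_labels
    if loci is None:
        loci = sorted({s.split(":")[0] for s in sites})
    fig, axes = plt.subplots(
        1, len(loci), figsize=(3.2 * len(loci), 4.5), sharex=True, squeeze=False
    )
    for ax, locus in zip(axes[0], loci):
        locus_sites = [s for s in sites if s.split(":")[0] == locus]
        for row, site in enumerate(sorted(locus_sites, key=lambda s: int(s.split(":")[1]))):
            d = draws.contrast_draws(site).ravel()
            lo, hi = hdi(d, mass)
            grid = np.linspace(d.min() - 1, d.max() + 1, 200)
            bw = 1.06 * d.std() * len(d) ** -0.2
            dens = np.exp(-0.5 * ((grid[:, None] - d[None, ::10]) / bw) ** 2).sum(axis=1)
            dens = 0.9 * dens / dens.max()
            base = row
            inside = (grid >= lo) & (grid <= hi)
            ax.fill_between(grid, base, base + dens, color="#c6dbef", lw=0)
            ax.fill_between(
                grid, base, np.where(inside, base, base + dens), color="#4a77a8", lw=0
            )
            ax.plot(grid, base + dens, color="#2b4c6f", lw=0.7)
            ax.text(grid[0], base + 0.25, site.split(":")[1], fontsize=8, ha="right")
        ax.axvline(0.0, color="0.3", lw=0.8, ls="--")
        ax.set_title(locus, style="italic")
        ax.set_yticks([])
        ax.set_xlabel(
            f"{draws.spec.focal_population} − {draws.spec.reference_population} (pp)"
        )
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
    return fig
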