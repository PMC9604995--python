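"""Plotting conveniences: distance heatmap and family homozygosity panels.

These are presentation helpers over the fitted objects; nothing here is part
of the numerical contract.  Requires matplotlib (``pip install selfpath[plot]``).
"""

from __future__ import annotations

import numpy as np


def plot_distance_heatmap(dist, ax=None, cmap: str = "viridis"):
    """Heatmap of a :class:`~selfpath.DistanceMatrix` with sample labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(dist.values, cmap=cmap)
    ax.set_xticks(range(len(dist.ids)), dist.ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(dist.ids)), dist.ids, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="genotypic distance")
    return ax


def plot_family_homozygosity(results, ax=None):
    """Observed per-offspring homozygosities by family, with the Mendelian
    expectation marked, from a fitted :class:`~selfpath.SelfingResults`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    fam_ids = list(results.families.index)
    off = results.offspring.dropna(subset=["z"])
    for x, fam in enumerate(fam_ids):
        homs = off.loc[off["family"] == fam, "obs_hom"]
        jitter = (np.arange(len(homs)) - len(homs) / 2) * 0.015
        ax.plot(x + jitter, homs, "o", ms=4, alpha=0.8)
        exp = results.families.loc[fam, "expected_mean_hom"]
        ax.hlines(exp, x - 0.3, x + 0.3, color="k", lw=1.2)
    ax.set_xticks(range(len(fam_ids)), fam_ids)
    ax.set_xlabel("family")
    ax.set_ylabel("observed homozygosity")
    return ax


def plot_program_trajectories(replicates, ax=None):
    """Mean selected-individual homozygosity per generation and strategy from
    :func:`~selfpath.program_replicates` output."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for strategy, grp in replicates.groupby("strategy"):
        mean = grp.groupby("generation")["selected_hom"].mean()
        ax.plot(mean.index, mean.values, marker="o", label=strategy)
    ax.set_xlabel("selfed generation")
    ax.set_ylabel("homozygosity of advanced individual")
    ax.legend()
    return ax
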