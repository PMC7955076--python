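"""Diagnostic plots for MSN case-control and PLS results."""

from __future__ import annotations

import numpy as np


def plot_coupling(tmap_results, control_mean_strength, ax=None):
    """Scatter of control-group mean strength vs case-control t, by quadrant."""
    import matplotlib.pyplot as plt

    from .groupstats import classify_regions

    if ax is None:
        _, ax = plt.subplots()
    labels, fractions = classify_regions(tmap_results, control_mean_strength)
    t = tmap_results.t
    colors = {"decoupling": "tab:blue", "dedifferentiation": "tab:red",
              "coupled_increase": "tab:orange", "differentiated_decrease": "tab:purple",
              "null": "gray"}
    for quad, frac in fractions.items():
        idx = labels.index[labels == quad]
        if not len(idx):
            continue
        ax.scatter(control_mean_strength.loc[idx], t.loc[idx], s=14,
                   color=colors[quad], label=f"{quad} ({100 * frac:.0f}%)")
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    ax.set_xlabel("control mean regional strength")
    ax.set_ylabel("case-control t")
    ax.legend(fontsize=7)
    return ax


def plot_map_on_sphere(atlas, values, hemisphere="L", ax=None):
    """Flat polar projection of a regional map over one hemisphere's parcels."""
    import matplotlib.pyplot as plt

    mask = atlas.hemisphere_mask(hemisphere)
    cen = atlas.centroids[mask]
    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(cen[:, 1], cen[:, 2], c=np.asarray(values), cmap="coolwarm", s=40)
    ax.set_aspect("equal")
    ax.set_xlabel("y")
    ax.set_ylabel("z")
    plt.colorbar(sc, ax=ax, shrink=0.8)
    return ax
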