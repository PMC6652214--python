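"""Plots: typical-profile polylines and cluster/background intersections."""

from __future__ import annotations

import numpy as np

from .dominance import IntersectionTable, TypicalProfile

_UNITS = {"PH": "plant height (cm)", "AGRPH": "growth rate (cm/day)",
          "CRPH": "contribution rate (%)"}


def plot_typical_profiles(profiles: list[TypicalProfile], ax=None):
    """Centroid polylines over days after sowing, one line per cluster."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for tp in profiles:
        label = f"cluster {tp.cluster_id}"
        if tp.dominant_background:
            label += f" ({tp.dominant_background})"
        ax.plot(tp.days, tp.centroid, marker="o", label=label)
    trait = profiles[0].trait_name if profiles else "PH"
    ax.set_xlabel("days after sowing")
    ax.set_ylabel(_UNITS.get(trait, trait))
    ax.legend()
    return ax


def plot_intersections(table: IntersectionTable, ax=None):
    """Grouped bars of profile counts per (cluster, background)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    counts = table.counts
    x = np.arange(len(counts.index))
    width = 0.8 / max(len(counts.columns), 1)
    for j, bg in enumerate(counts.columns):
        ax.bar(x + j * width, counts[bg].to_numpy(), width, label=str(bg))
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels([f"cluster {c}" for c in counts.index])
    ax.set_ylabel("profiles")
    ax.legend(title="background")
    return ax
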