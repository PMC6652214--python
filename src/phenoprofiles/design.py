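"""Breeding-field layout: rectangular plots with genetic-background labels.

The emulated trial is a long, narrow maize breeding strip: plots of
2 m x 2.4 m (three planting rows, 0.6 m row spacing) abutting across the
field's width, separated by 0.8 m alleys along its length, seeded at
6 plants per square meter.  Each plot carries one genetic-background label
(by default mixed / TEM / TST, the temperate and tropical-subtropical
sub-populations plus a mixed pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FieldDesign", "make_field_design", "DEFAULT_BACKGROUNDS"]

DEFAULT_BACKGROUNDS = {"mixed": 1 / 3, "TEM": 1 / 3, "TST": 1 / 3}


@dataclass
class FieldDesign:
    """Axis-aligned rectangular plots in the field frame (meters).

    ``rects`` holds one (xmin, ymin, xmax, ymax) per plot.  Plot rectangles
    are pairwise disjoint; assignment of points to plots treats rectangles
    as half-open (left/bottom edge inclusive) so shared edges are
    unambiguous.
    """

    rects: np.ndarray                # (n_plots, 4)
    plot_ids: list[str]
    backgrounds: list[str]
    plot_width_m: float
    plot_length_m: float
    row_spacing_m: float = 0.6
    column_spacing_m: float = 0.8
    seeding_density: float = 6.0     # plants per m^2

    def __post_init__(self) -> None:
        self.rects = np.atleast_2d(np.asarray(self.rects, dtype=float))
        n = len(self.rects)
        if len(self.plot_ids) != n or len(self.backgrounds) != n:
            raise ValueError("plot_ids and backgrounds must match rects")
        if len(set(self.plot_ids)) != n:
            raise ValueError("plot_ids must be unique")
        if self.plot_width_m <= 0 or self.plot_length_m <= 0:
            raise ValueError("plot dimensions must be positive")

    @property
    def n_plots(self) -> int:
        return len(self.rects)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        r = self.rects
        return (r[:, 0].min(), r[:, 1].min(), r[:, 2].max(), r[:, 3].max())

    def background_map(self) -> dict[str, str]:
        return dict(zip(self.plot_ids, self.backgrounds))

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Plot index containing each (x, y), or -1.  Half-open rectangles."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        out = np.full(x.shape, -1, dtype=int)
        for i, (x0, y0, x1, y1) in enumerate(self.rects):
            inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
            out[inside] = i
        return out

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.rects, columns=["xmin", "ymin", "xmax", "ymax"])
        df.insert(0, "plot_id", self.plot_ids)
        df["background"] = self.backgrounds
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "FieldDesign":
        df = pd.read_csv(path)
        rects = df[["xmin", "ymin", "xmax", "ymax"]].to_numpy(float)
        width = float(np.median(rects[:, 2] - rects[:, 0]))
        length = float(np.median(rects[:, 3] - rects[:, 1]))
        return cls(
            rects=rects,
            plot_ids=[str(p) for p in df["plot_id"]],
            backgrounds=[str(b) for b in df["background"]],
            plot_width_m=kwargs.pop("plot_width_m", width),
            plot_length_m=kwargs.pop("plot_length_m", length),
            **kwargs,
        )


def make_field_design(
    n_plots: int,
    plot_width_m: float = 2.0,
    plot_length_m: float = 2.4,
    backgrounds: dict[str, float] | None = None,
    seed: int = 0,
    n_cols: int | None = None,
    row_spacing_m: float = 0.6,
    column_spacing_m: float = 0.8,
    seeding_density: float = 6.0,
    margin_m: float = 1.0,
) -> FieldDesign:
    """Lay out ``n_plots`` disjoint rectangular plots on a grid.

    Plots abut across the field width (x) and are separated by
    ``column_spacing_m`` alleys along its length (y); ``n_cols`` defaults to
    the number of plot columns that fit a ~27 m-wide breeding strip, the
    footprint this generator emulates.  Background labels are drawn from the
    given proportions with a seeded generator.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    if plot_width_m <= 0 or plot_length_m <= 0:
        raise ValueError("plot dimensions must be positive")
    if backgrounds is None:
        backgrounds = dict(DEFAULT_BACKGROUNDS)
    total = sum(backgrounds.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"background proportions must sum to 1, got {total}")
    if n_cols is None:
        n_cols = max(1, min(n_plots, int(round(27.0 / plot_width_m))))
    if n_cols < 1:
        raise ValueError("n_cols must be >= 1")

    pitch_y = plot_length_m + column_spacing_m
    rects = np.empty((n_plots, 4))
    for k in range(n_plots):
        col, row = k % n_cols, k // n_cols
        x0 = margin_m + col * plot_width_m
        y0 = margin_m + row * pitch_y
        rects[k] = (x0, y0, x0 + plot_width_m, y0 + plot_length_m)

    rng = np.random.default_rng(seed)
    names = list(backgrounds)
    probs = np.array([backgrounds[n] for n in names])
    # draw labels with near-exact proportions: shuffle a deterministic pool
    counts = np.floor(probs * n_plots).astype(int)
    while counts.sum() < n_plots:
        counts[np.argmax(probs * n_plots - counts)] += 1
    pool = np.repeat(names, counts)
    rng.shuffle(pool)

    return FieldDesign(
        rects=rects,
        plot_ids=[f"P{k + 1:04d}" for k in range(n_plots)],
        backgrounds=list(pool),
        plot_width_m=plot_width_m,
        plot_length_m=plot_length_m,
        row_spacing_m=row_spacing_m,
        column_spacing_m=column_spacing_m,
        seeding_density=seeding_density,
    )
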