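"""Temporal trait profiles: PH, AGRPH and CRPH, with record cleaning.

Given plant height PH observed per plot at ordered days T_1 < ... < T_n
(days after sowing), two derived traits describe how the height increment
is distributed across the season:

* AGRPH, the average growth rate per interval:
  ``(PH_{i+1} - PH_i) / (T_{i+1} - T_i)``  (cm/day);
* CRPH, the contribution rate, the increment as a percentage of the final
  height: ``(PH_{i+1} - PH_i) / PH_n * 100``  (%).

Both derived profiles have one value per adjacent-day interval, indexed by
the interval's start day.  Cleaning drops plots flagged abnormal (lodging,
aberrant growth) and then winsorizes each trait column-wise at the 2nd and
98th percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TemporalProfile", "CleaningReport", "build_profiles", "agrph", "crph",
           "remove_abnormal", "winsorize", "profiles_to_frame", "frame_to_profiles"]


@dataclass
class TemporalProfile:
    """One plot's trait trajectory over ordered observation days."""

    plot_id: str
    background: str
    days: tuple[int, ...]
    values: np.ndarray
    trait_name: str = "PH"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        expected = len(self.days) if self.trait_name == "PH" else len(self.days) - 1
        if len(self.values) != expected:
            raise ValueError(
                f"{self.trait_name} profile over {len(self.days)} days needs "
                f"{expected} values, got {len(self.values)}")


@dataclass
class CleaningReport:
    n_input: int
    n_removed: int
    winsor_bounds: dict = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "n_output": self.n_output,
            "removed_fraction": self.removed_fraction,
            "winsor_bounds": self.winsor_bounds,
        }


def build_profiles(heights: pd.DataFrame, backgrounds: dict[str, str]
                   ) -> tuple[list[TemporalProfile], list[str]]:
    """Assemble one PH profile per plot with a complete height record.

    ``heights`` is long-format with columns plot_id, das, height_cm.
    Returns (profiles, incomplete_plot_ids); plots missing any retained
    date are reported, not silently dropped.
    """
    if heights.empty:
        return [], []
    dup = heights.duplicated(subset=["plot_id", "das"])
    if dup.any():
        raise ValueError(f"duplicate (plot, date) records: "
                         f"{heights.loc[dup, ['plot_id', 'das']].to_dict('records')[:5]}")
    days = tuple(sorted(heights["das"].unique()))
    wide = heights.pivot(index="plot_id", columns="das", values="height_cm")
    profiles, incomplete = [], []
    for pid, row in wide.iterrows():
        vals = row.reindex(days).to_numpy(float)
        if np.any(np.isnan(vals)):
            incomplete.append(str(pid))
            continue
        profiles.append(TemporalProfile(
            plot_id=str(pid),
            background=backgrounds.get(str(pid), "unknown"),
            days=days,
            values=vals,
            trait_name="PH",
        ))
    return profiles, incomplete


def agrph(profile: TemporalProfile) -> TemporalProfile:
    """Average growth rate per interval (cm/day)."""
    if profile.trait_name != "PH":
        raise ValueError("AGRPH derives from a PH profile")
    days = np.asarray(profile.days, float)
    dt = np.diff(days)
    if np.any(dt == 0):
        raise ZeroDivisionError("repeated observation day")
    rates = np.diff(profile.values) / dt
    return TemporalProfile(profile.plot_id, profile.background, profile.days,
                           rates, trait_name="AGRPH")


def crph(profile: TemporalProfile) -> TemporalProfile:
    """Contribution rate per interval: increment as % of final height."""
    if profile.trait_name != "PH":
        raise ValueError("CRPH derives from a PH profile")
    final = profile.values[-1]
    if final <= 0:
        raise ValueError(f"final height must be positive, got {final}")
    contrib = np.diff(profile.values) / final * 100.0
    return TemporalProfile(profile.plot_id, profile.background, profile.days,
                           contrib, trait_name="CRPH")


def remove_abnormal(profiles: list[TemporalProfile], flags: dict[str, bool]
                    ) -> tuple[list[TemporalProfile], CleaningReport]:
    """Drop profiles whose plot is flagged abnormal."""
    missing = [p.plot_id for p in profiles if p.plot_id not in flags]
    if missing:
        raise KeyError(f"no abnormal flag for plots: {missing[:5]}")
    kept = [p for p in profiles if not flags[p.plot_id]]
    return kept, CleaningReport(n_input=len(profiles), n_removed=len(profiles) - len(kept))


def winsorize(profiles: list[TemporalProfile], lower_pct: float = 2.0,
              upper_pct: float = 98.0) -> tuple[list[TemporalProfile], CleaningReport]:
    """Cap/floor each trait column (per time point) at its percentiles.

    Values above the ``upper_pct`` percentile are set to it; values below
    the ``lower_pct`` percentile likewise.  Percentiles use linear
    interpolation between order statistics.  Profile count is preserved.
    """
    if len(profiles) < 2:
        warnings.warn("winsorize needs >= 2 profiles; returning input unchanged")
        return list(profiles), CleaningReport(n_input=len(profiles), n_removed=0)
    mat = np.vstack([p.values for p in profiles])
    lo = np.percentile(mat, lower_pct, axis=0)
    hi = np.percentile(mat, upper_pct, axis=0)
    clipped = np.clip(mat, lo, hi)
    out = [TemporalProfile(p.plot_id, p.background, p.days, clipped[i], p.trait_name)
           for i, p in enumerate(profiles)]
    report = CleaningReport(
        n_input=len(profiles), n_removed=0,
        winsor_bounds={"lower": lo.tolist(), "upper": hi.tolist(),
                       "lower_pct": lower_pct, "upper_pct": upper_pct},
    )
    return out, report


# -- long-format CSV round-trip --------------------------------------------
def profiles_to_frame(profiles: list[TemporalProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        days = p.days if p.trait_name == "PH" else p.days[:-1]
        for d, v in zip(days, p.values):
            rows.append((p.plot_id, p.background, int(d), p.trait_name, float(v)))
    return pd.DataFrame(rows, columns=["plot_id", "background", "das", "trait", "value"])


def frame_to_profiles(df: pd.DataFrame, trait: str, full_days: tuple[int, ...] | None = None
                      ) -> list[TemporalProfile]:
    sub = df[df["trait"] == trait]
    profiles = []
    for pid, grp in sub.groupby("plot_id", sort=True):
        grp = grp.sort_values("das")
        days = tuple(int(d) for d in grp["das"])
        if trait != "PH":
            if full_days is None:
                # interval-indexed traits store start days; append a sentinel
                # final day one past the last start to satisfy the contract
                days = days + (days[-1] + 1,)
            else:
                days = tuple(full_days)
        profiles.append(TemporalProfile(
            plot_id=str(pid),
            background=str(grp["background"].iloc[0]),
            days=days,
            values=grp["value"].to_numpy(float),
            trait_name=trait,
        ))
    return profiles
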