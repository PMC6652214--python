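"""Cluster x genetic-background intersections and dominance detection.

After hard-assigning each profile to its maximum-membership cluster, the
cluster x background count matrix yields two ratios per cell:

* ClusterProportion = NG_incluster / NC_total — the share of the cluster
  made of one background;
* TotalProportion  = NG_incluster / NG_total — the share of that
  background falling in the cluster.

A background dominates a cluster iff ClusterProportion >= 1/3 and
TotalProportion >= 2/3 (both non-strict).  A cluster's typical temporal
profile is its centroid polyline, annotated with the dominant background
when one exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcm import FCMResults

__all__ = ["IntersectionTable", "TypicalProfile", "hard_assign", "intersections",
           "dominant_background", "typical_profiles",
           "CLUSTER_PROPORTION_THRESHOLD", "TOTAL_PROPORTION_THRESHOLD"]

CLUSTER_PROPORTION_THRESHOLD = 1 / 3
TOTAL_PROPORTION_THRESHOLD = 2 / 3


def hard_assign(partition: FCMResults, plot_ids: list[str] | None = None
                ) -> tuple[dict, dict]:
    """Assign each profile to its maximum-membership cluster.

    Returns (assignments, tie_flags) keyed by plot id (or integer position
    when ids are not given).  Ties go to the lowest cluster index.
    """
    labels, ties = partition.hard_labels()
    keys = plot_ids if plot_ids is not None else list(range(len(labels)))
    if len(keys) != len(labels):
        raise ValueError("plot_ids length must match partition size")
    return dict(zip(keys, labels.tolist())), dict(zip(keys, ties.tolist()))


@dataclass
class IntersectionTable:
    """Cluster x background counts with derived proportions."""

    counts: pd.DataFrame          # index cluster, columns background

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)

    @property
    def nc_total(self) -> pd.Series:
        """Sample size of each cluster."""
        return self.counts.sum(axis=1)

    @property
    def ng_total(self) -> pd.Series:
        """Total sample size of each genetic background."""
        return self.counts.sum(axis=0)

    @property
    def cluster_proportion(self) -> pd.DataFrame:
        """NG_incluster / NC_total; NaN for empty clusters."""
        denom = self.nc_total.replace(0, np.nan)
        return self.counts.div(denom, axis=0)

    @property
    def total_proportion(self) -> pd.DataFrame:
        """NG_incluster / NG_total; NaN for absent backgrounds."""
        denom = self.ng_total.replace(0, np.nan)
        return self.counts.div(denom, axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with counts and both proportions per cell."""
        cp = self.cluster_proportion
        tp = self.total_proportion
        rows = []
        for cl in self.counts.index:
            for bg in self.counts.columns:
                rows.append({
                    "cluster": cl, "background": bg,
                    "ng_incluster": int(self.counts.loc[cl, bg]),
                    "nc_total": int(self.nc_total[cl]),
                    "ng_total": int(self.ng_total[bg]),
                    "cluster_proportion": cp.loc[cl, bg],
                    "total_proportion": tp.loc[cl, bg],
                })
        return pd.DataFrame(rows)

    def to_upset_frame(self, assignments: dict, backgrounds: dict) -> pd.DataFrame:
        """Per-profile set-membership indicators (UpSet-style long format)."""
        clusters = sorted(set(assignments.values()))
        rows = []
        for pid, cl in assignments.items():
            row = {"plot_id": pid, "background": backgrounds[pid]}
            for c in clusters:
                row[f"cluster_{c}"] = int(cl == c)
            rows.append(row)
        return pd.DataFrame(rows)


def intersections(assignments: dict, backgrounds: dict) -> IntersectionTable:
    """Tabulate profile counts per (cluster, background)."""
    if set(assignments) != set(backgrounds):
        raise ValueError("assignments and backgrounds must cover the same plots")
    df = pd.DataFrame({
        "cluster": [assignments[k] for k in assignments],
        "background": [backgrounds[k] for k in assignments],
    })
    counts = df.groupby(["cluster", "background"]).size().unstack(fill_value=0)
    return IntersectionTable(counts)


def dominant_background(table: IntersectionTable,
                        cluster_threshold: float = CLUSTER_PROPORTION_THRESHOLD,
                        total_threshold: float = TOTAL_PROPORTION_THRESHOLD
                        ) -> dict:
    """Per-cluster dominant background, or None.

    A background qualifies iff its ClusterProportion >= cluster_threshold
    AND its TotalProportion >= total_threshold (non-strict inequalities).
    If several qualify in one cluster, the highest ClusterProportion wins
    and all qualifiers are reported.
    """
    cp = table.cluster_proportion
    tp = table.total_proportion
    out = {}
    for cl in table.counts.index:
        qual = [bg for bg in table.counts.columns
                if cp.loc[cl, bg] >= cluster_threshold and tp.loc[cl, bg] >= total_threshold]
        if not qual:
            out[cl] = {"dominant": None, "qualifiers": []}
        else:
            best = max(qual, key=lambda bg: cp.loc[cl, bg])
            out[cl] = {"dominant": best, "qualifiers": qual,
                       "cluster_proportion": float(cp.loc[cl, best]),
                       "total_proportion": float(tp.loc[cl, best])}
    return out


@dataclass
class TypicalProfile:
    """A cluster's centroid polyline over the trait's time axis."""

    cluster_id: int
    days: tuple[int, ...]
    centroid: np.ndarray
    dominant_background: str | None = None
    trait_name: str = "PH"


def typical_profiles(partition: FCMResults, dominance: dict,
                     days: tuple[int, ...], trait_name: str = "PH"
                     ) -> list[TypicalProfile]:
    """One centroid polyline per cluster, annotated with its dominant
    background when one exists."""
    out = []
    for i, centroid in enumerate(partition.centroids):
        if len(centroid) != len(days):
            raise ValueError(
                f"centroid length {len(centroid)} does not match {len(days)} time points")
        dom = dominance.get(i, {}).get("dominant")
        out.append(TypicalProfile(cluster_id=i, days=tuple(days),
                                  centroid=np.asarray(centroid, float),
                                  dominant_background=dom, trait_name=trait_name))
    return out
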