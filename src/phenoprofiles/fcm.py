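"""Fuzzy c-means clustering with validity-index model selection.

The fuzzy c-means (FCM) model partitions N profiles x_j in R^D into C
clusters softly: memberships u_ij in [0, 1] with sum_i u_ij = 1, fuzzifier
m > 1 (m = 2 by default), Euclidean distance.  Fitting alternates

    v_i = sum_j u_ij^m x_j / sum_j u_ij^m          (centroids)
    u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1))       (memberships)

which monotonically decreases the objective J = sum_ij u_ij^m d_ij^2.

Six cluster-validity indices drive the choice of C:

* PC  (partition coefficient, maximize): mean squared membership; 1 for a
  crisp partition, 1/C when no cluster structure exists.
* PE  (partition entropy, minimize): mean membership entropy in [0, ln C].
* XB  (Xie-Beni, minimize): fuzzy within-cluster scatter over N times the
  minimum squared centroid separation.
* FS  (Fukuyama-Sugeno, minimize): fuzzy scatter penalized by centroid
  spread around the data grand mean.
* FHV (fuzzy hypervolume, minimize): sum of sqrt(det) of the fuzzy
  cluster covariances.
* PD  (partition density, maximize): summed central memberships over FHV.

Each index proposes a C over a scan range (2-15 by default); the final C
is chosen by an unweighted majority vote with a 50% threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = ["FuzzyCMeans", "FCMResults", "validity_indices", "scan_cluster_sizes",
           "ClusterScanResults", "majority_rule", "MajorityResult",
           "MINIMIZED_INDICES", "MAXIMIZED_INDICES"]

MINIMIZED_INDICES = ("PE", "XB", "FS", "FHV")
MAXIMIZED_INDICES = ("PC", "PD")
INDEX_ORDER = ("PC", "PE", "XB", "FS", "FHV", "PD")


class FuzzyCMeans:
    """Fuzzy c-means model for an (N, D) data matrix.

    Parameters
    ----------
    data : array-like (N, D)
        One row per profile (plot), one column per time point / interval.
    n_clusters : int
        Number of clusters C, at least 2 and below N.
    m : float
        Fuzzifier, > 1; 2 is the conventional default.
    """

    def __init__(self, data: np.ndarray, n_clusters: int, m: float = 2.0):
        self.data = np.atleast_2d(np.asarray(data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (N, D)")
        n = len(self.data)
        if not 2 <= n_clusters < n:
            raise ValueError(f"need N > C >= 2, got N={n}, C={n_clusters}")
        if m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        self.n_clusters = int(n_clusters)
        self.m = float(m)

    # -- fitting ------------------------------------------------------------
    def fit(self, seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
            n_restarts: int = 5) -> "FCMResults":
        """Fit by alternating minimization; best of ``n_restarts`` seeded
        random initializations by final objective."""
        best: FCMResults | None = None
        rng = np.random.default_rng(seed)
        for _ in range(max(1, n_restarts)):
            res = self._fit_once(rng, max_iter, tol)
            if best is None or res.objective < best.objective:
                best = res
        best.seed = seed
        return best

    def _fit_once(self, rng: np.random.Generator, max_iter: int, tol: float) -> "FCMResults":
        x = self.data
        n, _ = x.shape
        c, m = self.n_clusters, self.m
        u = rng.dirichlet(np.ones(c), size=n)          # (N, C), rows sum to 1
        history: list[float] = []
        n_iter = 0
        centroids = np.tile(x.mean(axis=0), (c, 1))
        for n_iter in range(1, max_iter + 1):
            centroids = _centroids(x, u, m, centroids)
            d2 = _sq_distances(x, centroids)
            u_new = _memberships(d2, m)
            history.append(float(np.sum(u_new**m * d2)))
            if np.max(np.abs(u_new - u)) < tol:
                u = u_new
                break
            u = u_new
        centroids = _centroids(x, u, m, centroids)
        if c > 1 and np.allclose(x, x[0]):
            warnings.warn("all data points identical: centroids coincide")
        return FCMResults(model=self, memberships=u, centroids=centroids,
                          objective=history[-1], n_iterations=n_iter,
                          objective_history=np.array(history))


@dataclass
class FCMResults:
    """Fitted fuzzy partition: memberships, centroids, objective."""

    model: FuzzyCMeans
    memberships: np.ndarray        # (N, C)
    centroids: np.ndarray          # (C, D)
    objective: float
    n_iterations: int
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return self.model.n_clusters

    @property
    def fuzzifier_m(self) -> float:
        return self.model.m

    def hard_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Maximum-membership assignment; ties go to the lowest cluster
        index and are flagged."""
        u = self.memberships
        labels = np.argmax(u, axis=1)
        rowmax = u[np.arange(len(u)), labels]
        ties = np.sum(np.isclose(u, rowmax[:, None], rtol=0, atol=1e-12), axis=1) > 1
        return labels, ties

    def validity_indices(self) -> dict[str, float]:
        return validity_indices(self.memberships, self.centroids,
                                self.model.data, self.model.m)

    def summary(self) -> str:
        idx = self.validity_indices()
        lines = [
            "Fuzzy c-means results",
            "=" * 44,
            f"N profiles        {len(self.model.data):>10d}",
            f"Dimensions        {self.model.data.shape[1]:>10d}",
            f"Clusters (C)      {self.n_clusters:>10d}",
            f"Fuzzifier (m)     {self.fuzzifier_m:>10.2f}",
            f"Iterations        {self.n_iterations:>10d}",
            f"Objective         {self.objective:>10.4g}",
            "-" * 44,
            "Validity indices",
        ] + [f"  {k:<5s} {v:>12.5g}" for k, v in idx.items()] + [
            "-" * 44,
            "Centroids",
        ] + [
            "  " + "  ".join(f"{v:9.3f}" for v in row) for row in self.centroids
        ]
        return "\n".join(lines)


def _centroids(x: np.ndarray, u: np.ndarray, m: float,
               previous: np.ndarray) -> np.ndarray:
    """u^m-weighted means; a cluster with vanishing total weight keeps its
    previous centroid instead of dividing by zero."""
    um = u**m
    wsum = um.sum(axis=0)
    alive = wsum > 1e-300
    out = previous.copy()
    out[alive] = (um[:, alive].T @ x) / wsum[alive, None]
    return out


def _sq_distances(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - centroids[None, :, :]
    return np.sum(diff**2, axis=2)


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """u_ij = 1 / sum_k (d_ij/d_kj)^(2/(m-1)); a point coinciding with one
    or more centroids splits its membership equally among them."""
    power = 1.0 / (m - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-power)                       # inf where d2 == 0
    zero = d2 <= 0
    any_zero = zero.any(axis=1)
    u = np.empty_like(d2)
    ok = ~any_zero
    u[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return u


# -- validity indices ------------------------------------------------------
def validity_indices(memberships: np.ndarray, centroids: np.ndarray,
                     data: np.ndarray, m: float = 2.0) -> dict[str, float]:
    """Compute PC, PE, XB, FS, FHV and PD for one fuzzy partition.

    Singular fuzzy covariances are regularized (with a warning) by an
    eigenvalue floor before the determinant / inverse.
    """
    u = np.asarray(memberships, float)
    v = np.atleast_2d(np.asarray(centroids, float))
    x = np.atleast_2d(np.asarray(data, float))
    n, c = u.shape
    um = u**m
    d2 = _sq_distances(x, v)

    pc = float(np.sum(u**2) / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        logu = np.where(u > 0, np.log(u), 0.0)
    pe = float(-np.sum(u * logu) / n)

    sep = _sq_distances(v, v)
    np.fill_diagonal(sep, np.inf)
    min_sep = float(sep.min())
    xb = float(np.sum(um * d2) / (n * min_sep)) if np.isfinite(min_sep) and min_sep > 0 else float("inf")

    grand = x.mean(axis=0)
    v_spread = np.sum((v - grand) ** 2, axis=1)        # (C,)
    fs = float(np.sum(um * (d2 - v_spread[None, :])))

    fhv = 0.0
    s_central = 0.0
    dim = x.shape[1]
    for i in range(c):
        w = um[:, i]
        wsum = w.sum()
        diff = x - v[i]
        cov = (diff * w[:, None]).T @ diff / max(wsum, 1e-300)
        eigvals, eigvecs = np.linalg.eigh(cov)
        floor = 1e-12 * max(float(np.trace(cov)), 1e-12)
        if np.any(eigvals <= floor):
            warnings.warn(f"singular fuzzy covariance in cluster {i}; regularized")
            eigvals = np.maximum(eigvals, floor)
        fhv_i = float(np.sqrt(np.prod(eigvals)))
        fhv += fhv_i
        inv = (eigvecs / eigvals[None, :]) @ eigvecs.T
        maha = np.einsum("nd,de,ne->n", diff, inv, diff)
        s_central += float(u[maha < 1.0, i].sum())
    pd_idx = s_central / fhv if fhv > 0 else float("inf")

    return {"PC": pc, "PE": pe, "XB": xb, "FS": fs, "FHV": fhv, "PD": pd_idx}


# -- model selection -------------------------------------------------------
class MajorityResult(NamedTuple):
    selected_c: int
    has_majority: bool
    votes: dict


def majority_rule(proposals: dict[str, int], threshold: float = 0.5) -> MajorityResult:
    """Unweighted vote over per-index cluster-size proposals.

    The C proposed by strictly more than ``threshold`` of the indices wins.
    Without a majority, the smallest C among the plurality winners is
    returned with ``has_majority=False``.
    """
    if not proposals:
        raise ValueError("no proposals to vote on")
    votes: dict[int, int] = {}
    for c in proposals.values():
        votes[c] = votes.get(c, 0) + 1
    n = len(proposals)
    top = max(votes.values())
    winners = sorted(c for c, k in votes.items() if k == top)
    has_majority = top > threshold * n
    return MajorityResult(selected_c=winners[0], has_majority=has_majority, votes=votes)


@dataclass
class ClusterScanResults:
    """Validity indices over a scan of candidate cluster sizes."""

    table: pd.DataFrame                  # index C, columns PC..PD
    proposals: dict[str, int]
    selection: MajorityResult
    fits: dict[int, FCMResults]

    @property
    def selected_c(self) -> int:
        return self.selection.selected_c

    def best_fit(self) -> FCMResults:
        return self.fits[self.selected_c]

    def summary(self) -> str:
        lines = ["Cluster-size scan", "=" * 60, self.table.round(5).to_string(), "-" * 60]
        lines.append("Proposed C per index: "
                     + ", ".join(f"{k}={v}" for k, v in self.proposals.items()))
        flag = "" if self.selection.has_majority else "  (no majority; smallest plurality)"
        lines.append(f"Majority-rule selection: C = {self.selected_c}{flag}")
        return "\n".join(lines)


def scan_cluster_sizes(data: np.ndarray, c_range: Iterable[int] = range(2, 16),
                       m: float = 2.0, seed: int = 0, max_iter: int = 500,
                       tol: float = 1e-6, n_restarts: int = 5,
                       standardize: bool = False) -> ClusterScanResults:
    """Fit FCM for every C in ``c_range`` and vote on the cluster size.

    Minimized indices (PE, XB, FS, FHV) propose their arg-min C; maximized
    indices (PC, PD) their arg-max.  ``standardize`` z-scores each column
    first (off by default: a trait's coordinates share units).
    """
    data = np.atleast_2d(np.asarray(data, float))
    if standardize:
        sd = data.std(axis=0)
        data = (data - data.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    cs = sorted(set(int(c) for c in c_range))
    if not cs:
        raise ValueError("empty scan range")
    if len(data) <= max(cs):
        raise ValueError(f"N={len(data)} must exceed the largest C={max(cs)}")
    rows, fits = [], {}
    for k, c in enumerate(cs):
        res = FuzzyCMeans(data, c, m=m).fit(seed=seed + k, max_iter=max_iter,
                                            tol=tol, n_restarts=n_restarts)
        fits[c] = res
        rows.append(res.validity_indices())
    table = pd.DataFrame(rows, index=pd.Index(cs, name="C"))[list(INDEX_ORDER)]
    proposals = {}
    for name in INDEX_ORDER:
        col = table[name]
        proposals[name] = int(col.idxmin() if name in MINIMIZED_INDICES else col.idxmax())
    selection = majority_rule(proposals)
    return ClusterScanResults(table=table, proposals=proposals,
                              selection=selection, fits=fits)
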