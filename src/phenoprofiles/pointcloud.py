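"""Point clouds with optional ground / non-ground labels."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PointCloud", "GROUND", "NON_GROUND", "UNCLASSIFIED"]

UNCLASSIFIED = 0
GROUND = 1
NON_GROUND = 2

_LABEL_NAMES = {UNCLASSIFIED: "unclassified", GROUND: "ground", NON_GROUND: "non-ground"}


@dataclass
class PointCloud:
    """A set of 3-D points (meters) with optional per-point class labels.

    ``labels`` uses the integer codes UNCLASSIFIED (0), GROUND (1),
    NON_GROUND (2).  When absent all points are unclassified.
    """

    xyz: np.ndarray                     # (n, 3) float
    labels: np.ndarray | None = None    # (n,) int or None

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.xyz),):
                raise ValueError("labels must cover all points")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def ground(self) -> "PointCloud":
        """Subset of points labeled ground."""
        if self.labels is None:
            raise ValueError("point cloud is unclassified")
        keep = self.labels == GROUND
        return PointCloud(self.xyz[keep], self.labels[keep])

    # -- I/O: whitespace-separated ``x y z [class]`` text -------------------
    def to_xyz(self, path: str | Path) -> None:
        if self.labels is None:
            np.savetxt(path, self.xyz, fmt="%.6f")
        else:
            data = np.column_stack([self.xyz, self.labels.astype(float)])
            np.savetxt(path, data, fmt=["%.6f", "%.6f", "%.6f", "%d"])

    @classmethod
    def from_xyz(cls, path: str | Path) -> "PointCloud":
        data = np.loadtxt(path, ndmin=2)
        if data.shape[1] == 4:
            return cls(data[:, :3], data[:, 3].astype(int))
        if data.shape[1] == 3:
            return cls(data)
        raise ValueError(f"{path}: expected 3 or 4 columns, got {data.shape[1]}")

    def label_counts(self) -> dict[str, int]:
        if self.labels is None:
            return {"unclassified": len(self)}
        return {
            _LABEL_NAMES[k]: int(np.sum(self.labels == k))
            for k in (GROUND, NON_GROUND, UNCLASSIFIED)
            if np.any(self.labels == k)
        }
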