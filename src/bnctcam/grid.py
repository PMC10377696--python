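"""Reconstruction voxel grid, 3-D image container, and the 8-field image CSV.

The default grid is the 100^3 cube over [-60, 60] mm per axis (1.2 mm cubic
voxels) used by all reconstructions. Images are exchanged as CSV with exactly
eight comma-separated fields per voxel row:

    intensity, x, y, z, i, j, k, source

where (x, y, z) is the voxel center in mm, (i, j, k) the 0-based indices and
``source`` a binary ground-truth flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CsvParseError

_IMAGE_COLUMNS = ["intensity", "x", "y", "z", "i", "j", "k", "source"]


@dataclass(frozen=True)
class VoxelGrid:
    """Cubic voxel grid: ``n_per_axis`` voxels per axis over [lower, upper] mm.

    Voxel centers sit at ``lower + (k + 0.5) * voxel_side``; indices are
    0-based (i, j, k) for (x, y, z).
    """

    n_per_axis: int = 100
    lower: float = -60.0
    upper: float = 60.0

    def __post_init__(self):
        if self.n_per_axis < 1:
            raise ValueError("n_per_axis must be >= 1")
        if not self.upper > self.lower:
            raise ValueError("upper bound must exceed lower bound")

    @property
    def voxel_side(self) -> float:
        return (self.upper - self.lower) / self.n_per_axis

    @property
    def shape(self):
        n = self.n_per_axis
        return (n, n, n)

    @property
    def n_voxels(self) -> int:
        return self.n_per_axis**3

    def centers(self) -> np.ndarray:
        """1-D array of voxel-center coordinates along one axis."""
        k = np.arange(self.n_per_axis)
        return self.lower + (k + 0.5) * self.voxel_side

    def flat_centers(self) -> np.ndarray:
        """(n^3, 3) voxel centers, C order (i outer, k inner)."""
        c = self.centers()
        X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def index_of(self, coord: float) -> int:
        """Index of the voxel containing ``coord`` along one axis (clipped to
        the grid, so the upper bound maps to the last voxel)."""
        if coord < self.lower or coord > self.upper:
            raise ValueError(f"coordinate {coord} outside [{self.lower}, {self.upper}]")
        i = int((coord - self.lower) / self.voxel_side)
        return min(max(i, 0), self.n_per_axis - 1)

    @property
    def origin_index(self) -> int:
        """Index of the voxel containing the coordinate origin."""
        return self.index_of(0.0)


@dataclass
class Image3D:
    """Non-negative intensity on a :class:`VoxelGrid`, with an optional
    binary truth mask of the same shape."""

    grid: VoxelGrid
    intensity: np.ndarray
    truth_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.grid.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} != grid {self.grid.shape}")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask).astype(bool)
            if self.truth_mask.shape != self.grid.shape:
                raise ValueError("truth mask shape mismatch")

    @classmethod
    def zeros(cls, grid: VoxelGrid, truth_mask=None) -> "Image3D":
        return cls(grid, np.zeros(grid.shape), truth_mask)

    def normalized(self) -> "Image3D":
        """Copy with maximum intensity scaled to 1 (all-zero images are
        returned unchanged)."""
        m = self.intensity.max()
        arr = self.intensity / m if m > 0 else self.intensity.copy()
        return Image3D(self.grid, arr, self.truth_mask)

    @property
    def max_voxel_index(self):
        return np.unravel_index(int(np.argmax(self.intensity)), self.grid.shape)


def write_image_csv(path, image: Image3D) -> None:
    """Write the 8-field image CSV (one row per voxel, C index order)."""
    grid = image.grid
    n = grid.n_per_axis
    idx = np.indices((n, n, n)).reshape(3, -1)
    centers = grid.centers()
    src = (image.truth_mask.astype(int).ravel()
           if image.truth_mask is not None else np.zeros(n**3, dtype=int))
    df = pd.DataFrame({
        "intensity": image.intensity.ravel(),
        "x": centers[idx[0]],
        "y": centers[idx[1]],
        "z": centers[idx[2]],
        "i": idx[0],
        "j": idx[1],
        "k": idx[2],
        "source": src,
    })
    df.to_csv(path, index=False)


def read_image_csv(path, grid: Optional[VoxelGrid] = None) -> Image3D:
    """Read an 8-field image CSV back into an :class:`Image3D`.

    The grid is inferred from the index/position columns unless supplied.
    Raises :class:`CsvParseError` on a wrong field count and a validation
    error if the source flag is not binary.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise CsvParseError(f"malformed image CSV: {exc}") from None
    if list(df.columns) != _IMAGE_COLUMNS:
        raise CsvParseError(
            f"expected columns {_IMAGE_COLUMNS}, got {list(df.columns)}")
    if not df["source"].isin([0, 1]).all():
        raise ValueError("source field must be 0 or 1")
    i = df["i"].to_numpy(dtype=int)
    j = df["j"].to_numpy(dtype=int)
    k = df["k"].to_numpy(dtype=int)
    if grid is None:
        n = int(max(i.max(), j.max(), k.max())) + 1
        if len(df) != n**3:
            raise CsvParseError(
                f"expected {n**3} rows for a {n}^3 grid, got {len(df)}")
        x = df["x"].to_numpy()
        if n > 1:
            side = (x.max() - x.min()) / (n - 1)
        else:
            side = 1.0
        lower = float(x.min() - side / 2.0)
        grid = VoxelGrid(n, lower, lower + n * side)
    n = grid.n_per_axis
    arr = np.zeros(grid.shape)
    arr[i, j, k] = df["intensity"].to_numpy()
    mask = np.zeros(grid.shape, dtype=bool)
    mask[i, j, k] = df["source"].to_numpy() == 1
    return Image3D(grid, arr, truth_mask=mask if mask.any() else mask)
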