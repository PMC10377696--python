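"""List-mode MLEM tomographic reconstruction.

The multiplicative update per voxel j and iteration n is

    lambda_j^(n+1) = lambda_j^(n) / s_j * sum_i t_ij / (sum_k t_ik lambda_k^(n))

over the M measured events i. The system matrix element t_ij is a Gaussian
kernel in the angular residual between voxel j and event i's Compton cone
(optionally damped by the inverse squared apex distance); s_j is the
sensitivity (uniform by default, or the solid angle of the scatter layer).

The matrix is assembled once as CSR (rows = events) and iterations run in a
fused forward/back-projection numba kernel, so a reconstruction of a few
thousand events on the 100^3 grid stays desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import _kernels
from .backprojection import (DEFAULT_ANGULAR_SIGMA, DEFAULT_CUTOFF_SIGMAS,
                             cone_from_event, cones_from_events)
from .errors import DegenerateImageError, EmptyInputError
from .events import ComptonEvent, EventList
from .geometry import DetectorGeometry
from .grid import Image3D, VoxelGrid

#: forward projections below this contribute nothing (0/0 guard)
DENOMINATOR_GUARD = 1e-30


@dataclass(frozen=True)
class SystemModel:
    """Parameters of the system matrix t_ij and sensitivity s_j."""

    angular_sigma: float = DEFAULT_ANGULAR_SIGMA
    distance_weighting: bool = False
    sensitivity_mode: str = "uniform"
    cutoff_sigmas: float = DEFAULT_CUTOFF_SIGMAS

    def __post_init__(self):
        if not self.angular_sigma > 0:
            raise ValueError("angular_sigma must be positive")
        if self.sensitivity_mode not in ("uniform", "solid_angle"):
            raise ValueError(f"unknown sensitivity mode {self.sensitivity_mode!r}")


@dataclass
class SensitivityMap:
    """Per-voxel detection probability s_j (> 0 everywhere)."""

    grid: VoxelGrid
    s: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != self.grid.shape:
            raise ValueError("sensitivity shape mismatch")
        if np.any(self.s <= 0):
            raise ValueError("sensitivity must be strictly positive")


def _rect_solid_angle(px, py, h, x1, x2, y1, y2):
    """Solid angle of the rectangle [x1,x2]x[y1,y2] in a plane at distance h
    (> 0) from points (px, py) projected onto that plane."""
    def corner(x, y):
        return np.arctan2(x * y, h * np.sqrt(x * x + y * y + h * h))
    return (corner(x2 - px, y2 - py) - corner(x1 - px, y2 - py)
            - corner(x2 - px, y1 - py) + corner(x1 - px, y1 - py))


def sensitivity_map(grid: VoxelGrid, detector: Optional[DetectorGeometry] = None,
                    model: Optional[SystemModel] = None) -> SensitivityMap:
    """Sensitivity s_j on the grid.

    ``uniform`` mode: s_j = 1 everywhere. ``solid_angle`` mode: s_j is
    proportional to the solid angle of the layer-1 front face seen from the
    voxel center, normalized to max 1; voxels at (or beyond) the detector
    plane are clamped to the maximum finite value.
    """
    model = model or SystemModel()
    if model.sensitivity_mode == "uniform":
        return SensitivityMap(grid, np.ones(grid.shape))
    if detector is None:
        raise ValueError("solid_angle sensitivity requires the detector geometry")
    lo, hi = detector.layer_bounds(1)
    centers = grid.flat_centers()
    h = lo[2] - centers[:, 2]
    valid = h > 1e-9
    omega = np.zeros(centers.shape[0])
    omega[valid] = _rect_solid_angle(centers[valid, 0], centers[valid, 1],
                                     h[valid], lo[0], hi[0], lo[1], hi[1])
    omega = np.abs(omega)
    if valid.any():
        omega[~valid] = omega[valid].max()
    else:
        omega[:] = 1.0
    omega /= omega.max()
    omega = np.maximum(omega, 1e-12)  # strict positivity for division safety
    return SensitivityMap(grid, omega.reshape(grid.shape))


def event_voxel_probability(event: ComptonEvent, voxel_center,
                            model: Optional[SystemModel] = None) -> float:
    """System-matrix element t_ij for one event and one voxel center.

    Gaussian in the angular residual between the voxel direction from the
    cone apex and the cone half-angle, optionally multiplied by the inverse
    squared apex distance; values below 1e-12 (and the apex voxel itself)
    return exactly 0.
    """
    model = model or SystemModel()
    cone = cone_from_event(event)
    d = np.asarray(voxel_center, dtype=float) - cone.apex
    dist2 = float(d @ d)
    if dist2 < 1e-16:
        return 0.0
    cosd = float(d @ cone.axis) / np.sqrt(dist2)
    delta = np.arccos(min(max(cosd, -1.0), 1.0)) - cone.half_angle
    w = float(np.exp(-delta * delta / (2.0 * model.angular_sigma**2)))
    if model.distance_weighting:
        w /= dist2
    return w if w >= _kernels.WEIGHT_FLOOR_DEFAULT else 0.0


@dataclass
class SystemMatrix:
    """CSR system matrix (rows = events, columns = voxels)."""

    data: np.ndarray
    indices: np.ndarray
    indptr: np.ndarray
    grid: VoxelGrid
    model: SystemModel
    n_events: int

    @property
    def nnz(self) -> int:
        return int(self.data.shape[0])

    def to_scipy(self):
        import scipy.sparse as sp

        return sp.csr_matrix((self.data, self.indices, self.indptr),
                             shape=(self.n_events, self.grid.n_voxels))


def build_system_matrix(events: EventList, grid: VoxelGrid,
                        model: Optional[SystemModel] = None,
                        method: str = "auto",
                        dtype=None) -> SystemMatrix:
    """Assemble t_ij for all events as CSR.

    ``method='sparse'`` enumerates the cone band per event (numba);
    ``'dense'`` evaluates every voxel per event (numpy) and is used
    automatically for small problems. Both apply the identical Gaussian
    cutoff (``model.cutoff_sigmas``) and 1e-12 weight floor. ``dtype``
    defaults to float64 for small problems and float32 for large ones
    (memory).
    """
    if len(events) == 0:
        raise EmptyInputError("cannot build a system matrix without events")
    model = model or SystemModel()
    apex, axis, theta = cones_from_events(events)
    m = len(events)
    small = m * grid.n_voxels <= 3_000_000
    if method == "auto":
        method = "dense" if small else "sparse"
    if dtype is None:
        dtype = np.float64 if small else np.float32

    if method == "dense":
        centers = grid.flat_centers()
        rows_idx, rows_w = [], []
        half = model.cutoff_sigmas * model.angular_sigma
        inv2s2 = 1.0 / (2.0 * model.angular_sigma**2)
        for i in range(m):
            d = centers - apex[i]
            dist2 = np.einsum("ij,ij->i", d, d)
            ok = dist2 >= 1e-16
            cosd = np.where(ok, (d @ axis[i]) / np.sqrt(np.maximum(dist2, 1e-16)), 2.0)
            delta = np.where(ok, np.arccos(np.clip(cosd, -1, 1)) - theta[i], np.inf)
            w = np.exp(-np.minimum(delta * delta, 700.0 / inv2s2) * inv2s2)
            if model.distance_weighting:
                w = w / np.maximum(dist2, 1e-16)
            keep = ok & (np.abs(delta) <= half) & (w >= _kernels.WEIGHT_FLOOR_DEFAULT)
            rows_idx.append(np.flatnonzero(keep).astype(np.int64))
            rows_w.append(w[keep])
        counts = np.array([r.shape[0] for r in rows_idx], dtype=np.int64)
        indptr = np.zeros(m + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        indices = (np.concatenate(rows_idx) if rows_idx else
                   np.zeros(0, np.int64)).astype(np.int32)
        data = np.concatenate(rows_w).astype(dtype)
        return SystemMatrix(data, indices, indptr, grid, model, m)

    # sparse path: two numba passes writing straight into the CSR arrays
    args = (apex, axis, theta, grid.n_per_axis, grid.lower, grid.voxel_side,
            float(model.angular_sigma), float(model.cutoff_sigmas),
            bool(model.distance_weighting), _kernels.WEIGHT_FLOOR_DEFAULT)
    counts = _kernels._count_rows(*args)
    indptr = np.zeros(m + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    nnz = int(indptr[-1])
    indices = np.empty(nnz, dtype=np.int32)
    data = np.empty(nnz, dtype=dtype)
    _kernels._fill_rows(*args, indptr, indices, data)
    return SystemMatrix(data, indices, indptr, grid, model, m)


@dataclass
class ReconstructionRun:
    """MLEM result: final image plus snapshots every ``snapshot_every``
    iterations (all max-normalized)."""

    final: Image3D
    image_history: Dict[int, Image3D] = field(default_factory=dict)
    n_iterations: int = 0
    model: Optional[SystemModel] = None


def mlem_reconstruct(events: EventList, grid: Optional[VoxelGrid] = None,
                     n_iter: int = 50, model: Optional[SystemModel] = None,
                     sensitivity: Optional[SensitivityMap] = None,
                     detector: Optional[DetectorGeometry] = None,
                     initial: Optional[Image3D] = None,
                     snapshot_every: int = 10,
                     system: Optional[SystemMatrix] = None,
                     normalized: bool = True) -> ReconstructionRun:
    """Run ``n_iter`` list-mode MLEM iterations.

    Starts from a uniform positive image unless ``initial`` is given. A
    prebuilt ``system`` matrix may be passed to amortize assembly across
    runs. Snapshots are stored every ``snapshot_every`` iterations. Output
    images are max-normalized unless ``normalized=False`` (raw iterates, as
    needed e.g. for likelihood monitoring).
    """
    if len(events) == 0:
        raise EmptyInputError("MLEM needs at least one event")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    model = model or SystemModel()
    if grid is None:
        grid = VoxelGrid()
    if system is None:
        system = build_system_matrix(events, grid, model)
    if sensitivity is None:
        if model.sensitivity_mode == "solid_angle":
            sensitivity = sensitivity_map(grid, detector, model)
        else:
            sensitivity = SensitivityMap(grid, np.ones(grid.shape))
    s_flat = sensitivity.s.ravel()

    if initial is not None:
        lam = initial.intensity.ravel().astype(np.float64).copy()
        if not np.all(lam > 0):
            raise ValueError("initial image must be strictly positive")
    else:
        lam = np.ones(grid.n_voxels, dtype=np.float64)

    def snap(arr):
        img = Image3D(grid, arr.reshape(grid.shape).copy())
        return img.normalized() if normalized else img

    history: Dict[int, Image3D] = {}
    for it in range(1, n_iter + 1):
        lam = _kernels._mlem_iteration(system.data, system.indices,
                                       system.indptr, lam, s_flat,
                                       DENOMINATOR_GUARD)
        if snapshot_every and (it % snapshot_every == 0) and it != n_iter:
            history[it] = snap(lam)
    final = snap(lam)
    history[n_iter] = final
    return ReconstructionRun(final=final, image_history=history,
                             n_iterations=n_iter, model=model)


def poisson_loglikelihood(system: SystemMatrix, image: np.ndarray,
                          sensitivity: Optional[np.ndarray] = None) -> float:
    """List-mode Poisson log-likelihood sum_i log(t_i . lam) - s . lam (up to
    a constant); MLEM is guaranteed not to decrease it."""
    lam = np.asarray(image, dtype=float).ravel()
    q = _kernels._forward_project(system.data, system.indices, system.indptr, lam)
    q = np.maximum(q, 1e-300)
    s = (np.ones_like(lam) if sensitivity is None
         else np.asarray(sensitivity, dtype=float).ravel())
    return float(np.sum(np.log(q)) - s @ lam)


def granularity_metric(image: Image3D, region: Optional[np.ndarray] = None) -> float:
    """Coefficient of variation of the intensity inside ``region`` of the
    central XY slice (a proxy for the speckle that develops at high
    iteration counts).

    ``region`` is a 2-D boolean mask over the slice; default: the truth
    mask's central slice, else the whole slice.
    """
    k = image.grid.origin_index
    sl = image.intensity[:, :, k]
    if region is None:
        region = (image.truth_mask[:, :, k] if image.truth_mask is not None
                  else np.ones_like(sl, dtype=bool))
    region = np.asarray(region, dtype=bool)
    if region.shape != sl.shape:
        raise ValueError("region mask shape mismatch")
    if not region.any():
        raise ValueError("empty region")
    vals = sl[region]
    mean = vals.mean()
    if mean == 0:
        raise DegenerateImageError("zero-mean region: granularity undefined")
    return float(vals.std() / mean)
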