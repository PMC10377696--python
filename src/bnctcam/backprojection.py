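"""Compton cones and cone back-projection.

Each true event defines a cone with apex at the layer-1 scatter position,
axis pointing from the layer-2 absorption hit back toward the scatter hit,
and half-angle from the Compton relation

    cos(theta) = 1 - m_e c^2 (1/E2 - 1/E_gamma),    E_gamma = E1 + E2.

The source lies on the cone surface. Back-projection accumulates, per event
and voxel, a Gaussian weight in the angular residual between the voxel
direction (seen from the apex) and the cone half-angle; the superposition
peak marks the most likely source position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import _kernels
from .errors import EmptyInputError, KinematicsError
from .events import ComptonEvent, EventList
from .geometry import M_E_C2
from .grid import Image3D, VoxelGrid, read_image_csv, write_image_csv  # noqa: F401

#: Default angular kernel width (radians); a tunable resolution knob.
DEFAULT_ANGULAR_SIGMA = np.deg2rad(2.0)

#: Gaussian band truncation for voxel enumeration, in units of sigma.
DEFAULT_CUTOFF_SIGMAS = 3.0


@dataclass(frozen=True)
class ComptonCone:
    """Event cone: apex (mm), unit axis (from absorber hit toward scatter
    hit), half-angle (radians)."""

    apex: np.ndarray
    axis: np.ndarray
    half_angle: float


def compton_cos_theta(e2: float, gamma_energy: float) -> float:
    """cos(theta) of the Compton scattering angle from the absorbed energy."""
    return 1.0 - M_E_C2 * (1.0 / e2 - 1.0 / gamma_energy)


def cone_from_event(event: ComptonEvent,
                    gamma_energy: float | None = None) -> ComptonCone:
    """Build the Compton cone of one event.

    Raises :class:`KinematicsError` when the energy split implies
    |cos(theta)| > 1 (corrupt input beyond the backscatter limit
    ``E2 >= E_gamma / (1 + 2 E_gamma / m_e c^2)``).
    """
    if gamma_energy is None:
        gamma_energy = event.e1 + event.e2
    if not event.e2 > 0:
        raise ValueError("absorbed energy e2 must be positive")
    if abs(event.e1 + event.e2 - gamma_energy) > 1e-6 * gamma_energy:
        raise ValueError("e1 + e2 inconsistent with the photon energy")
    c = compton_cos_theta(event.e2, gamma_energy)
    if c > 1.0 + 1e-12 or c < -1.0 - 1e-12:
        raise KinematicsError(
            f"energy split (e1={event.e1}, e2={event.e2}) gives cos(theta)={c:.6f}")
    c = min(max(c, -1.0), 1.0)
    r1 = np.asarray(event.r1, dtype=float)
    r2 = np.asarray(event.r2, dtype=float)
    axis = r1 - r2
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("degenerate event: r1 == r2")
    return ComptonCone(apex=r1, axis=axis / norm, half_angle=float(np.arccos(c)))


def cones_from_events(events: EventList):
    """Vectorized cone parameters: (apex (M,3), axis (M,3), theta (M,))."""
    e2 = events.e2
    if np.any(e2 <= 0):
        raise ValueError("absorbed energies must be positive")
    c = 1.0 - M_E_C2 * (1.0 / e2 - 1.0 / events.gamma_energy)
    if np.any(c > 1.0 + 1e-12) or np.any(c < -1.0 - 1e-12):
        raise KinematicsError("event list contains kinematically forbidden events")
    theta = np.arccos(np.clip(c, -1.0, 1.0))
    axis = events.r1 - events.r2
    axis = axis / np.linalg.norm(axis, axis=1, keepdims=True)
    return np.ascontiguousarray(events.r1), np.ascontiguousarray(axis), theta


def backproject_events(events: EventList, grid: Union[VoxelGrid, None] = None,
                       angular_sigma: float = DEFAULT_ANGULAR_SIGMA,
                       cutoff_sigmas: float = DEFAULT_CUTOFF_SIGMAS,
                       distance_weighting: bool = False,
                       normalize: bool = True) -> Image3D:
    """Accumulate the Gaussian cone weights of all events onto the grid.

    Per event, a voxel at angular residual ``delta`` from the cone surface
    receives ``exp(-delta^2 / (2 angular_sigma^2))``; the result is
    max-normalized (when ``normalize``).
    """
    if len(events) == 0:
        raise EmptyInputError("cannot back-project an empty event list")
    if not angular_sigma > 0:
        raise ValueError("angular_sigma must be positive")
    if grid is None:
        grid = VoxelGrid()
    apex, axis, theta = cones_from_events(events)
    img = np.zeros(grid.n_voxels, dtype=np.float64)
    _kernels._accumulate_cones(
        apex, axis, theta, grid.n_per_axis, grid.lower, grid.voxel_side,
        float(angular_sigma), float(cutoff_sigmas), bool(distance_weighting),
        _kernels.WEIGHT_FLOOR_DEFAULT, img)
    image = Image3D(grid, img.reshape(grid.shape))
    return image.normalized() if normalize else image
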