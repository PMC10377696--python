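"""Slice extraction, 1-D axis profiles, Gaussian fits, and the Z-stretching
study.

Reconstructed Compton images elongate along the detector axis (Z); the
elongation grows with the source-detector distance because the detector's
angular aperture shrinks. Fitting the Z profile with a Gaussian and tracking
its sigma against distance quantifies the effect (and, inverted, offers a
handle on the source depth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateImageError, FitError
from .geometry import SimulationConfig
from .grid import Image3D, VoxelGrid
from .events import generate_true_events
from .mlem import SystemModel, mlem_reconstruct

_AXES = {"x": 0, "y": 1, "z": 2, "X": 0, "Y": 1, "Z": 2}
_PLANES = {"XY": 2, "XZ": 1, "xy": 2, "xz": 1}


@dataclass
class AxisProfile:
    """Normalized 1-D intensity along a grid line through the origin."""

    axis: str
    positions: np.ndarray
    values: np.ndarray


@dataclass
class GaussianFit:
    """Parameters of A*exp(-(x-mu)^2/(2 sigma^2)) + c fitted to a profile."""

    amplitude: float
    mean: float
    sigma: float
    offset: float
    rmse: float


def extract_slice(image: Image3D, plane: str, coord: float = 0.0) -> np.ndarray:
    """2-D max-normalized slice of the image nearest the fixed coordinate.

    ``plane='XY'`` fixes z; ``'XZ'`` fixes y. ``coord`` must lie within the
    grid bounds (the upper bound maps to the last slice).
    """
    if plane not in _PLANES:
        raise ValueError(f"unknown plane {plane!r} (use 'XY' or 'XZ')")
    fixed_axis = _PLANES[plane]
    k = image.grid.index_of(coord)  # raises on out-of-range coordinates
    sl = np.take(image.intensity, k, axis=fixed_axis)
    m = sl.max()
    return sl / m if m > 0 else sl.copy()


def axis_profile(image: Image3D, axis: str, mode: str = "line") -> AxisProfile:
    """Intensity profile along the line through the origin parallel to the
    given axis, one sample per voxel, max-normalized.

    ``mode='line'`` reads the single central voxel line; ``'projection'``
    sums over the perpendicular plane instead.
    """
    if axis not in _AXES:
        raise ValueError(f"unknown axis {axis!r}")
    ax = _AXES[axis]
    grid = image.grid
    if mode == "line":
        c = grid.origin_index
        idx = [c, c, c]
        idx[ax] = slice(None)
        vals = image.intensity[tuple(idx)].astype(float).copy()
    elif mode == "projection":
        other = tuple(i for i in range(3) if i != ax)
        vals = image.intensity.sum(axis=other).astype(float)
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    m = vals.max()
    if m == 0:
        raise DegenerateImageError("all-zero profile")
    return AxisProfile(axis=axis.upper(), positions=grid.centers(), values=vals / m)


def fit_gaussian(profile: AxisProfile) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit of a profile.

    Initialization: A = max, mu = argmax, sigma = HWHM / 1.177, c = min;
    sigma bounded to (0.1, 120) mm. Raises :class:`FitError` on flat
    profiles or non-convergence.
    """
    x = np.asarray(profile.positions, dtype=float)
    y = np.asarray(profile.values, dtype=float)
    if x.size < 5:
        raise FitError("need at least 5 samples to fit")
    if np.ptp(y) < 1e-12:
        raise FitError("flat profile: Gaussian fit undefined")

    amp0 = float(y.max())
    mu0 = float(x[int(np.argmax(y))])
    c0 = float(y.min())
    half = c0 + 0.5 * (amp0 - c0)
    above = x[y >= half]
    hwhm = max((above.max() - above.min()) / 2.0, x[1] - x[0]) if above.size else x[1] - x[0]
    sig0 = min(max(hwhm / 1.177, 0.15), 119.0)

    def model(x, a, mu, sig, c):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sig**2)) + c

    try:
        popt, _ = curve_fit(
            model, x, y, p0=[amp0 - c0, mu0, sig0, c0],
            bounds=([0.0, x.min(), 0.1, -np.inf],
                    [np.inf, x.max(), 120.0, np.inf]),
            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Gaussian fit failed: {exc}") from None
    resid = y - model(x, *popt)
    return GaussianFit(amplitude=float(popt[0]), mean=float(popt[1]),
                       sigma=float(popt[2]), offset=float(popt[3]),
                       rmse=float(np.sqrt(np.mean(resid**2))))


def stretching_study(base_config: SimulationConfig,
                     distances: Sequence[float],
                     n_iter: int = 250,
                     n_true: int = 1000,
                     grid: Optional[VoxelGrid] = None,
                     model: Optional[SystemModel] = None,
                     profile_mode: str = "line") -> pd.DataFrame:
    """Z-stretching versus detector distance.

    For each distance: simulate ``n_true`` true events, reconstruct with
    ``n_iter`` MLEM iterations, fit Gaussians to the Z and X profiles.
    Returns a DataFrame sorted by distance with columns
    ``distance_mm, sigma_z_mm, sigma_x_mm, rmse_z``.
    """
    import dataclasses

    rows = []
    model = model or SystemModel()
    grid = grid or VoxelGrid()
    for dist in sorted(distances):
        detector = dataclasses.replace(base_config.detector, distance=float(dist))
        config = base_config.replace(detector=detector)
        try:
            events = generate_true_events(config, n_true)
            run = mlem_reconstruct(events, grid, n_iter=n_iter, model=model,
                                   snapshot_every=0)
            fz = fit_gaussian(axis_profile(run.final, "z", mode=profile_mode))
            fx = fit_gaussian(axis_profile(run.final, "x", mode=profile_mode))
        except Exception as exc:
            raise RuntimeError(f"stretching study failed at distance "
                               f"{dist} mm: {exc}") from exc
        rows.append({"distance_mm": float(dist), "sigma_z_mm": fz.sigma,
                     "sigma_x_mm": fx.sigma, "rmse_z": fz.rmse})
    return pd.DataFrame(rows)
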