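"""Phantom, source and detector geometry for the simulated BNCT setup.

Units are mm and keV throughout. The coordinate system is right-handed with
the Compton camera on the +Z axis. The cylindrical phantom approximates a
mouse body lying along Y: radius in the XZ plane, height along Y, centered at
the origin. The gamma source (tumor surrogate) sits at the origin, so the
detector can approach down to one phantom radius without entering tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np

from .errors import GeometryError

#: Electron rest energy, keV.
M_E_C2 = 511.0

#: Prompt-gamma energy of the 10B(n, alpha)7Li capture reaction, keV.
E_PROMPT_GAMMA = 478.0

#: Linear attenuation coefficient of soft tissue near 478 keV, 1/mm.
MU_SOFT_TISSUE = 0.0105

_MATERIAL_MU = {"air": 0.0, "soft_tissue": MU_SOFT_TISSUE}


@dataclass(frozen=True)
class PhantomGeometry:
    """Solid cylinder of air or soft tissue, axis along Y, centered at origin.

    Parameters
    ----------
    radius : float
        Cylinder radius in the XZ plane, mm.
    height : float
        Cylinder extent along Y, mm.
    material : str
        ``"air"`` or ``"soft_tissue"``.
    attenuation_coeff : float, optional
        Linear attenuation coefficient at 478 keV in 1/mm. Defaults to the
        material's tabulated value (0 for air).
    """

    radius: float = 30.0
    height: float = 100.0
    material: str = "soft_tissue"
    attenuation_coeff: Optional[float] = None

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0:
            raise GeometryError("phantom radius and height must be positive")
        if self.material not in _MATERIAL_MU:
            raise GeometryError(f"unknown phantom material {self.material!r}")
        if self.attenuation_coeff is None:
            object.__setattr__(self, "attenuation_coeff", _MATERIAL_MU[self.material])
        elif self.attenuation_coeff < 0:
            raise GeometryError("attenuation coefficient must be >= 0")

    @classmethod
    def air(cls, **kw) -> "PhantomGeometry":
        return cls(material="air", **kw)

    @classmethod
    def soft_tissue(cls, **kw) -> "PhantomGeometry":
        return cls(material="soft_tissue", **kw)

    @property
    def volume(self) -> float:
        """Cylinder volume, mm^3."""
        return float(np.pi * self.radius**2 * self.height)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the cylinder. ``points`` is (N, 3)."""
        p = np.atleast_2d(points)
        radial = p[:, 0] ** 2 + p[:, 2] ** 2 <= self.radius**2
        axial = np.abs(p[:, 1]) <= self.height / 2.0
        return radial & axial

    def chord_to_exit(self, origins: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Distance from each origin (inside the cylinder) to the cylinder exit
        along the given unit direction, mm. Points outside return 0."""
        o = np.atleast_2d(origins)
        d = np.atleast_2d(directions)
        big = 1e30
        # radial exit: (ox + t dx)^2 + (oz + t dz)^2 = R^2
        a = d[:, 0] ** 2 + d[:, 2] ** 2
        b = o[:, 0] * d[:, 0] + o[:, 2] * d[:, 2]
        c = o[:, 0] ** 2 + o[:, 2] ** 2 - self.radius**2
        disc = b * b - a * c
        safe_a = np.where(a > 1e-300, a, 1e-300)
        t_rad = np.where(
            (a > 1e-300) & (disc >= 0),
            (-b + np.sqrt(np.maximum(disc, 0.0))) / safe_a,
            big,
        )
        # cap exit along Y
        dy = np.where(np.abs(d[:, 1]) > 1e-300, d[:, 1], 1e-300)
        t_cap = (np.sign(dy) * self.height / 2.0 - o[:, 1]) / dy
        t_cap = np.where(np.abs(d[:, 1]) > 1e-300, t_cap, big)
        t = np.minimum(t_rad, t_cap)
        inside = self.contains(o)
        return np.where(inside, np.maximum(t, 0.0), 0.0)


@dataclass(frozen=True)
class SourceModel:
    """Gamma source: a 10 mm-radius sphere or five point emitters 6 mm apart.

    ``tn_ratio`` is the tumor-to-healthy boron concentration ratio T/N.
    ``None`` means no background: every gamma starts inside the source.
    Emission density is proportional to boron concentration, so with
    background the tumor draw probability is
    ``p_T = (T/N * V_tumor) / (T/N * V_tumor + V_healthy)``.
    """

    shape: str = "sphere"
    center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    sphere_radius: float = 10.0
    point_spacing: float = 6.0
    gamma_energy: float = E_PROMPT_GAMMA
    tn_ratio: Optional[float] = None
    #: Effective emitting volume for zero-measure shapes (five_points) when a
    #: finite T/N background is requested; ignored for the sphere.
    emission_volume: Optional[float] = None

    def __post_init__(self):
        if self.shape not in ("sphere", "five_points"):
            raise GeometryError(f"unknown source shape {self.shape!r}")
        if self.gamma_energy <= 0:
            raise GeometryError("gamma energy must be positive")
        if self.shape == "sphere" and self.sphere_radius <= 0:
            raise GeometryError("sphere radius must be positive")
        if self.tn_ratio is not None and not self.tn_ratio > 0:
            raise GeometryError("T/N ratio must be positive")

    @property
    def points(self) -> np.ndarray:
        """Vertex positions for the five-point source: a cross in the XY
        plane, center plus 4 points ``point_spacing`` away."""
        c = np.asarray(self.center, dtype=float)
        s = self.point_spacing
        offsets = np.array(
            [[0, 0, 0], [s, 0, 0], [-s, 0, 0], [0, s, 0], [0, -s, 0]], dtype=float
        )
        return c + offsets

    @property
    def tumor_volume(self) -> float:
        """Emitting tumor volume, mm^3 (used for the T/N emission split)."""
        if self.shape == "sphere":
            return float(4.0 / 3.0 * np.pi * self.sphere_radius**3)
        if self.emission_volume is not None:
            return float(self.emission_volume)
        return 0.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Mask of points inside the source region."""
        p = np.atleast_2d(points)
        if self.shape == "sphere":
            c = np.asarray(self.center, dtype=float)
            return np.sum((p - c) ** 2, axis=1) <= self.sphere_radius**2
        d2 = np.min(
            np.sum((p[:, None, :] - self.points[None, :, :]) ** 2, axis=2), axis=1
        )
        return d2 <= 1e-12


@dataclass(frozen=True)
class DetectorGeometry:
    """Two adjacent CZT layers on the +Z axis, transverse faces centered on Z.

    ``distance`` is measured from the source center (coordinate origin) to the
    front face of layer 1 along +Z. Layer 2 sits directly behind layer 1,
    separated by ``layer_gap`` (0 = touching).
    """

    layer_size: Tuple[float, float] = (20.0, 20.0)
    layer_thickness: float = 5.0
    layer_gap: float = 0.0
    distance: float = 60.0
    density: float = 5.78

    def __post_init__(self):
        if min(self.layer_size) <= 0 or self.layer_thickness <= 0:
            raise GeometryError("detector layer dimensions must be positive")
        if self.layer_gap < 0:
            raise GeometryError("layer gap must be >= 0")
        if self.distance <= 0:
            raise GeometryError("detector distance must be positive")

    def layer_bounds(self, layer: int) -> Tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the axis-aligned box of layer 1 or 2."""
        hx, hy = self.layer_size[0] / 2.0, self.layer_size[1] / 2.0
        if layer == 1:
            z0 = self.distance
        elif layer == 2:
            z0 = self.distance + self.layer_thickness + self.layer_gap
        else:
            raise ValueError("layer must be 1 or 2")
        lo = np.array([-hx, -hy, z0])
        hi = np.array([hx, hy, z0 + self.layer_thickness])
        return lo, hi


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one Monte Carlo run.

    The same config and seed always produce the identical event list.
    ``idealized_detection=True`` (default) forces a Compton scatter at every
    geometric layer-1 hit and a photoabsorption at every geometric layer-2
    hit; the alternative rejects interactions with probability derived from
    an effective interaction length (crude cross-section stand-in).
    """

    phantom: PhantomGeometry = field(default_factory=PhantomGeometry)
    source: SourceModel = field(default_factory=SourceModel)
    detector: DetectorGeometry = field(default_factory=DetectorGeometry)
    n_emitted: int = 8_000_000
    seed: int = 0
    idealized_detection: bool = True

    def __post_init__(self):
        if self.n_emitted <= 0:
            raise ValueError("n_emitted must be positive")

    def replace(self, **kw) -> "SimulationConfig":
        import dataclasses

        return dataclasses.replace(self, **kw)

    # -- JSON round trip ----------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        phantom = PhantomGeometry(**d["phantom"])
        src = d["source"]
        src["center"] = tuple(src["center"])
        source = SourceModel(**src)
        det = d["detector"]
        det["layer_size"] = tuple(det["layer_size"])
        detector = DetectorGeometry(**det)
        return cls(
            phantom=phantom,
            source=source,
            detector=detector,
            n_emitted=d["n_emitted"],
            seed=d["seed"],
            idealized_detection=d["idealized_detection"],
        )


def tumor_probability(source: SourceModel, phantom: PhantomGeometry) -> float:
    """Probability that an emitted gamma originates in the tumor region.

    With no background (``tn_ratio is None``) this is 1. Otherwise emission
    rate is proportional to boron concentration, giving
    ``p_T = (T/N * V_t) / (T/N * V_t + V_healthy)``.
    """
    if source.tn_ratio is None:
        return 1.0
    v_t = source.tumor_volume
    if v_t <= 0:
        raise GeometryError(
            "finite T/N background requires a positive tumor emission volume; "
            "set SourceModel.emission_volume for point-like sources"
        )
    v_h = phantom.volume - v_t
    if v_h <= 0:
        raise GeometryError("tumor volume exceeds phantom volume")
    tn = source.tn_ratio
    return float(tn * v_t / (tn * v_t + v_h))


def check_source_in_phantom(source: SourceModel, phantom: PhantomGeometry) -> None:
    """Raise :class:`GeometryError` unless the source fits inside the phantom."""
    if source.shape == "sphere":
        c = np.asarray(source.center, dtype=float)
        r = source.sphere_radius
        radial = np.hypot(c[0], c[2]) + r <= phantom.radius + 1e-9
        axial = abs(c[1]) + r <= phantom.height / 2.0 + 1e-9
        if not (radial and axial):
            raise GeometryError("spherical source extends outside the phantom")
    else:
        if not np.all(phantom.contains(source.points)):
            raise GeometryError("point source vertices lie outside the phantom")
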