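"""Monte Carlo generation of true Compton events.

A *true event* is one photon that Compton-scatters in detector layer 1 and is
photoabsorbed in layer 2. The generator emits 478 keV gammas isotropically
from the source (plus optional T/N healthy-tissue background), attenuates
them over their chord through the phantom, forces an interaction point
uniformly along the chord inside each CZT layer (ideal detector: no energy or
position blurring), and samples the scattering angle from the Klein-Nishina
differential cross-section. Energy bookkeeping is exact: ``e1 + e2`` equals
the emission energy bit-for-bit.

All randomness flows through one ``numpy.random.Generator``; per-photon draws
are made in a fixed order *before* any geometric acceptance test, so runs
that differ only in phantom material consume identical random streams (the
tissue run's true events are a subset of the air run's).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .errors import CsvParseError
from .geometry import (
    M_E_C2,
    PhantomGeometry,
    SimulationConfig,
    SourceModel,
    check_source_in_phantom,
    tumor_probability,
)

# Effective interaction lengths in CZT used by the optional non-idealized
# detection mode (crude stand-in for tabulated cross sections), mm.
_CZT_SCATTER_LENGTH = 19.0
_CZT_ABSORB_LENGTH = 12.0


@dataclass(frozen=True)
class ComptonEvent:
    """One true event: scatter hit (r1, e1) in layer 1, absorption hit
    (r2, e2) in layer 2. ``truth_vertex`` is simulation-only ground truth."""

    r1: np.ndarray
    r2: np.ndarray
    e1: float
    e2: float
    truth_vertex: Optional[np.ndarray] = None


@dataclass
class EventList:
    """Column-oriented list of true events sharing one gamma energy.

    Arrays: ``r1``/``r2`` are (N, 3) mm, ``e1``/``e2`` are (N,) keV,
    ``truth_vertex`` is (N, 3) mm or None when read from a file without
    ground-truth columns.
    """

    r1: np.ndarray
    r2: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    gamma_energy: float
    truth_vertex: Optional[np.ndarray] = None
    config: Optional[SimulationConfig] = None

    def __post_init__(self):
        self.r1 = np.atleast_2d(np.asarray(self.r1, dtype=float)).reshape(-1, 3)
        self.r2 = np.atleast_2d(np.asarray(self.r2, dtype=float)).reshape(-1, 3)
        self.e1 = np.asarray(self.e1, dtype=float).reshape(-1)
        self.e2 = np.asarray(self.e2, dtype=float).reshape(-1)
        if self.truth_vertex is not None:
            self.truth_vertex = np.atleast_2d(
                np.asarray(self.truth_vertex, dtype=float)
            ).reshape(-1, 3)

    @classmethod
    def empty(cls, gamma_energy: float, config=None) -> "EventList":
        z = np.zeros((0, 3))
        return cls(z, z.copy(), np.zeros(0), np.zeros(0), gamma_energy,
                   truth_vertex=np.zeros((0, 3)), config=config)

    def __len__(self) -> int:
        return self.e1.shape[0]

    def __getitem__(self, i: int) -> ComptonEvent:
        tv = None if self.truth_vertex is None else self.truth_vertex[i]
        return ComptonEvent(self.r1[i], self.r2[i], float(self.e1[i]),
                            float(self.e2[i]), tv)

    def __iter__(self) -> Iterator[ComptonEvent]:
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventList):
            return NotImplemented
        same = (
            len(self) == len(other)
            and self.gamma_energy == other.gamma_energy
            and np.array_equal(self.r1, other.r1)
            and np.array_equal(self.r2, other.r2)
            and np.array_equal(self.e1, other.e1)
            and np.array_equal(self.e2, other.e2)
        )
        if not same:
            return False
        if (self.truth_vertex is None) != (other.truth_vertex is None):
            return False
        if self.truth_vertex is not None:
            return np.array_equal(self.truth_vertex, other.truth_vertex)
        return True

    def permuted(self, order: np.ndarray) -> "EventList":
        tv = None if self.truth_vertex is None else self.truth_vertex[order]
        return EventList(self.r1[order], self.r2[order], self.e1[order],
                         self.e2[order], self.gamma_energy, truth_vertex=tv,
                         config=self.config)


# ---------------------------------------------------------------------------
# Klein-Nishina sampling
# ---------------------------------------------------------------------------

def klein_nishina_pdf(theta: np.ndarray, energy: float) -> np.ndarray:
    """Unnormalized density of the polar Compton scattering angle,
    ``dsigma/dOmega * sin(theta)``, at the given photon energy (keV)."""
    theta = np.asarray(theta, dtype=float)
    alpha = energy / M_E_C2
    c = np.cos(theta)
    eps = 1.0 / (1.0 + alpha * (1.0 - c))  # E'/E
    return eps**2 * (eps + 1.0 / eps - 1.0 + c**2) * np.sin(theta)


def _kn_cos_theta(energy: float, rng: np.random.Generator, n: int) -> np.ndarray:
    """Rejection-sample n Klein-Nishina cos(theta) values at ``energy`` keV."""
    alpha = energy / M_E_C2
    out = np.empty(n)
    n_left = n
    pos = 0
    # envelope: f(cos=1) = 2 is the forward-peak maximum for alpha > 0
    while n_left > 0:
        m = max(int(n_left * 2.5) + 16, 32)
        c = rng.uniform(-1.0, 1.0, m)
        u = rng.uniform(0.0, 2.0, m)
        eps = 1.0 / (1.0 + alpha * (1.0 - c))
        f = eps**2 * (eps + 1.0 / eps - 1.0 + c * c)
        acc = c[u < f]
        k = min(acc.shape[0], n_left)
        out[pos:pos + k] = acc[:k]
        pos += k
        n_left -= k
    return out


def sample_klein_nishina_angle(energy: float, rng: np.random.Generator,
                               size: Optional[int] = None):
    """Polar Compton scattering angle(s) in radians, distributed per the
    Klein-Nishina differential cross-section at ``energy`` keV.

    Returns a scalar when ``size`` is None, else an array of shape (size,).
    The azimuth is uniform and left to the caller.
    """
    if not energy > 0:
        raise ValueError("photon energy must be positive")
    n = 1 if size is None else int(size)
    theta = np.arccos(np.clip(_kn_cos_theta(energy, rng, n), -1.0, 1.0))
    return float(theta[0]) if size is None else theta


# ---------------------------------------------------------------------------
# Vertex sampling
# ---------------------------------------------------------------------------

def _uniform_in_cylinder(phantom: PhantomGeometry, rng, n: int) -> np.ndarray:
    """n points uniform in the phantom cylinder (axis along Y)."""
    rho = phantom.radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    y = rng.uniform(-phantom.height / 2.0, phantom.height / 2.0, n)
    return np.column_stack([rho * np.cos(phi), y, rho * np.sin(phi)])


def _uniform_in_ball(center, radius, rng, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0)
    return np.asarray(center, dtype=float) + v * r[:, None]


def sample_source_vertex(source: SourceModel, phantom: PhantomGeometry,
                         rng: np.random.Generator, size: Optional[int] = None):
    """Sample emission vertices.

    A vertex is drawn inside the tumor region with probability
    ``p_T = (T/N * V_t) / (T/N * V_t + V_healthy)`` (1 when no background),
    else uniformly in the healthy phantom volume. Sphere vertices are uniform
    in the ball; five-point vertices uniform among the five points.
    """
    check_source_in_phantom(source, phantom)
    n = 1 if size is None else int(size)
    p_t = tumor_probability(source, phantom)
    in_tumor = rng.uniform(0.0, 1.0, n) < p_t
    out = np.empty((n, 3))
    k = int(in_tumor.sum())
    if k:
        if source.shape == "sphere":
            out[in_tumor] = _uniform_in_ball(source.center, source.sphere_radius,
                                             rng, k)
        else:
            out[in_tumor] = source.points[rng.integers(0, 5, k)]
    m = n - k
    if m:
        idx = np.flatnonzero(~in_tumor)
        remaining = idx
        while remaining.size:
            cand = _uniform_in_cylinder(phantom, rng, remaining.size)
            good = ~source.contains(cand)
            out[remaining[good]] = cand[good]
            remaining = remaining[~good]
    return out[0] if size is None else out


# ---------------------------------------------------------------------------
# Photon transport to the two detector layers
# ---------------------------------------------------------------------------

def _ray_box(o: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Vectorized slab test. Returns (tmin, tmax, hit) for rays o + t d with
    t > 0; ``hit`` requires a positive-length chord in front of the origin."""
    d_safe = np.where(np.abs(d) > 1e-300, d, 1e-300)
    t1 = (lo[None, :] - o) / d_safe
    t2 = (hi[None, :] - o) / d_safe
    tmin = np.max(np.minimum(t1, t2), axis=1)
    tmax = np.min(np.maximum(t1, t2), axis=1)
    hit = (tmax > np.maximum(tmin, 0.0)) & (tmin > 0.0)
    return tmin, tmax, hit


def _perp_basis(d: np.ndarray):
    """Two unit vectors orthogonal to each unit vector in d (N, 3)."""
    helper = np.where(np.abs(d[:, 2:3]) < 0.9,
                      np.array([[0.0, 0.0, 1.0]]),
                      np.array([[1.0, 0.0, 0.0]]))
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    return e1, e2


def _exact_energy_split(e_gamma: float, cos_t: np.ndarray):
    """Energies (e1, e2) of the Compton split with e1 + e2 == e_gamma exactly.

    The scattered energy follows the Compton formula; a complement fix-up
    iteration absorbs the (at most 1 ulp) float rounding so the sum is
    bit-exact, as expected of an ideal detector.
    """
    alpha = e_gamma / M_E_C2
    e2 = e_gamma / (1.0 + alpha * (1.0 - cos_t))
    e1 = e_gamma - e2
    for _ in range(20):
        bad = (e1 + e2) != e_gamma
        if not bad.any():
            break
        e2b = e_gamma - e1[bad]
        e1b = e_gamma - e2b
        e1[bad] = e1b
        e2[bad] = e2b
    return e1, e2


def _trace_chunk(config: SimulationConfig, vertices: np.ndarray,
                 directions: np.ndarray, rng: np.random.Generator):
    """Trace one chunk of emitted photons; returns true-event field arrays.

    All random draws (survival, scattering angle, azimuth, interaction
    depths, interaction acceptances) are made for the *full* chunk up front,
    in a fixed order, so acceptance masks never shift the stream.
    """
    n = vertices.shape[0]
    e_gamma = config.source.gamma_energy
    u_surv = rng.uniform(0.0, 1.0, n)
    cos_t = _kn_cos_theta(e_gamma, rng, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    u_depth1 = rng.uniform(0.0, 1.0, n)
    u_depth2 = rng.uniform(0.0, 1.0, n)
    u_int1 = rng.uniform(0.0, 1.0, n)
    u_int2 = rng.uniform(0.0, 1.0, n)

    mu = config.phantom.attenuation_coeff
    if mu > 0:
        chord = config.phantom.chord_to_exit(vertices, directions)
        alive = u_surv < np.exp(-mu * chord)
    else:
        alive = np.ones(n, dtype=bool)

    lo1, hi1 = config.detector.layer_bounds(1)
    t1min, t1max, hit1 = _ray_box(vertices, directions, lo1, hi1)
    cand = alive & hit1
    if not config.idealized_detection:
        chord1 = np.maximum(t1max - t1min, 0.0)
        cand &= u_int1 < 1.0 - np.exp(-chord1 / _CZT_SCATTER_LENGTH)
    if not cand.any():
        empty = np.zeros((0, 3))
        return empty, empty, np.zeros(0), np.zeros(0), empty, np.zeros(0)

    o = vertices[cand]
    d = directions[cand]
    t_in = t1min[cand]
    t_out = t1max[cand]
    r1 = o + (t_in + u_depth1[cand] * (t_out - t_in))[:, None] * d

    c = cos_t[cand]
    s = np.sqrt(np.maximum(1.0 - c * c, 0.0))
    b1, b2 = _perp_basis(d)
    ph = phi[cand]
    sdir = (c[:, None] * d
            + (s * np.cos(ph))[:, None] * b1
            + (s * np.sin(ph))[:, None] * b2)

    lo2, hi2 = config.detector.layer_bounds(2)
    t2min, t2max, hit2 = _ray_box(r1, sdir, lo2, hi2)
    if not config.idealized_detection:
        chord2 = np.maximum(t2max - t2min, 0.0)
        hit2 &= u_int2[cand] < 1.0 - np.exp(-chord2 / _CZT_ABSORB_LENGTH)
    if not hit2.any():
        empty = np.zeros((0, 3))
        return empty, empty, np.zeros(0), np.zeros(0), empty, np.zeros(0)

    r1 = r1[hit2]
    r2 = (r1 + (t2min[hit2] + u_depth2[cand][hit2]
                * (t2max[hit2] - t2min[hit2]))[:, None] * sdir[hit2])
    e1, e2 = _exact_energy_split(e_gamma, c[hit2])
    return r1, r2, e1, e2, o[hit2], c[hit2]


def propagate_and_detect(vertex, direction, config: SimulationConfig,
                         rng: np.random.Generator) -> Optional[ComptonEvent]:
    """Trace a single photon; returns the true event or None (non-detection
    is a valid outcome, not an error)."""
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if not np.isclose(norm, 1.0, rtol=1e-9):
        raise ValueError("direction must be a unit vector")
    r1, r2, e1, e2, tv, _ = _trace_chunk(
        config, np.atleast_2d(np.asarray(vertex, dtype=float)),
        np.atleast_2d(direction), rng)
    if e1.shape[0] == 0:
        return None
    return ComptonEvent(r1[0], r2[0], float(e1[0]), float(e2[0]), tv[0])


def _isotropic_directions(rng, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v


def _generate(config: SimulationConfig, n_emitted: int, rng,
              chunk: int = 1_000_000):
    parts = []
    emitted = 0
    while emitted < n_emitted:
        m = min(chunk, n_emitted - emitted)
        vertices = sample_source_vertex(config.source, config.phantom, rng, size=m)
        dirs = _isotropic_directions(rng, m)
        parts.append(_trace_chunk(config, vertices, dirs, rng))
        emitted += m
    r1 = np.concatenate([p[0] for p in parts])
    r2 = np.concatenate([p[1] for p in parts])
    e1 = np.concatenate([p[2] for p in parts])
    e2 = np.concatenate([p[3] for p in parts])
    tv = np.concatenate([p[4] for p in parts])
    return r1, r2, e1, e2, tv


def generate_events(config: SimulationConfig) -> EventList:
    """Emit ``config.n_emitted`` isotropic gammas and return all true events.

    Deterministic under a fixed config (seed included). Emits a warning if no
    photon produced a true event.
    """
    rng = np.random.default_rng(config.seed)
    r1, r2, e1, e2, tv = _generate(config, config.n_emitted, rng)
    if e1.shape[0] == 0:
        warnings.warn("no true events after %d emissions" % config.n_emitted)
    return EventList(r1, r2, e1, e2, config.source.gamma_energy,
                     truth_vertex=tv, config=config)


def generate_true_events(config: SimulationConfig, n_true: int,
                         chunk: int = 400_000,
                         max_emitted: int = 500_000_000) -> EventList:
    """Emit photons in chunks until ``n_true`` true events are recorded, then
    truncate to exactly ``n_true``. Deterministic under a fixed config."""
    rng = np.random.default_rng(config.seed)
    parts = []
    got = 0
    emitted = 0
    while got < n_true:
        if emitted >= max_emitted:
            raise RuntimeError(
                f"only {got}/{n_true} true events after {emitted} emissions")
        p = _generate(config, chunk, rng, chunk=chunk)
        emitted += chunk
        parts.append(p)
        got += p[2].shape[0]
    r1 = np.concatenate([p[0] for p in parts])[:n_true]
    r2 = np.concatenate([p[1] for p in parts])[:n_true]
    e1 = np.concatenate([p[2] for p in parts])[:n_true]
    e2 = np.concatenate([p[3] for p in parts])[:n_true]
    tv = np.concatenate([p[4] for p in parts])[:n_true]
    return EventList(r1, r2, e1, e2, config.source.gamma_energy,
                     truth_vertex=tv, config=config)


# ---------------------------------------------------------------------------
# List-mode CSV I/O
# ---------------------------------------------------------------------------

_EVENT_HEADER = ["x1", "y1", "z1", "e1", "x2", "y2", "z2", "e2"]
_TRUTH_HEADER = ["vx", "vy", "vz"]


def write_event_csv(path, events: EventList) -> None:
    """Write the list-mode event CSV: one header line, one row per event,
    full float precision (exact round trip)."""
    cols = list(_EVENT_HEADER)
    with_truth = events.truth_vertex is not None
    if with_truth:
        cols += _TRUTH_HEADER
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for i in range(len(events)):
            row = [*events.r1[i], events.e1[i], *events.r2[i], events.e2[i]]
            if with_truth:
                row += list(events.truth_vertex[i])
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_event_csv(path, gamma_energy: Optional[float] = None) -> EventList:
    """Read a list-mode event CSV written by :func:`write_event_csv`.

    Raises :class:`CsvParseError` naming the offending line on a wrong field
    count or a non-numeric field. ``gamma_energy`` defaults to max(e1 + e2)
    over the file (478 for an empty file).
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().strip()
        ncol = len(header.split(","))
        if ncol not in (8, 11):
            raise CsvParseError(
                f"expected 8 or 11 columns in header, got {ncol}", 1)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != ncol:
                raise CsvParseError(
                    f"expected {ncol} fields, got {len(fields)}", lineno)
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise CsvParseError(f"non-numeric field ({exc})", lineno) from None
    data = np.asarray(rows, dtype=float).reshape(-1, ncol)
    r1 = data[:, 0:3]
    e1 = data[:, 3]
    r2 = data[:, 4:7]
    e2 = data[:, 7]
    tv = data[:, 8:11] if ncol == 11 else None
    if gamma_energy is None:
        gamma_energy = float(np.max(e1 + e2)) if len(e1) else 478.0
    return EventList(r1, r2, e1, e2, gamma_energy, truth_vertex=tv)
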