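"""Spherical dot-cloud environment and head-coupled optic-flow geometry.

The simulated scene is a dense cloud of small squares filling a spherical
shell around the observer, viewed through a head-mounted display while the
display's virtual viewpoint is coupled to the observer's yaw head rotation
under one of three rules.  Each rule is parameterised by a single
focus-of-expansion (FOE) gain ``k``:

* ``contralateral`` (k = 0): the display fully compensates head rotation, so
  the flow field stays fixed in world (spatiotopic) coordinates and its FOE
  sweeps opposite to the head in head-relative coordinates.
* ``pure_radial``   (k = 1): the display ignores head rotation; the FOE is
  glued to the nose.
* ``ipsilateral``   (k = 2): the FOE moves with the head but through twice
  the head's yaw excursion in world coordinates.

For any gain, the spatiotopic FOE azimuth is ``k * yaw`` and the
head-relative FOE azimuth is ``(k - 1) * yaw``; their difference is always
exactly the head yaw.

Coordinate convention (fixed throughout the package): right-handed frame
with the observer at the origin, forward = -z, up = +y, right = +x.
Positive yaw is a leftward head turn (counter-clockwise seen from above).
Azimuth is measured in the horizontal plane from straight ahead, positive
leftward; elevation is positive upward.  All angles are degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "SceneConfig",
    "DotCloud",
    "CouplingCondition",
    "FlowField",
    "CONTRALATERAL",
    "PURE_RADIAL",
    "IPSILATERAL",
    "CONDITIONS",
    "optical_size",
    "edge_for_far_size",
    "distance_for_size",
    "generate_cloud",
    "foe_azimuth",
    "project",
    "advance_translation",
    "visible_fraction",
]


def optical_size(edge: float, distance: float) -> float:
    """Angular size in degrees of a square of side ``edge`` seen at ``distance``.

    Uses the exact subtense 2*atan(edge / (2*distance)); strictly decreasing
    in distance.  Both arguments are metres and must be positive.
    """
    edge = np.asarray(edge, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if np.any(edge <= 0) or np.any(distance <= 0):
        raise DomainError("optical_size requires edge > 0 and distance > 0")
    out = 2.0 * np.degrees(np.arctan(edge / (2.0 * distance)))
    return float(out) if out.ndim == 0 else out


def edge_for_far_size(size_deg: float, distance: float) -> float:
    """Square side (m) whose angular size at ``distance`` equals ``size_deg``."""
    if size_deg <= 0 or distance <= 0:
        raise DomainError("size and distance must be positive")
    return 2.0 * distance * math.tan(math.radians(size_deg / 2.0))


def distance_for_size(size_deg: float, edge: float) -> float:
    """Distance (m) at which a square of side ``edge`` subtends ``size_deg``."""
    if size_deg <= 0 or size_deg >= 180 or edge <= 0:
        raise DomainError("size must be in (0, 180) and edge positive")
    return edge / (2.0 * math.tan(math.radians(size_deg / 2.0)))


# Default shell geometry: the squares subtend 0.25 deg at the 3 m outer
# radius and 2.5 deg at the inner radius, which pins the square side and the
# inner radius jointly.
DEFAULT_OUTER_RADIUS = 3.0
DEFAULT_EDGE = edge_for_far_size(0.25, DEFAULT_OUTER_RADIUS)      # ~0.01309 m
DEFAULT_INNER_RADIUS = distance_for_size(2.5, DEFAULT_EDGE)       # ~0.2999 m

#: Outward yaw of each eye's frustum (deg) in the binocular union model,
#: calibrated once so that the default cloud/frustum pair makes ~20% of the
#: squares visible, the device's published figure.
DEFAULT_EYE_YAW_OFFSET = 8.5


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the simulated environment and display.

    Attributes
    ----------
    n_dots : int
        Number of squares in the cloud.
    outer_radius, inner_radius : float
        Shell bounds in metres; dots live at distances within the shell.
    edge_length : float
        Physical side of each square (m); sets optical size with proximity.
    fov_diagonal : float
        Diagonal field of view of each eye's frustum, degrees.
    aspect_ratio : float
        Width:height ratio of each eye's frustum in tangent space.
    translation_speed : float
        Simulated forward self-motion speed, m/s.
    frame_rate : float
        Display update rate, Hz.
    frustum_model : str
        ``"binocular"`` (two off-axis eye frusta, union) or ``"cone"``
        (single cone of half-angle fov_diagonal/2).
    eye_yaw_offset : float
        Outward yaw of each eye frustum in the binocular model, degrees.
    """

    n_dots: int = 163_840
    outer_radius: float = DEFAULT_OUTER_RADIUS
    inner_radius: float = DEFAULT_INNER_RADIUS
    edge_length: float = DEFAULT_EDGE
    fov_diagonal: float = 110.0
    aspect_ratio: float = 0.8
    translation_speed: float = 1.0
    frame_rate: float = 80.0
    frustum_model: str = "binocular"
    eye_yaw_offset: float = DEFAULT_EYE_YAW_OFFSET

    def __post_init__(self):
        if self.n_dots <= 0:
            raise ConfigurationError("n_dots must be positive")
        if not 0 < self.inner_radius < self.outer_radius:
            raise ConfigurationError(
                "radii must satisfy 0 < inner_radius < outer_radius"
            )
        if not 0 < self.fov_diagonal < 180:
            raise ConfigurationError("fov_diagonal must be in (0, 180) degrees")
        if self.aspect_ratio <= 0:
            raise ConfigurationError("aspect_ratio must be positive")
        if self.translation_speed < 0:
            raise ConfigurationError("translation_speed must be >= 0")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if self.frustum_model not in ("binocular", "cone"):
            raise ConfigurationError("frustum_model must be 'binocular' or 'cone'")


@dataclass(frozen=True)
class CouplingCondition:
    """A visual-vestibular coupling rule, identified by its FOE gain ``k``."""

    name: str
    k: int

    _NAME_TO_K = {"contralateral": 0, "pure_radial": 1, "ipsilateral": 2}

    def __post_init__(self):
        expected = self._NAME_TO_K.get(self.name)
        if expected is None or expected != self.k:
            raise ConfigurationError(
                f"invalid coupling condition {self.name!r} with k={self.k}; "
                f"must be one of {self._NAME_TO_K}"
            )

    @classmethod
    def from_name(cls, name: str) -> "CouplingCondition":
        if name not in cls._NAME_TO_K:
            raise ConfigurationError(f"unknown coupling condition {name!r}")
        return cls(name, cls._NAME_TO_K[name])


CONTRALATERAL = CouplingCondition("contralateral", 0)
PURE_RADIAL = CouplingCondition("pure_radial", 1)
IPSILATERAL = CouplingCondition("ipsilateral", 2)
CONDITIONS = (CONTRALATERAL, PURE_RADIAL, IPSILATERAL)


@dataclass
class DotCloud:
    """World-frame positions of the cloud's squares.

    ``positions`` is an (n, 3) float array in metres; ``edge_length`` is the
    shared physical side of the squares.
    """

    positions: np.ndarray
    edge_length: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ConfigurationError("positions must be an (n, 3) array")

    @property
    def n_dots(self) -> int:
        return self.positions.shape[0]

    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)


@dataclass
class FlowField:
    """Per-dot head-relative optic-array sample for one frame.

    ``azimuth``/``elevation`` are head-relative angles (deg);
    ``spatiotopic_azimuth`` is the same dot's world-frame azimuth after the
    condition's scene rotation, kept for world-stationarity checks;
    ``angular_velocity`` is the translation-induced flow speed (deg/s);
    ``optical_size`` the angular side of the square (deg); ``visible`` a
    boolean frustum flag.
    """

    azimuth: np.ndarray
    elevation: np.ndarray
    spatiotopic_azimuth: np.ndarray
    angular_velocity: np.ndarray
    optical_size: np.ndarray
    visible: np.ndarray

    def visible_fraction(self) -> float:
        return float(np.mean(self.visible))


def generate_cloud(config: SceneConfig, seed: int) -> DotCloud:
    """Sample ``config.n_dots`` positions volume-uniformly in the shell.

    Directions are isotropic and radii follow the r^3 law so that the number
    density is constant throughout the shell; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(config.n_dots, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r3 = rng.uniform(config.inner_radius**3, config.outer_radius**3,
                     size=config.n_dots)
    return DotCloud(v * np.cbrt(r3)[:, None], config.edge_length)


def foe_azimuth(condition: CouplingCondition,
                head_yaw: float) -> tuple[float, float]:
    """FOE azimuth implied by the coupling gain at a given head yaw.

    Returns ``(spatiotopic, head_relative)`` = ``(k*yaw, (k-1)*yaw)`` in
    degrees; the two always differ by exactly the head yaw.
    """
    if not np.isfinite(head_yaw):
        raise DomainError("head_yaw must be finite")
    return condition.k * head_yaw, (condition.k - 1) * head_yaw


def _rotate_yaw(points: np.ndarray, yaw_deg: float) -> np.ndarray:
    """Rotate points about the vertical (+y) axis by ``yaw_deg`` (CCW from above)."""
    a = math.radians(yaw_deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    return np.column_stack((c * x + s * z, y, -s * x + c * z))


def _azimuth_elevation(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Head-relative azimuth/elevation (deg) of unit-norm-free direction vectors."""
    norm = np.linalg.norm(dirs, axis=1)
    az = np.degrees(np.arctan2(dirs[:, 0], -dirs[:, 2]))
    # positive azimuth = leftward = -x; arctan2(x, -z) gives rightward-positive
    az = -az
    az = (az + 180.0) % 360.0 - 180.0
    el = np.degrees(np.arcsin(np.clip(dirs[:, 1] / norm, -1.0, 1.0)))
    return az, el


def _in_frustum(dirs: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Visibility of direction vectors under the configured frustum model."""
    if config.frustum_model == "cone":
        half = math.radians(config.fov_diagonal / 2.0)
        norm = np.linalg.norm(dirs, axis=1)
        cosang = -dirs[:, 2] / norm        # angle from forward (-z)
        return cosang >= math.cos(half)
    # binocular union: each eye a symmetric rectangular frustum in tangent
    # space with tan-width : tan-height = aspect_ratio and the configured
    # diagonal, yawed outward by eye_yaw_offset
    tan_diag = math.tan(math.radians(config.fov_diagonal / 2.0))
    tan_h = tan_diag / math.sqrt(1.0 + config.aspect_ratio**2)
    tan_w = config.aspect_ratio * tan_h
    visible = np.zeros(len(dirs), dtype=bool)
    for sign in (+1.0, -1.0):
        eye = _rotate_yaw(dirs, -sign * config.eye_yaw_offset)
        z = eye[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            ok = (z < 0) & (np.abs(eye[:, 0] / -z) <= tan_w) \
                         & (np.abs(eye[:, 1] / -z) <= tan_h)
        visible |= ok
    return visible


def project(cloud: DotCloud, head_yaw: float, condition: CouplingCondition,
            config: SceneConfig) -> FlowField:
    """Render the cloud into the head-relative optic array for one frame.

    The coupling rule rigidly yaws the scene (dots and heading together) by
    ``k * head_yaw`` in world coordinates; the observer's head sits at
    ``head_yaw``.  The net head-relative rotation is therefore
    ``(k - 1) * head_yaw``, so with k = 0 the spatiotopic dot directions are
    invariant to head yaw (world-stationary scene) and with k = 1 the
    head-relative directions are invariant (display ignores the head).
    """
    if not np.isfinite(head_yaw):
        raise DomainError("head_yaw must be finite")
    spat = _rotate_yaw(cloud.positions, condition.k * head_yaw)
    rel = _rotate_yaw(cloud.positions, (condition.k - 1) * head_yaw)
    az, el = _azimuth_elevation(rel)
    spat_az, _ = _azimuth_elevation(spat)
    dist = np.linalg.norm(rel, axis=1)
    size = optical_size(cloud.edge_length, dist)
    # translation-induced flow: for forward speed v, a dot at distance d and
    # angle theta from the heading streams at v*sin(theta)/d (rad/s); the
    # heading is the scene frame's forward axis, i.e. head-relative azimuth
    # (k-1)*head_yaw.
    heading = _rotate_yaw(np.array([[0.0, 0.0, -1.0]]),
                          (condition.k - 1) * head_yaw)[0]
    sin_theta = np.linalg.norm(np.cross(rel / dist[:, None], heading), axis=1)
    ang_vel = np.degrees(config.translation_speed * sin_theta / dist)
    return FlowField(az, el, spat_az, ang_vel, size, _in_frustum(rel, config))


def advance_translation(cloud: DotCloud, dt: float, config: SceneConfig,
                        rng: np.random.Generator | None = None) -> DotCloud:
    """Advance forward self-motion by ``dt`` seconds, recycling passed dots.

    Every dot is displaced by ``translation_speed * dt`` opposite the
    heading (-z), i.e. toward +z relative to the observer.  Dots that leave
    the shell (pass inside the inner radius or drift beyond the outer
    radius behind the observer) are recycled to the outer-radius sphere at a
    fresh random direction, preserving the dot count.
    """
    if dt < 0:
        raise DomainError("dt must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    pos = cloud.positions.copy()
    pos[:, 2] += config.translation_speed * dt
    d = np.linalg.norm(pos, axis=1)
    out = (d < config.inner_radius) | (d > config.outer_radius)
    n_out = int(out.sum())
    if n_out:
        v = rng.normal(size=(n_out, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos[out] = v * config.outer_radius
    return DotCloud(pos, cloud.edge_length)


def visible_fraction(cloud: DotCloud, head_yaw: float,
                     condition: CouplingCondition,
                     config: SceneConfig) -> float:
    """Fraction of the cloud's dots inside the display frustum this frame."""
    if cloud.n_dots == 0:
        raise DomainError("cannot compute visibility of an empty cloud")
    return project(cloud, head_yaw, condition, config).visible_fraction()
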