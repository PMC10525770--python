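"""Wall shear stress, its cycle average (TAWSS), and vortex/WSS overlap.

Instantaneous WSS is the tangential viscous traction on the no-slip wall,
``tau_w = mu (du/dy)_wall`` with ``y`` the wall-normal coordinate; TAWSS is
the period average of ``|tau_w|``.  The overlap statistic quantifies how
much the "high-WSS band" on the wall coincides with the wall footprint of
identified vortex regions (Szymkiewicz-Simpson coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .boundary import FluidProperties
from .fields import FlowSnapshot

__all__ = ["WallPatch", "WSSField", "TAWSSField", "pipe_wall_patch",
           "compute_wss", "compute_tawss", "wss_vortex_overlap"]


@dataclass
class WallPatch:
    """Wall faces with outward normals and wall-adjacent interior samples.

    ``sample_points`` sit at wall-normal distance ``y`` inside the fluid;
    the optional second row of samples (at ``2y``) enables the second-order
    one-sided derivative.
    """

    face_centers: np.ndarray       # (M, 3)
    normals: np.ndarray            # (M, 3) outward unit
    sample_points: np.ndarray      # (M, 3) interior, distance y from wall
    y: np.ndarray                  # (M,)
    sample_points_2: np.ndarray | None = None   # (M, 3) at distance 2y
    cell_size: float = 0.0

    def __post_init__(self) -> None:
        self.normals = np.asarray(self.normals, dtype=float)
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("wall normals must be unit length")
        self.y = np.asarray(self.y, dtype=float) * np.ones(len(self.face_centers))
        if np.any(self.y <= 0):
            raise ValueError("wall-normal sample distance y must be positive")


def pipe_wall_patch(a: float, length: float, n_theta: int = 64, n_x: int = 8,
                    y: float | None = None, x0: float = 0.0) -> WallPatch:
    """Wall patch of a circular pipe of radius ``a`` along +x."""
    if y is None:
        y = 0.01 * a
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    xs = np.linspace(x0, x0 + length, n_x)
    TH, X = np.meshgrid(theta, xs, indexing="ij")
    th, x = TH.ravel(), X.ravel()
    normals = np.column_stack([np.zeros_like(th), np.cos(th), np.sin(th)])
    centers = np.column_stack([x, a * np.cos(th), a * np.sin(th)])
    s1 = centers - y * normals
    s2 = centers - 2.0 * y * normals
    return WallPatch(face_centers=centers, normals=normals, sample_points=s1,
                     y=np.full(len(x), float(y)), sample_points_2=s2,
                     cell_size=2 * np.pi * a / n_theta)


@dataclass
class WSSField:
    """Wall shear stress vectors per face at one phase."""

    tau: np.ndarray                # (M, 3) Pa, tangent to the wall
    wall: WallPatch
    phase: float
    fluid: FluidProperties | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=1)


@dataclass
class TAWSSField:
    """Time-averaged WSS magnitude per face over one cycle (Pa)."""

    tawss: np.ndarray
    wall: WallPatch
    metadata: dict = field(default_factory=dict)


def _sample_velocity(snapshot: FlowSnapshot, pts: np.ndarray) -> np.ndarray:
    """Velocity at arbitrary points: exact lookup when the points coincide
    with snapshot points (point-cloud fixtures), trilinear interpolation on
    structured grids otherwise."""
    tree = cKDTree(snapshot.points)
    d, idx = tree.query(pts)
    scale = max(float(np.abs(snapshot.points).max()), 1.0)
    exact = d < 1e-9 * scale
    out = np.empty((len(pts), 3))
    out[exact] = snapshot.velocity[idx[exact]]
    rest = ~exact
    if np.any(rest):
        if not snapshot.structured:
            raise ValueError(
                f"{int(rest.sum())} sample points lie off the snapshot point "
                "cloud; supply a structured snapshot or matching samples")
        shape = snapshot.shape
        vel = snapshot.velocity.reshape(shape + (3,))
        for j in range(3):
            interp = RegularGridInterpolator(snapshot.axes, vel[..., j],
                                             bounds_error=True)
            out[rest, j] = interp(pts[rest])
    return out


def compute_wss(snapshot: FlowSnapshot, wall: WallPatch,
                fluid: FluidProperties, scheme: str = "one_point") -> WSSField:
    """Instantaneous WSS per wall face.

    one_point : ``tau = mu * u_t(y) / y`` (first-order one-sided derivative)
    two_point : ``tau = mu * (4 u_t(y) - u_t(2y)) / (2 y)`` (second order)

    The wall-normal velocity component is removed by tangent-plane
    projection, so ``tau`` is tangent to the wall by construction.
    """
    u1 = _sample_velocity(snapshot, wall.sample_points)
    if scheme == "one_point":
        dudy = u1 / wall.y[:, None]
    elif scheme == "two_point":
        if wall.sample_points_2 is None:
            raise ValueError("two_point scheme needs sample_points_2 on the patch")
        u2 = _sample_velocity(snapshot, wall.sample_points_2)
        dudy = (4.0 * u1 - u2) / (2.0 * wall.y[:, None])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    normal_part = np.einsum("ij,ij->i", dudy, wall.normals)
    dudy_t = dudy - normal_part[:, None] * wall.normals
    tau = fluid.mu * dudy_t
    return WSSField(tau=tau, wall=wall, phase=snapshot.phase, fluid=fluid,
                    metadata={"scheme": scheme, "rho": fluid.rho, "nu": fluid.nu})


def compute_tawss(wss_fields, T: float) -> TAWSSField:
    """Periodic trapezoidal time average of ``|tau_w|`` over one cycle.

    Phases must be uniformly spaced with the closing endpoint excluded
    (``t = 0, dt, ..., T - dt``); the periodic trapezoid rule then reduces
    to the plain mean over phases.
    """
    fields = list(wss_fields)
    if len(fields) == 1:
        return TAWSSField(tawss=fields[0].magnitude.copy(), wall=fields[0].wall)
    phases = np.array([f.phase for f in fields])
    d = np.diff(phases)
    if not (np.allclose(d, d[0], rtol=1e-6, atol=1e-12) and
            np.isclose(phases[-1] + d[0], phases[0] + 1.0, rtol=1e-6)):
        raise ValueError("WSS fields must uniformly cover exactly one period")
    mags = np.stack([f.magnitude for f in fields])
    return TAWSSField(tawss=mags.mean(axis=0), wall=fields[0].wall,
                      metadata={"n_phases": len(fields), "T": T})


def wss_vortex_overlap(wss: WSSField, regions, wall: WallPatch,
                       quantile: float = 0.8, distance: float | None = None,
                       warn: list | None = None) -> float:
    """Szymkiewicz-Simpson overlap between the high-WSS wall band and the
    wall footprint of the vortex regions.

    high set   : faces with ``|tau_w|`` above the ``quantile`` quantile
    footprint  : faces within ``distance`` of any region member point
    overlap    : ``|A & B| / min(|A|, |B|)`` in [0, 1]
    """
    if distance is None:
        distance = 2.0 * wall.cell_size if wall.cell_size > 0 else None
    if distance is None:
        raise ValueError("projection distance required (wall has no cell size)")
    mag = wss.magnitude
    cut = np.quantile(mag, quantile)
    high = np.flatnonzero(mag > cut)
    regions = list(regions)
    if len(regions) == 0 or len(high) == 0:
        if warn is not None:
            warn.append("empty vortex footprint or empty high-WSS set")
        return 0.0
    member_points = np.vstack([_region_points(reg) for reg in regions])
    tree = cKDTree(member_points)
    d, _ = tree.query(wall.face_centers)
    footprint = np.flatnonzero(d <= distance)
    if len(footprint) == 0:
        if warn is not None:
            warn.append("vortex regions project to no wall faces")
        return 0.0
    inter = len(np.intersect1d(high, footprint, assume_unique=True))
    return inter / min(len(high), len(footprint))


def _region_points(region) -> np.ndarray:
    """Member coordinates of a VortexRegion, or a raw (N, 3) point array."""
    if hasattr(region, "points"):
        return np.asarray(region.points, dtype=float)
    return np.asarray(region, dtype=float).reshape(-1, 3)
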