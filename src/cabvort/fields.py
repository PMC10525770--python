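"""In-memory containers for time-resolved flow fields.

A :class:`FlowSnapshot` holds one instant of a 3D velocity/pressure field,
either on a structured Cartesian grid (axes stored, enabling finite-difference
stencils and fast interpolation) or on an arbitrary point cloud.  A
:class:`FlowSeries` is an ordered, uniformly sampled sequence of snapshots
covering exactly one cardiac period, phases ``t/T`` in ``[0, 1)``.

Synthetic generators attach machine-readable ground truth (analytic wall
shear, prescribed core trajectories, filament geometry, ...) in the
``ground_truth`` dict so downstream analyses can be verified against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class FlowSnapshot:
    """One instant of a 3D flow field.

    Parameters
    ----------
    points : (N, 3) float array
        Sample coordinates in meters.
    velocity : (N, 3) float array
        Velocity vectors ``(u, v, w)`` in m/s.
    pressure : (N,) float array
        Static pressure in Pa.
    t : float
        Time in seconds.
    period : float
        Cardiac period ``T`` in seconds (``phase = t / T``).
    axes : optional tuple of three 1D arrays
        Grid axes when the snapshot is a structured box; ``points`` then
        corresponds to ``meshgrid(*axes, indexing='ij')`` raveled in C order.
    mask : optional (N,) bool array
        ``True`` where the point lies in the fluid domain.  Points outside
        (e.g. corners of a box bounding a pipe) carry zero velocity and are
        excluded from analyses.
    """

    points: np.ndarray
    velocity: np.ndarray
    pressure: np.ndarray
    t: float
    period: float = 1.0
    axes: Optional[tuple] = None
    mask: Optional[np.ndarray] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        n = self.points.shape[0]
        if self.points.shape != (n, 3):
            raise ValueError("points must have shape (N, 3)")
        if self.velocity.shape != (n, 3):
            raise ValueError("velocity must have one vector per point")
        if self.pressure.shape != (n,):
            raise ValueError("pressure must have one value per point")
        if not (np.all(np.isfinite(self.velocity)) and np.all(np.isfinite(self.pressure))):
            raise ValueError("velocity/pressure must be finite everywhere")
        if self.axes is not None:
            shape = tuple(len(a) for a in self.axes)
            if int(np.prod(shape)) != n:
                raise ValueError("axes inconsistent with number of points")

    @property
    def phase(self) -> float:
        """Phase ``t/T`` in ``[0, 1)``."""
        return (self.t / self.period) % 1.0

    @property
    def shape(self) -> Optional[tuple]:
        """Structured grid shape, or None for point clouds."""
        if self.axes is None:
            return None
        return tuple(len(a) for a in self.axes)

    @property
    def structured(self) -> bool:
        return self.axes is not None

    @property
    def spacing(self) -> Optional[tuple]:
        """Grid spacing per axis (requires uniform axes)."""
        if self.axes is None:
            return None
        return tuple(float(a[1] - a[0]) if len(a) > 1 else 0.0 for a in self.axes)

    def field_on_grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-point array onto the structured grid."""
        if self.axes is None:
            raise ValueError("snapshot is not structured")
        return np.asarray(values).reshape(self.shape + np.asarray(values).shape[1:])


def structured_snapshot(axes, velocity, pressure, t, period=1.0, mask=None,
                        ground_truth=None) -> FlowSnapshot:
    """Build a snapshot from grid axes and (nx, ny, nz, ...) field arrays."""
    xs, ys, zs = (np.asarray(a, dtype=float) for a in axes)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vel = np.asarray(velocity, dtype=float).reshape(-1, 3)
    p = np.asarray(pressure, dtype=float).ravel()
    m = None if mask is None else np.asarray(mask, dtype=bool).ravel()
    return FlowSnapshot(pts, vel, p, t=t, period=period, axes=(xs, ys, zs),
                        mask=m, ground_truth=ground_truth or {})


@dataclass
class FlowSeries:
    """Uniformly sampled periodic sequence of snapshots over one period.

    Snapshots cover ``t = 0, dt, ..., T - dt``; the closing sample at
    ``t = T`` is identified with the first one (periodicity).
    """

    snapshots: list
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.snapshots) < 2:
            raise ValueError("a series needs at least two snapshots")
        t = np.array([s.t for s in self.snapshots])
        if not np.all(np.diff(t) > 0):
            raise ValueError("snapshot times must be strictly increasing")
        T = self.snapshots[0].period
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("snapshots must be uniformly spaced in time")
        # periodic closure: last sample is one step short of t0 + T
        if not np.isclose(t[-1] - t[0] + dt[0], T, rtol=1e-8):
            raise ValueError("series must cover exactly one period (endpoint excluded)")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i):
        return self.snapshots[i]

    @property
    def period(self) -> float:
        return self.snapshots[0].period

    @property
    def dt(self) -> float:
        return self.snapshots[1].t - self.snapshots[0].t

    @property
    def phases(self) -> np.ndarray:
        return np.array([s.phase for s in self.snapshots])
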