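"""Wall pressure-minimum vortex-core tracking in the sinus frame.

The origin of the sinus hairpin vortex is a local pressure minimum on the
vessel wall.  A reduced field of view (search window, stationary or advected
with the bulk flow) restricts the candidate points; the core is the
minimum-pressure candidate each phase.  Its path, expressed through the
axial sinus coordinate ``xi(t)``, is differentiated to core velocity and
acceleration, and kinematic events (stillstand, onset of upstream motion,
trajectory end) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .fields import FlowSeries, FlowSnapshot

__all__ = ["SearchWindow", "CoreTrajectory", "locate_core", "track_core",
           "trajectory_kinematics"]


@dataclass
class SearchWindow:
    """Axis-aligned box in sinus-frame coordinates.

    mode 'stationary' keeps the box fixed; 'advected' translates it along
    the axial direction with the instantaneous bulk (cross-section mean)
    velocity, or with ``advection_velocity`` if given explicitly.
    """

    bounds: np.ndarray                 # (2, 3): [lo, hi] in frame coords
    mode: str = "stationary"
    advection_velocity: float | None = None   # m/s along the axial direction

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.shape != (2, 3):
            raise ValueError("bounds must be a (2, 3) [lo, hi] array")
        if np.any(self.bounds[1] <= self.bounds[0]):
            raise ValueError("window extents must be positive")
        if self.mode not in ("stationary", "advected"):
            raise ValueError("mode must be 'stationary' or 'advected'")

    def contains(self, coords: np.ndarray, axial_offset: float = 0.0):
        lo = self.bounds[0] + np.array([axial_offset, 0.0, 0.0])
        hi = self.bounds[1] + np.array([axial_offset, 0.0, 0.0])
        return np.all((coords >= lo) & (coords <= hi), axis=1)


@dataclass
class CoreTrajectory:
    """Tracked wall pressure-minimum path in the sinus frame."""

    phases: np.ndarray                 # t/T, strictly increasing
    positions: np.ndarray              # (n, 3) lab coordinates (m)
    xi: np.ndarray                     # (n,) axial sinus coordinate (m)
    pressure: np.ndarray               # (n,) Pa
    p_over_P0: np.ndarray              # nondimensional core pressure
    period: float
    truncated_at: float | None = None  # phase where the core was lost
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd
        v, a, _ = trajectory_kinematics(self, smooth_window=self.metadata.get(
            "smooth_window", 3))
        return pd.DataFrame({
            "t_over_T": self.phases, "xi_m": self.xi,
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2], "p_Pa": self.pressure,
            "p_over_P0": self.p_over_P0, "v_m_per_s": v, "a_m_per_s2": a})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _candidates(snapshot: FlowSnapshot, frame, window: SearchWindow,
                axial_offset: float, wall=None, wall_tol: float | None = None):
    coords = frame.to_frame(snapshot.points)
    sel = window.contains(coords, axial_offset)
    if snapshot.mask is not None:
        sel &= snapshot.mask
    if wall is not None:
        tol = wall_tol if wall_tol is not None else 2.0 * max(wall.cell_size, 0.0)
        if tol <= 0:
            raise ValueError("wall-restricted search needs a positive tolerance")
        tree = cKDTree(wall.face_centers)
        d, _ = tree.query(snapshot.points)
        sel &= d <= tol
    return np.flatnonzero(sel), coords


def locate_core(snapshot: FlowSnapshot, window: SearchWindow, frame,
                wall=None, wall_tol: float | None = None,
                axial_offset: float = 0.0, prev_position=None,
                warn: list | None = None):
    """Minimum-pressure point among the window candidates.

    Ties are broken deterministically: nearest to the previous core
    position, or most upstream (smallest xi) at the first frame.  Returns
    ``(point, pressure, index)``.
    """
    idx, coords = _candidates(snapshot, frame, window, axial_offset, wall,
                              wall_tol)
    if len(idx) == 0:
        raise ValueError("search window contains no candidate points")
    p = snapshot.pressure[idx]
    pmin = p.min()
    if len(idx) > 1 and np.all(p == p[0]):
        if warn is not None:
            warn.append(f"all-equal pressure at phase {snapshot.phase:.4f}; "
                        "returning most-upstream candidate")
        winners = idx
    else:
        winners = idx[p <= pmin]
    if len(winners) > 1:
        if prev_position is not None:
            d = np.linalg.norm(snapshot.points[winners] - prev_position, axis=1)
            winners = winners[d <= d.min()]
        if len(winners) > 1:
            xi = coords[winners, 0]
            winners = winners[np.argsort(xi, kind="stable")]
    best = int(winners[0])
    return snapshot.points[best], float(snapshot.pressure[best]), best


def _bulk_axial_velocity(snapshot: FlowSnapshot, frame, window, offset) -> float:
    coords = frame.to_frame(snapshot.points)
    sel = window.contains(coords, offset)
    if snapshot.mask is not None:
        sel &= snapshot.mask
    if not np.any(sel):
        return 0.0
    return float((snapshot.velocity[sel] @ frame.axial_unit).mean())


def track_core(series: FlowSeries, window: SearchWindow, frame, wall=None,
               wall_tol: float | None = None, P0: float | None = None,
               P0_phase: float = 0.191, k_missing: int = 3,
               phase_range: tuple | None = None,
               log: list | None = None) -> CoreTrajectory:
    """Track the pressure-minimum core over the cycle.

    The window advects per its mode; trajectory continuity comes from the
    nearest-to-previous tie-break.  Core pressure is nondimensionalized by
    ``P0`` (explicit value, or the tracked core pressure at the reference
    phase, default ``t/T = 0.191``).  If the core cannot be located for more
    than ``k_missing`` consecutive frames the trajectory is truncated and
    the end phase logged (structure deterioration).  ``phase_range`` limits
    tracking to the phases where the structure of interest exists (as first
    identified by the lambda2 stage).
    """
    dt = series.dt
    offset = 0.0
    phases, pos, press = [], [], []
    prev = None
    missing = 0
    truncated_at = None
    for snap in series:
        if phase_range is not None and not (
                phase_range[0] - 1e-12 <= snap.phase <= phase_range[1] + 1e-12):
            continue
        if window.mode == "advected":
            v = (window.advection_velocity if window.advection_velocity is not None
                 else _bulk_axial_velocity(snap, frame, window, offset))
            if prev is not None:
                offset += v * dt
        try:
            point, p, _ = locate_core(snap, window, frame, wall=wall,
                                      wall_tol=wall_tol, axial_offset=offset,
                                      prev_position=prev)
            # a minimum pinned to the window's axial boundary means the true
            # minimum has left the field of view: treat the core as missing
            if snap.structured:
                tol = 0.55 * snap.spacing[0]
                xi_pt = float(frame.xi(point))
                if (xi_pt >= window.bounds[1][0] + offset - tol
                        or xi_pt <= window.bounds[0][0] + offset + tol):
                    raise ValueError("core at window boundary")
        except ValueError:
            missing += 1
            if missing > k_missing and len(phases) > 0:
                truncated_at = snap.phase
                if log is not None:
                    log.append(f"core lost for {missing} frames; trajectory "
                               f"truncated at phase {snap.phase:.4f}")
                break
            continue
        missing = 0
        prev = point
        phases.append(snap.phase)
        pos.append(point)
        press.append(p)
    if len(phases) == 0:
        raise ValueError("no core could be located in any frame")
    phases = np.asarray(phases)
    pos = np.asarray(pos)
    press = np.asarray(press)
    if P0 is None:
        j = int(np.argmin(np.abs(phases - P0_phase)))
        P0 = press[j] if press[j] != 0.0 else 1.0
    xi = frame.xi(pos)
    return CoreTrajectory(phases=phases, positions=pos, xi=np.asarray(xi),
                          pressure=press, p_over_P0=press / P0,
                          period=series.period, truncated_at=truncated_at,
                          metadata={"P0": float(P0), "mode": window.mode})


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    if w % 2 == 0:
        raise ValueError("smoothing window must be odd")
    pad = w // 2
    xp = np.concatenate([x[:1].repeat(pad), x, x[-1:].repeat(pad)])
    kernel = np.ones(w) / w
    return np.convolve(xp, kernel, mode="valid")


def trajectory_kinematics(traj: CoreTrajectory, smooth_window: int = 3):
    """Central-difference velocity and acceleration of ``xi(t)`` with
    optional moving-average pre-smoothing; detected events:

    - 'stillstand'      : zero crossing of the core velocity
    - 'upstream_onset'  : velocity sign change + -> - (upstream motion)
    - 'deterioration'   : truncated trajectory end

    Returns ``(velocity, acceleration, events)``; event phases are linear
    interpolations between samples.
    """
    if len(traj.phases) < 3:
        raise ValueError("kinematics needs at least 3 phases")
    t = traj.phases * traj.period
    xi = _smooth(traj.xi, smooth_window)
    v = np.gradient(xi, t, edge_order=2)
    a = np.gradient(v, t, edge_order=2)
    events = []
    s = np.sign(v)
    last_sign, last_idx = 0, 0
    for i, si in enumerate(s):
        if si == 0:
            # exact standstill sample
            events.append({"event": "stillstand",
                           "phase": float(traj.phases[i])})
            continue
        if last_sign != 0 and si != last_sign:
            f = v[last_idx] / (v[last_idx] - v[i])
            phase = traj.phases[last_idx] + f * (traj.phases[i]
                                                 - traj.phases[last_idx])
            events.append({"event": "stillstand", "phase": float(phase)})
            if last_sign > 0 and si < 0:
                events.append({"event": "upstream_onset",
                               "phase": float(phase)})
        last_sign, last_idx = si, i
    if traj.truncated_at is not None:
        events.append({"event": "deterioration", "phase": float(traj.truncated_at)})
    return v, a, events
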