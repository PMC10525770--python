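"""Analytic velocity/pressure fields with attached ground truth.

These generators emulate the features of pulsatile carotid-bifurcation CFD
data that the downstream analyses consume — steady and pulsatile (Womersley)
pipe flow, isolated vortex tubes, a hairpin-shaped vortex filament, and
pressure minima advecting along a wall — with every field carrying
machine-readable ground truth (analytic wall shear, prescribed trajectories,
filament geometry) so each analysis stage can be verified independently.

All fields are exact solutions or exact constructions; no Navier-Stokes
solver is involved.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from scipy.special import erf, jv

from .boundary import BLOOD_ANALOG, FluidProperties, InflowWaveform
from .fields import FlowSeries, FlowSnapshot, structured_snapshot

__all__ = [
    "box_grid", "pipe_point_grid", "poiseuille_snapshot", "womersley_series",
    "womersley_number", "vortex_tube_field", "hairpin_filament",
    "hairpin_field", "moving_min_series", "divergence",
]


# ---------------------------------------------------------------------------
# grids

def box_grid(bounds, shape):
    """Structured Cartesian axes for a box ``bounds = ((x0,x1),(y0,y1),(z0,z1))``."""
    return tuple(np.linspace(lo, hi, n) for (lo, hi), n in zip(bounds, shape))


def pipe_point_grid(a: float, length: float, n_x: int = 5, n_r: int = 64,
                    n_theta: int = 32, extra_radii=None) -> np.ndarray:
    """Point cloud filling a circular pipe of radius ``a`` along +x.

    Radial stations are sine-clustered toward the wall, where pulsatile
    boundary layers live; ``extra_radii`` inserts exact sample radii (used by
    wall patches so no interpolation error enters wall-shear checks).
    """
    if a <= 0:
        raise ValueError("pipe radius must be positive")
    j = np.arange(1, n_r + 1)
    radii = a * np.sin(0.5 * np.pi * j / n_r)
    if extra_radii is not None:
        radii = np.unique(np.concatenate([radii, np.asarray(extra_radii, float)]))
        radii = radii[(radii > 0) & (radii <= a)]
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    xs = np.linspace(0.0, length, n_x)
    R, TH, X = np.meshgrid(radii, theta, xs, indexing="ij")
    pts = np.column_stack([X.ravel(), (R * np.cos(TH)).ravel(),
                           (R * np.sin(TH)).ravel()])
    axis_pts = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
    return np.vstack([axis_pts, pts])


def _grid_points(grid):
    """Normalize a grid argument: axes tuple -> (points, axes, mask_fn hook)."""
    if isinstance(grid, tuple) and len(grid) == 3:
        xs, ys, zs = (np.asarray(a, dtype=float) for a in grid)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        return pts, (xs, ys, zs)
    pts = np.asarray(grid, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("grid must be an axes 3-tuple or an (N, 3) point array")
    return pts, None


# ---------------------------------------------------------------------------
# pipe flows

def poiseuille_snapshot(a: float, U_mean: float, fluid: FluidProperties = BLOOD_ANALOG,
                        grid=None, t: float = 0.0, period: float = 1.0,
                        p0: float = 0.0) -> FlowSnapshot:
    """Steady Hagen-Poiseuille pipe flow along +x.

    ``u(r) = 2 U_mean (1 - r^2/a^2)``, ``dp/dx = -8 mu U_mean / a^2``
    (favorable, negative for forward flow); analytic wall shear magnitude
    ``4 mu U_mean / a`` attached as ground truth.  Grid points outside the
    pipe are masked out, not an error.
    """
    if a <= 0:
        raise ValueError("pipe radius must be positive")
    if grid is None:
        grid = pipe_point_grid(a, length=10 * a)
    pts, axes = _grid_points(grid)
    r2 = pts[:, 1] ** 2 + pts[:, 2] ** 2
    inside = r2 <= a * a * (1 + 1e-12)
    u = np.zeros(len(pts))
    u[inside] = 2.0 * U_mean * (1.0 - r2[inside] / a ** 2)
    vel = np.column_stack([u, np.zeros_like(u), np.zeros_like(u)])
    dpdx = -8.0 * fluid.mu * U_mean / a ** 2
    p = p0 + dpdx * pts[:, 0]
    gt = {"wall_shear": 4.0 * fluid.mu * U_mean / a, "dpdx": dpdx,
          "a": a, "U_mean": U_mean}
    return FlowSnapshot(pts, vel, p, t=t, period=period, axes=axes,
                        mask=inside, ground_truth=gt)


def womersley_number(a: float, T: float, nu: float) -> float:
    """Womersley number ``alpha = a * sqrt(2 pi / (T nu))`` of the
    fundamental cardiac harmonic."""
    return a * np.sqrt(2.0 * np.pi / (T * nu))


def _womersley_profile_coeffs(modes: np.ndarray, a: float, T: float, nu: float):
    """Per-mode radial profile and wall-derivative factors.

    For mean-velocity mode ``Utilde_k e^{i omega_k t}`` the velocity profile
    is ``Utilde_k f_k(r)`` with cross-sectional mean of ``f_k`` equal to 1:

        f_0(r) = 2 (1 - r^2/a^2)
        f_k(r) = (1 - J0(L r/a)/J0(L)) / (1 - 2 J1(L)/(L J0(L))),
                 L = i^{3/2} alpha_k,  alpha_k = a sqrt(k omega / nu)

    Returns (profiles, dfdr_wall) where profiles[k] is a callable of r.
    """
    omega = 2.0 * np.pi / T
    i32 = np.exp(0.75j * np.pi)  # i^{3/2}
    profiles, dwall = [], []
    for k in range(len(modes)):
        if k == 0:
            profiles.append(lambda r: 2.0 * (1.0 - (r / a) ** 2))
            dwall.append(-4.0 / a)
            continue
        alpha_k = a * np.sqrt(k * omega / nu)
        lam = i32 * alpha_k
        j0 = jv(0, lam)
        denom = 1.0 - 2.0 * jv(1, lam) / (lam * j0)

        def f(r, lam=lam, j0=j0, denom=denom):
            return (1.0 - jv(0, lam * np.asarray(r) / a) / j0) / denom

        profiles.append(f)
        dwall.append((lam / a) * jv(1, lam) / j0 / denom)
    return profiles, np.asarray(dwall, dtype=complex)


def womersley_series(a: float, waveform: InflowWaveform,
                     fluid: FluidProperties = BLOOD_ANALOG, grid=None,
                     n_steps: int = 200, p_ref: float = 0.0,
                     truncation_tol: float = 1e-10) -> FlowSeries:
    """Exact unsteady axisymmetric pipe flow matching the waveform's
    cross-sectional mean velocity, mode by mode.

    Attaches as ground truth the Womersley number, the analytic wall shear
    time trace (``tau(t) = -mu du/dr|_{r=a}``, positive for forward flow),
    and the per-mode pressure-gradient amplitudes.
    """
    if a <= 0:
        raise ValueError("pipe radius must be positive")
    T, nu = waveform.T, fluid.nu
    modes = waveform.fourier_modes()
    metadata = {}
    tail = np.abs(modes[-1]) / max(np.abs(modes).max(), 1e-300)
    if tail > truncation_tol:
        metadata["truncation_warning"] = (
            f"last retained Fourier mode has relative amplitude {tail:.2e}")
    profiles, dwall = _womersley_profile_coeffs(modes, a, T, nu)
    omega = 2.0 * np.pi / T

    if grid is None:
        grid = pipe_point_grid(a, length=10 * a)
    pts, axes = _grid_points(grid)
    r = np.sqrt(pts[:, 1] ** 2 + pts[:, 2] ** 2)
    inside = r <= a * (1 + 1e-12)
    rin = np.minimum(r, a)

    # pressure-gradient amplitude per mode (dp/dx = Re{P_k e^{i omega k t}})
    P = np.zeros(len(modes), dtype=complex)
    P[0] = -8.0 * fluid.mu * modes[0].real / a ** 2
    for k in range(1, len(modes)):
        i32 = np.exp(0.75j * np.pi)
        lam = i32 * a * np.sqrt(k * omega / nu)
        denom = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
        P[k] = -1j * fluid.rho * (k * omega) * modes[k] / denom

    prof_at_r = np.column_stack([np.asarray(f(rin), dtype=complex) for f in profiles])

    times = np.arange(n_steps) * (T / n_steps)
    shear_trace = np.empty(n_steps)
    snaps = []
    for j, t in enumerate(times):
        phases = np.exp(1j * omega * np.arange(len(modes)) * t)
        u = (prof_at_r * (modes * phases)).sum(axis=1).real
        u[~inside] = 0.0
        dudr_wall = float((modes * dwall * phases).sum().real)
        tau = -fluid.mu * dudr_wall
        shear_trace[j] = tau
        dpdx = float((P * phases).sum().real)
        p = p_ref + dpdx * pts[:, 0]
        vel = np.column_stack([u, np.zeros_like(u), np.zeros_like(u)])
        gt = {"wall_shear": tau, "dpdx": dpdx, "a": a}
        snaps.append(FlowSnapshot(pts, vel, p, t=float(t), period=T, axes=axes,
                                  mask=inside, ground_truth=gt))
    alpha = womersley_number(a, T, nu)

    def analytic_wall_shear(t):
        t = np.asarray(t, dtype=float)
        ph = np.exp(1j * omega * np.multiply.outer(np.arange(len(modes)), t))
        return -fluid.mu * np.tensordot(modes * dwall, ph, axes=(0, 0)).real

    gt = {"alpha": alpha, "wall_shear_trace": shear_trace, "times": times,
          "wall_shear_fn": analytic_wall_shear, "pressure_modes": P,
          "fluid": fluid, **metadata}
    return FlowSeries(snaps, ground_truth=gt)


# ---------------------------------------------------------------------------
# vortex constructions

def _lamb_oseen_utheta(r, gamma, r_c):
    """Azimuthal Lamb-Oseen velocity with a finite r -> 0 limit."""
    r = np.asarray(r, dtype=float)
    out = np.empty_like(r)
    small = r < 1e-12 * r_c
    rs = np.where(small, 1.0, r)
    out = gamma / (2.0 * np.pi * rs) * (1.0 - np.exp(-rs ** 2 / r_c ** 2))
    out[small] = gamma * r[small] / (2.0 * np.pi * r_c ** 2)
    return out


def _lamb_oseen_pressure_spline(gamma, r_c, r_max, rho):
    """p(r) from radial momentum balance, p(inf) = 0, by quadrature of
    ``rho u_theta^2 / r`` plus the analytic far-field tail."""
    rr = np.linspace(1e-6 * r_c, max(r_max, 10 * r_c), 4000)
    integrand = rho * _lamb_oseen_utheta(rr, gamma, r_c) ** 2 / rr
    cum = cumulative_trapezoid(integrand, rr, initial=0.0)
    tail = rho * (gamma / (2.0 * np.pi)) ** 2 / (2.0 * rr[-1] ** 2)
    p = -(cum[-1] - cum + tail)
    return CubicSpline(rr, p)


def vortex_tube_field(kind: str, grid, gamma: float | None = None,
                      omega: float | None = None, shear_rate: float | None = None,
                      r_c: float | None = None, center=(0.0, 0.0),
                      axis: str = "x", fluid: FluidProperties = BLOOD_ANALOG,
                      t: float = 0.0, period: float = 1.0) -> FlowSnapshot:
    """Canonical velocity-gradient test fields on a structured grid.

    kind = 'lamb_oseen' : tube of circulation ``gamma`` and core ``r_c``
    around ``axis``; pressure from radial-momentum quadrature, p(inf) = 0.
    kind = 'rigid_rotation' : solid-body rotation ``u_theta = omega r``.
    kind = 'simple_shear' : unidirectional shear ``u = (shear_rate * y, 0, 0)``.
    """
    pts, axes = _grid_points(grid)
    idx = {"x": 0, "y": 1, "z": 2}[axis]
    i1, i2 = [i for i in range(3) if i != idx]
    y1 = pts[:, i1] - center[0]
    y2 = pts[:, i2] - center[1]
    r = np.hypot(y1, y2)
    vel = np.zeros_like(pts)
    p = np.zeros(len(pts))
    gt: dict = {"kind": kind, "axis": axis, "center": tuple(center)}
    if kind == "lamb_oseen":
        if gamma is None or r_c is None or r_c <= 0:
            raise ValueError("lamb_oseen needs circulation gamma and core r_c > 0")
        uth = _lamb_oseen_utheta(r, gamma, r_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            ct = np.where(r > 0, y1 / np.where(r > 0, r, 1.0), 1.0)
            st = np.where(r > 0, y2 / np.where(r > 0, r, 1.0), 0.0)
        vel[:, i1] = -uth * st
        vel[:, i2] = uth * ct
        spl = _lamb_oseen_pressure_spline(gamma, r_c, float(r.max()), fluid.rho)
        p = spl(np.maximum(r, 1e-6 * r_c))
        gt.update(gamma=gamma, r_c=r_c)
    elif kind == "rigid_rotation":
        if omega is None:
            raise ValueError("rigid_rotation needs angular velocity omega")
        vel[:, i1] = -omega * y2
        vel[:, i2] = omega * y1
        p = 0.5 * fluid.rho * omega ** 2 * r ** 2
        gt.update(omega=omega, lambda2=-omega ** 2)
    elif kind == "simple_shear":
        if shear_rate is None:
            raise ValueError("simple_shear needs shear_rate")
        vel[:, 0] = shear_rate * pts[:, 1]
        gt.update(shear_rate=shear_rate, lambda2=0.0)
    else:
        raise ValueError(f"unknown vortex field kind: {kind!r}")
    return FlowSnapshot(pts, vel, p, t=t, period=period, axes=axes,
                        ground_truth=gt)


def hairpin_filament(width: float, height: float, leg_length: float,
                     n: int = 257) -> np.ndarray:
    """Parametric hairpin (Lambda-shaped) filament: two streamwise legs
    separated by ``width`` joined by a semicircular head lifted to
    ``height``.  Open polyline, (n, 3), axis along +x."""
    n_leg = n // 3
    n_head = n - 2 * n_leg
    y0 = width / 2.0
    # leg 1: from upstream toward the head, at z ramping up to height
    s = np.linspace(0.0, 1.0, n_leg, endpoint=False)
    leg1 = np.column_stack([-leg_length * (1 - s), -y0 * np.ones(n_leg),
                            height * s ** 2])
    phi = np.linspace(-np.pi / 2, np.pi / 2, n_head)
    head = np.column_stack([y0 * np.cos(phi), y0 * np.sin(phi),
                            height + 0.0 * phi])
    s2 = np.linspace(1.0, 0.0, n_leg)
    s2 = s2[:-1] if n_leg > 1 else s2
    leg2 = np.column_stack([-leg_length * (1 - s2), y0 * np.ones(len(s2)),
                            height * s2 ** 2])
    return np.vstack([leg1, head, leg2])


def _biot_savart(points: np.ndarray, filament: np.ndarray, gamma: float,
                 r_c: float, chunk: int = 2048) -> np.ndarray:
    """Regularized Biot-Savart sum over filament segments.

    Gaussian (spherical) core smoothing with sigma = r_c / sqrt(2); the
    induced field of a straight filament is then exactly the Lamb-Oseen
    profile with core radius ``r_c``.
    """
    seg = np.diff(filament, axis=0)           # (M, 3)
    mid = 0.5 * (filament[:-1] + filament[1:])
    out = np.zeros_like(points)
    pref = gamma / (4.0 * np.pi)
    for lo in range(0, len(points), chunk):
        P = points[lo:lo + chunk]
        rvec = P[:, None, :] - mid[None, :, :]          # (n, M, 3)
        dist = np.linalg.norm(rvec, axis=2)
        rho = dist / r_c
        q = erf(rho) - (2.0 / np.sqrt(np.pi)) * rho * np.exp(-rho ** 2)
        d3 = np.maximum(dist, 1e-300) ** 3
        cross = np.cross(np.broadcast_to(seg[None, :, :], rvec.shape), rvec)
        out[lo:lo + chunk] = pref * np.einsum("nm,nmk->nk", q / d3, cross)
    return out


def hairpin_field(filament: np.ndarray, gamma: float, r_c: float, grid,
                  background=(0.0, 0.0, 0.0), t: float = 0.0,
                  period: float = 1.0, quad_tol: float = 1e-8,
                  max_refine: int = 6) -> FlowSnapshot:
    """Velocity induced by a vortex filament plus a uniform background flow.

    The filament is refined (segment halving) until the maximum pointwise
    velocity change is below ``quad_tol`` (m/s); non-convergence raises with
    a step-size report.  The true filament polyline is attached as ground
    truth.
    """
    filament = np.asarray(filament, dtype=float)
    if r_c <= 0:
        raise ValueError("core radius must be positive")
    pts, axes = _grid_points(grid)
    bg = np.asarray(background, dtype=float)
    if gamma == 0.0:
        vel = np.tile(bg, (len(pts), 1))
        return FlowSnapshot(pts, vel, np.zeros(len(pts)), t=t, period=period,
                            axes=axes, ground_truth={"filament": filament,
                                                     "gamma": 0.0, "r_c": r_c})
    cur = filament
    prev = _biot_savart(pts, cur, gamma, r_c)
    err = np.inf
    for _ in range(max_refine):
        fine = np.empty((2 * len(cur) - 1, 3))
        fine[0::2] = cur
        fine[1::2] = 0.5 * (cur[:-1] + cur[1:])
        new = _biot_savart(pts, fine, gamma, r_c)
        err = float(np.abs(new - prev).max())
        cur, prev = fine, new
        if err < quad_tol:
            break
    else:
        h = float(np.linalg.norm(np.diff(cur, axis=0), axis=1).max())
        raise RuntimeError(
            f"Biot-Savart quadrature did not converge: last change {err:.3e} "
            f"m/s at segment length {h:.3e} m")
    vel = prev + bg
    gt = {"filament": filament, "gamma": gamma, "r_c": r_c,
          "quad_error": err, "n_segments": len(cur) - 1}
    return FlowSnapshot(pts, vel, np.zeros(len(pts)), t=t, period=period,
                        axes=axes, ground_truth=gt)


# ---------------------------------------------------------------------------
# moving pressure-minimum series (core-tracking oracle)

def moving_min_series(trajectory, grid, n_steps: int, T: float = 1.0,
                      depth: float = 10.0, width: float = 1e-3,
                      background_pressure=0.0, bulk_velocity=(0.0, 0.0, 0.0),
                      velocity_fn=None) -> FlowSeries:
    """Series whose pressure is a background minus a Gaussian well centered
    on a prescribed trajectory; the tracking stage must recover it.

    ``trajectory`` is a callable ``t -> (3,)`` position (or an (n_steps, 3)
    array); ``velocity_fn`` optionally supplies the analytic trajectory
    velocity for the ground truth.  The well must stay inside the grid at
    every step.
    """
    pts, axes = _grid_points(grid)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    times = np.arange(n_steps) * (T / n_steps)
    if callable(trajectory):
        centers = np.array([np.asarray(trajectory(t), dtype=float) for t in times])
    else:
        centers = np.asarray(trajectory, dtype=float)
        if centers.shape != (n_steps, 3):
            raise ValueError("trajectory array must have shape (n_steps, 3)")
    if np.any(centers < lo) or np.any(centers > hi):
        raise ValueError("prescribed well trajectory exits the grid")
    bulk = np.asarray(bulk_velocity, dtype=float)
    snaps = []
    for t, c in zip(times, centers):
        pbg = background_pressure(pts, t) if callable(background_pressure) \
            else float(background_pressure)
        d2 = np.sum((pts - c) ** 2, axis=1)
        p = pbg - depth * np.exp(-d2 / (2.0 * width ** 2))
        vel = np.tile(bulk, (len(pts), 1))
        snaps.append(FlowSnapshot(pts, vel, p, t=float(t), period=T, axes=axes,
                                  ground_truth={"well_center": c}))
    if velocity_fn is not None:
        true_vel = np.array([np.asarray(velocity_fn(t), dtype=float) for t in times])
    else:
        true_vel = np.gradient(centers, times, axis=0)
    gt = {"trajectory": centers, "times": times, "trajectory_velocity": true_vel,
          "depth": depth, "width": width}
    return FlowSeries(snaps, ground_truth=gt)


# ---------------------------------------------------------------------------
# checks

def divergence(snapshot: FlowSnapshot) -> np.ndarray:
    """Numerical divergence of a structured snapshot (central differences)."""
    if not snapshot.structured:
        raise ValueError("divergence check requires a structured snapshot")
    xs, ys, zs = snapshot.axes
    shape = snapshot.shape
    vel = snapshot.velocity.reshape(shape + (3,))
    div = (np.gradient(vel[..., 0], xs, axis=0, edge_order=2)
           + np.gradient(vel[..., 1], ys, axis=1, edge_order=2)
           + np.gradient(vel[..., 2], zs, axis=2, edge_order=2))
    return div.ravel()
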