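"""Secondary-flow decomposition on centerline-perpendicular planes and the
axial pressure-gradient trace over the ICA sinus.

Secondary flow is the in-plane velocity on planes perpendicular to the local
centerline tangent; vessel curvature drives counter-rotating (Dean-type)
vortex pairs visible in the in-plane vorticity.  The axial pressure gradient
``dP/dxi`` over the sinus is the area-averaged pressure difference between
the sinus exit and entry stations divided by the sinus length; negative
values are favorable (flow-driving), positive values adverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import find_peaks

from .fields import FlowSeries, FlowSnapshot

__all__ = [
    "CrossSectionPlane", "SecondaryField", "AxialGradientTrace",
    "planes_along_axis", "sinus_planes", "slice_and_decompose",
    "count_vortex_pairs", "axial_pressure_gradient_trace", "classify_extrema",
    "percent_differences",
]


@dataclass
class CrossSectionPlane:
    """A sampling plane perpendicular to the local centerline tangent.

    Samples form a square (m x m) in-plane grid over [-radius, radius]^2
    with a circular mask; plane index 1 is the most upstream.
    """

    index: int
    center: np.ndarray
    normal: np.ndarray
    basis: np.ndarray                  # (2, 3) in-plane orthonormal
    radius: float
    n_grid: int = 41

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        self.normal /= np.linalg.norm(self.normal)
        self.center = np.asarray(self.center, dtype=float)

    @property
    def grid_1d(self) -> np.ndarray:
        return np.linspace(-self.radius, self.radius, self.n_grid)

    def sample_points(self):
        g = self.grid_1d
        U, V = np.meshgrid(g, g, indexing="ij")
        pts = (self.center + U.ravel()[:, None] * self.basis[0]
               + V.ravel()[:, None] * self.basis[1])
        mask = (U.ravel() ** 2 + V.ravel() ** 2) <= self.radius ** 2
        return pts, mask


def _plane_basis(normal: np.ndarray) -> np.ndarray:
    n = normal / np.linalg.norm(normal)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ref, n)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return np.vstack([e1, e2])


def planes_along_axis(origin, axis, stations, radius, n_grid: int = 41) -> list:
    """Planes perpendicular to a straight axis at the given arc stations."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    basis = _plane_basis(axis)
    origin = np.asarray(origin, dtype=float)
    return [CrossSectionPlane(index=i + 1, center=origin + s * axis,
                              normal=axis, basis=basis, radius=radius,
                              n_grid=n_grid)
            for i, s in enumerate(stations)]


def sinus_planes(geom, n_planes: int = 6, radius: float | None = None,
                 n_grid: int = 41) -> list:
    """Default plane set: uniformly spaced in arc length across the ICA
    sinus segment, plane 1 most upstream."""
    cl, s = geom.centerlines["ICA"]
    s0, s1 = geom.sinus_range
    stations = np.linspace(s0, s1, n_planes)
    if radius is None:
        radius = 0.55 * max(geom.mesh.extents.min(), 0.0)
    axis = (cl[-1] - cl[0]) / np.linalg.norm(cl[-1] - cl[0])
    return planes_along_axis(cl[0], axis, stations, radius, n_grid)


@dataclass
class SecondaryField:
    """Velocity decomposition on one plane: axial component along the plane
    normal, secondary components in the in-plane basis, nondimensional
    secondary magnitude u/U."""

    plane: CrossSectionPlane
    axial: np.ndarray                  # (n,) m/s
    secondary: np.ndarray              # (n, 2) m/s in plane basis
    u_over_U: np.ndarray               # (n,) nondimensional secondary magnitude
    U_ref: float
    vorticity_n: np.ndarray            # (n,) 1/s, in-plane vorticity
    mask: np.ndarray                   # (n,) inside the circular section

    @property
    def secondary_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.secondary, axis=1)


def slice_and_decompose(snapshot: FlowSnapshot, planes, U_ref: float) -> list:
    """Interpolate velocity to each plane and decompose into axial and
    secondary parts; ``U_ref`` is the mean inlet speed at the reference
    phase (the figure convention is ``t/T = 0.27``)."""
    if not snapshot.structured:
        raise ValueError("plane slicing requires a structured snapshot")
    shape = snapshot.shape
    vel = snapshot.velocity.reshape(shape + (3,))
    interps = [RegularGridInterpolator(snapshot.axes, vel[..., j],
                                       bounds_error=True) for j in range(3)]
    out = []
    for plane in planes:
        pts, mask = plane.sample_points()
        try:
            u = np.column_stack([itp(pts) for itp in interps])
        except ValueError as err:
            raise ValueError(f"plane {plane.index} lies outside the flow "
                             f"domain: {err}") from None
        axial = u @ plane.normal
        sec = np.column_stack([u @ plane.basis[0], u @ plane.basis[1]])
        m = plane.n_grid
        g = plane.grid_1d
        s1 = sec[:, 0].reshape(m, m)
        s2 = sec[:, 1].reshape(m, m)
        om = np.gradient(s2, g, axis=0) - np.gradient(s1, g, axis=1)
        out.append(SecondaryField(
            plane=plane, axial=axial, secondary=sec,
            u_over_U=np.linalg.norm(sec, axis=1) / U_ref, U_ref=U_ref,
            vorticity_n=om.ravel(), mask=mask))
    return out


def count_vortex_pairs(sf: SecondaryField, vorticity_fraction: float = 0.2) -> dict:
    """Counter-rotating pair detection from in-plane vorticity blobs.

    Blobs are 8-connected components of ``|omega_n| > f * max|omega_n|``;
    each blob's circulation is its vorticity area integral.  A pair is two
    opposite-sign blobs with circulation ratio in [0.5, 2] and centroid
    separation below the plane diameter; matching is deterministic (largest
    circulation first, nearest compatible partner).
    """
    m = sf.plane.n_grid
    g = sf.plane.grid_1d
    dA = (g[1] - g[0]) ** 2
    om = np.where(sf.mask, sf.vorticity_n, 0.0).reshape(m, m)
    peak = np.abs(om).max()
    if peak == 0.0:
        return {"n_pairs": 0, "pairs": [], "unpaired": []}
    blobs = []
    for sign in (1.0, -1.0):
        lab, n = ndimage.label(sign * om > vorticity_fraction * peak,
                               structure=np.ones((3, 3), dtype=int))
        for b in range(1, n + 1):
            sel = lab == b
            gamma = float(om[sel].sum() * dA)
            jj, kk = np.nonzero(sel)
            cen = np.array([g[jj].mean(), g[kk].mean()])
            blobs.append({"circulation": gamma, "centroid": cen})
    order = np.argsort([-abs(b["circulation"]) for b in blobs], kind="stable")
    used = set()
    pairs = []
    for i in order:
        if i in used:
            continue
        bi = blobs[i]
        best = None
        for j in order:
            if j == i or j in used:
                continue
            bj = blobs[j]
            if bi["circulation"] * bj["circulation"] >= 0:
                continue
            ratio = abs(bi["circulation"] / bj["circulation"])
            if not 0.5 <= ratio <= 2.0:
                continue
            d = float(np.linalg.norm(bi["centroid"] - bj["centroid"]))
            if d >= 2.0 * sf.plane.radius:
                continue
            if best is None or d < best[1]:
                best = (j, d)
        if best is not None:
            used.update({i, best[0]})
            pairs.append({
                "blobs": (int(i), int(best[0])),
                "circulations": (blobs[i]["circulation"],
                                 blobs[best[0]]["circulation"]),
                "separation": best[1]})
    unpaired = [int(i) for i in order if i not in used]
    return {"n_pairs": len(pairs), "pairs": pairs, "unpaired": unpaired,
            "n_blobs": len(blobs)}


@dataclass
class AxialGradientTrace:
    """Axial pressure gradient ``dP/dxi`` (Pa/m) over the cycle."""

    phases: np.ndarray
    values: np.ndarray                 # Pa/m
    dxi: float                         # sinus length (m)
    extrema: list = field(default_factory=list)


def _plane_mean_pressure(snapshot: FlowSnapshot, plane: CrossSectionPlane) -> float:
    shape = snapshot.shape
    p = snapshot.pressure.reshape(shape)
    interp = RegularGridInterpolator(snapshot.axes, p, bounds_error=True)
    pts, mask = plane.sample_points()
    try:
        vals = interp(pts[mask])
    except ValueError as err:
        raise ValueError(f"pressure station (plane {plane.index}) outside "
                         f"domain: {err}") from None
    return float(vals.mean())


def axial_pressure_gradient_trace(series: FlowSeries,
                                  entry_plane: CrossSectionPlane,
                                  exit_plane: CrossSectionPlane) -> AxialGradientTrace:
    """Per-phase ``(P_exit - P_entry) / dxi`` with area-averaged station
    pressures; ``dxi`` spans the ICA sinus (entry to exit station)."""
    dxi = float((exit_plane.center - entry_plane.center) @ entry_plane.normal)
    if dxi <= 0:
        raise ValueError("exit station must lie downstream of the entry station")
    phases, vals = [], []
    for snap in series:
        pe = _plane_mean_pressure(snap, entry_plane)
        px = _plane_mean_pressure(snap, exit_plane)
        phases.append(snap.phase)
        vals.append((px - pe) / dxi)
    return AxialGradientTrace(phases=np.asarray(phases), values=np.asarray(vals),
                              dxi=dxi)


def classify_extrema(trace: AxialGradientTrace, prominence: float | None = None) -> list:
    """Label periodic local extrema of the gradient trace.

    Local minima with negative value are 'favorable', local maxima with
    positive value 'adverse'; extrema with prominence below the threshold
    (default 10% of the trace range) are suppressed.  The labeled list is
    stored on the trace and returned.
    """
    v = trace.values
    n = len(v)
    if n < 5:
        raise ValueError("extremum classification needs >= 5 phases")
    rng = float(v.max() - v.min())
    if prominence is None:
        prominence = 0.1 * rng
    if rng == 0.0:
        trace.extrema = []
        return []
    ext = []
    tiled = np.concatenate([v, v, v])
    for kind, sig in (("max", 1.0), ("min", -1.0)):
        peaks, _ = find_peaks(sig * tiled, prominence=prominence)
        peaks = peaks[(peaks >= n) & (peaks < 2 * n)] - n
        for i in peaks:
            val = float(v[i])
            if kind == "min" and val < 0:
                ext.append({"phase": float(trace.phases[i]), "value": val,
                            "class": "favorable"})
            elif kind == "max" and val > 0:
                ext.append({"phase": float(trace.phases[i]), "value": val,
                            "class": "adverse"})
    ext.sort(key=lambda e: e["phase"])
    trace.extrema = ext
    return ext


def percent_differences(extrema_a, extrema_b) -> list:
    """Pair extrema of two traces by nearest phase (same class) and report
    ``(a - b) / |b| * 100`` per pair."""
    out = []
    for ea in extrema_a:
        cands = [eb for eb in extrema_b if eb["class"] == ea["class"]]
        if not cands:
            continue
        eb = min(cands, key=lambda e: abs(e["phase"] - ea["phase"]))
        out.append({"class": ea["class"], "phase_a": ea["phase"],
                    "phase_b": eb["phase"], "value_a": ea["value"],
                    "value_b": eb["value"],
                    "percent_difference": (ea["value"] - eb["value"])
                    / abs(eb["value"]) * 100.0})
    return out
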