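"""Parametric carotid-artery-bifurcation (CAB) geometry.

The common carotid artery (CCA) runs along +x, tapers linearly toward the
bifurcation apex at the origin, and branches in the x-y plane into the
internal carotid artery (ICA, +y side) and the external carotid artery
(ECA, -y side).  The ICA carries a spindle-shaped sinus bulge (cosine-squared
radial profile) whose maximum diameter and length are configurable.  Entry
and exit extensions are appended to stabilize inflow/outflow in downstream
analyses; branch ends are closed with spherical caps so the surface is
watertight.

The surface is the zero level set of a smooth-min union of variable-radius
capsule distance fields, polygonized with marching cubes.  The smooth-min
blending width plays the role of an apex fillet: it rounds the crease where
branches meet and prevents self-intersection at large total branch angles.

``measure_geometry`` recovers the defining parameters from the mesh alone
(cross-section slicing with a chord-sagitta correction for the inward bias
of an inscribed triangulation, centerline tangents for branch angles), which
makes build/measure a verifiable round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import trimesh
from skimage.measure import marching_cubes

__all__ = [
    "CABParameters", "CABGeometry", "SinusFrame", "GeometryError",
    "build_geometry", "measure_geometry", "sinus_frame",
    "healthy_parameters", "predisposed_parameters", "PRESETS",
]


class GeometryError(ValueError):
    """Invalid parameters or failed surface construction."""


@dataclass(frozen=True)
class CABParameters:
    """Defining parameters of the bifurcation model (SI units, angles in
    degrees from the CCA axis).

    Unstated dimensions default to anatomically plausible multiples of the
    CCA inlet diameter: sinus max diameter 1.1 x inlet, sinus length 3 x ICA
    downstream diameter, ECA diameter 0.7 x inlet, entry length 3 inlet
    diameters, exit lengths 8 branch diameters.
    """

    cca_inlet_diameter: float = 6.5e-3
    ica_cca_diameter_ratio: float = 0.7
    ica_branch_angle: float = 30.0
    eca_branch_angle: float = 30.0
    sinus_max_diameter: Optional[float] = None
    sinus_length: Optional[float] = None
    cca_taper_ratio: float = 0.9
    entry_length: Optional[float] = None
    ica_exit_length: Optional[float] = None
    eca_exit_length: Optional[float] = None
    eca_diameter: Optional[float] = None
    blend_fraction: float = 0.2       # smooth-min width / CCA radius (fillet)

    def resolved(self) -> "CABParameters":
        """Fill unset dimensions from their documented defaults."""
        D = self.cca_inlet_diameter
        d_ica = self.ica_cca_diameter_ratio * D
        upd = {}
        if self.sinus_max_diameter is None:
            upd["sinus_max_diameter"] = 1.1 * D
        if self.sinus_length is None:
            upd["sinus_length"] = 3.0 * d_ica
        if self.entry_length is None:
            upd["entry_length"] = 3.0 * D
        if self.ica_exit_length is None:
            upd["ica_exit_length"] = 8.0 * d_ica
        if self.eca_diameter is None:
            upd["eca_diameter"] = 0.7 * D
        p = replace(self, **upd)
        if p.eca_exit_length is None:
            p = replace(p, eca_exit_length=8.0 * p.eca_diameter)
        return p

    def validate(self) -> "CABParameters":
        p = self.resolved()
        for name in ("cca_inlet_diameter", "sinus_max_diameter", "sinus_length",
                     "entry_length", "ica_exit_length", "eca_exit_length",
                     "eca_diameter"):
            if getattr(p, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if not 0.0 < p.ica_cca_diameter_ratio <= 1.0:
            raise GeometryError("ica_cca_diameter_ratio must be in (0, 1]")
        for name in ("ica_branch_angle", "eca_branch_angle"):
            if not 0.0 < getattr(p, name) < 90.0:
                raise GeometryError(f"{name} must be in (0, 90) degrees")
        if not 0.0 < p.cca_taper_ratio <= 1.2:
            raise GeometryError("cca_taper_ratio must be in (0, 1.2]")
        d_ica = p.ica_cca_diameter_ratio * p.cca_inlet_diameter
        if p.sinus_max_diameter < d_ica - 1e-12:
            raise GeometryError(
                "sinus_max_diameter must be >= the ICA downstream diameter")
        return p


def healthy_parameters(**overrides) -> CABParameters:
    """Symmetric 60 degree total branch angle, diameter ratio 0.7."""
    return CABParameters(ica_branch_angle=30.0, eca_branch_angle=30.0,
                         ica_cca_diameter_ratio=0.7, **overrides)


def predisposed_parameters(**overrides) -> CABParameters:
    """Asymmetric 75 degree total branch angle (ICA 45), ratio 0.5."""
    return CABParameters(ica_branch_angle=45.0, eca_branch_angle=30.0,
                         ica_cca_diameter_ratio=0.5, **overrides)


PRESETS = {"healthy": healthy_parameters, "predisposed": predisposed_parameters}


# ---------------------------------------------------------------------------
# branch description

def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class _Branch:
    name: str
    start: np.ndarray
    direction: np.ndarray              # unit
    length: float
    radius_fn: callable                # r(s), s in [0, length]

    def distance_field(self, pts: np.ndarray) -> np.ndarray:
        rel = pts - self.start
        s = np.clip(rel @ self.direction, 0.0, self.length)
        closest = self.start + s[:, None] * self.direction
        d = np.linalg.norm(pts - closest, axis=1)
        return d - self.radius_fn(s)

    def centerline(self, n: int = 200):
        s = np.linspace(0.0, self.length, n)
        return self.start + s[:, None] * self.direction, s


def _branches(p: CABParameters):
    D = p.cca_inlet_diameter
    r_in = 0.5 * D
    r_apex = p.cca_taper_ratio * r_in
    r_ica = 0.5 * p.ica_cca_diameter_ratio * D
    r_sinus = 0.5 * p.sinus_max_diameter
    r_eca = 0.5 * p.eca_diameter

    ai = np.radians(p.ica_branch_angle)
    ae = np.radians(p.eca_branch_angle)
    d_ica = np.array([np.cos(ai), np.sin(ai), 0.0])
    d_eca = np.array([np.cos(ae), -np.sin(ae), 0.0])
    apex = np.zeros(3)

    L_cca = p.entry_length

    def r_cca(s):
        return r_in + (r_apex - r_in) * np.asarray(s) / L_cca

    # junction clearance before branch radii settle to their downstream value
    gap_i = 1.0 * D
    gap_e = 1.0 * D
    s0 = gap_i                             # sinus start arc length from apex
    s1 = s0 + p.sinus_length
    L_ica = s1 + p.ica_exit_length
    L_eca = gap_e + p.eca_exit_length

    def r_ica_fn(s):
        s = np.asarray(s, dtype=float)
        base = r_apex + (r_ica - r_apex) * _smoothstep(s / gap_i)
        mid = 0.5 * (s0 + s1)
        inside = (s >= s0) & (s <= s1)
        bulge = np.zeros_like(s)
        bulge[inside] = (r_sinus - r_ica) * np.cos(
            np.pi * (s[inside] - mid) / p.sinus_length) ** 2
        return base + bulge

    def r_eca_fn(s):
        return r_apex + (r_eca - r_apex) * _smoothstep(np.asarray(s) / gap_e)

    cca = _Branch("CCA", np.array([-L_cca, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]),
                  L_cca, r_cca)
    ica = _Branch("ICA", apex, d_ica, L_ica, r_ica_fn)
    eca = _Branch("ECA", apex, d_eca, L_eca, r_eca_fn)
    return [cca, ica, eca], (s0, s1)


# ---------------------------------------------------------------------------
# construction

@dataclass
class SinusFrame:
    """Sinus-anchored coordinate frame: origin at the bifurcation apex, the
    first (axial, xi) direction along the ICA sinus center axis, completed to
    a right-handed orthonormal basis."""

    origin: np.ndarray
    basis: np.ndarray                  # rows: axial, in-plane 1, in-plane 2

    def __post_init__(self) -> None:
        G = self.basis @ self.basis.T
        if not np.allclose(G, np.eye(3), atol=1e-12):
            raise GeometryError("sinus frame basis must be orthonormal")

    @property
    def axial_unit(self) -> np.ndarray:
        return self.basis[0]

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.origin) @ self.basis.T
        return out if np.ndim(points) == 2 else out[0]

    def from_frame(self, coords: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(np.asarray(coords, dtype=float))
        out = c @ self.basis + self.origin
        return out if np.ndim(coords) == 2 else out[0]

    def xi(self, points: np.ndarray) -> np.ndarray:
        """Axial coordinate (m) of points in the sinus frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.origin) @ self.axial_unit
        return out if np.ndim(points) == 2 else float(out[0])


@dataclass
class CABGeometry:
    """Watertight bifurcation surface mesh with branch centerlines."""

    mesh: trimesh.Trimesh
    centerlines: dict                  # name -> (points (n,3), arclength (n,))
    apex: np.ndarray
    face_labels: np.ndarray            # per-face: CCA / ICA / ECA / sinus
    sinus_range: tuple                 # (s_start, s_end) on the ICA centerline
    metadata: dict = field(default_factory=dict)


def _implicit(pts: np.ndarray, branches, k: float) -> np.ndarray:
    f = np.stack([b.distance_field(pts) for b in branches])
    # smooth min (log-sum-exp): rounds the apex crease by ~k
    m = f.min(axis=0)
    return m - k * np.log(np.exp(-(f - m) / k).sum(axis=0))


def build_geometry(params: CABParameters, resolution: int = 140) -> CABGeometry:
    """Construct the watertight parametric surface mesh.

    ``resolution`` is the number of grid points along the longest bounding
    box edge of the implicit-surface sampling grid.
    """
    p = params.validate()
    branches, sinus_range = _branches(p)
    k = p.blend_fraction * 0.5 * p.cca_inlet_diameter

    # self-intersection guard: beyond the junction blend the ICA and ECA
    # tubes must remain laterally separated
    ica, eca = branches[1], branches[2]
    s_free = 1.2 * sinus_range[0]          # past the junction clearance
    si = np.linspace(min(s_free, ica.length), ica.length, 40)
    se = np.linspace(min(s_free, eca.length), eca.length, 40)
    pi = ica.start + si[:, None] * ica.direction
    pe = eca.start + se[:, None] * eca.direction
    d = np.linalg.norm(pi[:, None, :] - pe[None, :, :], axis=2)
    clearance = d - ica.radius_fn(si)[:, None] - eca.radius_fn(se)[None, :]
    if clearance.min() < 0:
        raise GeometryError("branch tubes merge downstream of the apex "
                            "(angles too small for the requested lengths)")

    r_max = max(0.5 * p.cca_inlet_diameter, 0.5 * p.sinus_max_diameter,
                0.5 * p.eca_diameter)
    ends = np.array([b.start for b in branches] +
                    [b.start + b.length * b.direction for b in branches])
    pad = r_max + 3.0 * k
    lo = ends.min(axis=0) - pad
    hi = ends.max(axis=0) + pad
    extent = hi - lo
    h = extent.max() / (resolution - 1)
    lo -= 2 * h
    hi += 2 * h
    extent = hi - lo
    ns = [max(int(np.ceil(e / h)) + 1, 12) for e in extent]
    axes = [np.linspace(lo[i], hi[i], ns[i]) for i in range(3)]

    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    F = np.empty(len(pts))
    chunk = 500_000
    for i in range(0, len(pts), chunk):
        F[i:i + chunk] = _implicit(pts[i:i + chunk], branches, k)
    F = F.reshape(ns)
    if F.min() > 0 or F.max() < 0:
        raise GeometryError("implicit surface does not cross zero on the grid")

    spacing = tuple(float(a[1] - a[0]) for a in axes)
    verts, faces, _, _ = marching_cubes(F, level=0.0, spacing=spacing)
    verts += lo
    # process merges duplicate marching-cubes vertices; face validation is
    # skipped because dropping degenerate slivers would open pinholes
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True,
                           validate=False)
    if not mesh.is_watertight:
        mesh.merge_vertices()
        mesh.remove_unreferenced_vertices()
    if not mesh.is_watertight:
        raise GeometryError("constructed surface is not watertight "
                            f"(resolution {resolution} too coarse?)")
    # outward normals
    mesh.fix_normals()

    centerlines = {b.name: b.centerline() for b in branches}
    centers = mesh.triangles_center
    fvals = np.stack([b.distance_field(centers) for b in branches])
    lab_idx = np.argmin(fvals, axis=0)
    names = np.array([b.name for b in branches])
    labels = names[lab_idx].astype(object)
    # sinus sub-label on the ICA
    rel = centers - ica.start
    s_ica = np.clip(rel @ ica.direction, 0.0, ica.length)
    in_sinus = (labels == "ICA") & (s_ica >= sinus_range[0]) & (s_ica <= sinus_range[1])
    labels[in_sinus] = "sinus"
    return CABGeometry(mesh=mesh, centerlines=centerlines,
                       apex=np.zeros(3), face_labels=labels.astype(str),
                       sinus_range=sinus_range,
                       metadata={"resolution": resolution, "h": h, "blend_k": k,
                                 "grid_shape": tuple(ns),
                                 "eca_gap": p.cca_inlet_diameter})


# ---------------------------------------------------------------------------
# measurement

def _section_radius(mesh: trimesh.Trimesh, origin, normal, guide,
                    sagitta_correct: bool = True) -> float:
    """Radius of the (near-circular) cross section nearest ``guide``.

    Fits a circle (Kasa fit) to the plane/mesh intersection loop and adds the
    mean chord-sagitta correction: section vertices lie on mesh edges, i.e.
    on chords of the smooth surface, so the raw polygon is inscribed and
    biased inward by O(h^2 / R).
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    segs, fidx = trimesh.intersections.mesh_plane(
        mesh, plane_normal=normal, plane_origin=np.asarray(origin, float),
        return_faces=True)
    if len(segs) == 0:
        raise GeometryError("section plane misses the surface")
    pts = segs.reshape(-1, 3)

    # cluster segments into loops (union-find on shared endpoints)
    scale = float(np.abs(pts).max())
    key = np.round(pts / (1e-9 * scale)).astype(np.int64)
    _, inv = np.unique(key, axis=0, return_inverse=True)
    n_nodes = inv.max() + 1
    parent = np.arange(n_nodes)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    e = inv.reshape(-1, 2)
    for a, b in e:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    seg_root = np.array([find(a) for a in e[:, 0]])

    guide = np.asarray(guide, dtype=float)
    roots = np.unique(seg_root)
    best_root, best_d = None, np.inf
    for r in roots:
        c = pts[np.repeat(seg_root == r, 2)].mean(axis=0)
        d = np.linalg.norm(c - guide)
        if d < best_d:
            best_root, best_d = r, d
    sel = seg_root == best_root
    loop_pts = segs[sel].reshape(-1, 3)
    loop_faces = np.repeat(fidx[sel], 2)

    # in-plane coordinates and circle fit
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ normal) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = loop_pts - origin
    uv = np.column_stack([rel @ e1, rel @ e2])
    A = np.column_stack([2 * uv, np.ones(len(uv))])
    b = (uv ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    R = float(np.sqrt(c + cx * cx + cy * cy))
    if not sagitta_correct:
        return R

    center3 = np.asarray(origin) + cx * e1 + cy * e2
    tri = mesh.triangles[loop_faces]        # (m, 3, 3)
    deficits = np.zeros(len(loop_pts))
    for j, (pt, t) in enumerate(zip(loop_pts, tri)):
        edges = [(t[0], t[1]), (t[1], t[2]), (t[2], t[0])]
        best = None
        for pa, pb in edges:
            ev = pb - pa
            L2 = float(ev @ ev)
            if L2 == 0.0:
                continue
            s = float(np.clip((pt - pa) @ ev / L2, 0.0, 1.0))
            d = float(np.linalg.norm(pt - (pa + s * ev)))
            if best is None or d < best[0]:
                best = (d, s, ev, np.sqrt(L2))
        _, s, ev, L = best
        radial = pt - center3
        radial -= (radial @ normal) * normal
        rn = np.linalg.norm(radial)
        if rn == 0.0:
            continue
        radial /= rn
        circ = np.cross(normal, radial)
        L_circ = abs(ev @ circ)
        deficits[j] = s * (1.0 - s) * L_circ ** 2 / (2.0 * R)
    return R + float(deficits.mean())


def _tangent(points: np.ndarray, s: np.ndarray, s_lo: float, s_hi: float):
    sel = (s >= s_lo) & (s <= s_hi)
    seg = points[sel]
    d = seg[-1] - seg[0]
    return d / np.linalg.norm(d)


def measure_geometry(geom: CABGeometry) -> CABParameters:
    """Recover the defining parameters from a constructed geometry.

    The ICA diameter is measured downstream of the sinus, matching the
    convention that defines the ICA/CCA diameter ratio; the inlet diameter
    is extrapolated to the inlet plane from two stations inside the tapered
    entry segment.
    """
    if geom.face_labels is None or len(geom.face_labels) == 0:
        raise GeometryError("geometry has no branch labels")
    mesh = geom.mesh
    cl_cca, s_cca = geom.centerlines["CCA"]
    cl_ica, s_ica = geom.centerlines["ICA"]
    cl_eca, s_eca = geom.centerlines["ECA"]
    L_cca, L_ica, L_eca = s_cca[-1], s_ica[-1], s_eca[-1]
    t_cca = _tangent(cl_cca, s_cca, 0.0, L_cca)

    # inlet diameter: linear extrapolation from two entry stations
    sA, sB = 0.15 * L_cca, 0.55 * L_cca
    rA = _section_radius(mesh, cl_cca[np.argmin(np.abs(s_cca - sA))], t_cca,
                         cl_cca[np.argmin(np.abs(s_cca - sA))])
    rB = _section_radius(mesh, cl_cca[np.argmin(np.abs(s_cca - sB))], t_cca,
                         cl_cca[np.argmin(np.abs(s_cca - sB))])
    slope = (rB - rA) / (sB - sA)
    r_inlet = rA - slope * sA
    r_apex = rA + slope * (L_cca - sA)
    taper = r_apex / r_inlet

    # branch tangents at the apex (first straight stretch)
    t_ica = _tangent(cl_ica, s_ica, 0.0, 0.3 * L_ica)
    t_eca = _tangent(cl_eca, s_eca, 0.0, 0.3 * L_eca)
    ang_ica = np.degrees(np.arccos(np.clip(t_ica @ t_cca, -1, 1)))
    ang_eca = np.degrees(np.arccos(np.clip(t_eca @ t_cca, -1, 1)))

    # ICA downstream of the sinus
    s0, s1 = geom.sinus_range
    down = [s1 + f * (L_ica - s1) for f in (0.3, 0.6)]
    r_ica = np.mean([
        _section_radius(mesh, cl_ica[np.argmin(np.abs(s_ica - sd))], t_ica,
                        cl_ica[np.argmin(np.abs(s_ica - sd))])
        for sd in down])

    # sinus max: probe stations across the bulge (peak at mid by profile)
    probes = np.linspace(s0, s1, 9)
    r_sinus = max(
        _section_radius(mesh, cl_ica[np.argmin(np.abs(s_ica - sp))], t_ica,
                        cl_ica[np.argmin(np.abs(s_ica - sp))])
        for sp in probes)

    # ECA downstream (constant radius beyond its junction gap)
    eca_st = [0.5 * L_eca, 0.8 * L_eca]
    r_eca = np.mean([
        _section_radius(mesh, cl_eca[np.argmin(np.abs(s_eca - sd))], t_eca,
                        cl_eca[np.argmin(np.abs(s_eca - sd))])
        for sd in eca_st])

    return CABParameters(
        cca_inlet_diameter=2.0 * r_inlet,
        ica_cca_diameter_ratio=r_ica / r_inlet,
        ica_branch_angle=float(ang_ica),
        eca_branch_angle=float(ang_eca),
        sinus_max_diameter=2.0 * float(r_sinus),
        sinus_length=float(s1 - s0),
        cca_taper_ratio=float(taper),
        entry_length=float(L_cca),
        ica_exit_length=float(L_ica - s1),
        eca_exit_length=float(L_eca - geom.metadata.get("eca_gap", s0)),
        eca_diameter=2.0 * float(r_eca),
    )


def sinus_frame(geom: CABGeometry) -> SinusFrame:
    """Sinus-anchored frame: origin at the apex, axial direction the unit
    tangent of the ICA centerline over the sinus segment."""
    cl, s = geom.centerlines["ICA"]
    if s[-1] <= 0:
        raise GeometryError("degenerate (zero-length) ICA centerline")
    s0, s1 = geom.sinus_range
    axial = _tangent(cl, s, s0, s1)
    up = np.array([0.0, 0.0, 1.0])
    if abs(axial @ up) > 0.9:
        up = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(up, axial)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(axial, e2)
    return SinusFrame(origin=np.asarray(geom.apex, dtype=float),
                      basis=np.vstack([axial, e2, e3]))
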