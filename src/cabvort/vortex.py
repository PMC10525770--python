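"""Velocity-gradient tensor, lambda2 field, and vortex-region extraction.

The lambda2 criterion labels a point as part of a vortex core when the
second-largest eigenvalue of ``S^2 + Omega^2`` is negative, where ``S`` and
``Omega`` are the symmetric (strain-rate) and antisymmetric (rotation-rate)
parts of the velocity gradient ``J``.  Vortex regions are connected
components of sub-threshold points; tracking them frame to frame over one
cardiac cycle yields each structure's existence window (lifespan).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .fields import FlowSeries, FlowSnapshot

__all__ = [
    "GradientField", "Lambda2Field", "VortexRegion", "velocity_gradient",
    "lambda2_field", "extract_vortex_regions", "region_presence_window",
    "auto_threshold",
]


@dataclass
class GradientField:
    """Per-point velocity-gradient tensor ``J`` (1/s) and its decomposition
    into strain rate ``S = (J + J^T)/2`` and rotation rate
    ``Omega = (J - J^T)/2``."""

    J: np.ndarray                      # (N, 3, 3)
    snapshot: FlowSnapshot

    @property
    def S(self) -> np.ndarray:
        return 0.5 * (self.J + np.swapaxes(self.J, 1, 2))

    @property
    def Omega(self) -> np.ndarray:
        return 0.5 * (self.J - np.swapaxes(self.J, 1, 2))


@dataclass
class Lambda2Field:
    """Sorted eigenvalues ``lam1 >= lam2 >= lam3`` of ``S^2 + Omega^2``."""

    eigenvalues: np.ndarray            # (N, 3) descending
    snapshot: FlowSnapshot

    @property
    def lam1(self) -> np.ndarray:
        return self.eigenvalues[:, 0]

    @property
    def lam2(self) -> np.ndarray:
        return self.eigenvalues[:, 1]

    @property
    def lam3(self) -> np.ndarray:
        return self.eigenvalues[:, 2]


@dataclass
class VortexRegion:
    """One connected sub-threshold region at one phase."""

    id: int
    members: np.ndarray                # point indices
    points: np.ndarray                 # (n, 3) member coordinates
    volume: float                      # m^3 (cell volume x count on grids)
    centroid: np.ndarray               # (3,) m
    bounds: np.ndarray                 # (2, 3) min/max corner
    min_lambda2: float
    phase: float

    @property
    def n_points(self) -> int:
        return len(self.members)


def _structured_gradient(snapshot: FlowSnapshot) -> np.ndarray:
    xs, ys, zs = snapshot.axes
    if min(len(xs), len(ys), len(zs)) < 3:
        raise ValueError("structured gradients need >= 3 points per axis")
    shape = snapshot.shape
    vel = snapshot.velocity.reshape(shape + (3,))
    J = np.empty(shape + (3, 3))
    for comp in range(3):
        # row `comp` of J: gradient of velocity component `comp`
        gx, gy, gz = np.gradient(vel[..., comp], xs, ys, zs, edge_order=2)
        J[..., comp, 0] = gx
        J[..., comp, 1] = gy
        J[..., comp, 2] = gz
    return J.reshape(-1, 3, 3)


def _least_squares_gradient(snapshot: FlowSnapshot, n_neighbors: int) -> np.ndarray:
    """Weighted least-squares gradient over nearest neighbors; exact for
    affine velocity fields."""
    pts = snapshot.points
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=n_neighbors + 1)
    J = np.empty((len(pts), 3, 3))
    for i in range(len(pts)):
        nb = idx[i, 1:]
        dx = pts[nb] - pts[i]
        du = snapshot.velocity[nb] - snapshot.velocity[i]
        scale = np.linalg.norm(dx, axis=1)
        w = 1.0 / np.maximum(scale, 1e-300)
        A = dx * w[:, None]
        B = du * w[:, None]
        sol, _, rank, _ = np.linalg.lstsq(A, B, rcond=None)
        if rank < 3:
            raise ValueError(
                f"singular gradient fit at point {i}: neighborhood is coplanar")
        J[i] = sol.T
    return J


def velocity_gradient(snapshot: FlowSnapshot, n_neighbors: int = 16) -> GradientField:
    """Velocity-gradient tensor per point.

    Structured grids use second-order central differences (one-sided at the
    boundary); point clouds use a distance-weighted least-squares fit over
    ``n_neighbors`` nearest neighbors.
    """
    if snapshot.structured:
        J = _structured_gradient(snapshot)
    else:
        J = _least_squares_gradient(snapshot, n_neighbors)
    return GradientField(J=J, snapshot=snapshot)


def lambda2_field(grad: GradientField) -> Lambda2Field:
    """Eigenvalues of ``S^2 + Omega^2``, sorted descending per point.

    The tensor is symmetrized before the eigensolve to absorb round-off
    (``S^2 + Omega^2`` is symmetric analytically).
    """
    if not np.all(np.isfinite(grad.J)):
        bad = int(np.argwhere(~np.isfinite(grad.J).all(axis=(1, 2)))[0, 0])
        raise ValueError(f"non-finite velocity gradient at point {bad}")
    S, O = grad.S, grad.Omega
    M = S @ S + O @ O
    M = 0.5 * (M + np.swapaxes(M, 1, 2))
    eig = np.linalg.eigvalsh(M)        # ascending
    return Lambda2Field(eigenvalues=eig[:, ::-1], snapshot=grad.snapshot)


def auto_threshold(lam2_fields, fraction: float = 0.05,
                   percentile: float = 99.0) -> float:
    """Scale-free default threshold: ``-fraction`` times the given
    percentile of ``|lambda2|`` over the supplied fields (99th by default;
    use ``percentile=100`` to key off the strongest core when weaker
    background vortices must be filtered out)."""
    vals = np.concatenate([np.abs(f.lam2) for f in lam2_fields])
    return -fraction * float(np.percentile(vals, percentile))


def _region_from_members(members: np.ndarray, rid: int, field: Lambda2Field,
                         cell_volume: float) -> VortexRegion:
    pts = field.snapshot.points[members]
    return VortexRegion(
        id=rid, members=members, points=pts, volume=cell_volume * len(members),
        centroid=pts.mean(axis=0),
        bounds=np.array([pts.min(axis=0), pts.max(axis=0)]),
        min_lambda2=float(field.lam2[members].min()),
        phase=field.snapshot.phase)


def extract_vortex_regions(field: Lambda2Field, threshold: float = 0.0,
                           min_size: int = 10, adjacency=None) -> list:
    """Connected components of ``{lambda2 < threshold}``.

    Structured grids use 26-connectivity voxel labeling; point clouds use the
    supplied ``adjacency`` (sparse matrix or (i, j) edge array).  Components
    smaller than ``min_size`` points are discarded; regions are returned
    sorted by volume, largest first.
    """
    if threshold > 0:
        raise ValueError("lambda2 threshold must be <= 0")
    snap = field.snapshot
    sub = field.lam2 < threshold
    if snap.mask is not None:
        sub &= snap.mask
    if snap.structured:
        cell = float(np.prod([s for s in snap.spacing]))
        labels, n = ndimage.label(sub.reshape(snap.shape),
                                  structure=np.ones((3, 3, 3), dtype=int))
        labels = labels.ravel()
        regions = []
        for lab in range(1, n + 1):
            members = np.flatnonzero(labels == lab)
            if len(members) >= min_size:
                regions.append(_region_from_members(members, 0, field, cell))
    else:
        if adjacency is None:
            raise ValueError("point-cloud extraction needs an adjacency")
        idx = np.flatnonzero(sub)
        if len(idx) == 0:
            return []
        if hasattr(adjacency, "tocsr"):
            A = adjacency.tocsr()[idx][:, idx]
        else:
            edges = np.asarray(adjacency)
            keep = sub[edges[:, 0]] & sub[edges[:, 1]]
            e = edges[keep]
            remap = -np.ones(len(sub), dtype=int)
            remap[idx] = np.arange(len(idx))
            A = coo_matrix((np.ones(len(e)), (remap[e[:, 0]], remap[e[:, 1]])),
                           shape=(len(idx), len(idx)))
        n, lab = connected_components(A, directed=False)
        regions = []
        for k in range(n):
            members = idx[lab == k]
            if len(members) >= min_size:
                regions.append(_region_from_members(members, 0, field, 0.0))
    regions.sort(key=lambda r: (-r.volume, -r.n_points, tuple(r.centroid)))
    for i, r in enumerate(regions):
        r.id = i
    return regions


def _bbox_overlap(a: VortexRegion, b: VortexRegion) -> float:
    lo = np.maximum(a.bounds[0], b.bounds[0])
    hi = np.minimum(a.bounds[1], b.bounds[1])
    ext = np.maximum(hi - lo, 0.0)
    return float(np.prod(ext))


def region_presence_window(series: FlowSeries, threshold: float,
                           min_size: int = 10, lam2_fields=None,
                           log: list | None = None) -> list:
    """Track regions frame to frame at a constant threshold and return each
    track's existence window ``(phase_start, phase_end)``.

    Matching rule: maximum bounding-box overlap with the previous frame's
    region, ties broken by smallest centroid distance, then by lowest region
    id (deterministic).  Returns a list of dicts sorted by start phase, then
    duration descending.
    """
    if lam2_fields is None:
        lam2_fields = [lambda2_field(velocity_gradient(s)) for s in series]
    frames = [extract_vortex_regions(f, threshold, min_size) for f in lam2_fields]
    tracks = []           # each: {"start", "end", "region", "open"}
    for snap, regions in zip(series, frames):
        phase = snap.phase
        open_tracks = [tr for tr in tracks if tr["open"]]
        used = set()
        # match previous regions to current ones
        for tr in open_tracks:
            prev = tr["region"]
            best = None
            for r in regions:
                if r.id in used:
                    continue
                score = (_bbox_overlap(prev, r),
                         -float(np.linalg.norm(prev.centroid - r.centroid)),
                         -r.id)
                if score[0] <= 0.0:
                    continue
                if best is None or score > best[1]:
                    best = (r, score)
                elif score == best[1] and log is not None:
                    log.append(f"ambiguous match at phase {phase:.4f}; kept "
                               f"region {best[0].id} over {r.id}")
            if best is None:
                tr["open"] = False
            else:
                used.add(best[0].id)
                tr["region"] = best[0]
                tr["end"] = phase
        for tr in open_tracks:
            if tr["open"]:
                tr["max_volume"] = max(tr["max_volume"], tr["region"].volume)
        for r in regions:
            if r.id not in used:
                tracks.append({"start": phase, "end": phase, "region": r,
                               "open": True, "max_volume": r.volume})
    out = [{"phase_start": tr["start"], "phase_end": tr["end"],
            "lifespan": tr["end"] - tr["start"],
            "max_volume": tr["max_volume"]} for tr in tracks]
    out.sort(key=lambda w: (w["phase_start"], -w["lifespan"]))
    return out
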