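"""Velocity-gradient tensor, lambda2 criterion and region extraction."""

import numpy as np
import pytest

from cabvort import synthetic as S, vortex as V
from cabvort.fields import FlowSeries, FlowSnapshot


def _affine_snapshot(A, b, pts, axes=None):
    vel = pts @ A.T + b
    return FlowSnapshot(pts, vel, np.zeros(len(pts)), t=0.0, axes=axes)


class TestVelocityGradient:
    def test_exact_on_affine_fields_structured(self, rng):
        A = rng.normal(size=(3, 3))
        axes = S.box_grid(((-1, 1), (-1, 1), (-1, 1)), (7, 7, 7))
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        grad = V.velocity_gradient(_affine_snapshot(A, rng.normal(size=3),
                                                    pts, axes))
        assert np.abs(grad.J - A).max() < 1e-10

    def test_exact_on_affine_fields_unstructured(self, rng):
        A = rng.normal(size=(3, 3))
        pts = rng.uniform(-1, 1, size=(400, 3))
        grad = V.velocity_gradient(_affine_snapshot(A, np.zeros(3), pts))
        assert np.abs(grad.J - A).max() < 1e-9

    def test_uniform_flow_has_zero_gradient(self):
        axes = S.box_grid(((-1, 1), (-1, 1), (-1, 1)), (5, 5, 5))
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        snap = FlowSnapshot(pts, np.tile([1.0, -2.0, 0.5], (len(pts), 1)),
                            np.zeros(len(pts)), t=0.0, axes=axes)
        assert np.abs(V.velocity_gradient(snap).J).max() == 0.0

    def test_decomposition_identities(self, rng):
        A = rng.normal(size=(3, 3))
        pts = rng.uniform(-1, 1, size=(200, 3))
        grad = V.velocity_gradient(_affine_snapshot(A, np.zeros(3), pts))
        assert np.allclose(grad.S, np.swapaxes(grad.S, 1, 2), atol=1e-12)
        assert np.allclose(grad.Omega, -np.swapaxes(grad.Omega, 1, 2), atol=1e-12)
        assert np.allclose(grad.S + grad.Omega, grad.J)

    def test_coplanar_neighborhood_raises(self):
        pts = np.column_stack([np.linspace(0, 1, 30),
                               np.linspace(0, 2, 30), np.zeros(30)])
        snap = FlowSnapshot(pts, np.zeros((30, 3)), np.zeros(30), t=0.0)
        with pytest.raises(ValueError, match="coplanar"):
            V.velocity_gradient(snap, n_neighbors=8)

    def test_poiseuille_profile_derivative_recovered(self):
        """Second-order differences reproduce the analytic parabolic-profile
        derivative du/dy = -4 U y / a^2 exactly (quadratic profile)."""
        a, U = 1.0, 0.5
        axes = S.box_grid(((0, 1), (-1, 1), (-1, 1)), (3, 21, 21))
        snap = S.poiseuille_snapshot(a, U, grid=axes)
        grad = V.velocity_gradient(snap)
        pts = snap.points
        on_axis = (np.abs(pts[:, 2]) < 1e-12) & (np.abs(pts[:, 0]) < 1e-12)
        y = pts[on_axis, 1]
        inside = np.abs(y) < 0.9 * a        # avoid the masked-wall kink
        dudy = grad.J[on_axis, 0, 1]
        assert np.abs(dudy[inside] + 4 * U * y[inside] / a ** 2).max() < 1e-10


class TestLambda2:
    def test_rigid_rotation_eigenvalues(self):
        axes = S.box_grid(((-1, 1), (-1, 1), (-1, 1)), (13, 13, 13))
        snap = S.vortex_tube_field("rigid_rotation", axes, omega=2.0)
        lam = V.lambda2_field(V.velocity_gradient(snap))
        off = np.hypot(snap.points[:, 1], snap.points[:, 2]) > 0.05
        assert np.abs(lam.lam2[off] + 4.0).max() / 4.0 < 1e-9

    def test_pure_shear_gives_zero_lambda2(self):
        gam = 3.0
        axes = S.box_grid(((-1, 1), (-1, 1), (-1, 1)), (9, 9, 9))
        snap = S.vortex_tube_field("simple_shear", axes, shear_rate=gam)
        lam = V.lambda2_field(V.velocity_gradient(snap))
        assert np.abs(lam.lam2).max() < 1e-9 * gam ** 2

    def test_lamb_oseen_sign_field_matches_bruteforce_eigensolve(self):
        """Per-point nonsymmetric eigensolve of S^2 + Omega^2 (independent
        route) agrees in sign with the module's symmetric path at 100% of
        points."""
        axes = S.box_grid(((-1, 1), (-1, 1), (-1, 1)), (5, 31, 31))
        snap = S.vortex_tube_field("lamb_oseen", axes, gamma=1.0, r_c=0.25)
        grad = V.velocity_gradient(snap)
        lam = V.lambda2_field(grad)
        M = grad.S @ grad.S + grad.Omega @ grad.Omega
        brute = np.sort(np.real(np.linalg.eigvals(M)), axis=1)[:, 1]
        scale = np.abs(lam.lam2).max()
        significant = np.abs(lam.lam2) > 1e-9 * scale
        assert np.all(np.sign(brute[significant])
                      == np.sign(lam.lam2[significant]))

    def test_eigenvalue_ordering_and_trace_identity(self, rng):
        pts = rng.uniform(-1, 1, size=(300, 3))
        A = rng.normal(size=(3, 3))
        grad = V.velocity_gradient(_affine_snapshot(A, np.zeros(3), pts))
        lam = V.lambda2_field(grad)
        ev = lam.eigenvalues
        assert np.all(ev[:, 0] >= ev[:, 1]) and np.all(ev[:, 1] >= ev[:, 2])
        M = grad.S @ grad.S + grad.Omega @ grad.Omega
        tr = np.trace(M, axis1=1, axis2=2)
        assert np.allclose(ev.sum(axis=1), tr, rtol=1e-9)

    def test_galilean_invariance(self):
        axes = S.box_grid(((-1, 1), (-1, 1), (-1, 1)), (9, 9, 9))
        snap = S.vortex_tube_field("lamb_oseen", axes, gamma=1.0, r_c=0.3)
        lam = V.lambda2_field(V.velocity_gradient(snap)).lam2
        boosted = FlowSnapshot(snap.points, snap.velocity + [3.0, -1.0, 2.0],
                               snap.pressure, t=0.0, axes=snap.axes)
        lam_b = V.lambda2_field(V.velocity_gradient(boosted)).lam2
        assert np.abs(lam - lam_b).max() < 1e-12 * max(np.abs(lam).max(), 1.0)

    def test_rotation_equivariance(self, rng):
        """Rigidly rotating points and velocity leaves the sorted
        eigenvalues unchanged (least-squares gradient path)."""
        pts = rng.uniform(-1, 1, size=(500, 3))
        vel = np.column_stack([
            -S._lamb_oseen_utheta(np.hypot(pts[:, 0], pts[:, 1]), 1.0, 0.3)
            * pts[:, 1] / np.hypot(pts[:, 0], pts[:, 1]),
            S._lamb_oseen_utheta(np.hypot(pts[:, 0], pts[:, 1]), 1.0, 0.3)
            * pts[:, 0] / np.hypot(pts[:, 0], pts[:, 1]),
            np.zeros(len(pts))])
        snap = FlowSnapshot(pts, vel, np.zeros(len(pts)), t=0.0)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        R = R @ np.array([[1, 0, 0], [0, np.cos(0.3), -np.sin(0.3)],
                          [0, np.sin(0.3), np.cos(0.3)]])
        rot = FlowSnapshot(pts @ R.T, vel @ R.T, np.zeros(len(pts)), t=0.0)
        ev1 = V.lambda2_field(V.velocity_gradient(snap)).eigenvalues
        ev2 = V.lambda2_field(V.velocity_gradient(rot)).eigenvalues
        scale = np.abs(ev1).max()
        assert np.abs(ev1 - ev2).max() < 1e-9 * scale


def _two_tube_snapshot(centers=(-0.5, 0.5), n=41):
    axes = S.box_grid(((-0.2, 0.2), (-1, 1), (-1, 1)), (5, n, n))
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vel = np.zeros_like(pts)
    for yc in centers:
        dy, dz = pts[:, 1] - yc, pts[:, 2]
        r = np.hypot(dy, dz)
        uth = S._lamb_oseen_utheta(r, 1.0, 0.12)
        with np.errstate(invalid="ignore"):
            vel[:, 1] += -uth * np.where(r > 0, dz / np.where(r > 0, r, 1), 0)
            vel[:, 2] += uth * np.where(r > 0, dy / np.where(r > 0, r, 1), 1)
    return FlowSnapshot(pts, vel, np.zeros(len(pts)), t=0.0, axes=axes)


class TestRegionExtraction:
    def test_uniform_flow_yields_no_regions(self):
        axes = S.box_grid(((-1, 1), (-1, 1), (-1, 1)), (7, 7, 7))
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        snap = FlowSnapshot(pts, np.tile([1.0, 0, 0], (len(pts), 1)),
                            np.zeros(len(pts)), t=0.0, axes=axes)
        lam = V.lambda2_field(V.velocity_gradient(snap))
        assert V.extract_vortex_regions(lam, threshold=0.0) == []

    def test_two_parallel_tubes_found_separately(self):
        snap = _two_tube_snapshot()
        lam = V.lambda2_field(V.velocity_gradient(snap))
        regions = V.extract_vortex_regions(lam, threshold=-1.0, min_size=10)
        assert len(regions) == 2
        cell = snap.spacing[1]
        got = sorted(r.centroid[1] for r in regions)
        assert abs(got[0] - (-0.5)) <= cell and abs(got[1] - 0.5) <= cell
        assert np.allclose([r.centroid[2] for r in regions], 0.0, atol=cell)

    def test_matches_independent_flood_fill(self):
        """26-connected labeling agrees with a brute-force BFS flood fill."""
        snap = _two_tube_snapshot()
        lam = V.lambda2_field(V.velocity_gradient(snap))
        regions = V.extract_vortex_regions(lam, threshold=-1.0, min_size=1)
        # oracle: BFS on the voxel grid
        sub = (lam.lam2 < -1.0).reshape(snap.shape)
        seen = np.zeros_like(sub, dtype=bool)
        comps = []
        idx = np.argwhere(sub)
        for seed in map(tuple, idx):
            if seen[seed]:
                continue
            stack, comp = [seed], []
            seen[seed] = True
            while stack:
                c = stack.pop()
                comp.append(c)
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            n = (c[0] + dx, c[1] + dy, c[2] + dz)
                            if (0 <= n[0] < sub.shape[0] and
                                    0 <= n[1] < sub.shape[1] and
                                    0 <= n[2] < sub.shape[2] and
                                    sub[n] and not seen[n]):
                                seen[n] = True
                                stack.append(n)
            comps.append(len(comp))
        assert sorted(comps, reverse=True) == [r.n_points for r in regions]

    def test_threshold_monotonicity(self):
        snap = _two_tube_snapshot()
        lam = V.lambda2_field(V.velocity_gradient(snap))
        tight = V.extract_vortex_regions(lam, threshold=-5.0, min_size=1)
        loose = V.extract_vortex_regions(lam, threshold=-1.0, min_size=1)
        tight_pts = set(np.concatenate([r.members for r in tight]))
        loose_pts = set(np.concatenate([r.members for r in loose]))
        assert tight_pts <= loose_pts

    def test_min_size_filters_noise(self):
        snap = _two_tube_snapshot()
        lam = V.lambda2_field(V.velocity_gradient(snap))
        small = V.extract_vortex_regions(lam, threshold=-1.0, min_size=10 ** 6)
        assert small == []


def _scheduled_series(schedules, n_steps=20, n=25):
    """Series with Lamb-Oseen tubes existing over prescribed phase windows.

    schedules: list of (phase_start, phase_end, y_center)
    """
    axes = S.box_grid(((-0.2, 0.2), (-1, 1), (-1, 1)), (5, n, n))
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    snaps = []
    for j in range(n_steps):
        phase = j / n_steps
        vel = np.zeros_like(pts)
        for p0, p1, yc in schedules:
            if p0 <= phase <= p1:
                dy, dz = pts[:, 1] - yc, pts[:, 2]
                r = np.hypot(dy, dz)
                uth = S._lamb_oseen_utheta(r, 1.0, 0.12)
                with np.errstate(invalid="ignore"):
                    vel[:, 1] += -uth * np.where(r > 0, dz / np.where(r > 0, r, 1), 0)
                    vel[:, 2] += uth * np.where(r > 0, dy / np.where(r > 0, r, 1), 1)
        snaps.append(FlowSnapshot(pts, vel, np.zeros(len(pts)), t=phase,
                                  period=1.0, axes=axes))
    return FlowSeries(snaps)


class TestPresenceWindows:
    def test_window_matches_construction(self):
        ser = _scheduled_series([(0.20, 0.50, 0.0)])
        wins = V.region_presence_window(ser, threshold=-1.0, min_size=5)
        assert len(wins) == 1
        assert wins[0]["phase_start"] == pytest.approx(0.20)
        assert wins[0]["phase_end"] == pytest.approx(0.50)

    def test_always_present_region_spans_cycle(self):
        ser = _scheduled_series([(0.0, 1.0, 0.0)], n_steps=10)
        wins = V.region_presence_window(ser, threshold=-1.0, min_size=5)
        assert wins[0]["phase_start"] == 0.0
        assert wins[0]["phase_end"] == pytest.approx(0.9)  # 1 - dt/T

    def test_two_overlapping_lifespans(self):
        ser = _scheduled_series([(0.10, 0.60, -0.5), (0.30, 0.80, 0.5)])
        wins = V.region_presence_window(ser, threshold=-1.0, min_size=5)
        assert len(wins) == 2
        assert wins[0]["phase_start"] == pytest.approx(0.10)
        assert wins[0]["phase_end"] == pytest.approx(0.60)
        assert wins[1]["phase_start"] == pytest.approx(0.30)
        assert wins[1]["phase_end"] == pytest.approx(0.80)
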