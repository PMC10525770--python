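"""Secondary-flow decomposition, pair counting and pressure-gradient trace."""

import itertools

import numpy as np
import pytest

from cabvort import secondary as SEC, synthetic as S
from cabvort.fields import FlowSeries, FlowSnapshot

AXES = S.box_grid(((0.0, 0.06), (-0.01, 0.01), (-0.01, 0.01)), (31, 25, 25))
X, Y, Z = np.meshgrid(*AXES, indexing="ij")
PTS = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
PLANES = SEC.planes_along_axis(np.zeros(3), [1.0, 0.0, 0.0],
                               np.linspace(0.01, 0.05, 6), radius=8e-3,
                               n_grid=41)


def _snap(vel, pressure=None, t=0.0):
    p = np.zeros(len(PTS)) if pressure is None else pressure
    return FlowSnapshot(PTS, vel, p, t=t, period=1.0, axes=AXES)


def _swirl(centers_signs, gamma=1e-3, r_c=2.5e-3):
    vel = np.zeros_like(PTS)
    for yc, zc, sign in centers_signs:
        dy, dz = PTS[:, 1] - yc, PTS[:, 2] - zc
        r = np.hypot(dy, dz)
        uth = S._lamb_oseen_utheta(r, sign * gamma, r_c)
        with np.errstate(invalid="ignore"):
            vel[:, 1] += -uth * np.where(r > 0, dz / np.where(r > 0, r, 1), 0)
            vel[:, 2] += uth * np.where(r > 0, dy / np.where(r > 0, r, 1), 1)
    return vel


class TestDecomposition:
    def test_pure_axial_plug_flow_has_no_secondary(self):
        vel = np.tile([0.3, 0.0, 0.0], (len(PTS), 1))
        for sf in SEC.slice_and_decompose(_snap(vel), PLANES, U_ref=0.3):
            assert np.abs(sf.secondary_magnitude).max() < 1e-14
            assert np.allclose(sf.axial, 0.3)

    def test_in_plane_rotation_is_purely_secondary(self):
        om = 5.0
        vel = np.column_stack([np.zeros(len(PTS)), -om * PTS[:, 2],
                               om * PTS[:, 1]])
        sf = SEC.slice_and_decompose(_snap(vel), PLANES, U_ref=1.0)[2]
        assert np.abs(sf.axial).max() < 1e-12
        g = sf.plane.grid_1d
        U, V = np.meshgrid(g, g, indexing="ij")
        r = np.hypot(U.ravel(), V.ravel())
        assert np.allclose(sf.secondary_magnitude, om * r, atol=1e-9)

    def test_tilted_uniform_flow_ratio_is_tangent(self):
        theta = 0.3
        vel = np.tile([np.cos(theta), np.sin(theta), 0.0], (len(PTS), 1))
        sf = SEC.slice_and_decompose(_snap(vel), PLANES, U_ref=1.0)[0]
        ratio = sf.secondary_magnitude / sf.axial
        assert np.abs(ratio - np.tan(theta)).max() < 1e-8

    def test_energy_reconstruction(self, rng):
        """axial^2 + |secondary|^2 reconstructs |u|^2 to 1e-10 relative."""
        vel = _swirl([(0.004, 0.0, 1)], gamma=2e-3)
        vel[:, 0] += 0.2 * (1 - (PTS[:, 1] ** 2 + PTS[:, 2] ** 2) / 1e-4)
        snap = _snap(vel)
        from scipy.interpolate import RegularGridInterpolator
        shape = snap.shape
        v3 = snap.velocity.reshape(shape + (3,))
        for sf in SEC.slice_and_decompose(snap, PLANES, U_ref=0.2):
            pts, _ = sf.plane.sample_points()
            u = np.column_stack([
                RegularGridInterpolator(snap.axes, v3[..., j])(pts)
                for j in range(3)])
            lhs = sf.axial ** 2 + sf.secondary_magnitude ** 2
            rhs = (u ** 2).sum(axis=1)
            assert np.abs(lhs - rhs).max() <= 1e-10 * max(rhs.max(), 1e-300)

    def test_plane_outside_domain_names_the_plane(self):
        bad = SEC.planes_along_axis(np.zeros(3), [1, 0, 0], [0.2],
                                    radius=5e-3)
        vel = np.tile([0.1, 0, 0], (len(PTS), 1))
        with pytest.raises(ValueError, match="plane 1"):
            SEC.slice_and_decompose(_snap(vel), bad, U_ref=0.1)


class TestPairCounting:
    def test_dean_pair_counted_once_with_opposite_circulations(self):
        vel = _swirl([(0.004, 0.0, 1), (-0.004, 0.0, -1)])
        sf = SEC.slice_and_decompose(_snap(vel), PLANES, U_ref=0.1)[2]
        res = SEC.count_vortex_pairs(sf)
        assert res["n_pairs"] == 1
        g1, g2 = res["pairs"][0]["circulations"]
        assert g1 * g2 < 0
        assert abs(g1 + g2) < 0.01 * abs(g1)

    def test_single_vortex_is_unpaired(self):
        vel = _swirl([(0.0, 0.0, 1)])
        sf = SEC.slice_and_decompose(_snap(vel), PLANES, U_ref=0.1)[2]
        res = SEC.count_vortex_pairs(sf)
        assert res["n_pairs"] == 0
        assert len(res["unpaired"]) == 1

    def test_zero_vorticity_counts_nothing(self):
        vel = np.tile([0.2, 0.0, 0.0], (len(PTS), 1))
        sf = SEC.slice_and_decompose(_snap(vel), PLANES, U_ref=0.2)[0]
        assert SEC.count_vortex_pairs(sf)["n_pairs"] == 0

    def test_two_pairs_match_exhaustive_pairing(self):
        """Four constructed blobs pair up exactly as the brute-force
        minimum-total-distance matching does."""
        spots = [(0.005, 0.005, 1), (0.005, -0.005, -1),
                 (-0.005, 0.005, -1), (-0.005, -0.005, 1)]
        vel = _swirl(spots, gamma=1e-3, r_c=1.8e-3)
        sf = SEC.slice_and_decompose(_snap(vel), PLANES, U_ref=0.1)[2]
        res = SEC.count_vortex_pairs(sf)
        assert res["n_pairs"] == 2
        # oracle: enumerate all perfect matchings of opposite-sign blobs
        m = sf.plane.n_grid
        g = sf.plane.grid_1d
        dA = (g[1] - g[0]) ** 2
        om = np.where(sf.mask, sf.vorticity_n, 0).reshape(m, m)
        from scipy import ndimage
        blobs = []
        for sign in (1, -1):
            lab, n = ndimage.label(sign * om > 0.2 * np.abs(om).max(),
                                   structure=np.ones((3, 3)))
            for b in range(1, n + 1):
                sel = lab == b
                jj, kk = np.nonzero(sel)
                blobs.append((float(om[sel].sum() * dA),
                              np.array([g[jj].mean(), g[kk].mean()])))
        pos = [b for b in blobs if b[0] > 0]
        neg = [b for b in blobs if b[0] < 0]
        best = None
        for perm in itertools.permutations(range(len(neg))):
            ok = all(0.5 <= abs(p[0] / neg[j][0]) <= 2.0
                     for p, j in zip(pos, perm))
            if not ok:
                continue
            cost = sum(np.linalg.norm(p[1] - neg[j][1])
                       for p, j in zip(pos, perm))
            if best is None or cost < best[0]:
                best = (cost, perm)
        assert best is not None
        oracle_seps = sorted(np.linalg.norm(p[1] - neg[j][1])
                             for p, j in zip(pos, best[1]))
        got_seps = sorted(pair["separation"] for pair in res["pairs"])
        assert len(oracle_seps) == res["n_pairs"]
        assert np.allclose(got_seps, oracle_seps, rtol=1e-9)

    def test_rotation_invariance_of_pair_count(self, rng):
        """The counted number of pairs is unchanged under in-plane rigid
        rotation of the velocity field."""
        base = [(0.004, 0.0, 1), (-0.004, 0.0, -1)]
        for th in rng.uniform(0, 2 * np.pi, size=10):
            c, s = np.cos(th), np.sin(th)
            rot = [(c * y - s * z, s * y + c * z, sign) for y, z, sign in base]
            vel = _swirl(rot)
            sf = SEC.slice_and_decompose(_snap(vel), PLANES, U_ref=0.1)[2]
            assert SEC.count_vortex_pairs(sf)["n_pairs"] == 1


def _pressure_series(p_fn, n_steps=20):
    snaps = []
    for j in range(n_steps):
        t = j / n_steps
        vel = np.tile([0.1, 0.0, 0.0], (len(PTS), 1))
        snaps.append(_snap(vel, pressure=p_fn(PTS, t), t=t))
    return FlowSeries(snaps)


class TestGradientTrace:
    def test_spatially_linear_pressure_recovered_exactly(self):
        g = -123.4
        ser = _pressure_series(lambda pts, t: 7.0 + g * pts[:, 0])
        tr = SEC.axial_pressure_gradient_trace(ser, PLANES[0], PLANES[-1])
        assert np.allclose(tr.values, g, rtol=1e-12)
        assert tr.dxi == pytest.approx(0.04)

    def test_steady_poiseuille_gradient(self):
        """Favorable (negative) gradient -8 mu U / a^2 within 1%."""
        from cabvort.boundary import FluidProperties
        fl = FluidProperties(nu=1e-3, rho=1.0)
        a, U = 0.01, 0.1
        snaps = []
        for j in range(4):
            s = S.poiseuille_snapshot(a, U, fl, AXES, t=j / 4.0)
            snaps.append(s)
        ser = FlowSeries(snaps)
        planes = SEC.planes_along_axis(np.zeros(3), [1, 0, 0], [0.01, 0.05],
                                       radius=0.8 * a, n_grid=31)
        tr = SEC.axial_pressure_gradient_trace(ser, planes[0], planes[1])
        expect = -8 * fl.mu * U / a ** 2
        assert np.allclose(tr.values, expect, rtol=0.01)
        assert np.all(tr.values < 0)

    def test_prescribed_time_varying_gradient(self):
        g = lambda t: 50.0 * np.sin(2 * np.pi * t) - 20.0
        ser = _pressure_series(lambda pts, t: g(t) * pts[:, 0])
        tr = SEC.axial_pressure_gradient_trace(ser, PLANES[0], PLANES[-1])
        assert np.abs(tr.values - g(tr.phases)).max() <= 0.01 * np.abs(
            g(tr.phases)).max()

    def test_trace_scales_linearly_with_pressure(self):
        ser1 = _pressure_series(lambda pts, t: (1 + t) * pts[:, 0] * 10)
        ser3 = _pressure_series(lambda pts, t: 3 * (1 + t) * pts[:, 0] * 10)
        t1 = SEC.axial_pressure_gradient_trace(ser1, PLANES[0], PLANES[-1])
        t3 = SEC.axial_pressure_gradient_trace(ser3, PLANES[0], PLANES[-1])
        assert np.allclose(3 * t1.values, t3.values, rtol=1e-12)


class TestExtrema:
    def _trace(self, values):
        n = len(values)
        return SEC.AxialGradientTrace(phases=np.arange(n) / n,
                                      values=np.asarray(values, float),
                                      dxi=0.01)

    def test_negative_sine_classification(self):
        t = np.arange(40) / 40.0
        ext = SEC.classify_extrema(self._trace(-np.sin(2 * np.pi * t)))
        assert len(ext) == 2
        fav = [e for e in ext if e["class"] == "favorable"]
        adv = [e for e in ext if e["class"] == "adverse"]
        assert fav[0]["phase"] == pytest.approx(0.25)
        assert adv[0]["phase"] == pytest.approx(0.75)
        assert fav[0]["value"] < 0 < adv[0]["value"]

    def test_constant_trace_has_no_extrema(self):
        assert SEC.classify_extrema(self._trace(np.ones(12))) == []

    def test_sign_convention_enforced(self, rng):
        """Every favorable extremum is negative, every adverse positive."""
        t = np.arange(64) / 64.0
        v = (rng.normal(size=4)[:, None]
             * np.sin(2 * np.pi * np.arange(1, 5)[:, None] * t[None, :])).sum(0)
        for e in SEC.classify_extrema(self._trace(v)):
            if e["class"] == "favorable":
                assert e["value"] < 0
            else:
                assert e["value"] > 0

    def test_percent_difference_of_paired_peaks(self):
        """First favorable peaks -2.0 vs -0.9: the weaker trace is reported
        55% lower."""
        t = np.arange(40) / 40.0
        ta = self._trace(-2.0 * np.sin(2 * np.pi * t))
        tb = self._trace(-0.9 * np.sin(2 * np.pi * t))
        ea = SEC.classify_extrema(ta)
        eb = SEC.classify_extrema(tb)
        pct = SEC.percent_differences(
            [e for e in eb if e["class"] == "favorable"],
            [e for e in ea if e["class"] == "favorable"])
        assert pct[0]["percent_difference"] == pytest.approx(55.0, abs=1e-9)
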