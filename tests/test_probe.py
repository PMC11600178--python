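import numpy as np
import pytest

from microrheo import probe
from microrheo.errors import InputError

from conftest import make_trajectory


def brute_force_fcc_count(R_b, a):
    """Independent triple-loop enumeration of FCC sites within R_b."""
    n = int(np.ceil(R_b / a)) + 1
    basis = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    count = 0
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                for bx, by, bz in basis:
                    x, y, z = (i + bx) * a, (j + by) * a, (k + bz) * a
                    if x * x + y * y + z * z <= R_b ** 2 + 1e-9:
                        count += 1
    return count


class TestBuildProbe:
    def test_nearest_neighbor_distance(self):
        st = probe.build_probe(8.0)
        # FCC cell edge 2.12 Å: corner-face distance 2.12/√2 ≈ 1.5 Å
        assert st.min_interbead_distance() == pytest.approx(
            2.12 / np.sqrt(2), rel=1e-10)

    def test_tiny_radius_single_bead(self):
        with pytest.warns(UserWarning):
            st = probe.build_probe(1.0)
        assert st.n_beads == 1

    def test_bead_count_matches_enumeration_oracle(self):
        st = probe.build_probe(10.0)
        assert st.n_beads == brute_force_fcc_count(10.0, 2.12)

    def test_connected_single_body(self):
        assert probe.build_probe(6.0).is_connected()

    def test_deterministic(self):
        a = probe.build_probe(7.0)
        b = probe.build_probe(7.0)
        np.testing.assert_array_equal(a.bead_positions, b.bead_positions)
        np.testing.assert_array_equal(a.bonds, b.bonds)

    def test_bare_mass(self):
        st = probe.build_probe(5.0)
        assert st.m_bare == 100.0 * st.n_beads

    def test_exports(self, tmp_path):
        st = probe.build_probe(4.0)
        st.to_xyz(tmp_path / "p.xyz")
        st.to_lammps_data(tmp_path / "p.data")
        text = (tmp_path / "p.data").read_text()
        assert f"{st.n_beads} atoms" in text
        assert f"{len(st.bonds)} bonds" in text


class TestGeometry:
    def test_isotropic_six_beads_zero_anisotropy(self):
        pos = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]], float) * 5
        g = probe.geometry(pos)
        assert g.kappa2 == pytest.approx(0.0, abs=1e-12)

    def test_uniform_sphere_limit(self):
        # discrete carved probe approaches Rg = sqrt(3/5) R as R grows
        for rb, tol in ((10.0, 0.03), (20.0, 0.015)):
            st = probe.build_probe(rb)
            g = probe.geometry(st.bead_positions)
            assert g.Rg == pytest.approx(np.sqrt(3 / 5) * rb, rel=tol)

    def test_carved_probe_spherical(self):
        st = probe.build_probe(20.0)
        g = probe.geometry(st.bead_positions)
        assert g.kappa2 < 0.01
        assert abs(g.Rg / (np.sqrt(3 / 5) * 20.0) - 1) < 0.03

    def test_rotation_invariance(self, rng):
        st = probe.build_probe(6.0)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=7).as_matrix()
        g0 = probe.geometry(st.bead_positions)
        g1 = probe.geometry(st.bead_positions @ R.T)
        assert g1.Rg == pytest.approx(g0.Rg, rel=1e-10)
        assert g1.kappa2 == pytest.approx(g0.kappa2, abs=1e-10)


class TestRdf:
    def _traj_with_residues(self, res_pos, box=40.0):
        nf = res_pos.shape[0]
        n_res = res_pos.shape[1]
        center = np.full((nf, 1, 3), box / 2)
        pos = np.concatenate([center, res_pos], axis=1)
        roles = np.array(["probe_bead"] + ["residue"] * n_res, object)
        pid = np.array([0] + [-1] * n_res)
        return make_trajectory(pos, box=(box, box, box), roles=roles,
                               probe_ids=pid)

    def test_ideal_gas_is_flat(self, rng):
        res = rng.uniform(0, 40, size=(40, 3000, 3))
        tr = self._traj_with_residues(res)
        r, g = probe.rdf_probe_residue(tr, r_max=15.0, bin_width=1.0)
        assert np.all(np.abs(g[2:] - 1.0) < 0.15)

    def test_shell_delta_peak_located(self, rng):
        # residues on a 10.6 Å shell around the probe center
        n = 500
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        res = 20.0 + 10.6 * v[None, :, :]
        tr = self._traj_with_residues(res)
        r, g = probe.rdf_probe_residue(tr, r_max=15.0, bin_width=0.5)
        assert r[np.argmax(g)] == pytest.approx(10.6, abs=0.25)

    def test_histogram_equals_brute_force(self, rng):
        res = rng.uniform(0, 40, size=(3, 200, 3))
        tr = self._traj_with_residues(res)
        r, g = probe.rdf_probe_residue(tr, r_max=12.0, bin_width=1.5)
        # brute-force minimum-image pair counting
        edges = np.arange(0, 12.0 + 1.5, 1.5)
        counts = np.zeros(len(edges) - 1)
        box = np.array([40.0, 40.0, 40.0])
        for f in range(3):
            c = tr.positions[f, 0]
            for k in range(200):
                d = tr.positions[f, 1 + k] - c
                d -= box * np.round(d / box)
                rr = np.sqrt(d @ d)
                if rr < 12.0:
                    counts[np.searchsorted(edges, rr, side="right") - 1] += 1
        rho = 200 / 40.0 ** 3
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        g_ref = counts / (3 * 1 * rho * shell)
        np.testing.assert_allclose(g, g_ref, rtol=1e-12)


class TestHydrodynamicRadius:
    def test_gaussian_peak(self):
        r = np.arange(0.25, 20, 0.5)
        g = 1.0 + 2.0 * np.exp(-((r - 10.6) / 1.5) ** 2)
        assert probe.hydrodynamic_radius(r, g) == pytest.approx(10.6,
                                                                abs=0.25)

    def test_first_of_two_peaks(self):
        r = np.arange(0.25, 20, 0.5)
        g = 1.0 + 1.5 * np.exp(-((r - 8) / 0.8) ** 2) \
            + 2.5 * np.exp(-((r - 12) / 0.8) ** 2)
        assert probe.hydrodynamic_radius(r, g) == pytest.approx(8.0, abs=0.5)

    def test_noisy_peak_refined(self, rng):
        r = np.arange(0.05, 20, 0.1)
        g = 1.0 + 2.0 * np.exp(-((r - 10.6) / 1.5) ** 2) \
            + rng.normal(0, 0.01, len(r))
        assert probe.hydrodynamic_radius(r, g) == pytest.approx(10.6,
                                                                abs=0.05 + 0.1)

    def test_structureless_rejected(self):
        r = np.arange(0.5, 10, 0.5)
        with pytest.raises(InputError):
            probe.hydrodynamic_radius(r, np.full_like(r, 0.9))


class TestVelocityProfile:
    def _traj(self, res_positions_fn, nf=20, n_res=200, box=60.0):
        times = 0.1 * np.arange(nf)
        res = res_positions_fn(times)
        center = np.zeros((nf, 1, 3))
        center[:, 0, :] = box / 2
        pos = np.concatenate([center, res], axis=1)
        roles = np.array(["probe_bead"] + ["residue"] * n_res, object)
        pid = np.array([0] + [-1] * n_res)
        return make_trajectory(pos, dt=0.1, box=None, roles=roles,
                               probe_ids=pid)

    def test_comoving_residues_no_slip(self, rng):
        base = rng.uniform(20, 40, size=(200, 3))

        def fn(times):
            out = np.repeat(base[None], len(times), axis=0)
            out[:, :, 0] += 3.0 * times[:, None]
            return out

        tr = self._traj(fn)
        vp = probe.velocity_profile(tr, v_x_probe=3.0,
                                    bins=np.arange(0, 30, 5.0))
        assert vp.no_slip_diagnostic == pytest.approx(1.0, rel=1e-6)

    def test_stationary_residues_full_slip(self, rng):
        base = rng.uniform(20, 40, size=(200, 3))

        def fn(times):
            return np.repeat(base[None], len(times), axis=0)

        tr = self._traj(fn)
        vp = probe.velocity_profile(tr, v_x_probe=3.0,
                                    bins=np.arange(0, 30, 5.0))
        assert vp.no_slip_diagnostic == pytest.approx(0.0, abs=1e-9)

    def test_decaying_field_recovered(self, rng):
        # v(r) = v_p exp(−(r−Rh)/δ) sampled by residue displacement
        Rh, delta, vp0 = 10.0, 6.0, 2.0
        n = 4000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        radii = rng.uniform(Rh, 28.0, n)
        base = 30.0 + u * radii[:, None]
        vel = vp0 * np.exp(-(radii - Rh) / delta)

        def fn(times):
            out = np.repeat(base[None], len(times), axis=0)
            out[:, :, 0] += vel[None, :] * times[:, None]
            return out

        tr = self._traj(fn, n_res=n)
        bins = np.arange(Rh, 28, 3.0)
        prof = probe.velocity_profile(tr, v_x_probe=vp0, bins=bins)
        want = vp0 * np.exp(-(prof.r_bins - Rh) / delta)
        good = np.isfinite(prof.v_x)
        # binned means within a tolerance set by intra-bin field spread
        np.testing.assert_allclose(prof.v_x[good], want[good], rtol=0.15)
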