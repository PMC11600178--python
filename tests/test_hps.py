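import itertools

import numpy as np
import pytest

from microrheo import hps
from microrheo.errors import InputError


class TestBondEnergy:
    def test_zero_at_equilibrium(self):
        assert hps.bond_energy(3.8) == 0.0

    def test_symmetric_about_minimum(self):
        assert hps.bond_energy(3.8 + 0.5) == pytest.approx(
            hps.bond_energy(3.8 - 0.5))

    def test_half_k_convention_value(self):
        # U(r0 + 1 Å) = ½·20·1² = 10 kcal/mol
        assert hps.bond_energy(4.8) == pytest.approx(10.0, rel=1e-12)


class TestVdw:
    def test_full_hydropathy_minimum_depth(self):
        sig = 5.0
        r = 2 ** (1 / 6) * sig
        u = hps.vdw_energy(r, 1.0, 1.0, sig, sig)
        assert u == pytest.approx(-0.2, rel=1e-10)

    def test_zero_hydropathy_purely_repulsive(self):
        sig = 5.0
        r = np.linspace(0.5 * sig, 4 * sig, 300)
        u = hps.vdw_energy(r, 0.0, 0.0, sig, sig)
        assert np.all(u >= -1e-15)
        assert hps.vdw_energy(2 ** (1 / 6) * sig, 0.0, 0.0, sig, sig) == \
            pytest.approx(0.0, abs=1e-12)

    def test_branch_continuity_random_lambdas(self, rng):
        sig_i, sig_j = 5.2, 6.0
        rc = 2 ** (1 / 6) * 0.5 * (sig_i + sig_j)
        for lam in rng.uniform(0, 4, size=100):
            below = hps.vdw_energy(rc * (1 - 1e-12), lam, lam, sig_i, sig_j)
            above = hps.vdw_energy(rc * (1 + 1e-12), lam, lam, sig_i, sig_j)
            assert abs(below - above) < 1e-12

    def test_lambda_one_is_plain_lj(self, rng):
        sig = 5.5
        for r in rng.uniform(0.8 * sig, 3.9 * sig, size=50):
            assert hps.vdw_energy(r, 1.0, 1.0, sig, sig) == pytest.approx(
                hps.lj_energy(r, sig, 0.2), rel=1e-12)

    def test_truncated_beyond_four_sigma(self):
        sig = 5.0
        assert hps.vdw_energy(4 * sig + 1e-9, 1.0, 1.0, sig, sig) == 0.0


class TestCoulomb:
    def test_unscreened_limit(self):
        params = hps.HPSParams(debye_l=1e10)
        r = 10.0
        screened = hps.coulomb_energy(r, -1, 1, params)
        bare = hps.COULOMB_KCAL_A * (-1) / (80.0 * r)
        assert screened == pytest.approx(bare, rel=2e-9)

    def test_cutoff(self):
        assert hps.coulomb_energy(35.0 + 1e-9, -1, 1) == 0.0

    def test_ek_pair_hand_value(self):
        # E-K pair at 10 Å with l = 10 Å, ϵr = 80:
        # U = 332.06…·(−1)/(80·10)·e^{−1}
        want = hps.COULOMB_KCAL_A * (-1.0) / 800.0 * np.exp(-1.0)
        assert hps.coulomb_energy(10.0, -1, 1) == pytest.approx(want,
                                                               rel=1e-12)


class TestNscd:
    def test_alternating_is_zero(self):
        assert hps.nscd("EK" * 10) == pytest.approx(0.0, abs=1e-12)

    def test_diblock_is_one(self):
        assert hps.nscd("E" * 10 + "K" * 10) == pytest.approx(1.0, abs=1e-12)

    def test_random_sequences_bracketed_and_match_bruteforce(self, rng):
        for _ in range(20):
            letters = np.array(list("EK" * 10))
            seq = "".join(rng.permutation(letters))
            val = hps.nscd(seq)
            assert 0.0 <= val <= 1.0
            # independent double-loop SCD recomputation
            q = [1.0 if c == "K" else -1.0 for c in seq]
            scd = sum(q[i] * q[j] * np.sqrt(j - i)
                      for i in range(20) for j in range(i + 1, 20)) / 20
            assert hps.scd(hps.assign_charges(seq)) == pytest.approx(scd)

    def test_sign_flip_and_reversal_invariance(self, rng):
        seq = "".join(rng.choice(list("EK"), size=16))
        flipped = seq.translate(str.maketrans("EK", "KE"))
        assert hps.nscd(seq) == pytest.approx(hps.nscd(flipped), abs=1e-12)
        assert hps.nscd(seq) == pytest.approx(hps.nscd(seq[::-1]), abs=1e-12)

    @pytest.mark.parametrize("n_pair", [3, 4, 5])
    def test_constructed_extremes_are_exhaustive_extremes(self, n_pair):
        """Exhaustive check (N ≤ 10, equal composition): the diblock
        arrangement attains the exhaustive SCD minimum and the
        alternating arrangement the exhaustive maximum."""
        base = [1.0] * n_pair + [-1.0] * n_pair
        values = [hps.scd(np.array(p))
                  for p in set(itertools.permutations(base))]
        alt = hps.scd(hps._alternating(np.array(base)))
        db = hps.scd(hps._diblock(np.array(base)))
        assert min(values) == pytest.approx(db, abs=1e-12)
        assert max(values) == pytest.approx(alt, abs=1e-12)

    def test_uncharged_sequence_rejected(self):
        with pytest.raises(InputError):
            hps.nscd("GGGGGG")


class TestCorrelationLength:
    def test_overlap_concentration_anchor(self):
        res = hps.correlation_length(rho=hps.correlation_length(
            1.0, 40.0, 6407.0).rho_star, Re=40.0, Mw=6407.0)
        assert res.xi == pytest.approx(40.0, rel=1e-12)

    def test_ideal_chain_scaling(self):
        r1 = hps.correlation_length(0.01, 40.0, 6407.0, nu=0.5)
        r2 = hps.correlation_length(0.02, 40.0, 6407.0, nu=0.5)
        assert r2.xi == pytest.approx(r1.xi / 2, rel=1e-12)

    def test_fixture_hand_value(self):
        rho_star = 3 * 6407.0 / (4 * np.pi * 40.0 ** 3)
        res = hps.correlation_length(2 * rho_star, 40.0, 6407.0)
        assert res.xi == pytest.approx(20.0, rel=1e-12)

    def test_singular_exponent_rejected(self):
        with pytest.raises(InputError):
            hps.correlation_length(0.01, 40.0, 6407.0, nu=1.0 / 3.0)


class TestCriteria:
    def test_size_threshold_inclusive(self):
        assert hps.probe_size_criterion(1.5 * 7.0, 7.0)["verdict"] == "ok"
        assert hps.probe_size_criterion(1.49 * 7.0, 7.0)["verdict"] == \
            "too_small"

    def test_above_recommended_band_noted(self):
        out = hps.probe_size_criterion(2.5 * 7.0, 7.0)
        assert out["verdict"] == "ok" and "band" in out["note"]

    @pytest.mark.parametrize("ratio,verdict", [
        (0.0, "below_no_slip"), (0.5, "below_no_slip"),
        (1.0, "optimal"), (1.25, "optimal"), (1.5, "optimal"),
        (1.75, "adsorption_risk"), (2.0, "adsorption_risk"),
        (4.0, "adsorption_risk")])
    def test_interaction_window_bands(self, ratio, verdict):
        assert hps.interaction_window_check(ratio)["verdict"] == verdict


class TestTables:
    def test_both_scales_cover_20_residues(self):
        for scale in ("kr", "urry"):
            df = hps.residue_params(scale)
            assert len(df) == 20
            assert df["lambda"].between(0, 1.05).all()

    def test_charge_assignment(self):
        q = hps.assign_charges("EDKRH")
        np.testing.assert_allclose(q, [-1, -1, 1, 1, 0])
        q2 = hps.assign_charges("H", hps.with_his_charge(
            hps.DEFAULT_PARAMS, 0.5))
        assert q2[0] == 0.5


class TestPairEnergyProperties:
    """Property-based invariants of the pair potentials."""

    def test_vdw_cutoff_and_continuity_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(lam=st.floats(0.0, 4.0), sig=st.floats(4.5, 6.8),
               x=st.floats(0.7, 5.0))
        def check(lam, sig, x):
            r = x * sig
            u = hps.vdw_energy(r, lam, lam, sig, sig)
            if x > 4.0:
                assert u == 0.0
            rc = 2 ** (1 / 6) * sig
            lo = hps.vdw_energy(rc * (1 - 1e-12), lam, lam, sig, sig)
            hi = hps.vdw_energy(rc * (1 + 1e-12), lam, lam, sig, sig)
            assert abs(lo - hi) < 1e-10

        check()

    def test_nscd_symmetry_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=40, deadline=None, derandomize=True)
        @given(st.lists(st.sampled_from("EK"), min_size=4, max_size=24))
        def check(letters):
            seq = "".join(letters)
            q = hps.assign_charges(seq)
            if np.sum(q != 0) < 2 or np.all(q == q[0]):
                return
            s = hps.scd(q)
            assert hps.scd(-q) == pytest.approx(s, abs=1e-12)
            assert hps.scd(q[::-1]) == pytest.approx(s, abs=1e-12)

        check()
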