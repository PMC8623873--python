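"""Elastic-tensor analysis: averaging bounds, directional properties,
anisotropy, hardness and Bond Work Index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanosusp.constants import GPA_TO_KG_MM2
from nanosusp.elastic import (StabilityError, StiffnessTensor,
                              anisotropy_indices, bwi_from_hardness,
                              directional_properties, engineering_constants,
                              fracture_toughness, hill_from_bounds,
                              vickers_hardness, vrh_averages)
from nanosusp.synth import (cubic_stiffness, isotropic_stiffness,
                            random_spd_stiffness)


class TestStiffnessTensor:
    def test_compliance_inverse(self):
        t = random_spd_stiffness(3)
        assert np.allclose(t.S @ t.C, np.eye(6), atol=1e-8)

    def test_asymmetric_rejected(self):
        C = np.eye(6) * 10.0
        C[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            StiffnessTensor(C)

    def test_unstable_rejected_names_eigenvalue(self):
        C = np.eye(6) * 10.0
        C[5, 5] = -1.0
        with pytest.raises(StabilityError, match="eigenvalue"):
            StiffnessTensor(C)

    def test_text_and_json_io_roundtrip(self, tmp_path):
        t = random_spd_stiffness(7)
        txt = tmp_path / "cij.txt"
        txt.write_text("# GPa\n" + "\n".join(
            " ".join(f"{v:.12g}" for v in row) for row in t.C))
        jsn = tmp_path / "cij.json"
        jsn.write_text('{"Cij": ' + str(t.C.tolist()) + "}")
        assert np.allclose(StiffnessTensor.from_file(txt).C, t.C)
        assert np.allclose(StiffnessTensor.from_file(jsn).C, t.C)


class TestVRH:
    def test_isotropic_all_schemes_agree(self):
        avg = vrh_averages(isotropic_stiffness(10.0, 5.0))
        assert np.allclose([avg.K_V, avg.K_R, avg.K_H], 10.0, atol=1e-10)
        assert np.allclose([avg.G_V, avg.G_R, avg.G_H], 5.0, atol=1e-10)

    def test_hill_is_exact_mean_and_bounded(self, rng):
        """Reuss <= Hill <= Voigt for K and G on every SPD tensor."""
        for _ in range(1000):
            avg = vrh_averages(random_spd_stiffness(rng))
            assert avg.K_R <= avg.K_H <= avg.K_V
            assert avg.G_R <= avg.G_H <= avg.G_V
            assert avg.K_H == pytest.approx(0.5 * (avg.K_V + avg.K_R), abs=1e-12)
            assert avg.G_H == pytest.approx(0.5 * (avg.G_V + avg.G_R), abs=1e-12)
            assert -1.0 < avg.nu_V < 0.5 and -1.0 < avg.nu_R < 0.5

    def test_published_hill_average(self):
        """Voigt/Reuss bulk moduli 10.45/8.43 GPa average to Hill 9.44 GPa."""
        h = hill_from_bounds(10.45, 8.43, 6.11, 3.15)
        assert h["K_H"] == pytest.approx(9.44, abs=5e-3)
        assert h["G_H"] == pytest.approx(4.63, abs=5e-3)
        # both E/nu conventions at the printed precision
        assert h["E_H_closed"] == pytest.approx(11.94, abs=5e-3)
        assert h["nu_H_closed"] == pytest.approx(0.289, abs=5e-4)
        assert h["E_H_arith"] == pytest.approx(11.872, abs=5e-3)
        assert h["pugh_GK"] == pytest.approx(0.49, abs=5e-3)


class TestEngineeringConstants:
    def test_incompressible_limit(self):
        assert engineering_constants(10.0, 1e-9)["nu"] == pytest.approx(0.5, abs=1e-9)

    def test_closed_form(self):
        ec = engineering_constants(9.44, 4.63)
        assert ec["E"] == pytest.approx(9 * 9.44 * 4.63 / (3 * 9.44 + 4.63))
        assert ec["pugh_GK"] * ec["pugh_KG"] == pytest.approx(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            engineering_constants(-1.0, 5.0)


def _rotation_to(n):
    """A rotation matrix whose first row maps onto the direction n."""
    n = n / np.linalg.norm(n)
    ref = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return np.stack([n, u, v])


class TestDirectional:
    def test_isotropic_direction_independent(self, rng):
        t = isotropic_stiffness(10.0, 5.0)
        E_iso = 9 * 10.0 * 5.0 / (3 * 10.0 + 5.0)
        for _ in range(100):
            theta = np.arccos(rng.uniform(-1, 1))
            phi = rng.uniform(0, 2 * np.pi)
            p = directional_properties(t, theta, phi, n_chi=36)
            assert p.E_dir == pytest.approx(E_iso, abs=1e-9)
            assert p.LC_dir == pytest.approx(1e3 / (3 * 10.0), abs=1e-9)
            assert np.linalg.norm(p.unit_vector) == pytest.approx(1.0, abs=1e-12)

    def test_cubic_100_closed_form(self):
        t = cubic_stiffness(20.0, 8.0, 5.0)
        p = directional_properties(t, np.pi / 2, 0.0)  # [100]
        assert p.E_dir == pytest.approx(1.0 / t.S[0, 0], rel=1e-12)

    def test_matches_tensor_rotation_oracle(self, rng):
        """E(n) from the compliance contraction equals 1/S'_1111 of the
        explicitly rotated 4th-rank tensor."""
        for _ in range(20):
            t = random_spd_stiffness(rng)
            S4 = t.compliance_tensor()
            for _ in range(10):
                n = rng.normal(size=3)
                n /= np.linalg.norm(n)
                R = _rotation_to(n)
                S_rot = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, S4)
                E_oracle = 1.0 / S_rot[0, 0, 0, 0]
                theta = np.arccos(n[2])
                phi = np.arctan2(n[1], n[0])
                p = directional_properties(t, theta, phi, n_chi=8)
                assert p.E_dir == pytest.approx(E_oracle, abs=1e-8)


class TestAnisotropy:
    def test_isotropic_indices_vanish(self):
        a = anisotropy_indices(isotropic_stiffness(10.0, 5.0))
        assert abs(a.UAI) < 1e-9 and abs(a.A_CB) < 1e-9 and abs(a.A_log) < 1e-9

    def test_published_uai(self):
        uai = 5 * 6.11 / 3.15 + 10.45 / 8.43 - 6
        assert uai == pytest.approx(4.94, abs=5e-3)

    def test_cauchy_pressure_by_construction(self):
        a = anisotropy_indices(cubic_stiffness(20.0, 8.0, 5.0))
        assert a.cauchy_pressure == pytest.approx(3.0)

    def test_ucb_nonnegative_on_random(self, rng):
        for _ in range(50):
            a = anisotropy_indices(random_spd_stiffness(rng))
            assert a.UAI >= -1e-12
            assert 0.0 <= a.A_CB < 1.0


class TestHardness:
    def test_mazhnik_published_value(self):
        assert vickers_hardness(11.94, 0.289) == pytest.approx(0.61, abs=5e-3)

    def test_shear_empirical_reproduces_hardness_column(self):
        for G, H in [(6.11, 0.901), (3.15, 0.465), (4.63, 0.683)]:
            assert vickers_hardness(1.0, 0.0, "shear_empirical", G=G) == \
                pytest.approx(H, abs=5e-4)

    def test_mazhnik_chi_zero_nu(self):
        assert vickers_hardness(7.0, 0.0) == pytest.approx(0.096 * 7.0)

    def test_shear_model_requires_G(self):
        with pytest.raises(ValueError, match="requires G"):
            vickers_hardness(10.0, 0.2, "shear_empirical")


class TestFractureToughness:
    V0 = 306e-6 / 6.02214076e23

    def test_scaling_in_E(self):
        k1 = fracture_toughness(10.0, 0.25, self.V0)
        k2 = fracture_toughness(20.0, 0.25, self.V0)
        assert k2 / k1 == pytest.approx(2.0 ** 1.5, rel=1e-12)

    def test_finite_and_continuous_in_nu(self):
        ks = [fracture_toughness(11.94, nu, self.V0) for nu in np.linspace(0, 0.45, 50)]
        assert np.all(np.isfinite(ks))
        assert np.max(np.abs(np.diff(ks))) < 0.5 * np.max(np.abs(ks))

    def test_pinned_regression(self):
        # direct evaluation at the average elastic state of the API
        assert fracture_toughness(11.94, 0.289, self.V0) == \
            pytest.approx(0.0401, abs=2e-4)

    def test_v0_not_defaultable(self):
        with pytest.raises(ValueError, match="V0"):
            fracture_toughness(10.0, 0.2, None)


class TestBWI:
    def test_gent_quadratic_at_api_hardness(self):
        VH = 0.61 * GPA_TO_KG_MM2  # 0.61 GPa in kg/mm^2
        assert VH == pytest.approx(62.2, abs=0.1)
        assert bwi_from_hardness(VH)["BWI0"] == pytest.approx(9.53, abs=0.01)

    def test_unit_factors_identity(self):
        r = bwi_from_hardness(60.0)
        assert r["BWI"] == r["BWI0"]

    @given(f1=st.floats(0.5, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_multiplicative_correction(self, f1):
        base = bwi_from_hardness(60.0)["BWI0"]
        assert bwi_from_hardness(60.0, (f1, 1, 1, 1, 1))["BWI"] == \
            pytest.approx(f1 * base, rel=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            bwi_from_hardness(-5.0)
        with pytest.raises(ValueError):
            bwi_from_hardness(60.0, (0.0, 1, 1, 1, 1))
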