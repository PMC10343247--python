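"""Bridging micromechanics: constituent types, bridging matrix, bundle
constants and parameter back-solving."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from braidfe.bridging import (
    backsolve_params,
    bridging_matrix,
    bundle_compliance,
    bundle_constants,
)
from braidfe.materials import (
    BridgingParams,
    IsotropicMaterial,
    TransverselyIsotropicMaterial,
    shear_modulus,
)


class TestShearModulus:
    @pytest.mark.parametrize(
        "E, v, expected",
        [
            (57.0, 0.43, 19.93007),  # PCU, MPa
            (2.0, 0.0, 1.0),
            (128700.0, 0.3, 49500.0),  # Kevlar axial
        ],
    )
    def test_values(self, E, v, expected):
        assert shear_modulus(E, v) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("E, v", [(1.0, 0.5), (1.0, -1.0), (1.0, 0.7), (-1.0, 0.3)])
    def test_domain_errors(self, E, v):
        with pytest.raises(ValueError):
            shear_modulus(E, v)

    def test_isotropic_material_derives_G(self):
        m = IsotropicMaterial(E=57.0, v=0.43)
        assert m.G == pytest.approx(0.5 * 57.0 / 1.43, rel=1e-12)


class TestTransverselyIsotropic:
    def test_g23_identity_derived(self, kevlar):
        assert kevlar.G23 == pytest.approx(
            kevlar.E22 / (2 + 2 * kevlar.v23), rel=1e-12
        )

    def test_inconsistent_g23_rejected(self):
        with pytest.raises(ValueError, match="G23"):
            TransverselyIsotropicMaterial(
                E11=100.0, E22=10.0, v12=0.3, v23=0.3, G12=5.0, G23=9.0
            )

    def test_compliance_symmetric(self, kevlar, pcu):
        for m in (kevlar, TransverselyIsotropicMaterial.from_isotropic(pcu)):
            S = m.compliance()
            assert np.allclose(S, S.T, atol=0)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            BridgingParams(Vf=1.2)
        with pytest.raises(ValueError):
            BridgingParams(Vf=0.5, alpha=0.0)


class TestBridgingMatrix:
    def test_study_entries(self, kevlar, pcu, study_params):
        A = bridging_matrix(kevlar, pcu, study_params)
        assert A.a11 == pytest.approx(57.0 / 128700.0, rel=1e-9)  # 4.429e-4
        assert A.a22 == pytest.approx(0.3 + 0.7 * 57.0 / 12870.0, rel=1e-9)  # 0.30310
        assert A.a55 == pytest.approx(0.3 + 0.7 * pcu.G / 12870.0, rel=1e-9)
        M = A.A
        assert M[1, 1] == M[2, 2] == M[3, 3]
        assert M[4, 4] == M[5, 5]
        assert M[0, 1] == M[0, 2]
        # printed zero pattern
        assert M[1, 0] == M[2, 0] == M[1, 2] == M[2, 1] == 0.0

    def test_identical_constituents_give_identity(self, pcu):
        fib = TransverselyIsotropicMaterial.from_isotropic(pcu)
        for alpha, beta in [(0.3, 0.3), (0.45, 0.6), (0.9, 0.1)]:
            A = bridging_matrix(fib, pcu, BridgingParams(Vf=0.5, alpha=alpha, beta=beta))
            assert A.a11 == pytest.approx(1.0)
            assert A.a22 == pytest.approx(1.0)
            assert A.a55 == pytest.approx(1.0)


class TestBundleConstants:
    def test_study_bundle_row(self, kevlar, pcu, study_params):
        """Kevlar/PCU bundle at Vf=0.70 reproduces the published row."""
        b = bundle_constants(kevlar, pcu, study_params)
        ec = b.engineering_constants()
        assert ec["EL"] / 1000 == pytest.approx(90.107, rel=1e-4)
        assert ec["ET"] / 1000 == pytest.approx(0.47945, rel=1e-4)
        assert ec["GLT"] / 1000 == pytest.approx(0.172316, rel=1e-4)
        assert ec["GTZ"] / 1000 == pytest.approx(0.171314, rel=1e-4)
        assert ec["vLT"] == pytest.approx(0.7 * 0.3 + 0.3 * 0.43, rel=1e-9)

    def test_rule_of_mixtures_identity(self, kevlar, pcu):
        for Vf in (0.2, 0.5, 0.7, 0.9):
            b = bundle_constants(kevlar, pcu, BridgingParams(Vf=Vf))
            rom = Vf * kevlar.E11 + (1 - Vf) * pcu.E
            assert b.E11 == pytest.approx(rom, rel=1e-9)

    def test_limits(self, kevlar, pcu):
        near_fiber = bundle_constants(kevlar, pcu, BridgingParams(Vf=1 - 1e-9))
        assert near_fiber.E11 == pytest.approx(kevlar.E11, rel=1e-6)
        assert near_fiber.E22 == pytest.approx(kevlar.E22, rel=1e-4)
        assert near_fiber.G12 == pytest.approx(kevlar.G12, rel=1e-4)
        near_matrix = bundle_constants(kevlar, pcu, BridgingParams(Vf=1e-9))
        assert near_matrix.E11 == pytest.approx(pcu.E, rel=1e-4)
        assert near_matrix.E22 == pytest.approx(pcu.E, rel=1e-4)
        assert near_matrix.v23 == pytest.approx(pcu.v, rel=1e-4)

    def test_transverse_isotropy_holds_on_output(self, kevlar, pcu):
        b = bundle_constants(kevlar, pcu, BridgingParams(Vf=0.6, alpha=0.4, beta=0.5))
        assert b.G23 == pytest.approx(b.E22 / (2 + 2 * b.v23), rel=1e-9)

    @given(
        Vf=st.floats(0.05, 0.95),
        alpha=st.floats(0.05, 0.95),
        beta=st.floats(0.05, 0.95),
    )
    def test_bounds_between_constituents(self, kevlar, pcu, Vf, alpha, beta):
        """Every bundle modulus lies between matrix and fiber values."""
        b = bundle_constants(kevlar, pcu, BridgingParams(Vf=Vf, alpha=alpha, beta=beta))
        for mod, lo, hi in [
            (b.E11, pcu.E, kevlar.E11),
            (b.E22, pcu.E, kevlar.E22),
            (b.G12, pcu.G, kevlar.G12),
        ]:
            assert lo * (1 - 1e-9) <= mod <= hi * (1 + 1e-9)

    def test_monotone_in_volume_fraction(self, kevlar, pcu):
        grids = [bundle_constants(kevlar, pcu, BridgingParams(Vf=v))
                 for v in np.linspace(0.1, 0.9, 9)]
        for attr in ("E11", "E22", "G12"):
            vals = [getattr(b, attr) for b in grids]
            assert np.all(np.diff(vals) > 0)

    def test_coupled_variant_keeps_axial_rom(self, kevlar, pcu, study_params):
        S = bundle_compliance(kevlar, pcu, study_params, coupled=True)
        assert np.allclose(S, S.T)
        assert 1 / S[0, 0] == pytest.approx(0.7 * kevlar.E11 + 0.3 * pcu.E, rel=1e-6)


class TestBacksolve:
    def test_roundtrip_study_row(self, kevlar, pcu, study_params):
        target = bundle_constants(kevlar, pcu, study_params)
        got = backsolve_params(target, kevlar, pcu)
        assert got.Vf == pytest.approx(0.700, abs=1e-6)
        assert got.beta == pytest.approx(0.30, abs=1e-6)
        assert got.alpha == pytest.approx(0.30, abs=1e-6)
        re = bundle_constants(kevlar, pcu, got)
        for attr in ("E11", "E22", "G12"):
            assert getattr(re, attr) == pytest.approx(getattr(target, attr), rel=5e-3)

    @given(
        Vf=st.floats(0.1, 0.9),
        alpha=st.floats(0.1, 0.9),
        beta=st.floats(0.1, 0.9),
    )
    def test_roundtrip_property(self, kevlar, pcu, Vf, alpha, beta):
        target = bundle_constants(
            kevlar, pcu, BridgingParams(Vf=Vf, alpha=alpha, beta=beta)
        )
        got = backsolve_params(target, kevlar, pcu)
        re = bundle_constants(kevlar, pcu, got)
        for attr in ("E11", "E22", "G12"):
            assert getattr(re, attr) == pytest.approx(getattr(target, attr), rel=5e-3)

    def test_matrix_target_gives_vanishing_vf(self, kevlar, pcu):
        target = TransverselyIsotropicMaterial.from_isotropic(pcu)
        got = backsolve_params(target, kevlar, pcu)
        assert got.Vf < 1e-6

    def test_unattainable_target_reports_range(self, kevlar, pcu):
        hopeless = TransverselyIsotropicMaterial(
            E11=2 * kevlar.E11, E22=100.0, v12=0.3, v23=0.3, G12=100.0
        )
        with pytest.raises(ValueError, match="attainable"):
            backsolve_params(hopeless, kevlar, pcu)
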