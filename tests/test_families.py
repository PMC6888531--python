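"""Isotherm family definitions: prediction, Polanyi potential, transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorbfit import (
    Family,
    InvalidParameterError,
    IsothermDataset,
    MissingContextError,
    R,
    SolubilityExceededError,
    TransformDomainError,
    make_params,
    polanyi_potential,
    predict_qe,
    transform_points,
    untransform_qe,
)

CS = 69_000.0
T = 298.15


class TestPredict:
    def test_langmuir_hand_value(self):
        # independent scalar arithmetic on the hyperbolic form
        p = make_params("langmuir", qmax=169.5, k_l=2.745e-3)
        expected = 169.5 * 2.745e-3 * 1000.0 / (1.0 + 2.745e-3 * 1000.0)
        assert predict_qe(p, 1000.0) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(124.24, abs=0.01)

    @pytest.mark.parametrize("family,kv", [
        ("langmuir", dict(qmax=100.0, k_l=0.01)),
        ("freundlich", dict(k_f=2.0, n_f=2.0)),
        ("redlich_peterson", dict(k_rp=0.5, a_rp=0.01, beta=0.9)),
    ])
    def test_zero_concentration_gives_zero(self, family, kv):
        assert predict_qe(make_params(family, **kv), 0.0) == 0.0

    def test_dr_at_solubility_reaches_capacity(self):
        p = make_params("dubinin_radushkevich", qmax=282.9, k_dr=8.107e-9)
        assert predict_qe(p, CS, temperature=T, solubility=CS) == pytest.approx(
            282.9, rel=1e-14)

    def test_temkin_negative_below_unit_activity(self):
        # K_T*Ce < 1 gives a negative prediction, returned unclamped
        p = make_params("temkin", k_t=0.01, b_t=100.0)
        assert predict_qe(p, 10.0, temperature=T) < 0

    def test_polanyi_family_requires_solubility(self):
        p = make_params("dubinin_radushkevich", qmax=100.0, k_dr=1e-8)
        with pytest.raises(MissingContextError):
            predict_qe(p, 100.0, temperature=T)

    def test_ce_above_solubility_rejected(self):
        p = make_params("dubinin_astakhov", qmax=100.0, k_da=1e-10, n_da=2.5)
        with pytest.raises(SolubilityExceededError):
            predict_qe(p, 2 * CS, temperature=T, solubility=CS)

    @pytest.mark.parametrize("family,kv", [
        ("langmuir", dict(qmax=-1.0, k_l=0.01)),
        ("redlich_peterson", dict(k_rp=0.5, a_rp=0.01, beta=1.2)),
        ("freundlich", dict(k_f=2.0, n_f=0.5)),
        ("dubinin_astakhov", dict(qmax=100.0, k_da=1e-10, n_da=0.9)),
    ])
    def test_invalid_parameters_rejected(self, family, kv):
        with pytest.raises(InvalidParameterError):
            make_params(family, **kv)

    @pytest.mark.parametrize("family,kv", [
        ("langmuir", dict(qmax=150.0, k_l=3e-3)),
        ("freundlich", dict(k_f=2.5, n_f=1.9)),
        ("dubinin_radushkevich", dict(qmax=280.0, k_dr=8e-9)),
        ("dubinin_astakhov", dict(qmax=210.0, k_da=5e-12, n_da=2.7)),
    ])
    def test_nondecreasing_in_ce(self, family, kv):
        p = make_params(family, **kv)
        grid = np.geomspace(1.0, 6900.0, 200)
        q = predict_qe(p, grid, temperature=T, solubility=CS)
        assert np.all(np.diff(q) >= -1e-12 * np.abs(q[1:]))


class TestPolanyi:
    def test_vanishes_at_solubility(self):
        assert polanyi_potential(CS, CS, T) == 0.0

    def test_decade_hand_value(self):
        expected = R * T * math.log(10.0)
        assert polanyi_potential(CS / 10.0, CS, T) == pytest.approx(expected,
                                                                    rel=1e-14)
        assert expected == pytest.approx(5707.5, abs=0.5)

    def test_domain_violations(self):
        with pytest.raises(SolubilityExceededError):
            polanyi_potential(CS * 1.01, CS, T)
        with pytest.raises(TransformDomainError):
            polanyi_potential(0.0, CS, T)
        with pytest.raises(MissingContextError):
            polanyi_potential(10.0, CS, -1.0)
        with pytest.raises(MissingContextError):
            polanyi_potential(10.0, None, T)


class TestTransforms:
    def test_langmuir_reciprocals(self):
        x, y = transform_points("langmuir", [500.0], [100.0])
        assert (x[0], y[0]) == (0.002, 0.01)

    def test_freundlich_logs(self):
        x, y = transform_points("freundlich", [math.e], [math.e**2])
        assert x[0] == pytest.approx(1.0, rel=1e-14)
        assert y[0] == pytest.approx(2.0, rel=1e-14)

    def test_rp_boundary_is_error(self):
        # K_RP*Ce/Qe == 1 -> log of zero
        with pytest.raises(TransformDomainError):
            transform_points("redlich_peterson", [100.0], [50.0], k_rp=0.5)

    def test_domain_error_names_offending_point(self):
        with pytest.raises(TransformDomainError) as err:
            transform_points("langmuir", [100.0, 0.0, 50.0], [10.0, 5.0, 2.0])
        assert err.value.indices == (1,)

    @pytest.mark.parametrize("family,kv,aux", [
        ("langmuir", dict(qmax=150.0, k_l=3e-3), {}),
        ("freundlich", dict(k_f=2.5, n_f=1.9), {}),
        ("redlich_peterson", dict(k_rp=0.5, a_rp=5e-3, beta=0.9), {"k_rp": 0.5}),
        ("temkin", dict(k_t=5e-2, b_t=90.0), {}),
        ("dubinin_radushkevich", dict(qmax=280.0, k_dr=8e-9), {}),
        ("dubinin_astakhov", dict(qmax=210.0, k_da=5e-12, n_da=2.7),
         {"n_da": 2.7}),
    ])
    def test_transform_untransform_recovers_qe(self, family, kv, aux):
        p = make_params(family, **kv)
        ce = np.geomspace(50.0, 5000.0, 9)
        qe = np.atleast_1d(predict_qe(p, ce, temperature=T, solubility=CS))
        x, y = transform_points(family, ce, qe, temperature=T, solubility=CS,
                                **aux)
        back = untransform_qe(family, x, y, k_rp=aux.get("k_rp"))
        np.testing.assert_allclose(back, qe, rtol=1e-12)


class TestFamilyEquivalences:
    @given(k_rp=st.floats(0.05, 5.0), a_rp=st.floats(1e-4, 0.1),
           ce=st.floats(0.1, 1e4))
    @settings(deadline=None, max_examples=60)
    def test_rp_beta_one_is_langmuir(self, k_rp, a_rp, ce):
        rp = make_params("redlich_peterson", k_rp=k_rp, a_rp=a_rp, beta=1.0)
        lang = make_params("langmuir", qmax=k_rp / a_rp, k_l=a_rp)
        assert predict_qe(rp, ce) == pytest.approx(predict_qe(lang, ce),
                                                   rel=1e-12)

    @given(qmax=st.floats(10.0, 500.0), k=st.floats(1e-10, 1e-8),
           ce=st.floats(1.0, 6.9e3))
    @settings(deadline=None, max_examples=60)
    def test_da_exponent_two_is_dr(self, qmax, k, ce):
        da = make_params("dubinin_astakhov", qmax=qmax, k_da=k, n_da=2.0)
        dr = make_params("dubinin_radushkevich", qmax=qmax, k_dr=k)
        assert predict_qe(da, ce, temperature=T, solubility=CS) == pytest.approx(
            predict_qe(dr, ce, temperature=T, solubility=CS), rel=1e-12)


class TestDataset:
    def test_rejects_negative_values(self):
        with pytest.raises(InvalidParameterError):
            IsothermDataset(np.array([1.0, -2.0]), np.array([1.0, 2.0]))

    def test_solubility_headroom_enforced(self):
        with pytest.raises(SolubilityExceededError):
            IsothermDataset(np.array([100.0, 200.0]), np.array([1.0, 2.0]),
                            solubility=150.0)
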