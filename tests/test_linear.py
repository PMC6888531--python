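"""Linearized estimation: OLS engine, back-transforms, profile search."""

import numpy as np
import pytest

from sorbfit import (
    DegenerateDataError,
    Family,
    InsufficientDataError,
    IsothermDataset,
    SearchBoundsError,
    TransformDomainError,
    default_design,
    fit_linear,
    generate_dataset,
    make_params,
    ols_line,
    profile_fit_linear,
    transform_points,
)
from sorbfit.linear import _one_minus_r2

from conftest import TRUTH_PARAMS, noiseless_dataset, truth


class TestOlsLine:
    def test_exact_line(self):
        slope, intercept, r2 = ols_line([0, 1, 2], [1, 3, 5])
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_hand_computed_flat_fit(self):
        # closed-form OLS: x=(0,1,2), y=(0,1,0) -> slope 0, intercept 1/3, r2 0
        slope, intercept, r2 = ols_line([0, 1, 2], [0, 1, 0])
        assert slope == pytest.approx(0.0, abs=1e-15)
        assert intercept == pytest.approx(1 / 3, rel=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_and_short_inputs(self):
        with pytest.raises(DegenerateDataError):
            ols_line([2, 2, 2], [1, 2, 3])
        with pytest.raises(InsufficientDataError):
            ols_line([1, 2], [1, 2])

    def test_r2_invariant_under_affine_y_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 20)
        y = 2.0 * x + rng.normal(0, 1.0, 20)
        _, _, r2 = ols_line(x, y)
        _, _, r2_scaled = ols_line(x, 7.5 * y - 3.0)
        assert r2_scaled == pytest.approx(r2, rel=1e-12)


class TestFitLinear:
    def test_langmuir_round_trip_ten_points(self, langmuir_truth):
        dataset, _ = generate_dataset(langmuir_truth,
                                      default_design(n_points=10))
        fr = fit_linear("langmuir", dataset)
        assert fr.params.qmax == pytest.approx(169.5, rel=1e-8)
        assert fr.params.k_l == pytest.approx(2.745e-3, rel=1e-8)
        assert fr.r2 >= 1 - 1e-12
        assert fr.n == 10 and fr.p == 2

    def test_freundlich_exact_power_law(self):
        ds = IsothermDataset(np.array([1.0, 10.0, 100.0]),
                             np.array([2.0, 20.0, 200.0]))
        fr = fit_linear("freundlich", ds)
        assert fr.params.n_f == pytest.approx(1.0, rel=1e-12)
        assert fr.params.k_f == pytest.approx(2.0, rel=1e-12)
        assert fr.r2 == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        ds = IsothermDataset(np.array([1.0, 10.0]), np.array([2.0, 20.0]))
        with pytest.raises(InsufficientDataError):
            fit_linear("freundlich", ds)

    def test_out_of_domain_point_refused_by_default(self):
        ds = IsothermDataset(np.array([0.0, 10.0, 100.0, 1000.0]),
                             np.array([1.0, 20.0, 50.0, 90.0]))
        with pytest.raises(TransformDomainError) as err:
            fit_linear("langmuir", ds)
        assert 0 in err.value.indices

    def test_allow_drop_excludes_and_records(self):
        ds = IsothermDataset(np.array([0.0, 10.0, 100.0, 1000.0, 2000.0]),
                             np.array([1.0, 20.0, 50.0, 90.0, 95.0]))
        fr = fit_linear("langmuir", ds, allow_drop=True)
        assert fr.n == 4
        assert 0 not in fr.extras["used_indices"]

    @pytest.mark.parametrize("family", list(Family))
    def test_noiseless_round_trip_all_families(self, family):
        params, dataset = noiseless_dataset(family)
        fr = fit_linear(family, dataset)
        for name, true_value in params.as_dict().items():
            got = getattr(fr.params, name)
            assert got == pytest.approx(true_value, rel=1e-6), name
        assert fr.r2 >= 1 - 1e-10

    @pytest.mark.parametrize("family,kv", [
        ("langmuir", dict(qmax=95.0, k_l=8.2e-3)),
        ("freundlich", dict(k_f=0.8, n_f=2.6)),
        ("temkin", dict(k_t=2.1e-2, b_t=130.0)),
        ("dubinin_radushkevich", dict(qmax=140.0, k_dr=1.2e-8)),
        ("redlich_peterson", dict(k_rp=0.27, a_rp=1.9e-2, beta=0.76)),
        ("dubinin_astakhov", dict(qmax=130.0, k_da=2.6e-9, n_da=2.11)),
    ])
    def test_round_trip_away_from_fixture_truths(self, family, kv):
        params = make_params(family, **kv)
        dataset, _ = generate_dataset(params, default_design())
        fr = fit_linear(family, dataset)
        for name, true_value in kv.items():
            assert getattr(fr.params, name) == pytest.approx(
                true_value, rel=1e-6), name
        assert fr.r2 >= 1 - 1e-10


def _grid_oracle(family, dataset, bounds, n_grid=1000):
    """Independent dense-grid + local-parabola oracle for the profile search."""
    def score(theta):
        aux = {"k_rp": theta} if family is Family.REDLICH_PETERSON else {"n_da": theta}
        try:
            x, y = transform_points(family, dataset.ce, dataset.qe,
                                    temperature=dataset.temperature,
                                    solubility=dataset.solubility, **aux)
        except TransformDomainError:
            return np.inf
        return _one_minus_r2(np.asarray(x, float), np.asarray(y, float))

    grid = np.geomspace(bounds[0], bounds[1], n_grid)
    vals = np.array([score(t) for t in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    # golden-section refinement on the bracketing interval
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = np.log(lo), np.log(hi)
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = score(np.exp(c)), score(np.exp(d))
    for _ in range(200):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = score(np.exp(c))
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = score(np.exp(d))
        if b - a < 1e-12:
            break
    return float(np.exp((a + b) / 2.0))


class TestProfileSearch:
    def test_rp_fixture_recovery(self):
        params, dataset = noiseless_dataset(Family.REDLICH_PETERSON)
        fr = profile_fit_linear(Family.REDLICH_PETERSON, dataset)
        assert fr.params.k_rp == pytest.approx(0.471, rel=1e-3)
        assert fr.r2 >= 1 - 1e-8

    def test_da_fixture_recovery(self):
        params, dataset = noiseless_dataset(Family.DUBININ_ASTAKHOV)
        fr = profile_fit_linear(Family.DUBININ_ASTAKHOV, dataset)
        assert fr.params.n_da == pytest.approx(2.733, abs=1e-3)
        assert fr.r2 >= 1 - 1e-8

    def test_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(4):
            kv = dict(k_rp=rng.uniform(0.2, 0.6), a_rp=10 ** rng.uniform(-3, -1.5),
                      beta=rng.uniform(0.7, 0.95))
            dataset, _ = generate_dataset(
                make_params("redlich_peterson", **kv), default_design())
            fr = profile_fit_linear(Family.REDLICH_PETERSON, dataset)
            feas = (1 + 1e-6) * float(np.max(dataset.qe / dataset.ce))
            oracle = _grid_oracle(Family.REDLICH_PETERSON, dataset,
                                  (feas, 1e4 * feas))
            assert fr.params.k_rp == pytest.approx(oracle, rel=1e-6)

    def test_search_bounds_excluding_feasible_region(self):
        _, dataset = noiseless_dataset(Family.REDLICH_PETERSON)
        with pytest.raises(SearchBoundsError):
            profile_fit_linear(Family.REDLICH_PETERSON, dataset,
                               search_bounds=(1e-6, 1e-5))

    def test_profile_applies_only_to_three_parameter_families(self):
        _, dataset = noiseless_dataset(Family.LANGMUIR)
        with pytest.raises(Exception):
            profile_fit_linear(Family.LANGMUIR, dataset)
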