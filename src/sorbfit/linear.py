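"""Linearized least-squares estimation.

Each isotherm family has an exact straight-line form (see
:mod:`sorbfit.families`); its slope and intercept map back to the
physical parameters. The two three-parameter families (Redlich-Peterson
and Dubinin-Astakhov) are handled by profiling: an outer one-dimensional
search over K_RP (resp. n_da) maximizes the r^2 of the inner ordinary
least squares, reproducing the spreadsheet-solver procedure that is
standard practice in the adsorption literature.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidParameterError,
    MissingContextError,
    SearchBoundsError,
    TransformDomainError,
)
from .families import (
    R,
    Family,
    IsothermDataset,
    ParamSet,
    make_params,
    predict_qe,
    transform_points,
)
from .result import FitResult

#: Relative margin keeping the profiled K_RP strictly above max(Qe/Ce).
RP_LOWER_MARGIN = 1e-6

#: Default Dubinin-Astakhov exponent search interval.
DA_DEFAULT_BOUNDS = (1.0, 6.0)

#: Number of log-spaced candidates in the bracketing pre-scan.
PROFILE_GRID_SIZE = 64

#: Relative tolerance on the profiled parameter after refinement.
PROFILE_XTOL = 1e-10


class ProfileNonUnimodalWarning(UserWarning):
    """The profile r^2 had multiple local maxima on the pre-scan grid."""


def ols_line(xs, ys) -> Tuple[float, float, float]:
    """Unweighted simple linear regression: (slope, intercept, r2).

    r2 is the squared Pearson correlation of (x, y). Requires at least
    three points and nonzero variance in x.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise InvalidParameterError("ols_line: xs and ys must be 1-d of equal length")
    if xs.size < 3:
        raise InsufficientDataError(f"ols_line needs >= 3 points, got {xs.size}")
    if np.ptp(xs) == 0:
        raise DegenerateDataError("ols_line: zero variance in x")
    if np.ptp(ys) == 0:
        # a perfectly flat response: slope 0, correlation undefined -> r2 := 1
        # (the line reproduces y exactly)
        return 0.0, float(ys[0]), 1.0
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def back_transform(family: Family, slope: float, intercept: float, *,
                   temperature: float = 298.15,
                   profiled: Optional[float] = None) -> ParamSet:
    """Map a fitted (slope, intercept) back to the family's parameters."""
    family = Family(family)
    try:
        if family is Family.LANGMUIR:
            # 1/Qe = 1/(qmax k) * 1/Ce + 1/qmax
            return make_params(family, qmax=1.0 / intercept, k_l=intercept / slope)
        if family is Family.FREUNDLICH:
            # ln Qe = (1/n) ln Ce + ln K_F
            return make_params(family, k_f=float(np.exp(intercept)), n_f=1.0 / slope)
        if family is Family.REDLICH_PETERSON:
            # ln(K Ce/Qe - 1) = beta ln Ce + ln a
            return make_params(family, k_rp=profiled, a_rp=float(np.exp(intercept)),
                               beta=slope)
        if family is Family.TEMKIN:
            # Qe = (RT/b) ln K + (RT/b) ln Ce
            b_t = R * temperature / slope
            return make_params(family, k_t=float(np.exp(intercept / slope)), b_t=b_t)
        if family is Family.DUBININ_RADUSHKEVICH:
            # ln Qe = -K eps^2 + ln qmax
            return make_params(family, qmax=float(np.exp(intercept)), k_dr=-slope)
        if family is Family.DUBININ_ASTAKHOV:
            return make_params(family, qmax=float(np.exp(intercept)), k_da=-slope,
                               n_da=profiled)
    except InvalidParameterError as exc:
        raise InvalidParameterError(
            f"{family.value}: back-transformed parameters are unphysical "
            f"(slope={slope!r}, intercept={intercept!r}): {exc}"
        ) from exc
    raise InvalidParameterError(f"unknown family {family!r}")  # pragma: no cover


def _domain_mask(family: Family, ds: IsothermDataset,
                 k_rp: Optional[float] = None) -> np.ndarray:
    """Boolean mask of points inside the family's transform domain."""
    ce, qe = ds.ce, ds.qe
    if family in (Family.LANGMUIR, Family.FREUNDLICH):
        return (ce > 0) & (qe > 0)
    if family is Family.REDLICH_PETERSON:
        ok = (ce > 0) & (qe > 0)
        if k_rp is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                ok = ok & (k_rp * ce > qe)
        return ok
    if family is Family.TEMKIN:
        return ce > 0
    # Polanyi families: Ce > 0 (eps finite), Qe > 0, Ce <= Cs
    ds.require_solubility_headroom()
    return (ce > 0) & (qe > 0) & (ce <= ds.solubility)


def _select_points(family: Family, ds: IsothermDataset, allow_drop: bool,
                   k_rp: Optional[float] = None):
    mask = _domain_mask(family, ds, k_rp)
    if not allow_drop and not mask.all():
        bad = np.flatnonzero(~mask)
        raise TransformDomainError(
            f"{family.value}: {bad.size} point(s) outside the linear-form domain "
            f"at indices {bad.tolist()} (Ce={ds.ce[bad].tolist()}, "
            f"Qe={ds.qe[bad].tolist()}); pass allow_drop=True to exclude them",
            indices=bad,
        )
    return np.flatnonzero(mask)


def _finalize(family: Family, ds: IsothermDataset, used: np.ndarray,
              params: ParamSet, r2: float, extras: dict) -> FitResult:
    p = family.n_params
    predicted = predict_qe(params, ds.ce[used], temperature=ds.temperature,
                           solubility=ds.solubility)
    predicted = np.atleast_1d(predicted)
    mpsd = None
    qe = ds.qe[used]
    if np.all(qe > 0) and used.size > p:
        rel = (qe - predicted) / qe
        mpsd = float(100.0 * np.sqrt(np.sum(rel**2) / (used.size - p)))
    return FitResult(family=family, method="linear", params=params,
                     n=int(used.size), p=p, predicted=predicted, r2=r2,
                     mpsd=mpsd, extras={"used_indices": used, **extras})


def fit_linear(family: Family, dataset: IsothermDataset, *,
               allow_drop: bool = False,
               search_bounds: Optional[Tuple[float, float]] = None) -> FitResult:
    """Fit one family by its linearized form.

    Three-parameter families are dispatched to
    :func:`profile_fit_linear`. Out-of-domain points raise
    :class:`TransformDomainError` unless ``allow_drop`` is set, in which
    case they are excluded and recorded in ``extras["used_indices"]``.
    """
    family = Family(family)
    if family in (Family.REDLICH_PETERSON, Family.DUBININ_ASTAKHOV):
        return profile_fit_linear(family, dataset, search_bounds=search_bounds,
                                  allow_drop=allow_drop)
    used = _select_points(family, dataset, allow_drop)
    p = family.n_params
    if used.size <= p:
        raise InsufficientDataError(
            f"{family.value}: need more than p={p} in-domain points, "
            f"have {used.size}"
        )
    x, y = transform_points(family, dataset.ce[used], dataset.qe[used],
                            temperature=dataset.temperature,
                            solubility=dataset.solubility)
    slope, intercept, r2 = ols_line(x, y)
    params = back_transform(family, slope, intercept,
                            temperature=dataset.temperature)
    return _finalize(family, dataset, used, params, r2,
                     {"slope": slope, "intercept": intercept})


def _one_minus_r2(x: np.ndarray, y: np.ndarray) -> float:
    """1 - r^2 of the OLS line, computed as SS_res/SS_tot.

    Algebraically identical to 1 minus the squared Pearson correlation,
    but free of the catastrophic cancellation that flattens r^2 at
    machine precision near 1 — the resolution the profile refinement
    needs on noiseless data.
    """
    xc = x - x.mean()
    yc = y - y.mean()
    sstot = float(np.sum(yc**2))
    if sstot == 0:
        return 0.0
    slope = float(np.sum(xc * yc) / np.sum(xc**2))
    ssres = float(np.sum((yc - slope * xc) ** 2))
    return ssres / sstot


def _profile_objective(family: Family, ds: IsothermDataset, used: np.ndarray,
                       theta: float) -> float:
    """r^2 of the inner OLS at profiled value ``theta`` (-inf if infeasible).

    Returned as -(SS_res/SS_tot) shifted by 1, i.e. a well-conditioned
    r^2, so that maximizing it resolves the optimum far below the
    1 - 1e-16 plateau a correlation-based r^2 would hit.
    """
    kwargs = {}
    if family is Family.REDLICH_PETERSON:
        kwargs["k_rp"] = theta
    else:
        kwargs["n_da"] = theta
    try:
        x, y = transform_points(family, ds.ce[used], ds.qe[used],
                                temperature=ds.temperature,
                                solubility=ds.solubility, **kwargs)
        if np.ptp(x) == 0:
            return -np.inf
    except (TransformDomainError, DegenerateDataError, MissingContextError):
        return -np.inf
    return 1.0 - _one_minus_r2(np.asarray(x, float), np.asarray(y, float))


def profile_fit_linear(family: Family, dataset: IsothermDataset, *,
                       search_bounds: Optional[Tuple[float, float]] = None,
                       allow_drop: bool = False) -> FitResult:
    """Profiled linear fit for the three-parameter families.

    An outer scalar search over K_RP (Redlich-Peterson) or n_da
    (Dubinin-Astakhov) maximizes the inner straight-line r^2: a 64-point
    log-spaced pre-scan brackets the optimum, then a bounded scalar
    minimizer refines it to ~1e-10 relative. If the pre-scan reveals
    several local maxima a :class:`ProfileNonUnimodalWarning` is issued,
    every bracket is refined, and the best r^2 wins.
    """
    family = Family(family)
    if family not in (Family.REDLICH_PETERSON, Family.DUBININ_ASTAKHOV):
        raise InvalidParameterError(
            f"profile_fit_linear applies to three-parameter families, not {family.value}"
        )
    used = _select_points(family, dataset, allow_drop)
    p = family.n_params
    if used.size <= p:
        raise InsufficientDataError(
            f"{family.value}: need more than p={p} in-domain points, have {used.size}"
        )
    ce, qe = dataset.ce[used], dataset.qe[used]

    if family is Family.REDLICH_PETERSON:
        feas_lo = (1.0 + RP_LOWER_MARGIN) * float(np.max(qe / ce))
        lo, hi = search_bounds if search_bounds is not None else (feas_lo, 1e4 * feas_lo)
        if hi <= feas_lo / (1.0 + RP_LOWER_MARGIN):
            raise SearchBoundsError(
                f"redlich_peterson: search upper bound {hi} lies below the "
                f"feasible minimum K_RP > max(Qe/Ce) = {feas_lo}"
            )
        lo = max(lo, feas_lo)
    else:
        lo, hi = search_bounds if search_bounds is not None else DA_DEFAULT_BOUNDS
        lo = max(lo, 1e-6)
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo <= 0 or hi <= lo:
        raise SearchBoundsError(
            f"{family.value}: empty or invalid search interval ({lo}, {hi})"
        )

    grid = np.geomspace(lo, hi, PROFILE_GRID_SIZE)
    scores = np.array([_profile_objective(family, dataset, used, t) for t in grid])
    if not np.any(np.isfinite(scores)):
        raise SearchBoundsError(
            f"{family.value}: no feasible profiled value in ({lo}, {hi})"
        )

    # local maxima of the pre-scan (plateau-safe comparison)
    is_max = np.ones(grid.size, dtype=bool)
    is_max[1:] &= scores[1:] >= scores[:-1]
    is_max[:-1] &= scores[:-1] >= scores[1:]
    is_max &= np.isfinite(scores)
    maxima = np.flatnonzero(is_max)
    # collapse plateaus of equal score into one representative
    brackets = []
    for i in maxima:
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid.size - 1)]
        brackets.append((a, b, scores[i]))
    distinct = {round(float(np.log10(a)), 6) for a, _, _ in brackets}
    if len(distinct) > 1:
        warnings.warn(
            f"{family.value}: profile r^2 has {len(distinct)} local maxima on the "
            "pre-scan grid; refining all and keeping the best",
            ProfileNonUnimodalWarning,
            stacklevel=2,
        )

    best_theta, best_r2 = None, -np.inf
    for a, b, _ in brackets:
        if a == b:
            theta = a
        else:
            res = optimize.minimize_scalar(
                lambda u: -_profile_objective(family, dataset, used, 10.0**u),
                bounds=(np.log10(a), np.log10(b)),
                method="bounded",
                options={"xatol": PROFILE_XTOL / np.log(10.0)},
            )
            theta = float(10.0**res.x)
        r2 = _profile_objective(family, dataset, used, theta)
        if r2 > best_r2:
            best_theta, best_r2 = theta, r2

    kwargs = ({"k_rp": best_theta} if family is Family.REDLICH_PETERSON
              else {"n_da": best_theta})
    x, y = transform_points(family, ce, qe, temperature=dataset.temperature,
                            solubility=dataset.solubility, **kwargs)
    slope, intercept, r2 = ols_line(x, y)
    params = back_transform(family, slope, intercept,
                            temperature=dataset.temperature, profiled=best_theta)
    return _finalize(family, dataset, used, params, r2,
                     {"slope": slope, "intercept": intercept,
                      "profiled_name": ("k_rp" if family is Family.REDLICH_PETERSON
                                        else "n_da"),
                      "profiled_value": best_theta,
                      "search_interval": (float(lo), float(hi))})
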