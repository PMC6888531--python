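"""Nonlinear estimation by minimizing the MPSD error function.

MPSD (Marquardt's percent standard deviation) is a relative-error
least-squares objective with a degrees-of-freedom correction:

    MPSD = 100 * sqrt( 1/(n - p) * sum_i ((Qe_exp,i - Qe_calc,i)/Qe_exp,i)^2 )

Minimizing MPSD is equivalent to least squares on the relative
residuals, so the optimizer is a bounded trust-region least-squares run
in log-parameter space (strictly positive parameters are fitted as
log10; the Redlich-Peterson exponent is bounded in (0, 1], the
Dubinin-Astakhov exponent in [1, 6]). A deterministic multistart —
the linearized-form estimate first, then seeded log-perturbed starts —
guards against the local minima that three-parameter families exhibit
at small beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    FitConvergenceError,
    InsufficientDataError,
    InvalidParameterError,
    MissingContextError,
)
from .families import (
    R,
    Family,
    IsothermDataset,
    ParamSet,
    make_params,
    predict_qe,
)
from .linear import fit_linear
from .result import FitResult


def mpsd(qe_exp, qe_calc, p: int) -> float:
    """Marquardt percent standard deviation (reported on the x100 scale).

    Requires equal-length collections, n > p and all observed Qe > 0
    (the relative error is undefined at zero).
    """
    qe_exp = np.asarray(qe_exp, dtype=float)
    qe_calc = np.asarray(qe_calc, dtype=float)
    if qe_exp.shape != qe_calc.shape or qe_exp.ndim != 1:
        raise InvalidParameterError("mpsd: collections must be 1-d of equal length")
    n = qe_exp.size
    if n <= p:
        raise InsufficientDataError(f"mpsd requires n > p, got n={n}, p={p}")
    if np.any(qe_exp <= 0):
        raise InvalidParameterError(
            "mpsd: observed Qe must be strictly positive (relative error undefined)"
        )
    rel = (qe_exp - qe_calc) / qe_exp
    return float(100.0 * np.sqrt(np.sum(rel**2) / (n - p)))


# ---------------------------------------------------------------------------
# Parameter packing: log10 for strictly positive parameters, raw for n_da
# ---------------------------------------------------------------------------

# (name, kind) per family; kind "log" -> log10-transformed, "lin" -> raw
_PACKING = {
    Family.LANGMUIR: (("qmax", "log"), ("k_l", "log")),
    Family.FREUNDLICH: (("k_f", "log"), ("n_f", "log")),
    Family.REDLICH_PETERSON: (("k_rp", "log"), ("a_rp", "log"), ("beta", "log")),
    Family.TEMKIN: (("k_t", "log"), ("b_t", "log")),
    Family.DUBININ_RADUSHKEVICH: (("qmax", "log"), ("k_dr", "log")),
    Family.DUBININ_ASTAKHOV: (("qmax", "log"), ("k_da", "log"), ("n_da", "lin")),
}

# optimizer-space bounds per parameter name
_BOUNDS = {
    "qmax": (-6.0, 9.0),
    "k_l": (-15.0, 6.0),
    "k_f": (-15.0, 9.0),
    "n_f": (0.0, np.log10(50.0)),
    "k_rp": (-15.0, 9.0),
    "a_rp": (-15.0, 9.0),
    "beta": (-6.0, 0.0),
    "k_t": (-15.0, 6.0),
    "b_t": (-6.0, 9.0),
    "k_dr": (-30.0, 0.0),
    "k_da": (-30.0, 0.0),
    "n_da": (1.0, 6.0),
}

_RATE_NAMES = {"k_l", "k_f", "k_rp", "a_rp", "k_t", "k_dr", "k_da"}
_CAPACITY_NAMES = {"qmax", "b_t"}


def _pack(params: ParamSet) -> np.ndarray:
    vec = []
    d = params.as_dict()
    for name, kind in _PACKING[params.family]:
        v = d[name]
        vec.append(np.log10(v) if kind == "log" else v)
    return np.array(vec, dtype=float)


def _unpack(family: Family, vec: np.ndarray) -> ParamSet:
    kv = {}
    for (name, kind), u in zip(_PACKING[family], vec):
        kv[name] = float(10.0**u) if kind == "log" else float(u)
    if family is Family.REDLICH_PETERSON:
        kv["beta"] = min(kv["beta"], 1.0)
    if family is Family.FREUNDLICH:
        kv["n_f"] = max(kv["n_f"], 1.0)
    return make_params(family, **kv)


def _bounds(family: Family):
    lo = [_BOUNDS[name][0] for name, _ in _PACKING[family]]
    hi = [_BOUNDS[name][1] for name, _ in _PACKING[family]]
    return np.array(lo), np.array(hi)


def _heuristic_params(family: Family, ds: IsothermDataset) -> ParamSet:
    """Crude moment-style starting values when the linear fit is unavailable."""
    ce, qe = ds.ce[ds.ce > 0], ds.qe[ds.ce > 0]
    qtop = float(np.max(qe)) * 1.2 + 1e-12
    cmid = float(np.median(ce))
    if family is Family.LANGMUIR:
        return make_params(family, qmax=qtop, k_l=1.0 / cmid)
    if family is Family.FREUNDLICH:
        return make_params(family, k_f=float(np.median(qe / np.sqrt(ce))), n_f=2.0)
    if family is Family.REDLICH_PETERSON:
        k = 1.5 * float(np.max(qe / ce))
        return make_params(family, k_rp=k, a_rp=k / qtop, beta=0.9)
    if family is Family.TEMKIN:
        return make_params(family, k_t=1.0 / cmid, b_t=R * ds.temperature
                           * np.log(np.max(ce) / np.min(ce)) / max(np.ptp(qe), 1e-9))
    eps_mid = R * ds.temperature * np.log(ds.solubility / cmid)
    if family is Family.DUBININ_RADUSHKEVICH:
        return make_params(family, qmax=qtop, k_dr=0.5 / eps_mid**2)
    if family is Family.DUBININ_ASTAKHOV:
        return make_params(family, qmax=qtop, k_da=0.5 / eps_mid**2, n_da=2.0)
    raise InvalidParameterError(f"unknown family {family!r}")  # pragma: no cover


@dataclass
class NonlinearConfig:
    """Optimizer configuration for :func:`fit_nonlinear`.

    ``n_perturbed`` seeded log-perturbed starts (one decade on rate
    constants, +/-50% on capacities, exponents jittered inside their
    bounds) are added after the linearized-estimate start.
    """

    n_perturbed: int = 8
    seed: int = 0
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-14
    allow_drop: bool = False


def _perturb(params: ParamSet, rng: np.random.Generator) -> ParamSet:
    kv = {}
    for name, value in params.as_dict().items():
        if name in _RATE_NAMES:
            kv[name] = value * 10.0 ** rng.uniform(-1.0, 1.0)
        elif name in _CAPACITY_NAMES:
            kv[name] = value * rng.uniform(0.5, 1.5)
        elif name == "beta":
            kv[name] = rng.uniform(0.3, 1.0)
        elif name == "n_f":
            kv[name] = rng.uniform(1.0, 3.0)
        elif name == "n_da":
            kv[name] = rng.uniform(1.0, 4.0)
        else:  # pragma: no cover
            kv[name] = value
    return make_params(params.family, **kv)


def fit_nonlinear(family: Family, dataset: IsothermDataset,
                  config: Optional[NonlinearConfig] = None,
                  start: Optional[ParamSet] = None) -> FitResult:
    """Fit one family by direct MPSD minimization.

    Deterministic given the configuration seed. The returned
    :class:`FitResult` carries the MPSD at the optimum, the data size
    and parameter count entering its n - p correction, and the
    predicted Qe at the data's Ce.
    """
    family = Family(family)
    config = config or NonlinearConfig()
    p = family.n_params
    if len(dataset) <= p:
        raise InsufficientDataError(
            f"{family.value}: nonlinear fit needs n > p={p}, have {len(dataset)}"
        )
    if np.any(dataset.qe <= 0):
        raise InvalidParameterError(
            f"{family.value}: MPSD requires all observed Qe > 0"
        )
    if family.uses_polanyi:
        dataset.require_solubility_headroom()
    if family is Family.TEMKIN and np.any(dataset.ce <= 0):
        raise InvalidParameterError("temkin: requires Ce > 0")

    ce, qe = dataset.ce, dataset.qe
    dof = len(dataset) - p

    def residuals(u):
        try:
            pset = _unpack(family, u)
        except InvalidParameterError:
            return np.full(qe.shape, 1e6)
        pred = predict_qe(pset, ce, temperature=dataset.temperature,
                          solubility=dataset.solubility)
        return (qe - np.atleast_1d(pred)) / qe

    starts: list[ParamSet] = []
    if start is not None:
        starts.append(start)
    else:
        try:
            starts.append(fit_linear(family, dataset,
                                     allow_drop=config.allow_drop).params)
        except Exception:
            starts.append(_heuristic_params(family, dataset))
    rng = np.random.default_rng(config.seed)
    base = starts[0]
    starts.extend(_perturb(base, rng) for _ in range(config.n_perturbed))

    lo, hi = _bounds(family)
    best = None
    failures = []
    for s in starts:
        x0 = np.clip(_pack(s), lo + 1e-12, hi - 1e-12)
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=config.xtol, ftol=config.ftol, gtol=config.gtol,
            )
        except Exception as exc:  # optimizer hard failure on this start
            failures.append(exc)
            continue
        score = float(np.sum(sol.fun**2))
        if best is None or score < best[0]:
            best = (score, sol)
    if best is None:
        raise FitConvergenceError(
            f"{family.value}: optimizer failed on all {len(starts)} starts: "
            f"{failures[:1]!r}"
        )
    _, sol = best
    params = _unpack(family, sol.x)
    pred = np.atleast_1d(predict_qe(params, ce, temperature=dataset.temperature,
                                    solubility=dataset.solubility))
    value = mpsd(qe, pred, p)
    return FitResult(family=family, method="nonlinear", params=params,
                     n=len(dataset), p=p, predicted=pred, mpsd=value,
                     extras={"n_starts": len(starts), "optimizer": "trf",
                             "cost": float(np.sum(sol.fun**2))})


@dataclass
class FitEvaluation:
    """Cross-method diagnostics for any fit on any compatible dataset."""

    mpsd: float
    r2: float
    residuals: np.ndarray


def evaluate_fit(fit: FitResult, dataset: IsothermDataset) -> FitEvaluation:
    """Recompute MPSD and observed-vs-predicted r^2 for ``fit`` on ``dataset``.

    Enables ranking linear- and nonlinear-method fits on a common
    footing. Raises :class:`MissingContextError` when the fit's family
    needs solubility/temperature context the dataset lacks.
    """
    family = fit.params.family
    if family.uses_polanyi and dataset.solubility is None:
        raise MissingContextError(
            f"{family.value}: dataset lacks the solubility Cs this fit requires"
        )
    pred = np.atleast_1d(predict_qe(fit.params, dataset.ce,
                                    temperature=dataset.temperature,
                                    solubility=dataset.solubility))
    value = mpsd(dataset.qe, pred, fit.p)
    resid = dataset.qe - pred
    if np.ptp(pred) == 0 or np.ptp(dataset.qe) == 0:
        r2 = 1.0 if np.allclose(resid, 0) else 0.0
    else:
        r2 = float(stats.pearsonr(dataset.qe, pred).statistic ** 2)
    return FitEvaluation(mpsd=value, r2=r2, residuals=resid)
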