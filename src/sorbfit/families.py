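"""The six equilibrium isotherm families.

Each family maps an equilibrium solute concentration Ce (mg/dm^3) to an
adsorbed amount Qe (mg/g) at fixed temperature:

* Langmuir            Qe = Qmax*K_L*Ce / (1 + K_L*Ce)
* Freundlich          Qe = K_F * Ce^(1/n_F)
* Redlich-Peterson    Qe = K_RP*Ce / (1 + a_RP*Ce^beta)
* Temkin              Qe = (R*T/b_T) * ln(K_T*Ce)
* Dubinin-Radushkevich  Qe = Qmax * exp(-K_DR * eps^2)
* Dubinin-Astakhov      Qe = Qmax * exp(-K_DA * eps^n_DA)

where eps = R*T*ln(Cs/Ce) is the Polanyi adsorption potential (J/mol)
relative to the solubility limit Cs. Each family also carries the
standard straight-line form used by linearized least squares, and its
inverse.

Units are fixed package-wide: concentrations in mg/dm^3, Qe in mg/g,
eps in J/mol, temperature in kelvin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

from .errors import (
    InvalidParameterError,
    MissingContextError,
    SolubilityExceededError,
    TransformDomainError,
)

#: Molar gas constant, J/(mol K).
R = 8.314

#: Relative headroom required between max(Ce) and Cs before any
#: Polanyi-based operation (Cs must exceed every Ce strictly).
CS_HEADROOM = 1e-9


class Family(str, enum.Enum):
    """Isotherm family identifiers, with the field's usual short labels."""

    LANGMUIR = "langmuir"
    FREUNDLICH = "freundlich"
    REDLICH_PETERSON = "redlich_peterson"
    TEMKIN = "temkin"
    DUBININ_RADUSHKEVICH = "dubinin_radushkevich"
    DUBININ_ASTAKHOV = "dubinin_astakhov"

    @property
    def short_label(self) -> str:
        return _SHORT_LABELS[self]

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self]

    @property
    def uses_polanyi(self) -> bool:
        return self in (Family.DUBININ_RADUSHKEVICH, Family.DUBININ_ASTAKHOV)


_SHORT_LABELS = {
    Family.LANGMUIR: "L",
    Family.FREUNDLICH: "F",
    Family.REDLICH_PETERSON: "R-P",
    Family.TEMKIN: "T",
    Family.DUBININ_RADUSHKEVICH: "D-R",
    Family.DUBININ_ASTAKHOV: "D-A",
}

_N_PARAMS = {
    Family.LANGMUIR: 2,
    Family.FREUNDLICH: 2,
    Family.REDLICH_PETERSON: 3,
    Family.TEMKIN: 2,
    Family.DUBININ_RADUSHKEVICH: 2,
    Family.DUBININ_ASTAKHOV: 3,
}


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamSet:
    """Base class for one family's named parameters."""

    family: "Family" = field(init=False, repr=False, default=None)

    def validate(self) -> "ParamSet":
        return self

    def as_dict(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "family"
        }

    @property
    def n_params(self) -> int:
        return self.family.n_params


def _require_positive(cls_name: str, **kv) -> None:
    for name, value in kv.items():
        if not np.isfinite(value) or value <= 0:
            raise InvalidParameterError(
                f"{cls_name}: parameter {name!r} must be finite and > 0, got {value!r}"
            )


@dataclass(frozen=True)
class LangmuirParams(ParamSet):
    """Monolayer capacity qmax (mg/g) and affinity k_l (dm^3/mg)."""

    qmax: float
    k_l: float

    def __post_init__(self):
        object.__setattr__(self, "family", Family.LANGMUIR)
        _require_positive("LangmuirParams", qmax=self.qmax, k_l=self.k_l)


@dataclass(frozen=True)
class FreundlichParams(ParamSet):
    """Power-law prefactor k_f (mg^(1-1/n) dm^(3/n)/g) and exponent n_f >= 1."""

    k_f: float
    n_f: float

    def __post_init__(self):
        object.__setattr__(self, "family", Family.FREUNDLICH)
        _require_positive("FreundlichParams", k_f=self.k_f, n_f=self.n_f)
        if self.n_f < 1:
            raise InvalidParameterError(
                f"FreundlichParams: n_f must be >= 1, got {self.n_f!r}"
            )


@dataclass(frozen=True)
class RedlichPetersonParams(ParamSet):
    """Three-parameter hybrid: k_rp (dm^3/g), a_rp (dm^3b/mg^b), 0 < beta <= 1."""

    k_rp: float
    a_rp: float
    beta: float

    def __post_init__(self):
        object.__setattr__(self, "family", Family.REDLICH_PETERSON)
        _require_positive("RedlichPetersonParams", k_rp=self.k_rp, a_rp=self.a_rp,
                          beta=self.beta)
        if self.beta > 1:
            raise InvalidParameterError(
                f"RedlichPetersonParams: beta must be in (0, 1], got {self.beta!r}"
            )


@dataclass(frozen=True)
class TemkinParams(ParamSet):
    """Binding constant k_t (dm^3/mg) and heat parameter b_t (J g/(mol mg))."""

    k_t: float
    b_t: float

    def __post_init__(self):
        object.__setattr__(self, "family", Family.TEMKIN)
        _require_positive("TemkinParams", k_t=self.k_t, b_t=self.b_t)


@dataclass(frozen=True)
class DubininRadushkevichParams(ParamSet):
    """Pore-filling capacity qmax (mg/g) and energy constant k_dr (mol^2/J^2)."""

    qmax: float
    k_dr: float

    def __post_init__(self):
        object.__setattr__(self, "family", Family.DUBININ_RADUSHKEVICH)
        _require_positive("DubininRadushkevichParams", qmax=self.qmax, k_dr=self.k_dr)


@dataclass(frozen=True)
class DubininAstakhovParams(ParamSet):
    """General-exponent pore filling: qmax (mg/g), k_da (mol^n/J^n), n_da >= 1."""

    qmax: float
    k_da: float
    n_da: float

    def __post_init__(self):
        object.__setattr__(self, "family", Family.DUBININ_ASTAKHOV)
        _require_positive("DubininAstakhovParams", qmax=self.qmax, k_da=self.k_da,
                          n_da=self.n_da)
        if self.n_da < 1:
            raise InvalidParameterError(
                f"DubininAstakhovParams: n_da must be >= 1, got {self.n_da!r}"
            )


PARAM_CLASSES = {
    Family.LANGMUIR: LangmuirParams,
    Family.FREUNDLICH: FreundlichParams,
    Family.REDLICH_PETERSON: RedlichPetersonParams,
    Family.TEMKIN: TemkinParams,
    Family.DUBININ_RADUSHKEVICH: DubininRadushkevichParams,
    Family.DUBININ_ASTAKHOV: DubininAstakhovParams,
}


def make_params(family: Family, *args, **kwargs) -> ParamSet:
    """Construct the appropriate ParamSet variant for *family*."""
    return PARAM_CLASSES[Family(family)](*args, **kwargs)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EquilibriumPoint:
    """One (Ce, Qe) observation: mg/dm^3 and mg/g."""

    ce: float
    qe: float

    def __post_init__(self):
        if not (np.isfinite(self.ce) and self.ce >= 0):
            raise InvalidParameterError(f"EquilibriumPoint: Ce must be >= 0, got {self.ce!r}")
        if not (np.isfinite(self.qe) and self.qe >= 0):
            raise InvalidParameterError(f"EquilibriumPoint: Qe must be >= 0, got {self.qe!r}")


@dataclass
class IsothermDataset:
    """An ordered set of equilibrium observations with their context.

    Parameters
    ----------
    ce, qe : array-like
        Equilibrium concentrations (mg/dm^3) and adsorbed amounts (mg/g).
    temperature : float
        Absolute temperature in kelvin.
    solubility : float, optional
        Adsorbate solubility Cs (mg/dm^3); required for any
        Polanyi-potential operation and must strictly exceed max(Ce).
    sorbent : str, optional
        Label of the sorbent the data were collected on.
    """

    ce: np.ndarray
    qe: np.ndarray
    temperature: float = 298.15
    solubility: Optional[float] = None
    sorbent: str = ""

    def __post_init__(self):
        self.ce = np.asarray(self.ce, dtype=float)
        self.qe = np.asarray(self.qe, dtype=float)
        if self.ce.shape != self.qe.shape or self.ce.ndim != 1:
            raise InvalidParameterError(
                "IsothermDataset: ce and qe must be 1-d arrays of equal length"
            )
        if np.any(~np.isfinite(self.ce)) or np.any(self.ce < 0):
            raise InvalidParameterError("IsothermDataset: all Ce must be finite and >= 0")
        if np.any(~np.isfinite(self.qe)) or np.any(self.qe < 0):
            raise InvalidParameterError("IsothermDataset: all Qe must be finite and >= 0")
        if not (np.isfinite(self.temperature) and self.temperature > 0):
            raise InvalidParameterError(
                f"IsothermDataset: temperature must be > 0 K, got {self.temperature!r}"
            )
        if self.solubility is not None:
            self.require_solubility_headroom()

    def __len__(self) -> int:
        return self.ce.size

    @property
    def points(self) -> list:
        return [EquilibriumPoint(c, q) for c, q in zip(self.ce, self.qe)]

    def require_solubility_headroom(self) -> None:
        """Demand Cs > max(Ce) with a small strict margin."""
        if self.solubility is None:
            raise MissingContextError(
                "solubility Cs is required for Polanyi-potential operations "
                "but was not provided"
            )
        if len(self) and self.solubility <= self.ce.max() * (1.0 + CS_HEADROOM):
            raise SolubilityExceededError(
                f"solubility Cs={self.solubility} must exceed max(Ce)={self.ce.max()}"
            )


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a Celsius temperature to kelvin."""
    return t_celsius + 273.15


# ---------------------------------------------------------------------------
# Polanyi potential and forward prediction
# ---------------------------------------------------------------------------


def polanyi_potential(ce, cs: float, temperature: float):
    """Adsorption potential eps = R*T*ln(Cs/Ce) in J/mol.

    Vectorized over ``ce``. Requires 0 < Ce <= Cs and T > 0; eps is
    nonnegative and vanishes at the solubility limit.
    """
    ce = np.asarray(ce, dtype=float)
    if not (np.isfinite(temperature) and temperature > 0):
        raise MissingContextError(f"temperature must be > 0 K, got {temperature!r}")
    if cs is None or not np.isfinite(cs) or cs <= 0:
        raise MissingContextError(f"solubility Cs must be a positive number, got {cs!r}")
    if np.any(ce <= 0):
        raise TransformDomainError(
            "polanyi_potential requires Ce > 0",
            indices=np.flatnonzero(ce <= 0),
        )
    if np.any(ce > cs):
        raise SolubilityExceededError(
            f"Ce exceeds solubility Cs={cs}: offending values {ce[ce > cs]!r}"
        )
    out = R * temperature * np.log(cs / ce)
    return out if out.ndim else float(out)


def _predict_arr(params: ParamSet, ce: np.ndarray, temperature: float,
                 cs: Optional[float]) -> np.ndarray:
    fam = params.family
    if fam is Family.LANGMUIR:
        kc = params.k_l * ce
        return params.qmax * kc / (1.0 + kc)
    if fam is Family.FREUNDLICH:
        return params.k_f * np.power(ce, 1.0 / params.n_f)
    if fam is Family.REDLICH_PETERSON:
        return params.k_rp * ce / (1.0 + params.a_rp * np.power(ce, params.beta))
    if fam is Family.TEMKIN:
        with np.errstate(divide="ignore"):
            return (R * temperature / params.b_t) * np.log(params.k_t * ce)
    # Polanyi families
    eps = np.where(ce > 0, R * temperature * np.log(cs / np.where(ce > 0, ce, 1.0)),
                   np.inf)
    if fam is Family.DUBININ_RADUSHKEVICH:
        return params.qmax * np.exp(-params.k_dr * eps ** 2)
    if fam is Family.DUBININ_ASTAKHOV:
        return params.qmax * np.exp(-params.k_da * np.power(eps, params.n_da))
    raise InvalidParameterError(f"unknown family {fam!r}")  # pragma: no cover


def predict_qe(params: ParamSet, ce, *, temperature: float = 298.15,
               solubility: Optional[float] = None):
    """Forward isotherm prediction Qe(Ce) in mg/g, vectorized over ``ce``.

    Temkin predictions may be negative when K_T*Ce < 1; they are returned
    as-is (the linear form must still be fittable on such data). The
    Polanyi families require ``solubility`` and ``temperature`` and demand
    Ce <= Cs; at Ce = 0 they return 0 by the eps -> inf limit.
    """
    params.validate()
    ce_arr = np.asarray(ce, dtype=float)
    scalar = ce_arr.ndim == 0
    ce_arr = np.atleast_1d(ce_arr)
    if np.any(~np.isfinite(ce_arr)) or np.any(ce_arr < 0):
        raise InvalidParameterError("predict_qe: Ce must be finite and >= 0")
    fam = params.family
    if fam.uses_polanyi:
        if solubility is None:
            raise MissingContextError(
                f"{fam.value}: solubility Cs is required for prediction"
            )
        if not (np.isfinite(temperature) and temperature > 0):
            raise MissingContextError(
                f"{fam.value}: positive temperature (K) is required"
            )
        if np.any(ce_arr > solubility):
            raise SolubilityExceededError(
                f"{fam.value}: Ce values exceed Cs={solubility}"
            )
    if fam is Family.TEMKIN and not (np.isfinite(temperature) and temperature > 0):
        raise MissingContextError("temkin: positive temperature (K) is required")
    out = _predict_arr(params, ce_arr, temperature, solubility)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Linearizing transforms
# ---------------------------------------------------------------------------


def transform_points(family: Family, ce, qe, *, temperature: float = 298.15,
                     solubility: Optional[float] = None,
                     k_rp: Optional[float] = None,
                     n_da: Optional[float] = None):
    """Map (Ce, Qe) observations onto the family's straight-line (x, y) form.

    ========================  =====================  ======================
    family                    x                      y
    ========================  =====================  ======================
    Langmuir                  1/Ce                   1/Qe
    Freundlich                ln Ce                  ln Qe
    Redlich-Peterson          ln Ce                  ln(K_RP*Ce/Qe - 1)
    Temkin                    ln Ce                  Qe
    Dubinin-Radushkevich      eps^2                  ln Qe
    Dubinin-Astakhov          eps^n_da               ln Qe
    ========================  =====================  ======================

    The Redlich-Peterson form needs the profiled ``k_rp`` (and requires
    K_RP*Ce/Qe > 1 at every point); Dubinin-Astakhov needs the profiled
    exponent ``n_da``. Raises :class:`TransformDomainError` naming the
    offending point indices on any domain violation.
    """
    family = Family(family)
    ce = np.atleast_1d(np.asarray(ce, dtype=float))
    qe = np.atleast_1d(np.asarray(qe, dtype=float))
    if ce.shape != qe.shape:
        raise InvalidParameterError("transform_points: ce and qe must have equal length")

    def _bad(mask, what):
        idx = np.flatnonzero(mask)
        raise TransformDomainError(
            f"{family.value} linear form: {what} at point indices {idx.tolist()} "
            f"(Ce={ce[idx].tolist()}, Qe={qe[idx].tolist()})",
            indices=idx,
        )

    if family is Family.LANGMUIR:
        if np.any(ce <= 0) or np.any(qe <= 0):
            _bad((ce <= 0) | (qe <= 0), "requires Ce > 0 and Qe > 0")
        return 1.0 / ce, 1.0 / qe
    if family is Family.FREUNDLICH:
        if np.any(ce <= 0) or np.any(qe <= 0):
            _bad((ce <= 0) | (qe <= 0), "requires Ce > 0 and Qe > 0")
        return np.log(ce), np.log(qe)
    if family is Family.REDLICH_PETERSON:
        if k_rp is None or not np.isfinite(k_rp) or k_rp <= 0:
            raise MissingContextError(
                "redlich_peterson linear form requires the profiled K_RP > 0"
            )
        if np.any(ce <= 0) or np.any(qe <= 0):
            _bad((ce <= 0) | (qe <= 0), "requires Ce > 0 and Qe > 0")
        arg = k_rp * ce / qe - 1.0
        if np.any(arg <= 0):
            _bad(arg <= 0, f"requires K_RP*Ce/Qe > 1 (K_RP={k_rp})")
        return np.log(ce), np.log(arg)
    if family is Family.TEMKIN:
        if np.any(ce <= 0):
            _bad(ce <= 0, "requires Ce > 0")
        return np.log(ce), qe.copy()
    # Polanyi families
    if np.any(qe <= 0):
        _bad(qe <= 0, "requires Qe > 0")
    eps = polanyi_potential(ce, solubility, temperature)
    eps = np.atleast_1d(eps)
    if family is Family.DUBININ_RADUSHKEVICH:
        return eps ** 2, np.log(qe)
    if family is Family.DUBININ_ASTAKHOV:
        if n_da is None or not np.isfinite(n_da) or n_da <= 0:
            raise MissingContextError(
                "dubinin_astakhov linear form requires the profiled n_da > 0"
            )
        return np.power(eps, n_da), np.log(qe)
    raise InvalidParameterError(f"unknown family {family!r}")  # pragma: no cover


def untransform_qe(family: Family, x, y, *, k_rp: Optional[float] = None):
    """Invert the linear form back to Qe, given the transformed (x, y).

    Used by round-trip property checks: transform followed by untransform
    recovers Qe exactly (to floating precision).
    """
    family = Family(family)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if family is Family.LANGMUIR:
        return 1.0 / y
    if family in (Family.FREUNDLICH, Family.DUBININ_RADUSHKEVICH,
                  Family.DUBININ_ASTAKHOV):
        return np.exp(y)
    if family is Family.TEMKIN:
        return y.copy()
    if family is Family.REDLICH_PETERSON:
        if k_rp is None:
            raise MissingContextError("redlich_peterson inversion requires K_RP")
        ce = np.exp(x)
        return k_rp * ce / (np.exp(y) + 1.0)
    raise InvalidParameterError(f"unknown family {family!r}")  # pragma: no cover
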