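"""Derived physico-chemical quantities.

Batch mass-balance amounts and efficiencies, mean free adsorption
energies from the Polanyi-family constants, capacity normalizations by
functional-group content and BET surface area, percent-change
comparisons, and goodness-of-fit ranking of competing isotherm models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .errors import InvalidParameterError
from .families import Family
from .result import FitResult

#: Default molar mass of 18beta-glycyrrhetinic acid, C30H46O4 (g/mol).
DEFAULT_MOLAR_MASS = 470.68

#: Conventional mean-free-energy boundary between physisorption and
#: chemisorption-like binding (kJ/mol); reported as annotation only.
PHYSISORPTION_LIMIT_KJ_MOL = 8.0


@dataclass(frozen=True)
class ExperimentRecord:
    """One batch vial: initial/equilibrium concentration, volume, sorbent mass."""

    c0: float  # mg/dm^3
    ce: float  # mg/dm^3
    volume: float  # dm^3
    mass: float  # g

    def __post_init__(self):
        if not (0 <= self.ce <= self.c0):
            raise InvalidParameterError(
                f"ExperimentRecord requires 0 <= Ce <= C0, got Ce={self.ce}, C0={self.c0}"
            )
        if self.volume <= 0 or self.mass <= 0:
            raise InvalidParameterError(
                f"ExperimentRecord requires V > 0 and m > 0, got V={self.volume}, m={self.mass}"
            )


@dataclass(frozen=True)
class SorbentRecord:
    """Sorbent metadata: functional-group content and textural properties."""

    name: str
    modifying_agent: str = ""
    q_fg: float = 0.0  # functional-group content, mol/g
    s_bet: float = 1.0  # BET surface area, m^2/g
    pore_volume: Optional[float] = None  # cm^3/g
    pore_diameter: Optional[float] = None  # nm

    def __post_init__(self):
        if self.q_fg < 0:
            raise InvalidParameterError(f"SorbentRecord: Q_FG must be >= 0, got {self.q_fg}")
        if self.s_bet <= 0:
            raise InvalidParameterError(f"SorbentRecord: S_BET must be > 0, got {self.s_bet}")


@dataclass(frozen=True)
class CompoundInfo:
    """Adsorbate identity and molar mass (g/mol)."""

    name: str = "18beta-glycyrrhetinic acid"
    molar_mass: float = DEFAULT_MOLAR_MASS

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise InvalidParameterError(
                f"CompoundInfo: molar_mass must be > 0, got {self.molar_mass}"
            )


def adsorbed_amount(record: ExperimentRecord) -> float:
    """Equilibrium adsorbed amount Qe = (C0 - Ce) * V / m, in mg/g."""
    return (record.c0 - record.ce) * record.volume / record.mass


def adsorption_efficiency(c0: float, ce: float) -> float:
    """Percent of initial adsorbate removed: 100 * (C0 - Ce)/C0."""
    if c0 <= 0:
        raise InvalidParameterError(f"adsorption_efficiency: C0 must be > 0, got {c0}")
    if not (0 <= ce <= c0):
        raise InvalidParameterError(
            f"adsorption_efficiency requires 0 <= Ce <= C0, got Ce={ce}, C0={c0}"
        )
    return 100.0 * (c0 - ce) / c0


def energy_dr(k_dr: float) -> float:
    """Mean free adsorption energy from the Gaussian pore-filling constant.

    E = 1/sqrt(2*K_DR) in J/mol, returned in kJ/mol. Magnitudes below
    ~8 kJ/mol are conventionally read as physisorption.
    """
    if not (np.isfinite(k_dr) and k_dr > 0):
        raise InvalidParameterError(f"energy_dr: K_DR must be > 0, got {k_dr!r}")
    return 1.0 / np.sqrt(2.0 * k_dr) / 1000.0


def energy_da(k_da: float, n_da: float) -> float:
    """Mean free adsorption energy for the general-exponent pore-filling model.

    Uses the direct n-generalization of the Gaussian case,
    E = (2*K_DA)^(-1/n_da) in J/mol (kJ/mol returned), which reduces to
    :func:`energy_dr` at n_da = 2.
    """
    if not (np.isfinite(k_da) and k_da > 0):
        raise InvalidParameterError(f"energy_da: K_DA must be > 0, got {k_da!r}")
    if not (np.isfinite(n_da) and n_da >= 1):
        raise InvalidParameterError(f"energy_da: n_da must be >= 1, got {n_da!r}")
    return float((2.0 * k_da) ** (-1.0 / n_da)) / 1000.0


def molar_ratio(q_ads_max: float, sorbent: SorbentRecord,
                compound: CompoundInfo = CompoundInfo()) -> float:
    """Moles adsorbed at capacity per mole of surface functional groups.

    (Q_ads_max * 1e-3 / M) / Q_FG with Q_ads_max in mg/g, M in g/mol and
    Q_FG in mol/g. Values well below one indicate partially accessible
    binding sites.
    """
    if q_ads_max < 0:
        raise InvalidParameterError(f"molar_ratio: capacity must be >= 0, got {q_ads_max}")
    if sorbent.q_fg <= 0:
        raise InvalidParameterError(
            f"molar_ratio: sorbent {sorbent.name!r} has no functional-group content"
        )
    return (q_ads_max * 1e-3 / compound.molar_mass) / sorbent.q_fg


def surface_normalized_capacity(q_ads_max: float, sorbent: SorbentRecord) -> float:
    """Capacity per unit BET surface area, mg/m^2."""
    if q_ads_max < 0:
        raise InvalidParameterError(
            f"surface_normalized_capacity: capacity must be >= 0, got {q_ads_max}"
        )
    return q_ads_max / sorbent.s_bet


def percent_reduction(reference: float, value: float) -> float:
    """100*(reference - value)/reference; negative output means an increase."""
    if reference <= 0:
        raise InvalidParameterError(
            f"percent_reduction: reference must be > 0, got {reference}"
        )
    return 100.0 * (reference - value) / reference


# ---------------------------------------------------------------------------
# Model ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ranking:
    """An ordered model comparison with ">"/"≈" relations between neighbours."""

    labels: tuple
    scores: tuple
    relations: tuple  # len(labels) - 1 entries, each ">" or "≈"
    metric: str  # "mpsd" or "r2"

    def __str__(self) -> str:
        out = [self.labels[0]]
        for rel, lab in zip(self.relations, self.labels[1:]):
            out.append(rel)
            out.append(lab)
        return " ".join(out)


def rank_scores(scores: Mapping[str, float], metric: str = "mpsd", *,
                tie_threshold: float = 1.5, r2_tie: float = 0.01) -> Ranking:
    """Order model labels by goodness of fit and mark near-ties.

    ``metric="mpsd"`` sorts ascending and calls an adjacent pair tied
    when the larger/smaller MPSD ratio is at most ``tie_threshold``;
    ``metric="r2"`` sorts descending with ties at ``|dr2| <= r2_tie``.
    Exactly equal scores order alphabetically (stable).
    """
    if not scores:
        raise InvalidParameterError("rank_scores: empty score collection")
    if metric not in ("mpsd", "r2"):
        raise InvalidParameterError(f"rank_scores: unknown metric {metric!r}")
    reverse = metric == "r2"
    items = sorted(scores.items(), key=lambda kv: (kv[1] if not reverse else -kv[1],
                                                   kv[0]))
    labels = tuple(k for k, _ in items)
    vals = tuple(float(v) for _, v in items)
    relations = []
    for a, b in zip(vals, vals[1:]):
        if metric == "mpsd":
            lo, hi = min(a, b), max(a, b)
            tied = hi <= tie_threshold * lo if lo > 0 else hi == lo
        else:
            tied = abs(a - b) <= r2_tie
        relations.append("≈" if tied else ">")
    return Ranking(labels=labels, scores=vals, relations=tuple(relations),
                   metric=metric)


def rank_models(fits: Sequence[FitResult], *, tie_threshold: float = 1.5,
                r2_tie: float = 0.01, allow_mixed: bool = False) -> Ranking:
    """Rank fitted isotherm families on one dataset.

    Linear-method fits are ranked by descending r^2, nonlinear fits by
    ascending MPSD. Mixing methods requires ``allow_mixed`` (in which
    case MPSD, available for both, is used).
    """
    fits = list(fits)
    if not fits:
        raise InvalidParameterError("rank_models: no fits supplied")
    methods = {f.method for f in fits}
    if len(methods) > 1 and not allow_mixed:
        raise InvalidParameterError(
            f"rank_models: mixed methods {sorted(methods)}; pass allow_mixed=True "
            "to rank by MPSD across methods"
        )
    if len(methods) == 1 and methods == {"linear"}:
        metric = "r2"
        scores = {f.family.short_label: f.r2 for f in fits}
    else:
        metric = "mpsd"
        scores = {f.family.short_label: f.mpsd for f in fits}
        if any(v is None for v in scores.values()):
            raise InvalidParameterError(
                "rank_models: an MPSD value is missing; evaluate the fit first"
            )
    return rank_scores(scores, metric, tie_threshold=tie_threshold, r2_tie=r2_tie)
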