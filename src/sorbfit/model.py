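"""Model/Results interface over the estimation engines.

``IsothermModel`` binds one isotherm family to an equilibrium dataset;
``fit()`` dispatches to linearized least squares or nonlinear MPSD
minimization and returns an ``IsothermResults`` carrying the estimates,
diagnostics, fitted values and a text ``summary()``. ``fit_many`` runs
a grid of families/methods for comparative ranking.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError
from .families import Family, IsothermDataset, ParamSet, predict_qe
from .linear import fit_linear, profile_fit_linear
from .metrics import Ranking, energy_da, energy_dr, rank_models
from .nonlinear import FitEvaluation, NonlinearConfig, evaluate_fit, fit_nonlinear
from .result import FitResult

_PARAM_DISPLAY = {
    "qmax": ("Q_max", "mg/g"),
    "k_l": ("K_L", "dm^3/mg"),
    "k_f": ("K_F", "mg^(1-1/n) dm^(3/n)/g"),
    "n_f": ("n_F", "-"),
    "k_rp": ("K_RP", "dm^3/g"),
    "a_rp": ("a_RP", "dm^(3b)/mg^b"),
    "beta": ("beta", "-"),
    "k_t": ("K_T", "dm^3/mg"),
    "b_t": ("b_T", "J g/(mol mg)"),
    "k_dr": ("K_DR", "mol^2/J^2"),
    "k_da": ("K_DA", "mol^n/J^n"),
    "n_da": ("n_DA", "-"),
}


class IsothermModel:
    """One isotherm family bound to equilibrium adsorption data.

    Parameters
    ----------
    ce, qe : array-like
        Equilibrium concentrations (mg/dm^3) and adsorbed amounts (mg/g).
    family : Family or str
    temperature : float
        Absolute temperature (K); see
        :func:`sorbfit.families.celsius_to_kelvin` for Celsius input.
    solubility : float, optional
        Adsorbate solubility Cs (mg/dm^3); mandatory for the
        Polanyi-potential families.

    Examples
    --------
    >>> model = IsothermModel(ce, qe, "langmuir")
    >>> res = model.fit(method="nonlinear")
    >>> res.params.qmax, res.mpsd
    """

    def __init__(self, ce, qe, family: Union[Family, str], *,
                 temperature: float = 298.15,
                 solubility: Optional[float] = None,
                 sorbent: str = ""):
        self.family = Family(family)
        self.data = IsothermDataset(np.asarray(ce, float), np.asarray(qe, float),
                                    temperature=temperature,
                                    solubility=solubility, sorbent=sorbent)

    @classmethod
    def from_dataset(cls, dataset: IsothermDataset,
                     family: Union[Family, str]) -> "IsothermModel":
        m = cls.__new__(cls)
        m.family = Family(family)
        m.data = dataset
        return m

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, family: Union[Family, str], *,
                       ce_col: str = "ce_mg_dm3", qe_col: str = "qe_mg_g",
                       **context) -> "IsothermModel":
        """Build from an equilibrium-dialect DataFrame (unit-bearing columns)."""
        for col in (ce_col, qe_col):
            if col not in df.columns:
                raise ConfigError(f"from_dataframe: missing column {col!r}")
        return cls(df[ce_col].to_numpy(), df[qe_col].to_numpy(), family, **context)

    def predict(self, params: ParamSet, ce=None):
        """Forward prediction at ``ce`` (defaults to the data's Ce)."""
        ce = self.data.ce if ce is None else ce
        return predict_qe(params, ce, temperature=self.data.temperature,
                          solubility=self.data.solubility)

    def fit(self, method: str = "nonlinear", *,
            allow_drop: bool = False,
            search_bounds: Optional[Tuple[float, float]] = None,
            config: Optional[NonlinearConfig] = None) -> "IsothermResults":
        """Estimate the family's parameters.

        ``method="linear"`` uses the straight-line form (with the
        embedded profile search for three-parameter families);
        ``method="nonlinear"`` minimizes the MPSD relative-error
        objective with deterministic multistart.
        """
        if method == "linear":
            fr = fit_linear(self.family, self.data, allow_drop=allow_drop,
                            search_bounds=search_bounds)
        elif method == "nonlinear":
            cfg = config or NonlinearConfig(allow_drop=allow_drop)
            fr = fit_nonlinear(self.family, self.data, config=cfg)
        else:
            raise ConfigError(f"unknown method {method!r}; expected linear|nonlinear")
        return IsothermResults(self, fr)


class IsothermResults:
    """Estimates and diagnostics from :meth:`IsothermModel.fit`.

    Attributes
    ----------
    params : ParamSet
    r2, mpsd : float or None
    nobs, df_resid : int
    fittedvalues, resid : ndarray
        Aligned with the points used in the fit.
    """

    def __init__(self, model: IsothermModel, fit_result: FitResult):
        self.model = model
        self._fr = fit_result

    @property
    def family(self) -> Family:
        return self._fr.family

    @property
    def method(self) -> str:
        return self._fr.method

    @property
    def params(self) -> ParamSet:
        return self._fr.params

    @property
    def r2(self):
        return self._fr.r2

    @property
    def mpsd(self):
        return self._fr.mpsd

    @property
    def nobs(self) -> int:
        return self._fr.n

    @property
    def df_resid(self) -> int:
        return self._fr.n - self._fr.p

    @property
    def fittedvalues(self) -> np.ndarray:
        return self._fr.predicted

    @property
    def used_indices(self) -> np.ndarray:
        return self._fr.extras.get("used_indices",
                                   np.arange(len(self.model.data)))

    @property
    def resid(self) -> np.ndarray:
        return self.model.data.qe[self.used_indices] - self.fittedvalues

    @property
    def fit_result(self) -> FitResult:
        return self._fr

    def evaluate(self, dataset: Optional[IsothermDataset] = None) -> FitEvaluation:
        """Cross-method diagnostics (MPSD + observed-vs-predicted r^2)."""
        return evaluate_fit(self._fr, dataset or self.model.data)

    def energy(self) -> float:
        """Mean free adsorption energy (kJ/mol) for the Polanyi families."""
        p = self.params
        if self.family is Family.DUBININ_RADUSHKEVICH:
            return energy_dr(p.k_dr)
        if self.family is Family.DUBININ_ASTAKHOV:
            return energy_da(p.k_da, p.n_da)
        raise InvalidParameterError(
            f"energy() applies to the Polanyi-potential families, not {self.family.value}"
        )

    def predict(self, ce=None):
        return self.model.predict(self.params, ce)

    def params_frame(self) -> pd.DataFrame:
        """Parameters as a tidy DataFrame (name, symbol, unit, value)."""
        rows = []
        for name, value in self.params.as_dict().items():
            sym, unit = _PARAM_DISPLAY[name]
            rows.append({"name": name, "symbol": sym, "unit": unit, "value": value})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit report."""
        lines = []
        title = f"{self.family.value} isotherm — {self.method} fit"
        lines.append(title)
        lines.append("=" * len(title))
        if self.model.data.sorbent:
            lines.append(f"sorbent:        {self.model.data.sorbent}")
        lines.append(f"n obs:          {self.nobs}")
        lines.append(f"df resid:       {self.df_resid}")
        lines.append(f"temperature:    {self.model.data.temperature:.2f} K")
        if self.model.data.solubility is not None:
            lines.append(f"solubility Cs:  {self.model.data.solubility:g} mg/dm^3")
        if self.r2 is not None:
            lines.append(f"r^2:            {self.r2:.6f}")
        if self.mpsd is not None:
            lines.append(f"MPSD:           {self.mpsd:.4g}")
        lines.append("-" * len(title))
        for name, value in self.params.as_dict().items():
            sym, unit = _PARAM_DISPLAY[name]
            lines.append(f"{sym:<8} {value:>12.4g}   [{unit}]")
        if self.family.uses_polanyi:
            e = self.energy()
            note = ("physisorption-range" if e < 8.0 else "chemisorption-range")
            lines.append(f"{'E':<8} {e:>12.2f}   [kJ/mol] ({note}, 8 kJ/mol convention)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        gof = (f"r2={self.r2:.4f}" if self.r2 is not None
               else f"mpsd={self.mpsd:.3g}")
        return (f"<IsothermResults {self.family.value} {self.method} "
                f"n={self.nobs} {gof}>")


def fit_many(dataset: IsothermDataset,
             families: Optional[Iterable[Union[Family, str]]] = None,
             method: str = "nonlinear", *, allow_drop: bool = False,
             config: Optional[NonlinearConfig] = None,
             skip_failures: bool = False) -> Dict[Family, IsothermResults]:
    """Fit several families to one dataset with one method.

    With ``skip_failures`` a family whose fit raises a package error is
    silently omitted (mirroring published tables that leave unfittable
    families blank); otherwise errors propagate.
    """
    fams = [Family(f) for f in (families or list(Family))]
    out: Dict[Family, IsothermResults] = {}
    for fam in fams:
        model = IsothermModel.from_dataset(dataset, fam)
        try:
            out[fam] = model.fit(method, allow_drop=allow_drop, config=config)
        except Exception:
            if not skip_failures:
                raise
    return out


def rank_results(results: Dict[Family, IsothermResults], *,
                 tie_threshold: float = 1.5, r2_tie: float = 0.01) -> Ranking:
    """Rank a :func:`fit_many` output by its method's own score."""
    return rank_models([r.fit_result for r in results.values()],
                       tie_threshold=tie_threshold, r2_tie=r2_tie)
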