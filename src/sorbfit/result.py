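"""Container for one fitted isotherm."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InsufficientDataError
from .families import Family, ParamSet


@dataclass
class FitResult:
    """Parameters and goodness-of-fit for one (family, method) fit.

    Attributes
    ----------
    family : Family
    method : str
        ``"linear"`` or ``"nonlinear"``.
    params : ParamSet
    r2 : float or None
        Coefficient of determination of the straight-line fit (linear
        method); squared observed-vs-predicted correlation when attached
        by post-hoc evaluation of a nonlinear fit.
    mpsd : float or None
        Marquardt percent standard deviation (relative-error objective
        with n - p degrees of freedom), on the reported x100 scale.
    n, p : int
        Number of points used and number of model parameters.
    predicted : ndarray
        Model Qe at the data's Ce values.
    extras : dict
        Method-specific diagnostics (profile grid, optimizer info, ...).
    """

    family: Family
    method: str
    params: ParamSet
    n: int
    p: int
    predicted: np.ndarray
    r2: Optional[float] = None
    mpsd: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n <= self.p:
            raise InsufficientDataError(
                f"FitResult requires n > p, got n={self.n}, p={self.p}"
            )
        if self.r2 is not None and not (-1e-12 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 out of [0, 1]: {self.r2!r}")
        if self.mpsd is not None and self.mpsd < 0:
            raise ValueError(f"mpsd must be >= 0, got {self.mpsd!r}")
        self.predicted = np.asarray(self.predicted, dtype=float)

    @property
    def score(self) -> float:
        """The method's own quality score (r2 for linear, MPSD for nonlinear)."""
        return self.r2 if self.method == "linear" else self.mpsd
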