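"""Published reference values for 18beta-glycyrrhetinic acid adsorption
on amine-functionalized silicas.

Eight sorbents — mesoporous SBA-15 and non-porous fumed silica
(Aerosil), each grafted with one of four aminoalkyl-trimethoxysilanes —
were characterized (functional-group content from thermogravimetry, BET
surface area) and their equilibrium isotherms fitted by both linearized
regression and nonlinear MPSD minimization. The fitted parameter sets
and goodness-of-fit values reported for each sorbent x family x method
are transcribed here verbatim as fixtures for regression tests and
report regeneration; families the source reports as not fittable are
omitted. The raw (Ce, Qe) observations behind these fits were published
only graphically, so the tables — not re-fittable data — are the ground
truth this package can check itself against.
"""

from __future__ import annotations

from typing import Dict

from .errors import ConfigError
from .families import Family, ParamSet, make_params
from .metrics import CompoundInfo, SorbentRecord

F = Family

#: The study's adsorbate: a pentacyclic triterpenoid, C30H46O4.
COMPOUND = CompoundInfo(name="18beta-glycyrrhetinic acid", molar_mass=470.68)

#: Sorbent metadata: functional-group content (mol/g), BET area (m^2/g),
#: BJH pore volume (cm^3/g) and diameter (nm) where measured.
SORBENTS: Dict[str, SorbentRecord] = {
    "SBA-15": SorbentRecord("SBA-15", "", 0.0, 770.0, 0.96, 5.8),
    "SBA-15-AP": SorbentRecord("SBA-15-AP", "APTMS", 1.55e-3, 438.0, 0.67, 5.4),
    "SBA-15-MAP": SorbentRecord("SBA-15-MAP", "MAPTMS", 1.42e-3, 430.0, 0.67, 5.4),
    "SBA-15-DMAP": SorbentRecord("SBA-15-DMAP", "DMAPTMS", 1.30e-3, 425.0, 0.68, 5.4),
    "SBA-15-AEAP": SorbentRecord("SBA-15-AEAP", "AEAPTMS", 1.47e-3, 382.0, 0.66, 5.3),
    "Aer": SorbentRecord("Aer", "", 0.0, 181.0),
    "Aer-AP": SorbentRecord("Aer-AP", "APTMS", 5.63e-4, 168.0),
    "Aer-MAP": SorbentRecord("Aer-MAP", "MAPTMS", 4.99e-4, 163.0),
    "Aer-DMAP": SorbentRecord("Aer-DMAP", "DMAPTMS", 4.32e-4, 158.0),
    "Aer-AEAP": SorbentRecord("Aer-AEAP", "AEAPTMS", 6.10e-4, 149.0),
}

#: Modified (amine-grafted) sorbents, in table order.
MODIFIED_SBA15 = ("SBA-15-AP", "SBA-15-MAP", "SBA-15-DMAP", "SBA-15-AEAP")
MODIFIED_AEROSIL = ("Aer-AP", "Aer-MAP", "Aer-DMAP", "Aer-AEAP")
MODIFIED_SORBENTS = MODIFIED_SBA15 + MODIFIED_AEROSIL

# per (sorbent, method): {family: {"params": {...}, "r2"/"mpsd": ..., "e_*": ...}}
_TABLES = {
    # --- linearized regression, modified SBA-15 ---
    ("SBA-15-AP", "linear"): {
        F.LANGMUIR: {"params": dict(qmax=169.5, k_l=2.745e-3), "r2": 0.9992},
        F.FREUNDLICH: {"params": dict(k_f=2.973, n_f=1.948), "r2": 0.9440},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.488, a_rp=6.698e-3, beta=0.883),
                             "r2": 0.9993},
        F.TEMKIN: {"params": dict(k_t=3.765e-2, b_t=72.74), "r2": 0.9839},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=286.3, k_dr=8.110e-9),
                                 "r2": 0.9901, "e_dr": 7.85},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=210.4, k_da=5.462e-12, n_da=2.733),
                             "r2": 0.9988, "e_da": 9.34},
    },
    ("SBA-15-MAP", "linear"): {
        F.LANGMUIR: {"params": dict(qmax=151.5, k_l=2.794e-3), "r2": 0.9970},
        F.FREUNDLICH: {"params": dict(k_f=2.413, n_f=1.879), "r2": 0.9680},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.479, a_rp=1.581e-2, beta=0.778),
                             "r2": 0.9978},
        F.TEMKIN: {"params": dict(k_t=3.032e-2, b_t=72.42), "r2": 0.9659},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=272.9, k_dr=8.369e-9),
                                 "r2": 0.9971, "e_dr": 7.73},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=237.9, k_da=6.442e-10, n_da=2.257),
                             "r2": 0.9982, "e_da": 8.35},
    },
    ("SBA-15-DMAP", "linear"): {
        F.LANGMUIR: {"params": dict(qmax=61.0, k_l=3.072e-4), "r2": 0.9903},
        F.FREUNDLICH: {"params": dict(k_f=2.923e-2, n_f=1.126), "r2": 0.9941},
        F.TEMKIN: {"params": dict(k_t=4.372e-3, b_t=157.1), "r2": 0.8247},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=98.4, k_dr=1.616e-8),
                                 "r2": 0.9703, "e_dr": 5.56},
    },
    ("SBA-15-AEAP", "linear"): {
        F.LANGMUIR: {"params": dict(qmax=178.6, k_l=2.384e-3), "r2": 0.9993},
        F.FREUNDLICH: {"params": dict(k_f=2.868, n_f=1.938), "r2": 0.9422},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.441, a_rp=4.144e-3, beta=0.931),
                             "r2": 0.9949},
        F.TEMKIN: {"params": dict(k_t=3.571e-2, b_t=72.93), "r2": 0.9883},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=284.6, k_dr=8.209e-9),
                                 "r2": 0.9891, "e_dr": 7.80},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=203.0, k_da=2.030e-12, n_da=2.834),
                             "r2": 0.9996, "e_da": 9.45},
    },
    # --- linearized regression, modified Aerosil ---
    ("Aer-AP", "linear"): {
        F.LANGMUIR: {"params": dict(qmax=89.3, k_l=2.822e-3), "r2": 0.9952},
        F.FREUNDLICH: {"params": dict(k_f=2.179, n_f=2.152), "r2": 0.9533},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.288, a_rp=1.250e-2, beta=0.820),
                             "r2": 0.9987},
        F.TEMKIN: {"params": dict(k_t=2.942e-2, b_t=128.3), "r2": 0.9870},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=144.9, k_dr=7.809e-9),
                                 "r2": 0.9940, "e_dr": 8.00},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=118.2, k_da=4.273e-11, n_da=2.525),
                             "r2": 0.9987, "e_da": 9.04},
    },
    ("Aer-MAP", "linear"): {
        F.LANGMUIR: {"params": dict(qmax=84.0, k_l=2.663e-3), "r2": 0.9910},
        F.FREUNDLICH: {"params": dict(k_f=1.767, n_f=2.058), "r2": 0.9730},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.284, a_rp=2.345e-2, beta=0.744),
                             "r2": 0.9982},
        F.TEMKIN: {"params": dict(k_t=2.294e-2, b_t=124.9), "r2": 0.9731},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=141.7, k_dr=8.169e-9),
                                 "r2": 0.9980, "e_dr": 7.82},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=134.0, k_da=2.622e-9, n_da=2.114),
                             "r2": 0.9982, "e_da": 8.11},
    },
    ("Aer-DMAP", "linear"): {
        F.FREUNDLICH: {"params": dict(k_f=1.606e-2, n_f=1.101), "r2": 0.9840},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=65.0, k_dr=1.648e-8),
                                 "r2": 0.9376, "e_dr": 5.51},
    },
    ("Aer-AEAP", "linear"): {
        F.LANGMUIR: {"params": dict(qmax=89.3, k_l=2.046e-3), "r2": 0.9949},
        F.FREUNDLICH: {"params": dict(k_f=1.362, n_f=1.924), "r2": 0.9772},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.221, a_rp=1.691e-2, beta=0.748),
                             "r2": 0.9992},
        F.TEMKIN: {"params": dict(k_t=1.851e-2, b_t=116.6), "r2": 0.9703},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=149.8, k_dr=8.828e-9),
                                 "r2": 0.9993, "e_dr": 7.53},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=144.3, k_da=4.375e-9, n_da=2.071),
                             "r2": 0.9994, "e_da": 7.69},
    },
    # --- nonlinear MPSD fits, modified SBA-15 ---
    ("SBA-15-AP", "nonlinear"): {
        F.LANGMUIR: {"params": dict(qmax=183.7, k_l=2.357e-3), "mpsd": 4.66},
        F.FREUNDLICH: {"params": dict(k_f=2.634, n_f=1.918), "mpsd": 23.15},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.471, a_rp=5.068e-3, beta=0.914),
                             "mpsd": 2.72},
        F.TEMKIN: {"params": dict(k_t=5.728e-2, b_t=91.96), "mpsd": 22.22},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=282.9, k_dr=8.107e-9),
                                 "mpsd": 9.74, "e_dr": 7.85},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=210.3, k_da=5.448e-12, n_da=2.733),
                             "mpsd": 3.58, "e_da": 9.35},
    },
    ("SBA-15-MAP", "nonlinear"): {
        F.LANGMUIR: {"params": dict(qmax=176.7, k_l=2.033e-3), "mpsd": 10.53},
        F.FREUNDLICH: {"params": dict(k_f=2.268, n_f=1.867), "mpsd": 18.15},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.468, a_rp=1.412e-2, beta=0.790),
                             "mpsd": 5.01},
        F.TEMKIN: {"params": dict(k_t=5.412e-2, b_t=99.00), "mpsd": 24.26},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=271.5, k_dr=8.358e-9),
                                 "mpsd": 5.30, "e_dr": 7.73},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=237.3, k_da=6.414e-10, n_da=2.257),
                             "mpsd": 4.33, "e_da": 8.37},
    },
    ("SBA-15-DMAP", "nonlinear"): {
        F.LANGMUIR: {"params": dict(qmax=227.3, k_l=6.453e-5), "mpsd": 11.98},
        F.FREUNDLICH: {"params": dict(k_f=2.921e-2, n_f=1.128), "mpsd": 9.36},
        F.REDLICH_PETERSON: {"params": dict(k_rp=3.971, a_rp=135.1, beta=0.113),
                             "mpsd": 9.87},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=97.0, k_dr=1.654e-8),
                                 "mpsd": 20.62, "e_dr": 5.50},
    },
    ("SBA-15-AEAP", "nonlinear"): {
        F.LANGMUIR: {"params": dict(qmax=182.0, k_l=2.278e-3), "mpsd": 4.03},
        F.FREUNDLICH: {"params": dict(k_f=2.479, n_f=1.895), "mpsd": 23.45},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.446, a_rp=4.516e-3, beta=0.922),
                             "mpsd": 2.11},
        F.TEMKIN: {"params": dict(k_t=5.193e-2, b_t=89.23), "mpsd": 19.16},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=282.0, k_dr=8.234e-9),
                                 "mpsd": 10.16, "e_dr": 7.79},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=202.8, k_da=2.035e-12, n_da=2.834),
                             "mpsd": 1.99, "e_da": 9.44},
    },
    # --- nonlinear MPSD fits, modified Aerosil ---
    ("Aer-AP", "nonlinear"): {
        F.LANGMUIR: {"params": dict(qmax=99.6, k_l=2.191e-3), "mpsd": 7.47},
        F.FREUNDLICH: {"params": dict(k_f=2.011, n_f=2.125), "mpsd": 17.73},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.269, a_rp=8.902e-3, beta=0.853),
                             "mpsd": 3.59},
        F.TEMKIN: {"params": dict(k_t=4.093e-2, b_t=148.7), "mpsd": 14.43},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=144.2, k_dr=7.806e-9),
                                 "mpsd": 6.31, "e_dr": 8.00},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=118.2, k_da=4.282e-11, n_da=2.525),
                             "mpsd": 3.03, "e_da": 9.03},
    },
    ("Aer-MAP", "nonlinear"): {
        F.LANGMUIR: {"params": dict(qmax=98.1, k_l=1.835e-3), "mpsd": 11.28},
        F.FREUNDLICH: {"params": dict(k_f=1.705, n_f=2.052), "mpsd": 13.93},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.269, a_rp=1.916e-2, beta=0.762),
                             "mpsd": 4.65},
        F.TEMKIN: {"params": dict(k_t=3.689e-2, b_t=154.9), "mpsd": 17.03},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=141.4, k_dr=8.159e-9),
                                 "mpsd": 3.70, "e_dr": 7.83},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=133.7, k_da=2.628e-9, n_da=2.114),
                             "mpsd": 3.65, "e_da": 8.10},
    },
    ("Aer-DMAP", "nonlinear"): {
        F.FREUNDLICH: {"params": dict(k_f=1.380e-2, n_f=1.081), "mpsd": 15.21},
        F.REDLICH_PETERSON: {"params": dict(k_rp=3.910, a_rp=282.5, beta=0.075),
                             "mpsd": 16.04},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=64.0, k_dr=1.740e-8),
                                 "mpsd": 28.55, "e_dr": 5.36},
    },
    ("Aer-AEAP", "nonlinear"): {
        F.LANGMUIR: {"params": dict(qmax=104.1, k_l=1.468e-3), "mpsd": 10.26},
        F.FREUNDLICH: {"params": dict(k_f=1.295, n_f=1.908), "mpsd": 13.33},
        F.REDLICH_PETERSON: {"params": dict(k_rp=0.219, a_rp=1.629e-2, beta=0.751),
                             "mpsd": 2.82},
        F.TEMKIN: {"params": dict(k_t=3.117e-2, b_t=150.1), "mpsd": 18.60},
        F.DUBININ_RADUSHKEVICH: {"params": dict(qmax=149.6, k_dr=8.825e-9),
                                 "mpsd": 2.29, "e_dr": 7.53},
        F.DUBININ_ASTAKHOV: {"params": dict(qmax=144.2, k_da=4.363e-9, n_da=2.071),
                             "mpsd": 2.27, "e_da": 7.70},
    },
}

#: Published model-comparison orderings per sorbent and method.
REFERENCE_RANKINGS = {
    ("SBA-15-AP", "linear"): "R-P ≈ L ≈ D-A ≈ D-R > T > F",
    ("SBA-15-AP", "nonlinear"): "R-P ≈ D-A ≈ L > D-R > T ≈ F",
    ("SBA-15-MAP", "linear"): "D-A ≈ R-P ≈ D-R ≈ L > F ≈ T",
    ("SBA-15-MAP", "nonlinear"): "D-A ≈ R-P ≈ D-R > L > F > T",
    ("SBA-15-DMAP", "linear"): "F > L > D-R > T",
    ("SBA-15-DMAP", "nonlinear"): "F ≈ R-P > L > D-R",
    ("SBA-15-AEAP", "linear"): "D-A ≈ L ≈ R-P > D-R ≈ T > F",
    ("SBA-15-AEAP", "nonlinear"): "D-A ≈ R-P ≈ L > D-R > T > F",
    ("Aer-AP", "linear"): "D-A > R-P ≈ L ≈ D-R > T > F",
    ("Aer-AP", "nonlinear"): "D-A ≈ R-P > D-R ≈ L > T > F",
    ("Aer-MAP", "linear"): "D-A = R-P ≈ D-R ≈ L > T ≈ F",
    ("Aer-MAP", "nonlinear"): "D-A ≈ D-R ≈ R-P > L > F > T",
    ("Aer-DMAP", "linear"): "F > D-R",
    ("Aer-DMAP", "nonlinear"): "F ≈ R-P > D-R",
    ("Aer-AEAP", "linear"): "D-A ≈ D-R ≈ R-P ≈ L > F ≈ T",
    ("Aer-AEAP", "nonlinear"): "D-A ≈ D-R ≈ R-P > L > F > T",
}


def _lookup(sorbent: str, method: str) -> dict:
    if method not in ("linear", "nonlinear"):
        raise ConfigError(f"unknown method {method!r}; expected linear|nonlinear")
    key = (sorbent, method)
    if key not in _TABLES:
        raise ConfigError(
            f"no reference table for sorbent {sorbent!r}; known modified "
            f"sorbents: {', '.join(MODIFIED_SORBENTS)}"
        )
    return _TABLES[key]


def reference_params(sorbent: str, method: str) -> Dict[Family, ParamSet]:
    """Published parameter sets for one sorbent and estimation method.

    Families not reported for that sorbent are absent from the map.
    """
    table = _lookup(sorbent, method)
    return {fam: make_params(fam, **row["params"]) for fam, row in table.items()}


def reference_quality(sorbent: str, method: str) -> Dict[Family, float]:
    """Published goodness-of-fit (r2 for linear, MPSD for nonlinear)."""
    table = _lookup(sorbent, method)
    key = "r2" if method == "linear" else "mpsd"
    return {fam: row[key] for fam, row in table.items()}


def reference_energy_dr(sorbent: str, method: str) -> Dict[str, float]:
    """Published (K_DR, E_DR) pairs: {'k_dr': ..., 'e_dr': ...}."""
    row = _lookup(sorbent, method).get(F.DUBININ_RADUSHKEVICH)
    if row is None:
        raise ConfigError(f"no Dubinin-Radushkevich entry for {sorbent!r}/{method}")
    return {"k_dr": row["params"]["k_dr"], "e_dr": row["e_dr"]}


def reference_table(sorbent: str, method: str) -> Dict[Family, dict]:
    """The full transcribed row set (params + quality + printed energies)."""
    return {fam: dict(row) for fam, row in _lookup(sorbent, method).items()}
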