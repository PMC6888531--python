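"""Shared fixtures: noiseless synthetic datasets from published truths."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from sorbfit import (
    Family,
    default_design,
    generate_dataset,
    make_params,
    reference_params,
)

#: One published nonlinear parameter set per family (SBA-15-AP column).
TRUTH_PARAMS = {
    Family.LANGMUIR: dict(qmax=183.7, k_l=2.357e-3),
    Family.FREUNDLICH: dict(k_f=2.634, n_f=1.918),
    Family.REDLICH_PETERSON: dict(k_rp=0.471, a_rp=5.068e-3, beta=0.914),
    Family.TEMKIN: dict(k_t=5.728e-2, b_t=91.96),
    Family.DUBININ_RADUSHKEVICH: dict(qmax=282.9, k_dr=8.107e-9),
    Family.DUBININ_ASTAKHOV: dict(qmax=210.3, k_da=5.448e-12, n_da=2.733),
}


def truth(family) -> "ParamSet":
    return make_params(family, **TRUTH_PARAMS[Family(family)])


def noiseless_dataset(family, n_points=12, seed=0):
    params = truth(family)
    design = default_design(n_points=n_points, seed=seed)
    dataset, _ = generate_dataset(params, design)
    return params, dataset


@pytest.fixture(scope="session")
def langmuir_truth():
    return make_params(Family.LANGMUIR, qmax=169.5, k_l=2.745e-3)


@pytest.fixture(scope="session")
def langmuir_dataset(langmuir_truth):
    dataset, _ = generate_dataset(langmuir_truth, default_design())
    return dataset


@pytest.fixture(scope="session")
def sba15_ap_nonlinear():
    return reference_params("SBA-15-AP", "nonlinear")
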