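"""Shared fixtures: small synthetic cohorts and quiet logging."""

import logging

import numpy as np
import pytest

from fetalgrowth.cohort import CohortSpec, ParameterCurveSpec, generate_cohort
from fetalgrowth.defaults import (
    REFERENCE_COEFFICIENTS,
    REFERENCE_GA_RANGE,
    REFERENCE_R2_BY_DEGREE,
)
from fetalgrowth.records import Parameter


@pytest.fixture(autouse=True)
def _quiet_condition_warnings():
    # raw-day quadratics always trip the Gram condition warning; keep test
    # output readable
    logging.getLogger("fetalgrowth.polynomial").setLevel(logging.ERROR)
    yield
    logging.getLogger("fetalgrowth.polynomial").setLevel(logging.NOTSET)


def single_parameter_spec(
    parameter: Parameter,
    n_records: int,
    seed: int,
    target_r2: float | None = None,
    noise_sd: float | None = None,
    n_subjects: int = 300,
    **kwargs,
) -> CohortSpec:
    """Cohort spec with one parameter, default reference curve and range."""
    if target_r2 is None and noise_sd is None:
        target_r2 = REFERENCE_R2_BY_DEGREE[parameter][2]
    pspec = ParameterCurveSpec(
        coefficients=REFERENCE_COEFFICIENTS[parameter],
        ga_range=REFERENCE_GA_RANGE[parameter],
        target_r2=target_r2,
        noise_sd=noise_sd,
        n_records=n_records,
    )
    kwargs.setdefault("gdm_prevalence", 0.0)
    kwargs.setdefault("pe_prevalence", 0.0)
    return CohortSpec(
        n_subjects=n_subjects, parameters={parameter: pspec}, seed=seed, **kwargs
    )


@pytest.fixture(scope="session")
def ac_cohort_5000():
    """Noise-calibrated abdominal-circumference cohort, n = 5000."""
    return generate_cohort(single_parameter_spec(Parameter.AC, 5000, seed=3))


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort (all six parameters, condition shifts)."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
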