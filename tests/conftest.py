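"""Shared fixtures: default drug models, zero-variability variants, cohorts."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from tpt_adherence import (
    CohortConfig,
    DosingRegimen,
    PatientCovariates,
    default_drug_models,
    fat_free_mass,
    sample_individual,
)


@pytest.fixture(scope="session")
def specs():
    return default_drug_models()


@pytest.fixture(scope="session")
def pza(specs):
    return specs["pyrazinamide"]


@pytest.fixture(scope="session")
def rif(specs):
    return specs["rifampicin"]


def zero_bsv(spec):
    return replace(spec, bsv={k: 0.0 for k in spec.bsv})


@pytest.fixture(scope="session")
def pza0(pza):
    return zero_bsv(pza)


@pytest.fixture(scope="session")
def rif0(rif):
    return zero_bsv(rif)


@pytest.fixture(scope="session")
def typical_cov():
    return PatientCovariates(weight=56.0, height=1.63, sex="male")


@pytest.fixture(scope="session")
def typical_ffm(typical_cov):
    return fat_free_mass(typical_cov)


def deterministic_individual(spec, ffm):
    """Individual at the scaled typical values (all BSV variances zero)."""
    rng = np.random.default_rng(0)
    return sample_individual(zero_bsv(spec), ffm, rng, n=1)


@pytest.fixture(scope="session")
def pza_regimen():
    return DosingRegimen(dose_amount=1600.0)


@pytest.fixture(scope="session")
def rif_regimen():
    return DosingRegimen(dose_amount=600.0)


@pytest.fixture(scope="session")
def small_study(specs):
    """A small synthetic study shared across read-only tests."""
    from tpt_adherence import generate_study

    cfg = CohortConfig(n_cases=6, seed=123)
    return generate_study(cfg, specs)


@pytest.fixture(scope="session")
def default_study(specs):
    """The full-size (28 cases) synthetic study, generated once per session."""
    from tpt_adherence import generate_study

    return generate_study(CohortConfig(seed=2026), specs)
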