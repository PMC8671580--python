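import numpy as np
import pytest

import dpskin as dk


@pytest.fixture(scope="session")
def scan1():
    return dk.standard_schedule("scan1")


@pytest.fixture(scope="session")
def full_schedule():
    return dk.standard_schedule("full")


@pytest.fixture(scope="session")
def triexp_template():
    """Bolus-like mediastinal template used across fitting tests."""
    return dk.TriExpFit(
        t0_min=0.5,
        amplitudes=[10.0, 3.0, 1.0],
        rates_per_min=[1.0, 0.1, 0.01],
        constant=0.5,
    )


@pytest.fixture(scope="session")
def corrections():
    return dk.CorrectionCurves()


@pytest.fixture(scope="session")
def parametric_pif(triexp_template, corrections):
    return dk.ParametricPIF(triexp_template, corrections)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Six noise-free patients (3 LBD / 3 control), full schedule."""
    groups = {
        "PD_pRBDneg": dk.GroupParams(
            n=3, iloss_mean=0.0557, iloss_sd=0.0129, ratio_mean=2.30, ratio_sd=1.67
        ),
        "nonLBD": dk.GroupParams(
            n=3, iloss_mean=0.038, iloss_sd=0.007, ratio_mean=3.5, ratio_sd=1.0
        ),
    }
    cfg = dk.CohortConfig(groups=groups, noise_level=0.0)
    cohort, tacs = dk.generate_cohort(cfg, seed=11)
    return cfg, cohort, tacs


@pytest.fixture(scope="session")
def default_cohort():
    """The default 166-patient cohort at the default noise level."""
    cfg = dk.CohortConfig()
    cohort, tacs = dk.generate_cohort(cfg, seed=5)
    return cfg, cohort, tacs
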