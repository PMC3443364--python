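"""Session fixtures: one synthetic master cohort with its fits, and the
replicate study reused by the calibration, coverage and bias checks.

Simulation studies are fitted with the exact likelihood (two-year rule off,
since the simulator has no such approximation) and initialised at the
generating values, the standard design for simulation calibration work.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from semicr import FitOptions, fit
from semicr.inference import sensitivity_over_k
from semicr.simulate import default_params, simulate_cohort

import helpers


@pytest.fixture(scope="session")
def gen_params():
    return default_params()


@pytest.fixture(scope="session")
def exp_params():
    return helpers.exponential_params()


@pytest.fixture(scope="session")
def sim_fit_options():
    """Fitting settings for simulation studies: exact likelihood, 8-node
    quadrature, slightly relaxed stopping rule."""
    return FitOptions(
        quad_nodes=8,
        two_year_rule=False,
        compute_se=False,
        gtol=1e-3,
        ftol=1e-9,
    )


@pytest.fixture(scope="session")
def master_cohort(gen_params):
    """The n=1000 synthetic cohort behind the sensitivity / LRT fixtures."""
    return simulate_cohort(gen_params, 1000, seed=8001)


@pytest.fixture(scope="session")
def fits_by_k(master_cohort, gen_params, sim_fit_options):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sens = sensitivity_over_k(
            master_cohort.records,
            k_values=(0.5, 1.0, 2.0),
            init=gen_params,
            options=sim_fit_options,
        )
    assert not sens.errors
    return sens


@pytest.fixture(scope="session")
def full_and_reduced(master_cohort, fits_by_k, sim_fit_options):
    """Reduced fit alongside the shared k=1 full fit, with the LRT."""
    from semicr import fit_reduced_noninformative, lrt_informative_ltf

    full = fits_by_k.fits[1.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reduced = fit_reduced_noninformative(
            master_cohort.records, init=full.params, options=sim_fit_options
        )
    return full, reduced, lrt_informative_ltf(full, reduced)


@pytest.fixture(scope="session")
def recovery_fit(gen_params):
    """n=2000 cohort fitted at the generating k with the package's default
    initial values; standard errors from the numerical Hessian."""
    sim = simulate_cohort(gen_params, 2000, seed=7)
    opts = FitOptions(
        quad_nodes=8, two_year_rule=False, compute_se=True, gtol=1e-3, ftol=1e-9
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fr = fit(sim.records, k=1.0, options=opts)
    return sim, fr


@pytest.fixture(scope="session")
def replicate_study(gen_params):
    """20 replicate cohorts of n=250, each fitted with Hessian SEs; feeds
    the SE-calibration, Wald-coverage and bias checks."""
    opts = FitOptions(
        quad_nodes=8, two_year_rule=False, compute_se=True, gtol=1e-3, ftol=1e-9
    )
    thetas, ses = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(20):
            sim = simulate_cohort(gen_params, 250, seed=1000 + rep)
            fr = fit(sim.records, k=1.0, init=gen_params, options=opts)
            thetas.append(fr.theta)
            ses.append(fr.se)
    return {
        "theta": np.array(thetas),
        "se": np.array(ses),
        "truth": gen_params.to_vector(),
        "names": fr.names,
    }
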