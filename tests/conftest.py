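"""Shared fixtures and independent brute-force oracles."""

from itertools import product

import numpy as np
import pytest

import painlca as pl


def brute_force_pattern_prob(gamma, rho, pattern):
    """Direct evaluation of the mixture probability of one pattern,
    marginalising missing (NaN) items; independent of the package's
    log-sum-exp path."""
    gamma = np.asarray(gamma, float)
    rho = np.asarray(rho, float)
    total = 0.0
    for c in range(len(gamma)):
        term = gamma[c]
        for j, x in enumerate(pattern):
            if x is None or (isinstance(x, float) and np.isnan(x)):
                continue
            term *= rho[c, j] if x == 1 else (1.0 - rho[c, j])
        total += term
    return total


def brute_force_loglik(gamma, rho, items):
    """Sum of log pattern probabilities over records (all-missing rows
    contribute log 1 = 0)."""
    total = 0.0
    for row in items:
        pattern = [np.nan if np.isnan(v) else int(v) for v in row]
        p = brute_force_pattern_prob(gamma, rho, pattern)
        if all(np.isnan(v) for v in row):
            continue
        total += np.log(p)
    return total


def brute_force_posterior(gamma, rho, pattern):
    """Per-class joint masses normalised to a posterior row."""
    gamma = np.asarray(gamma, float)
    rho = np.asarray(rho, float)
    joints = []
    for c in range(len(gamma)):
        term = gamma[c]
        for j, x in enumerate(pattern):
            if x is None or (isinstance(x, float) and np.isnan(x)):
                continue
            term *= rho[c, j] if x == 1 else (1.0 - rho[c, j])
        joints.append(term)
    joints = np.array(joints)
    return joints / joints.sum()


def all_patterns(J):
    return [np.array(p) for p in product([0, 1], repeat=J)]


@pytest.fixture(scope="session")
def two_class_params():
    """The hand-checkable 2-class, 2-item example: P(1,1) = 0.132."""
    return pl.LCAParameters(gamma=[0.4, 0.6], rho=[[0.9, 0.1], [0.2, 0.8]],
                            item_names=("a", "b"))


@pytest.fixture(scope="session")
def table2():
    return pl.load_fixture("table2")


@pytest.fixture(scope="session")
def table5():
    return pl.load_fixture("table5_gender_age")


@pytest.fixture(scope="session")
def table2_params(table2):
    return table2.params.group_params(0)


@pytest.fixture(scope="session")
def well_separated_params():
    """Three cleanly separated classes on six items: enough observed pattern
    degrees of freedom (63) relative to parameters (20) that the classes are
    strongly identified; used where recovery should be easy."""
    return pl.LCAParameters(
        gamma=[0.5, 0.3, 0.2],
        rho=[[0.05, 0.1, 0.05, 0.1, 0.08, 0.06],
             [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
             [0.9, 0.95, 0.9, 0.95, 0.92, 0.93]],
    )


def fixture_from_params(params: pl.LCAParameters, name: str = "synthetic"):
    """Wrap single-group parameters as a one-stratum generator fixture."""
    return pl.Fixture(
        name=name,
        params=pl.MultigroupParameters(
            group_names=("all",),
            gamma=params.gamma[None, :],
            rho=params.rho[None, :, :],
            rho_invariant=False,
            item_names=params.item_names,
        ),
        group_fractions=[1.0],
    )


@pytest.fixture(scope="session")
def simulated_1611(table2):
    """One seeded table2 simulation at the design sample size."""
    return pl.simulate(table2, pl.GeneratorConfig(n_total=1611, seed=20180713))
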