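"""Shared fixtures: a small shelf system with known ground truth, fitted once
per session and reused by the evaluation/projection/metric tests."""

import numpy as np
import pytest

import fishcast as fc
from fishcast.model import SubmodelPosterior
from fishcast.synthetic import CommunityConfig


@pytest.fixture(scope="session")
def grid_small():
    return fc.make_grid(nlon=12, nlat=10, seed=0)


@pytest.fixture(scope="session")
def env_small(grid_small):
    return fc.simulate_environment(grid_small, seed=1)


@pytest.fixture(scope="session")
def tree8():
    return fc.simulate_tree(8, seed=2)


@pytest.fixture(scope="session")
def traits8(tree8):
    return fc.simulate_traits(tree8.species, seed=3)


@pytest.fixture(scope="session")
def community(env_small, tree8, traits8):
    cfg = CommunityConfig(
        rho=0.7,
        n_factors=0,
        covariates=("bottom_temperature", "depth", "oxygen"),
        quadratic_for=("bottom_temperature",),
    )
    survey, truth, design = fc.simulate_community(
        env_small, tree8, traits8, cfg, n_hauls=400, seed=4
    )
    return survey, truth, design


@pytest.fixture(scope="session")
def fitted(community, tree8, traits8):
    survey, truth, design = community
    model = fc.HurdleJSDM(survey, design, tree8, traits8, n_factors=0)
    return model.fit(fc.McmcConfig(n_chains=2, samples_per_chain=150, thin=2, burn_in=300, seed=5))


@pytest.fixture(scope="session")
def fit_report(fitted):
    return fc.explanatory_fit(fitted)


@pytest.fixture(scope="session")
def cube(fitted, env_small, community, fit_report):
    survey, _, _ = community
    return fc.project_cube(fitted, env_small, survey, fit_report.thresholds)


def make_posterior(
    beta, gamma=None, V=None, rho=None, Lambda=None, eta=None, alpha=None, sigma=None
):
    """Assemble a SubmodelPosterior from explicit draw arrays (tests only)."""
    beta = np.asarray(beta, dtype=float)
    c, n, p, S = beta.shape
    q = 0 if Lambda is None else np.asarray(Lambda).shape[-1]
    return SubmodelPosterior(
        beta=beta,
        gamma=np.zeros((c, n, p, 1)) if gamma is None else np.asarray(gamma, float),
        V=np.tile(np.eye(p), (c, n, 1, 1)) if V is None else np.asarray(V, float),
        rho=np.zeros((c, n)) if rho is None else np.asarray(rho, float),
        Lambda=np.zeros((c, n, S, q)) if Lambda is None else np.asarray(Lambda, float),
        eta=np.zeros((c, n, 0, q)) if eta is None else np.asarray(eta, float),
        alpha=np.zeros((c, n, q)) if alpha is None else np.asarray(alpha, float),
        sigma=sigma,
    )


@pytest.fixture()
def constant_beta_results(fitted):
    """Results whose occurrence/biomass posteriors are replaced by fixed draws."""

    def _make(beta_occ, beta_bio=None, sigma=None):
        model = fitted.model
        p = model.X.shape[1]
        S = len(model.species)
        occ = make_posterior(np.broadcast_to(beta_occ, (2, 5, p, S)).copy())
        posts = {"occurrence": occ}
        if beta_bio is not None:
            sig = np.ones((2, 5, S)) if sigma is None else np.broadcast_to(sigma, (2, 5, S)).copy()
            posts["biomass"] = make_posterior(
                np.broadcast_to(beta_bio, (2, 5, p, S)).copy(), sigma=sig
            )
        return fc.HurdleJSDMResults(model=model, config=fitted.config, posteriors=posts)

    return _make
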