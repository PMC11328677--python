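"""Shared fixtures: conjugate toy target, desk-scale recovery and two-group fits.

The expensive MCMC runs are session-scoped so that acceptance checks and
property tests share one fit instead of re-running it.
"""

import numpy as np
import pytest

from lbascale.cohort import PopulationConfig
from lbascale.pipeline import desk_settings, run_study1_config, run_study2
from lbascale.sampler import SamplerSettings, run_blocked_demcmc


class GaussianHierToy:
    """Hierarchical normal target with a closed-form posterior.

    theta_i ~ Normal(Mu, tau^2) with tau known; y_ij ~ Normal(theta_i, s^2)
    with s known; Mu ~ Normal(m0, s0^2).  Everything is conjugate, so the
    marginal posterior of Mu and of each theta_i is Gaussian and computable
    in closed form — an independent oracle for the DE-MCMC core.
    """

    def __init__(self, y, tau, s, m0, s0):
        self.y = [np.asarray(yi, float) for yi in y]
        self.tau, self.s, self.m0, self.s0 = tau, s, m0, s0
        self.n_participants = len(y)
        self.ind_dim = 1
        self.hyper_dim = 1
        self.out_names = ("theta",)
        self.out_free_mask = np.array([True])
        self.hyper_names = ("mu",)
        self.participant_ids = np.arange(len(y))
        self.ybar = np.array([yi.mean() for yi in self.y])
        self.ni = np.array([len(yi) for yi in self.y])

    # closed-form posterior -------------------------------------------------
    def mu_posterior(self):
        prec = 1 / self.s0**2 + (1 / (self.tau**2 + self.s**2 / self.ni)).sum()
        var = 1 / prec
        mean = var * (
            self.m0 / self.s0**2
            + (self.ybar / (self.tau**2 + self.s**2 / self.ni)).sum()
        )
        return mean, np.sqrt(var)

    def theta_posterior(self, i):
        mstar, sstar = self.mu_posterior()
        cv = 1 / (self.ni[i] / self.s**2 + 1 / self.tau**2)
        coef = cv / self.tau**2
        mean = cv * self.ni[i] * self.ybar[i] / self.s**2 + coef * mstar
        sd = np.sqrt(cv + coef**2 * sstar**2)
        return mean, sd

    # sampler interface -----------------------------------------------------
    def ind_loglik(self, i, x):
        th = x[:, 0]
        return -0.5 * ((self.y[i][None, :] - th[:, None]) ** 2).sum(1) / self.s**2

    def link_logpdf(self, x_all, h):
        mu = h[:, 0][:, None]
        return -0.5 * ((x_all[..., 0] - mu) / self.tau) ** 2 - np.log(self.tau)

    def link_logpdf_col(self, x, h):
        return -0.5 * ((x[:, 0] - h[:, 0]) / self.tau) ** 2 - np.log(self.tau)

    def hyper_logprior(self, h):
        return -0.5 * ((h[:, 0] - self.m0) / self.s0) ** 2

    @property
    def hyper_blocks(self):
        return [np.array([0])]

    def hyper_block_cond(self, bi, cols, x_all):
        mu = cols[:, 0][:, None]
        link = (-0.5 * ((x_all[..., 0] - mu) / self.tau) ** 2).sum(axis=1)
        return link + self.hyper_logprior(cols)

    def natural_output(self, x_all):
        return x_all.copy()

    def init(self, rng, m):
        x0 = self.ybar[None, :, None] + rng.normal(0, 0.5, (m, self.n_participants, 1))
        h0 = self.m0 + rng.normal(0, 0.5, (m, 1))
        return x0, h0


@pytest.fixture(scope="session")
def toy_run():
    """A seeded DE-MCMC run on the conjugate toy, with its closed-form oracle."""
    rng = np.random.default_rng(5)
    tau, s = 0.8, 1.0
    theta = rng.normal(1.0, tau, 2)
    y = [rng.normal(t, s, 20) for t in theta]
    toy = GaussianHierToy(y, tau=tau, s=s, m0=0.0, s0=2.0)
    settings = SamplerSettings(n_burn=500, n_samples=10000, thin=2, n_chains=8)
    draws = run_blocked_demcmc(toy, settings, seed=42)
    return toy, draws


#: the Study-1 configuration used for desk-scale recovery checks
DESK_CONFIG = PopulationConfig(
    means={"A": 2.0, "B": 2.5, "v_true": 2.5, "v_false": 0.8, "sv": 1.0},
    n_participants=20,
    n_trials=300,
)


@pytest.fixture(scope="session")
def study1_desk_fit():
    """One desk-scale recovery run (20 participants x 300 trials, new policy)."""
    return run_study1_config(
        DESK_CONFIG, "new", seed=123, settings=desk_settings(), fix_t0=True
    )


@pytest.fixture(scope="session")
def study2_desk_runs():
    """Three seeded desk-scale replicates of the two-group design, both policies."""
    return [
        run_study2(seed, n_per_group=15, n_trials=300, settings=desk_settings(), fix_t0=True)
        for seed in (101, 202, 303)
    ]
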