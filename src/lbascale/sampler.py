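"""Blocked differential-evolution MCMC for hierarchical models, plus convergence diagnostics.

The sampler runs many interacting chains (by convention three per free
parameter).  Each iteration updates one block per participant — that
participant's full parameter vector, conditional on the chain's current
hyper-parameters — and then the hyper state as per-parameter 2-d
(Mu_p, Sigma_p) blocks conditional on the individuals (the hierarchy
factorises over parameters, and several hyper sweeps run per iteration since
they cost no likelihood evaluations).  Proposals are differential-evolution
crossovers: x* = x + gamma (x_r1 - x_r2) + e with gamma = 2.38 / sqrt(2 d) and
small uniform jitter e; the chain-difference term self-scales to the target's
local geometry, which is what makes the near-degenerate Mu_sv support
sampleable without hand tuning.  An occasional migration step (cyclically
swapping block states among a random subset of chains, each swap accepted by
Metropolis) unsticks outlier chains during burn-in.

Convergence is assessed with the Gelman-Rubin potential scale reduction
factor (PSRF, R-hat), computed on the kept (post-thinning) draws without
chain splitting; R-hat < 1.1 is taken as converged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SamplerSettings",
    "PosteriorDraws",
    "run_mcmc",
    "run_blocked_demcmc",
    "psrf",
    "participant_convergence",
    "PSRF_THRESHOLD",
]

#: participants whose worst-case R-hat is at or above this are flagged unconverged
PSRF_THRESHOLD = 1.1


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration.

    Defaults follow the full-scale convention: 1,000 burn-in iterations,
    12,000 sampling iterations thinned by 12 (1,000 kept per chain), and
    3 chains per free parameter (``n_chains=None`` resolves at run time).
    """

    n_burn: int = 1000
    n_samples: int = 12000
    thin: int = 12
    n_chains: int | None = None  # None -> 3 x number of free parameters
    jitter: float = 1e-3
    p_migrate: float = 0.05
    migrate_burn_only: bool = True
    gamma_scale: float = 1.0
    mode_jump_prob: float = 0.1  # probability of a gamma = 1 proposal
    hyper_sweeps: int = 3  # hyper-block updates per iteration (they cost no likelihood)

    def __post_init__(self):
        if self.n_burn < 0 or self.n_samples < 1 or self.thin < 1:
            raise ValueError("invalid iteration counts")
        if self.n_samples % self.thin != 0:
            raise ValueError("thin must divide n_samples evenly")
        if self.n_chains is not None and self.n_chains < 4:
            raise ValueError("need at least 4 chains (PSRF requires multiple chains)")

    @property
    def n_kept(self) -> int:
        return self.n_samples // self.thin

    def resolve_chains(self, n_free: int) -> int:
        n = self.n_chains if self.n_chains is not None else 3 * n_free
        return max(n, 4)


@dataclass
class PosteriorDraws:
    """Kept posterior draws with chain structure, on the natural scale."""

    individual: np.ndarray  # (n_chains, n_kept, n_participants, n_out_params)
    hyper: np.ndarray  # (n_chains, n_kept, n_hyper)
    loglik: np.ndarray  # (n_chains, n_kept, n_participants) data log-likelihood
    ind_param_names: tuple
    hyper_names: tuple
    free_mask: np.ndarray  # which ind_param_names vary (non-fixed)
    participant_ids: np.ndarray
    accept_ind: float
    accept_hyper: float
    settings: SamplerSettings
    seed: int

    @property
    def n_chains(self) -> int:
        return self.individual.shape[0]

    def posterior_mean_individual(self) -> pd.DataFrame:
        """Posterior mean of each participant-level parameter, pooled over chains."""
        means = self.individual.mean(axis=(0, 1))  # (n_part, n_params)
        df = pd.DataFrame(means, columns=list(self.ind_param_names))
        df.insert(0, "participant", self.participant_ids)
        return df

    def hyper_mean(self) -> dict:
        means = self.hyper.mean(axis=(0, 1))
        return dict(zip(self.hyper_names, means))

    def to_long_dataframe(self) -> pd.DataFrame:
        """One row per (chain, iteration, participant, parameter) for persistence."""
        C, K, N, P = self.individual.shape
        chain, it, part, par = np.meshgrid(
            np.arange(C), np.arange(K), np.arange(N), np.arange(P), indexing="ij"
        )
        return pd.DataFrame(
            {
                "chain": chain.ravel(),
                "iteration": it.ravel(),
                "participant": self.participant_ids[part.ravel()],
                "parameter": np.asarray(self.ind_param_names)[par.ravel()],
                "value": self.individual.ravel(),
            }
        )


def _pairs(rng, m):
    """Random distinct pair indices (r1, r2), each distinct from the chain index."""
    idx = np.arange(m)
    r1 = rng.integers(0, m - 1, size=m)
    r1 += r1 >= idx
    r2 = rng.integers(0, m - 2, size=m)
    lo = np.minimum(idx, r1)
    hi = np.maximum(idx, r1)
    r2 += r2 >= lo
    r2 += r2 >= hi
    return r1, r2


def run_blocked_demcmc(target, settings: SamplerSettings, seed: int) -> PosteriorDraws:
    """Sample a hierarchical target with blocked DE-MCMC.

    ``target`` provides the blocked conditionals (see ``model.HierLBATarget``):
    ``ind_loglik(i, x)`` (hyper-independent participant terms),
    ``link_logpdf(x_all, h)`` / ``link_logpdf_col(x, h)`` (hierarchy densities),
    ``hyper_blocks`` / ``hyper_block_cond(bi, cols, x)`` (factorised hyper
    conditionals), ``hyper_logprior(h)``, ``init(rng, m)``, plus dimensions
    and output naming.
    """
    rng = np.random.default_rng(seed)
    m = settings.resolve_chains(target.ind_dim)
    n_part = target.n_participants
    d_ind = target.ind_dim
    d_hyp = target.hyper_dim
    gamma_ind = settings.gamma_scale * 2.38 / np.sqrt(2.0 * d_ind)
    hyper_blocks = target.hyper_blocks

    # --- initialise, re-jittering chains stuck at non-finite posterior ------
    for attempt in range(20):
        x, h = target.init(rng, m)
        ind_ll = np.column_stack([target.ind_loglik(i, x[:, i]) for i in range(n_part)])
        link = target.link_logpdf(x, h)
        hp = target.hyper_logprior(h)
        ok = (
            np.isfinite(ind_ll).all()
            and np.isfinite(link).all()
            and np.isfinite(hp).all()
            and (ind_ll > -1e9).all()
        )
        if ok:
            break
    else:
        raise RuntimeError(
            "sampler initialisation failed: non-finite posterior after 20 re-jitters"
        )

    n_iter = settings.n_burn + settings.n_samples
    n_kept = settings.n_kept
    out_dim = len(target.out_names)
    keep_ind = np.empty((m, n_kept, n_part, out_dim))
    keep_hyp = np.empty((m, n_kept, d_hyp))
    keep_ll = np.empty((m, n_kept, n_part))

    acc_ind = prop_ind = acc_hyp = prop_hyp = 0
    k = 0
    for it in range(n_iter):
        in_burn = it < settings.n_burn
        migrate_ok = in_burn or not settings.migrate_burn_only

        # ---- participant blocks -----------------------------------------
        for i in range(n_part):
            xi = x[:, i]
            if migrate_ok and rng.uniform() < settings.p_migrate:
                _migrate_ind(target, rng, m, i, x, h, ind_ll, link)
                continue
            r1, r2 = _pairs(rng, m)
            gamma = gamma_ind if rng.uniform() >= settings.mode_jump_prob else 1.0
            prop = xi + gamma * (xi[r1] - xi[r2]) + rng.uniform(
                -settings.jitter, settings.jitter, size=(m, d_ind)
            )
            new_ll = target.ind_loglik(i, prop)
            new_link = target.link_logpdf_col(prop, h)
            with np.errstate(invalid="ignore"):
                logr = (new_ll + new_link) - (ind_ll[:, i] + link[:, i])
            accept = np.log(rng.uniform(size=m)) < logr
            if accept.any():
                x[accept, i] = prop[accept]
                ind_ll[accept, i] = new_ll[accept]
                link[accept, i] = new_link[accept]
            if not in_burn:
                acc_ind += int(accept.sum())
                prop_ind += m

        # ---- hyper blocks (one 2-d (Mu_p, Sigma_p) block per parameter).
        # These cost no likelihood evaluations, so several sweeps per
        # iteration keep the (tight) hyper conditionals mixing in step with
        # the individual blocks.
        conds = [target.hyper_block_cond(bi, h[:, idx], x)
                 for bi, idx in enumerate(hyper_blocks)]
        for _ in range(settings.hyper_sweeps):
            acc = _update_hyper_blocks(target, rng, m, x, h, hyper_blocks, conds, settings)
            if not in_burn:
                acc_hyp += acc
                prop_hyp += m * len(hyper_blocks)
        # refresh the cached hierarchy densities under the updated hyper state
        link = target.link_logpdf(x, h)

        # ---- record ------------------------------------------------------
        if not in_burn and (it - settings.n_burn) % settings.thin == settings.thin - 1:
            keep_ind[:, k] = target.natural_output(x)
            keep_hyp[:, k] = h
            keep_ll[:, k] = ind_ll
            k += 1

    assert k == n_kept
    return PosteriorDraws(
        individual=keep_ind,
        hyper=keep_hyp,
        loglik=keep_ll,
        ind_param_names=tuple(target.out_names),
        hyper_names=tuple(target.hyper_names),
        free_mask=np.asarray(target.out_free_mask),
        participant_ids=np.asarray(target.participant_ids),
        accept_ind=acc_ind / max(prop_ind, 1),
        accept_hyper=acc_hyp / max(prop_hyp, 1),
        settings=settings,
        seed=seed,
    )


def _update_hyper_blocks(target, rng, m, x, h, hyper_blocks, conds, settings) -> int:
    """One DE sweep over all hyper blocks, in place; returns accepted count.

    ``conds`` caches each block's current conditional (valid while the
    individual states are unchanged) and is updated on acceptance.
    """
    accepted = 0
    for bi, idx in enumerate(hyper_blocks):
        cols = h[:, idx]
        cond_old = conds[bi]
        r1, r2 = _pairs(rng, m)
        gamma = (
            settings.gamma_scale * 2.38 / np.sqrt(2.0 * len(idx))
            if rng.uniform() >= settings.mode_jump_prob
            else 1.0
        )
        prop = cols + gamma * (cols[r1] - cols[r2]) + rng.uniform(
            -settings.jitter, settings.jitter, size=cols.shape
        )
        cond_new = target.hyper_block_cond(bi, prop, x)
        with np.errstate(invalid="ignore"):
            logr = cond_new - cond_old
        accept = np.log(rng.uniform(size=m)) < logr
        if accept.any():
            h[np.ix_(np.flatnonzero(accept), idx)] = prop[accept]
            conds[bi] = np.where(accept, cond_new, cond_old)
        accepted += int(accept.sum())
    return accepted


def _migrate_ind(target, rng, m, i, x, h, ind_ll, link):
    """Cyclic migration of participant i's states among a random chain subset."""
    k = int(rng.integers(1, m + 1))
    subset = rng.permutation(m)[:k]
    src = np.roll(subset, 1)  # chain subset[j] receives state from src[j]
    prop = x[src, i]
    new_ll = ind_ll[src, i]  # data term is chain-independent
    new_link = target.link_logpdf_col(prop, h[subset])
    with np.errstate(invalid="ignore"):
        logr = (new_ll + new_link) - (ind_ll[subset, i] + link[subset, i])
    accept = np.log(rng.uniform(size=k)) < logr
    tgt = subset[accept]
    x[tgt, i] = prop[accept]
    ind_ll[tgt, i] = new_ll[accept]
    link[tgt, i] = new_link[accept]


def run_mcmc(data, spec, settings: SamplerSettings, seed: int) -> PosteriorDraws:
    """Fit the hierarchical LBA defined by ``spec`` to a trial table.

    Thin wrapper: builds the blocked-conditional target from the model spec
    and the data, then runs the DE-MCMC core.  Reproducible given ``seed``.
    """
    from .model import HierLBATarget

    if len(data) == 0:
        raise ValueError("data is empty")
    target = HierLBATarget(data, spec)
    return run_blocked_demcmc(target, settings, seed)


def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist posterior draws (and run metadata) to an .npz archive."""
    np.savez_compressed(
        path,
        individual=draws.individual,
        hyper=draws.hyper,
        loglik=draws.loglik,
        ind_param_names=np.asarray(draws.ind_param_names),
        hyper_names=np.asarray(draws.hyper_names),
        free_mask=draws.free_mask,
        participant_ids=draws.participant_ids,
        accept=np.array([draws.accept_ind, draws.accept_hyper]),
        settings=np.array(
            [draws.settings.n_burn, draws.settings.n_samples, draws.settings.thin,
             draws.individual.shape[0]]
        ),
        seed=np.array([draws.seed]),
    )


def load_draws(path) -> PosteriorDraws:
    """Load posterior draws saved with ``save_draws``."""
    z = np.load(path, allow_pickle=False)
    n_burn, n_samples, thin, n_chains = (int(v) for v in z["settings"])
    return PosteriorDraws(
        individual=z["individual"],
        hyper=z["hyper"],
        loglik=z["loglik"],
        ind_param_names=tuple(str(s) for s in z["ind_param_names"]),
        hyper_names=tuple(str(s) for s in z["hyper_names"]),
        free_mask=z["free_mask"],
        participant_ids=z["participant_ids"],
        accept_ind=float(z["accept"][0]),
        accept_hyper=float(z["accept"][1]),
        settings=SamplerSettings(
            n_burn=n_burn, n_samples=n_samples, thin=thin, n_chains=n_chains
        ),
        seed=int(z["seed"][0]),
    )


def psrf(chains) -> float:
    """Gelman-Rubin potential scale reduction factor of one scalar quantity.

    ``chains`` has shape (n_chains, n_iterations).  R-hat =
    sqrt( ((n-1)/n W + B/n) / W ) with W the mean within-chain variance and
    B/n the variance of the chain means.  Zero within-chain variance with
    spread chains yields +inf (with a warning); fully constant chains count
    as converged only in the degenerate all-identical case, which also
    returns +inf here since no mixing information exists.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("psrf needs a (n_chains >= 2, n_iterations) matrix")
    n = chains.shape[1]
    if n < 2:
        raise ValueError("psrf needs at least 2 iterations per chain")
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = chains.mean(axis=1).var(ddof=1)
    if W == 0.0:
        warnings.warn("zero within-chain variance; PSRF undefined, returning inf")
        return np.inf
    return float(np.sqrt(((n - 1) / n * W + B_over_n) / W))


def participant_convergence(draws: PosteriorDraws, threshold: float = PSRF_THRESHOLD) -> pd.DataFrame:
    """Worst-case R-hat per participant over their free parameters.

    Returns a DataFrame with columns participant, max_psrf, converged
    (converged iff max R-hat < ``threshold``, 1.1 by default).
    """
    free_idx = np.flatnonzero(draws.free_mask)
    rows = []
    for j, pid in enumerate(draws.participant_ids):
        worst = max(
            psrf(draws.individual[:, :, j, p]) for p in free_idx
        )
        rows.append({"participant": pid, "max_psrf": worst, "converged": worst < threshold})
    return pd.DataFrame(rows)
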