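"""Hierarchical Bayesian LBA with two scale-setting policies.

Latent evidence units are undefined unless one parameter is constrained.  The
*classic* policy fixes sv = 1 for every participant, assuming away individual
differences in drift-rate variability.  The *new* policy instead constrains the
population mean of sv: its hyper-level Mu prior is a Beta(1, 1) density — i.e.
uniform — remapped to the near-degenerate interval [0.999, 1.001].  This de
facto fixes the population-mean sv at about 1 (one unit of evidence equals the
population-level sv) while leaving each participant's sv free to vary.

Model structure
---------------
individual p_i ~ Normal(Mu_p, Sigma_p) truncated below at 0, per parameter,
multiplied by a base-level prior TN(prior mean, generating SD) per
participant (the base priors anchor each participant's absolute evidence
scale, which the likelihood alone cannot identify);
Mu_p ~ Normal(prior mean, 1) truncated below at 0 (non-sv parameters);
Mu_sv ~ Uniform(0.999, 1.001)          (new policy only);
Sigma_p ~ Uniform(0, 3)                (Beta(1,1) remapped to [0, 3]).

The boundary is parameterised through the gap B (b = A + B), so b > A holds by
construction.  Strictly positive parameters (A, B, sv, t0) are sampled on the
log scale; the hierarchy itself lives on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from scipy.stats import beta as beta_dist

from .lba import LOGLIK_FLOOR, dataset_loglik

__all__ = [
    "ScaledBetaPrior",
    "TruncNormalPrior",
    "HyperParams",
    "ModelSpec",
    "build_model",
    "noisy_prior_means_study1",
    "noisy_prior_means_study2",
    "log_posterior",
    "HierLBATarget",
    "SV_SCALE_LO",
    "SV_SCALE_HI",
]

_LOG_SQRT2PI = 0.5 * np.log(2.0 * np.pi)

#: support of the near-degenerate uniform hyper-prior on the population-mean sv
SV_SCALE_LO, SV_SCALE_HI = 0.999, 1.001

#: support of the uninformative population-SD prior
SIGMA_LO, SIGMA_HI = 0.0, 3.0

#: canonical ordering of potentially-free model parameters
ALL_PARAMS = ("A", "B", "v_true", "v_false", "sv", "t0")

#: parameters sampled on the log scale (strictly positive domain)
LOG_SCALE = {"A": True, "B": True, "v_true": False, "v_false": False, "sv": True, "t0": True}


@dataclass(frozen=True)
class ScaledBetaPrior:
    """Beta(alpha, beta) density affinely remapped from [0, 1] to [lo, hi].

    With alpha = beta = 1 this is the uniform density on [lo, hi].
    """

    alpha: float
    beta: float
    lo: float
    hi: float

    def __post_init__(self):
        if not (self.hi > self.lo):
            raise ValueError("hi must exceed lo")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        u = (x - self.lo) / (self.hi - self.lo)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = beta_dist.logpdf(u, self.alpha, self.beta) - np.log(self.hi - self.lo)
        return np.where((x >= self.lo) & (x <= self.hi), lp, -np.inf)

    def rvs(self, rng, size=None):
        return self.lo + (self.hi - self.lo) * rng.beta(self.alpha, self.beta, size=size)


@dataclass(frozen=True)
class TruncNormalPrior:
    """Normal(mean, sd) truncated below at ``lower`` (default 0)."""

    mean: float
    sd: float
    lower: float = 0.0

    def logpdf(self, x):
        return trunc_normal_logpdf(x, self.mean, self.sd, self.lower)

    def rvs(self, rng, size=None):
        out = rng.normal(self.mean, self.sd, size=size)
        while np.any(out <= self.lower):
            bad = out <= self.lower
            out = np.where(bad, rng.normal(self.mean, self.sd, size=size), out)
        return out


def trunc_normal_logpdf(x, mu, sigma, lower=0.0):
    """Log density of Normal(mu, sigma) truncated below at ``lower``.

    The normaliser 1 - Phi((lower - mu)/sigma) is kept explicitly: it depends
    on (mu, sigma) and therefore matters for hyper-parameter updates.
    """
    x, mu, sigma = np.broadcast_arrays(
        np.asarray(x, float), np.asarray(mu, float), np.asarray(sigma, float)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mu) / sigma
        norm = np.maximum(ndtr((mu - lower) / sigma), 1e-300)
        lp = -0.5 * z * z - np.log(sigma) - _LOG_SQRT2PI - np.log(norm)
    lp = np.where((x > lower) & (sigma > 0), lp, -np.inf)
    return lp if lp.ndim else float(lp)


@dataclass(frozen=True)
class HyperParams:
    """Population-level mean (Mu) and SD (Sigma) per free parameter."""

    mu: dict
    sigma: dict

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("all Sigma values must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Full specification of one hierarchical LBA fit.

    ``base_priors`` are the individual-level ("base-level") priors: genuine
    per-participant densities at the participant level, alongside the
    population link.  They anchor each participant's absolute evidence scale,
    which the likelihood alone leaves free (it is invariant under jointly
    rescaling A, B, the drift means and sv).
    """

    method: str  # "new" or "classic"
    free_parameters: tuple
    mu_priors: dict  # name -> prior object with .logpdf/.rvs
    sigma_priors: dict  # name -> ScaledBetaPrior
    base_priors: dict = field(default_factory=dict)  # name -> TruncNormalPrior
    sv_fixed_value: float = 1.0  # classic policy only
    t0_fixed_value: float | None = None  # set when t0 is held constant

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)


#: default SDs of the individual-level (base) priors: the generating
#: population SDs — the spread a researcher planning this design assumes.
DEFAULT_BASE_PRIOR_SDS = {
    "A": 0.6, "B": 0.6, "v_true": 0.8, "v_false": 0.8, "sv": 0.4, "t0": 0.1,
}


def build_model(
    method: str,
    prior_means: dict,
    config=None,
    *,
    fix_t0: bool = False,
    t0_value: float = 0.3,
    mu_prior_sd: float = 1.0,
    base_prior_sds: dict | None = None,
) -> ModelSpec:
    """Build a ModelSpec under the requested scale-setting policy.

    ``prior_means`` supplies the centres of the (truncated normal) Mu priors
    and of the individual-level base priors for every non-sv free parameter
    (the sv base prior is centred at the scale value 1).  Under
    ``method="new"`` sv is free with Mu_sv ~ Uniform(0.999, 1.001); under
    ``method="classic"`` sv is fixed at 1 for every participant and excluded
    from the free parameters.
    """
    if method not in ("new", "classic"):
        raise ValueError(f"unknown method {method!r}; expected 'new' or 'classic'")
    sds = {**DEFAULT_BASE_PRIOR_SDS, **(base_prior_sds or {})}
    free = [p for p in ALL_PARAMS if p != "sv" or method == "new"]
    if fix_t0:
        free = [p for p in free if p != "t0"]
    mu_priors = {}
    base_priors = {}
    for p in free:
        if p == "sv":
            mu_priors[p] = ScaledBetaPrior(1.0, 1.0, SV_SCALE_LO, SV_SCALE_HI)
            base_priors[p] = TruncNormalPrior(1.0, sds[p])
        else:
            if p not in prior_means:
                raise ValueError(f"prior_means is missing free parameter {p!r}")
            mu_priors[p] = TruncNormalPrior(prior_means[p], mu_prior_sd)
            base_priors[p] = TruncNormalPrior(prior_means[p], sds[p])
    sigma_priors = {p: ScaledBetaPrior(1.0, 1.0, SIGMA_LO, SIGMA_HI) for p in free}
    return ModelSpec(
        method=method,
        free_parameters=tuple(free),
        mu_priors=mu_priors,
        sigma_priors=sigma_priors,
        base_priors=base_priors,
        t0_fixed_value=t0_value if fix_t0 else None,
    )


def noisy_prior_means_study1(true_means: dict, seed: int, sd: float = 0.1) -> dict:
    """Perturb each non-sv generating mean by an independent Normal(0, sd) draw."""
    rng = np.random.default_rng(seed)
    return {
        name: (mu if name == "sv" else mu + rng.normal(0.0, sd))
        for name, mu in true_means.items()
    }


def noisy_prior_means_study2(true_means: dict, sds: dict, n: int, seed: int) -> dict:
    """Draw each non-sv prior mean uniformly within +/- 2 standard errors of truth.

    SE = generating sd / sqrt(n); parameters without a generating SD (e.g. the
    constant t0) get SE = 0 and are returned exactly.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    out = {}
    for name, mu in true_means.items():
        if name == "sv":
            out[name] = mu
            continue
        se = sds.get(name, 0.0) / np.sqrt(n)
        out[name] = rng.uniform(mu - 2 * se, mu + 2 * se) if se > 0 else mu
    return out


# ---------------------------------------------------------------------------
# joint log posterior (reference implementation; the sampler uses HierLBATarget)
# ---------------------------------------------------------------------------

def log_posterior(ind_params, hyper: HyperParams, data, spec: ModelSpec) -> float:
    """Joint log posterior density (up to a constant) of a full parameter state.

    ``ind_params`` is a DataFrame (one row per participant, columns at least
    the free parameters plus whatever is fixed) on the natural scale; ``data``
    a trial table with participant_id/choice/rt columns.  Returns -inf outside
    the prior support.
    """
    total = 0.0
    for p in spec.free_parameters:
        mu, sig = hyper.mu[p], hyper.sigma[p]
        lp_mu = float(np.asarray(spec.mu_priors[p].logpdf(mu)))
        lp_sig = float(np.asarray(spec.sigma_priors[p].logpdf(sig)))
        if not np.isfinite(lp_mu + lp_sig):
            return -np.inf
        total += lp_mu + lp_sig
        vals = ind_params[p].to_numpy()
        link = trunc_normal_logpdf(vals, mu, sig)
        base = np.asarray(spec.base_priors[p].logpdf(vals)) if spec.base_priors else 0.0
        if not (np.all(np.isfinite(link)) and np.all(np.isfinite(base))):
            return -np.inf
        total += float(np.sum(link)) + float(np.sum(base))
    for pid, sub in data.groupby("participant_id", sort=True):
        row = ind_params.iloc[int(pid)]
        sv = row["sv"] if spec.method == "new" else spec.sv_fixed_value
        t0 = row["t0"] if spec.t0_fixed_value is None else spec.t0_fixed_value
        total += float(
            dataset_loglik(
                sub["rt"].to_numpy(),
                sub["choice"].to_numpy() == "true",
                row["A"],
                row["B"] if "B" in row else row["b"] - row["A"],
                row["v_true"],
                row["v_false"],
                sv,
                t0,
            )
        )
    return total


# ---------------------------------------------------------------------------
# sampling target: blocked conditionals on the sampling (partially log) scale
# ---------------------------------------------------------------------------

class HierLBATarget:
    """Blocked-conditional interface of the hierarchical LBA for DE-MCMC.

    State layout per chain: one row of length ``n_free`` per participant on
    the sampling scale (log for A, B, sv, t0; natural for drift means), plus a
    hyper vector ``[Mu_1..Mu_k, Sigma_1..Sigma_k]`` on the natural scale.
    """

    def __init__(self, data, spec: ModelSpec):
        self.spec = spec
        self.free = spec.free_parameters
        self.ind_dim = len(self.free)
        self.hyper_dim = 2 * self.ind_dim
        self._log_mask = np.array([LOG_SCALE[p] for p in self.free])
        self._sv_idx = self.free.index("sv") if "sv" in self.free else None
        self._t0_idx = self.free.index("t0") if "t0" in self.free else None

        pids = np.sort(data["participant_id"].unique())
        self.participant_ids = pids
        self.n_participants = len(pids)
        self._rt = []
        self._is_true = []
        for pid in pids:
            sub = data[data["participant_id"] == pid]
            self._rt.append(sub["rt"].to_numpy(dtype=float))
            self._is_true.append(sub["choice"].to_numpy() == "true")

        self.hyper_names = tuple(f"mu_{p}" for p in self.free) + tuple(
            f"sigma_{p}" for p in self.free
        )
        # natural-scale output columns (b derived from A + B; fixed values filled in)
        self.out_names = ("A", "b", "v_true", "v_false", "sv", "t0")
        self.out_free_mask = np.array(
            [
                name in ("A", "b")  # both derive from free A, B
                or name in self.free
                for name in self.out_names
            ]
        )

    # -- scale transforms ---------------------------------------------------

    def to_sampling(self, nat):
        nat = np.asarray(nat, dtype=float)
        return np.where(self._log_mask, np.log(np.maximum(nat, 1e-12)), nat)

    def to_natural(self, x):
        return np.where(self._log_mask, np.exp(x), x)

    def natural_output(self, x_all):
        """Map sampling-scale state (m, n_part, d) to output columns (m, n_part, 6)."""
        nat = np.where(self._log_mask, np.exp(x_all), x_all)
        cols = {}
        for j, p in enumerate(self.free):
            cols[p] = nat[..., j]
        shape = x_all.shape[:-1]
        A = cols["A"]
        out = np.empty(shape + (6,))
        out[..., 0] = A
        out[..., 1] = A + cols["B"]
        out[..., 2] = cols["v_true"]
        out[..., 3] = cols["v_false"]
        out[..., 4] = cols["sv"] if self._sv_idx is not None else self.spec.sv_fixed_value
        out[..., 5] = cols["t0"] if self._t0_idx is not None else self.spec.t0_fixed_value
        return out

    # -- conditionals -------------------------------------------------------

    def ind_loglik(self, i, x):
        """Hyper-independent terms of participant i's conditional at states x (m, d):
        data log-likelihood plus the individual-level base-prior densities."""
        nat = self.to_natural(x)
        cols = {p: nat[:, j] for j, p in enumerate(self.free)}
        sv = cols["sv"] if self._sv_idx is not None else np.full(len(x), self.spec.sv_fixed_value)
        t0 = cols["t0"] if self._t0_idx is not None else np.full(len(x), self.spec.t0_fixed_value)
        ll = dataset_loglik(
            self._rt[i], self._is_true[i],
            cols["A"], cols["B"], cols["v_true"], cols["v_false"], sv, t0,
        )
        base = np.zeros_like(ll)
        for j, p in enumerate(self.free):
            base += np.asarray(self.spec.base_priors[p].logpdf(nat[:, j]))
        with np.errstate(invalid="ignore"):
            out = ll + base
        return np.where(np.isfinite(base), out, LOGLIK_FLOOR)

    def _link_core(self, nat, x, mu, sigma):
        """Truncated-normal link + log-scale Jacobian; inputs broadcast over (..., d)."""
        lp = trunc_normal_logpdf(nat, mu, sigma)
        jac = np.where(self._log_mask, x, 0.0)
        with np.errstate(invalid="ignore"):
            out = lp + jac
        return np.where(np.isfinite(lp), out, -np.inf).sum(axis=-1)

    def link_logpdf(self, x_all, hyper):
        """Hierarchy density of all participants: (m, n_part, d), (m, 2d) -> (m, n_part)."""
        nat = np.where(self._log_mask, np.exp(x_all), x_all)
        mu = hyper[:, None, : self.ind_dim]
        sigma = hyper[:, None, self.ind_dim :]
        return self._link_core(nat, x_all, mu, sigma)

    def link_logpdf_col(self, x, hyper):
        """Hierarchy density of one participant: (m, d), (m, 2d) -> (m,)."""
        nat = self.to_natural(x)
        return self._link_core(nat, x, hyper[:, : self.ind_dim], hyper[:, self.ind_dim :])

    def hyper_logprior(self, hyper):
        """Log hyper-prior density at (m, 2d) natural-scale hyper states."""
        m = hyper.shape[0]
        out = np.zeros(m)
        for j, p in enumerate(self.free):
            out += np.asarray(self.spec.mu_priors[p].logpdf(hyper[:, j]))
            out += np.asarray(self.spec.sigma_priors[p].logpdf(hyper[:, self.ind_dim + j]))
        return out

    # -- per-parameter hyper blocks -----------------------------------------
    # The hierarchy factorises over parameters, so (Mu_p, Sigma_p) pairs form
    # independent 2-d blocks with conditionals that touch only column p.

    @property
    def hyper_blocks(self):
        return [np.array([j, self.ind_dim + j]) for j in range(self.ind_dim)]

    def hyper_block_cond(self, bi, cols, x_all):
        """Conditional of block bi (Mu_p, Sigma_p at ``cols`` (m, 2)) given x.

        Sum over participants of the truncated-normal link for parameter p,
        plus that parameter's Mu and Sigma prior densities.  The log-scale
        Jacobian is hyper-independent and omitted.
        """
        p = self.free[bi]
        nat = np.exp(x_all[..., bi]) if self._log_mask[bi] else x_all[..., bi]  # (m, n_part)
        mu, sigma = cols[:, 0][:, None], cols[:, 1][:, None]
        lp = trunc_normal_logpdf(nat, mu, sigma)  # (m, n_part)
        with np.errstate(invalid="ignore"):
            out = lp.sum(axis=1)
        out = np.where(np.isfinite(lp).all(axis=1), out, -np.inf)
        out = out + np.asarray(self.spec.mu_priors[p].logpdf(cols[:, 0]))
        out = out + np.asarray(self.spec.sigma_priors[p].logpdf(cols[:, 1]))
        return out

    # -- initialisation -----------------------------------------------------

    def init(self, rng, n_chains):
        """Initial states: individuals at prior means + jitter; Mu at prior means;
        Sigma at 0.5 with multiplicative jitter."""
        centers = []
        for p in self.free:
            if p == "sv":
                centers.append(1.0)
            else:
                centers.append(self.spec.mu_priors[p].mean)
        centers = np.asarray(centers)
        x0 = np.empty((n_chains, self.n_participants, self.ind_dim))
        h0 = np.empty((n_chains, self.hyper_dim))
        for c in range(n_chains):
            base = self.to_sampling(centers)
            x0[c] = base[None, :] + rng.normal(0.0, 0.1, size=(self.n_participants, self.ind_dim))
            for j, p in enumerate(self.free):
                if p == "sv":
                    h0[c, j] = self.spec.mu_priors[p].rvs(rng)
                else:
                    h0[c, j] = max(centers[j] * (1.0 + rng.normal(0.0, 0.05)), 1e-3)
                h0[c, self.ind_dim + j] = 0.5 * np.exp(rng.normal(0.0, 0.2))
        return x0, h0
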