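"""End-to-end recipes: simulate a cohort, fit it, score recovery, compare methods.

Two scale presets are provided.  ``full`` mirrors the original study
conditions (100 participants, 1,000 trials, burn-in 1,000, 12,000 samples
thinned by 12) and takes hours per fit on one CPU.  ``desk`` is a scaled-down
preset (20 participants, 300 trials, burn-in 500, 3,000 samples thinned by 3)
that keeps the qualitative recovery pattern demonstrable within minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    DEFAULT_SDS,
    PopulationConfig,
    draw_individual_params,
    simulate_dataset,
    study1_grid,
    study2_config,
)
from .metrics import (
    MethodComparison,
    RecoveryReport,
    dic,
    group_ttest,
    recovery_report,
)
from .model import (
    ModelSpec,
    build_model,
    noisy_prior_means_study1,
    noisy_prior_means_study2,
)
from .sampler import (
    PosteriorDraws,
    SamplerSettings,
    participant_convergence,
    run_mcmc,
)

__all__ = [
    "SCALE_PRESETS",
    "desk_settings",
    "full_settings",
    "Study1Result",
    "Study2Result",
    "run_study1_config",
    "run_study2",
    "subseeds",
]

#: (n_participants, n_trials, SamplerSettings, t0 policy) per scale preset.
#: Desk runs fix t0 at its generating constant: t0 recovery is never scored,
#: and freeing it adds a funnel-shaped hyper dimension (its population SD
#: collapses) that short desk chains cannot traverse reliably.
SCALE_PRESETS = {
    "full": dict(n_participants=100, n_trials=1000, fix_t0=False,
                 settings=dict(n_burn=1000, n_samples=12000, thin=12)),
    "desk": dict(n_participants=20, n_trials=300, fix_t0=True,
                 settings=dict(n_burn=500, n_samples=3000, thin=3)),
}


def full_settings() -> SamplerSettings:
    return SamplerSettings(**SCALE_PRESETS["full"]["settings"])


def desk_settings() -> SamplerSettings:
    return SamplerSettings(**SCALE_PRESETS["desk"]["settings"])


def subseeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit integer seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint32)]


@dataclass
class Study1Result:
    """One simulated dataset fitted with one scale-setting policy, scored."""

    cohort: Cohort
    data: pd.DataFrame
    spec: ModelSpec
    draws: PosteriorDraws
    convergence: pd.DataFrame
    report: RecoveryReport


def run_study1_config(
    config: PopulationConfig,
    method: str,
    seed: int,
    settings: SamplerSettings | None = None,
    *,
    prior_noise_sd: float = 0.1,
    fix_t0: bool = False,
) -> Study1Result:
    """Simulate one population configuration and recover its parameters.

    Prior means are the generating means perturbed by Normal(0, 0.1) noise
    (realistically "in the neighbourhood" of the truth).  All randomness
    derives from ``seed``.  With ``fix_t0`` the non-decision time is held at
    its generating constant instead of estimated (the desk-scale default).
    """
    settings = settings or full_settings()
    s_cohort, s_data, s_prior, s_mcmc = subseeds(seed, 4)
    cohort = draw_individual_params(config, s_cohort)
    if method == "classic":
        # generation-matched classic recovery: sv IS the fixed scale, so the
        # generating cohort has sv = 1 for every participant (the fixed-sv
        # model cannot be a recovery target for heterogeneous sv)
        cohort.true_params["sv"] = 1.0
    data = simulate_dataset(cohort, s_data)
    true_means = {**config.means, "t0": config.t0_fixed}
    prior_means = noisy_prior_means_study1(true_means, s_prior, sd=prior_noise_sd)
    spec = build_model(method, prior_means, fix_t0=fix_t0, t0_value=config.t0_fixed)
    draws = run_mcmc(data, spec, settings, s_mcmc)
    conv = participant_convergence(draws)
    report = recovery_report(cohort.true_params, draws)
    return Study1Result(cohort, data, spec, draws, conv, report)


@dataclass
class Study2Result:
    """Two-group design fitted under both policies, with DIC and group tests."""

    cohort: Cohort
    data: pd.DataFrame
    fits: dict  # method -> Study1Result-like per-method results
    comparison: MethodComparison


#: parameters tested for group differences (sv only exists under the new policy)
GROUP_TEST_PARAMS = ("A", "b", "v_true", "v_false", "sv")


def run_study2(
    seed: int,
    n_per_group: int = 50,
    n_trials: int = 1000,
    settings: SamplerSettings | None = None,
    methods=("new", "classic"),
    *,
    fix_t0: bool = False,
) -> Study2Result:
    """Run the two-group discrimination design end to end.

    Groups differ only in the sv generating mean (1.5 vs 0.5).  Prior means
    are drawn uniformly within two standard errors (SE = generating SD /
    sqrt(group n)) of the shared true means.  Each requested policy is fitted
    to the same trial table; group t-tests are computed per policy on the
    PSRF-retained participants, and DIC is compared on the participants
    retained under both policies.
    """
    settings = settings or full_settings()
    s_cohort, s_data, s_prior, s_new, s_classic = subseeds(seed, 5)
    config = study2_config(n_per_group, n_trials)
    cohort = draw_individual_params(config, s_cohort)
    data = simulate_dataset(cohort, s_data)
    true_means = {**config.means, "t0": config.t0_fixed}
    prior_means = noisy_prior_means_study2(true_means, DEFAULT_SDS, n_per_group, s_prior)

    groups = cohort.true_params.set_index("participant")["group"]
    fits = {}
    dic_per = {}
    dic_total = {}
    ttests = {}
    mcmc_seeds = {"new": s_new, "classic": s_classic}
    for method in methods:
        spec = build_model(method, prior_means, fix_t0=fix_t0, t0_value=config.t0_fixed)
        draws = run_mcmc(data, spec, settings, mcmc_seeds[method])
        conv = participant_convergence(draws)
        report = recovery_report(cohort.true_params, draws)
        fits[method] = Study1Result(cohort, data, spec, draws, conv, report)
        per, _total = dic(draws, data)
        dic_per[method] = per

        retained = conv.loc[conv["converged"], "participant"]
        est = draws.posterior_mean_individual()
        est = est[est["participant"].isin(retained)]
        names = list(draws.ind_param_names)
        ttests[method] = {}
        for p in GROUP_TEST_PARAMS:
            if p not in names or not draws.free_mask[names.index(p)]:
                continue
            ttests[method][p] = group_ttest(
                est[p].to_numpy(), groups.loc[est["participant"]].to_numpy()
            )

    if set(methods) >= {"new", "classic"}:
        common = set(
            fits["new"].convergence.loc[fits["new"].convergence["converged"], "participant"]
        ) & set(
            fits["classic"].convergence.loc[
                fits["classic"].convergence["converged"], "participant"
            ]
        )
        merged = dic_per["new"].merge(
            dic_per["classic"], on="participant", suffixes=("_new", "_classic")
        )
        merged = merged[merged["participant"].isin(common)]
        frac = float((merged["dic_new"] < merged["dic_classic"]).mean())
        dic_total = {
            "new": float(merged["dic_new"].sum()),
            "classic": float(merged["dic_classic"].sum()),
        }
    else:
        frac = np.nan
        dic_total = {m: float(dic_per[m]["dic"].sum()) for m in methods}

    comparison = MethodComparison(
        dic_per_participant=dic_per,
        dic_total=dic_total,
        fraction_new_better=frac,
        ttests=ttests,
    )
    return Study2Result(cohort, data, fits, comparison)
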