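"""Parameter-recovery scoring and method comparison.

Recovery of individual parameters is scored against the generating ("true")
values with the Pearson correlation (stability of relative standing) and the
intraclass correlation ICC(2,1) — two-way random effects, single measure,
absolute agreement (Shrout & Fleiss) — which additionally penalises
systematic shifts.  Per-configuration correlations are averaged through
Fisher's Z transform.  Participants whose worst-case R-hat is >= 1.1 are
excluded before any statistic is computed.  Model fit is compared with the
deviance information criterion (DIC = mean deviance + effective number of
parameters), and group differences in posterior-mean parameters with
pooled-variance two-sample t-tests (df = n1 + n2 - 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lba import dataset_loglik
from .sampler import PSRF_THRESHOLD, PosteriorDraws, participant_convergence

__all__ = [
    "RecoveryReport",
    "MethodComparison",
    "pearson_recovery",
    "icc_2_1",
    "fisher_z_mean",
    "filter_by_psrf",
    "dic",
    "group_ttest",
    "recovery_report",
    "RECOVERY_PARAMS",
]

#: parameters whose recovery is scored (t0 is generated as a constant and not scored)
RECOVERY_PARAMS = ("A", "b", "v_true", "v_false", "sv")


def pearson_recovery(true_vals, est_vals):
    """Pearson correlation between true and estimated values, with two-sided p.

    Returns (nan, nan) with a warning when either side has zero variance.
    """
    x = np.asarray(true_vals, dtype=float)
    y = np.asarray(est_vals, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 participants")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; Pearson correlation undefined")
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def icc_2_1(true_vals, est_vals, alpha: float = 0.05):
    """ICC(2,1): two-way random effects, single measures, absolute agreement.

    With k = 2 raters (true, estimated) and n targets (participants):
        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    where MSR, MSC, MSE are the rows (targets), columns (raters) and residual
    mean squares of the two-way ANOVA.  The significance test is
    F = MSR / MSE on (n - 1, (n - 1)(k - 1)) df; the confidence interval is
    the Shrout-Fleiss F-based interval.  Returns (icc, p, (lo, hi)).
    """
    x = np.asarray(true_vals, dtype=float)
    y = np.asarray(est_vals, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 participants")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; ICC undefined")
        return np.nan, np.nan, (np.nan, np.nan)
    k = 2
    data = np.column_stack([x, y])  # n targets x k raters
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    SSR = k * np.sum((row_means - grand) ** 2)
    SSC = n * np.sum((col_means - grand) ** 2)
    SST = np.sum((data - grand) ** 2)
    SSE = SST - SSR - SSC
    MSR = SSR / (n - 1)
    MSC = SSC / (k - 1)
    MSE = SSE / ((n - 1) * (k - 1))
    icc = (MSR - MSE) / (MSR + (k - 1) * MSE + k / n * (MSC - MSE))

    F = MSR / MSE
    p = stats.f.sf(F, n - 1, (n - 1) * (k - 1))

    # Shrout-Fleiss interval via Satterthwaite df for the column effect
    Fc = MSC / MSE
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        v = (a * MSC + b * MSE) ** 2 / (
            (a * MSC) ** 2 / (k - 1) + (b * MSE) ** 2 / ((n - 1) * (k - 1))
        )
        F1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        F2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (MSR - F1 * MSE) / (F1 * (k * MSC + (k * n - k - n) * MSE) + n * MSR)
        hi = n * (F2 * MSR - MSE) / (k * MSC + (k * n - k - n) * MSE + n * F2 * MSR)
    else:
        lo = hi = 1.0
    return float(icc), float(p), (float(lo), float(hi))


def fisher_z_mean(rs) -> float:
    """Average correlations through Fisher's Z: tanh(mean(atanh(r)))."""
    rs = np.asarray(rs, dtype=float)
    if np.any(np.abs(rs) >= 1):
        warnings.warn("|r| = 1 clipped before Fisher-Z averaging")
        rs = np.clip(rs, -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def filter_by_psrf(convergence: pd.DataFrame, *tables: pd.DataFrame):
    """Drop unconverged participants (max R-hat >= 1.1) from participant-keyed tables.

    ``convergence`` is the output of ``sampler.participant_convergence``.
    Returns (excluded_ids, filtered_table, ...) with one filtered table per
    input, subset by its 'participant' column.
    """
    excluded = convergence.loc[~convergence["converged"], "participant"].tolist()
    out = []
    for t in tables:
        out.append(t[~t["participant"].isin(excluded)].reset_index(drop=True))
    return (excluded, *out)


def dic(draws: PosteriorDraws, data: pd.DataFrame):
    """Deviance information criterion, per participant and summed.

    Per participant: mean deviance Dbar = mean over draws of -2 log L, and
    D(theta_bar) at the posterior-mean parameters; p_D = Dbar - D(theta_bar);
    DIC = Dbar + p_D.  Non-finite deviances are excluded with a warning.
    Returns (per-participant DataFrame, summed DIC).
    """
    ll = draws.loglik.reshape(-1, draws.loglik.shape[-1])  # (draws, n_part)
    means = draws.posterior_mean_individual()
    rows = []
    for j, pid in enumerate(draws.participant_ids):
        dev = -2.0 * ll[:, j]
        finite = np.isfinite(dev)
        if not finite.all():
            warnings.warn(
                f"participant {pid}: {np.count_nonzero(~finite)} non-finite deviances excluded"
            )
        dbar = dev[finite].mean()
        row = means.iloc[j]
        sub = data[data["participant_id"] == pid]
        ll_at_mean = dataset_loglik(
            sub["rt"].to_numpy(),
            sub["choice"].to_numpy() == "true",
            row["A"], row["b"] - row["A"], row["v_true"], row["v_false"],
            row["sv"], row["t0"],
        )
        d_hat = -2.0 * float(ll_at_mean)
        p_d = dbar - d_hat
        rows.append({"participant": pid, "dbar": dbar, "p_d": p_d, "dic": dbar + p_d})
    per = pd.DataFrame(rows)
    return per, float(per["dic"].sum())


def group_ttest(values, groups):
    """Pooled-variance two-sample t-test between two groups of participant scores.

    Returns a dict with t, df (= n1 + n2 - 2), p (two-sided), and the group
    means keyed by group label (labels sorted).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    g1 = values[groups == labels[0]]
    g2 = values[groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 retained participants")
    t, p = stats.ttest_ind(g1, g2, equal_var=True)
    return {
        "t": float(t),
        "df": len(g1) + len(g2) - 2,
        "p": float(p),
        "means": {labels[0]: float(g1.mean()), labels[1]: float(g2.mean())},
    }


@dataclass
class RecoveryReport:
    """Per-parameter recovery statistics for one fitted dataset."""

    stats: pd.DataFrame  # parameter, pearson_r, pearson_p, icc21, icc21_p, icc_lo, icc_hi
    excluded_participants: list
    n_retained: int

    def r_of(self, param: str) -> float:
        return float(self.stats.set_index("parameter").loc[param, "pearson_r"])

    def icc_of(self, param: str) -> float:
        return float(self.stats.set_index("parameter").loc[param, "icc21"])


@dataclass
class MethodComparison:
    """Study-2 style method comparison: DIC and group t-tests per method."""

    dic_per_participant: dict  # method -> DataFrame
    dic_total: dict  # method -> float
    fraction_new_better: float
    ttests: dict  # method -> {parameter -> group_ttest dict}


def recovery_report(
    true_params: pd.DataFrame,
    draws: PosteriorDraws,
    params=RECOVERY_PARAMS,
    threshold: float = PSRF_THRESHOLD,
) -> RecoveryReport:
    """Score recovery of a fitted dataset after PSRF-based exclusion.

    ``true_params`` is the cohort's true-parameter table (one row per
    participant); estimates are posterior means of the individual-level
    parameters pooled over chains and kept iterations.
    """
    conv = participant_convergence(draws, threshold)
    est = draws.posterior_mean_individual()
    truth = true_params.rename(columns={"participant_id": "participant"})
    excluded, truth_f, est_f = filter_by_psrf(conv, truth, est)
    merged = truth_f.merge(est_f, on="participant", suffixes=("_true", "_est"))
    if len(merged) < 3:
        warnings.warn(
            f"only {len(merged)} participants retained after the PSRF filter; "
            "recovery statistics are undefined"
        )
    rows = []
    names = list(draws.ind_param_names)
    for p in params:
        if p not in names or not draws.free_mask[names.index(p)]:
            continue  # fixed parameters (e.g. sv under the classic policy) are not scored
        tv = merged[f"{p}_true"].to_numpy()
        ev = merged[f"{p}_est"].to_numpy()
        if len(merged) < 3:
            rows.append({"parameter": p, "pearson_r": np.nan, "pearson_p": np.nan,
                         "icc21": np.nan, "icc21_p": np.nan,
                         "icc_lo": np.nan, "icc_hi": np.nan})
            continue
        r, rp = pearson_recovery(tv, ev)
        icc, icc_p, (lo, hi) = icc_2_1(tv, ev)
        rows.append(
            {
                "parameter": p,
                "pearson_r": r,
                "pearson_p": rp,
                "icc21": icc,
                "icc21_p": icc_p,
                "icc_lo": lo,
                "icc_hi": hi,
            }
        )
    return RecoveryReport(
        stats=pd.DataFrame(rows),
        excluded_participants=excluded,
        n_retained=len(merged),
    )
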