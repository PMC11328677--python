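"""Linear Ballistic Accumulator: first-passage densities, trial likelihood, simulation.

The LBA (Brown & Heathcote, 2008) models a two-alternative decision as a race
between independent linear accumulators. On each trial an accumulator starts at
a point drawn uniformly from [0, A], accrues evidence at a rate drawn once per
trial from Normal(v, s), and responds when it reaches the boundary b = A + B
(B > 0 is the gap between the top of the start-point range and the boundary).
There is no within-trial noise; the observed response time is the winning
accumulator's crossing time plus a non-decision offset t0.

The joint density of (choice, RT) is *defective*: the density of the winning
accumulator's crossing time multiplied by the survivor function of the loser,
which integrates to the probability of that choice rather than to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "AccumulatorSpec",
    "ParticipantParams",
    "Trial",
    "lba_fpt_pdf",
    "lba_fpt_cdf",
    "trial_loglik",
    "dataset_loglik",
    "simulate_trials",
    "LOGLIK_FLOOR",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)

#: z-scores are clipped at this magnitude before evaluating the normal pdf/cdf.
Z_CLIP = 38.0

#: log-likelihood floor used instead of -inf so MCMC chains remain movable.
LOGLIK_FLOOR = -1e10


def _phi(z):
    """Standard normal pdf with clipped argument."""
    z = np.clip(z, -Z_CLIP, Z_CLIP)
    return np.exp(-0.5 * z * z) / _SQRT2PI


def _Phi(z):
    """Standard normal cdf with clipped argument."""
    return ndtr(np.clip(z, -Z_CLIP, Z_CLIP))


@dataclass(frozen=True)
class AccumulatorSpec:
    """One accumulator: start range [0, A], boundary b > A, drift Normal(v, s)."""

    A: float
    b: float
    v: float
    s: float

    def __post_init__(self):
        if not (self.A > 0):
            raise ValueError(f"A must be positive, got {self.A}")
        if not (self.b > self.A):
            raise ValueError(f"b must exceed A, got b={self.b}, A={self.A}")
        if not (self.s > 0):
            raise ValueError(f"s must be positive, got {self.s}")


@dataclass(frozen=True)
class ParticipantParams:
    """Full parameter vector of one participant's two-accumulator LBA.

    ``sv`` (between-trial drift-rate SD) is shared by both accumulators;
    ``b`` is the absolute boundary (b = A + B with B > 0); ``t0`` is the
    non-decision time in seconds.
    """

    A: float
    b: float
    v_true: float
    v_false: float
    sv: float
    t0: float

    def __post_init__(self):
        if not (self.A > 0):
            raise ValueError(f"A must be positive, got {self.A}")
        if not (self.b > self.A):
            raise ValueError(f"b must exceed A, got b={self.b}, A={self.A}")
        if not (self.sv > 0):
            raise ValueError(f"sv must be positive, got {self.sv}")
        if not (self.t0 > 0):
            raise ValueError(f"t0 must be positive, got {self.t0}")

    def accumulator(self, choice: str) -> AccumulatorSpec:
        v = self.v_true if choice == "true" else self.v_false
        return AccumulatorSpec(A=self.A, b=self.b, v=v, s=self.sv)


@dataclass(frozen=True)
class Trial:
    """A single (choice, RT) observation; choice labels the winning accumulator."""

    choice: str
    rt: float

    def __post_init__(self):
        if self.choice not in ("true", "false"):
            raise ValueError(f"choice must be 'true' or 'false', got {self.choice!r}")
        if not (self.rt > 0):
            raise ValueError(f"rt must be positive, got {self.rt}")


def lba_fpt_pdf(t, acc: AccumulatorSpec):
    """First-passage-time density of a single accumulator at decision time ``t``.

    f(t) = (1/A) [ -v Phi(z2) + s phi(z2) + v Phi(z1) - s phi(z1) ]
    with z1 = (b - t v)/(t s) and z2 = (b - A - t v)/(t s).  Returns 0 for
    t <= 0.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    A, b, v, s = acc.A, acc.b, acc.v, acc.s
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(t > 0, t * s, 1.0)
        z1 = (b - t * v) / ts
        z2 = (b - A - t * v) / ts
        f = (-v * _Phi(z2) + s * _phi(z2) + v * _Phi(z1) - s * _phi(z1)) / A
    f = np.where(t > 0, np.maximum(f, 0.0), 0.0)
    return f if f.ndim else float(f)


def lba_fpt_cdf(t, acc: AccumulatorSpec):
    """First-passage-time CDF of a single accumulator, clipped to [0, 1].

    F(t) = 1 + ((b-A-tv)/A) Phi(z2) - ((b-tv)/A) Phi(z1)
             + (ts/A) phi(z2) - (ts/A) phi(z1).
    As t -> inf this tends to Phi(v/s), the probability the drift is positive
    (i.e. that the accumulator ever crosses).
    """
    t = np.asarray(t, dtype=float)
    A, b, v, s = acc.A, acc.b, acc.v, acc.s
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(t > 0, t * s, 1.0)
        z1 = (b - t * v) / ts
        z2 = (b - A - t * v) / ts
        F = (
            1.0
            + ((b - A - t * v) / A) * _Phi(z2)
            - ((b - t * v) / A) * _Phi(z1)
            + (t * s / A) * _phi(z2)
            - (t * s / A) * _phi(z1)
        )
    F = np.where(t > 0, np.clip(F, 0.0, 1.0), 0.0)
    return F if F.ndim else float(F)


def trial_loglik(trial: Trial, p: ParticipantParams) -> float:
    """Log defective density of one (choice, RT) trial.

    density = pdf of the winning accumulator at rt - t0, times the survivor
    function (1 - CDF) of the losing accumulator at rt - t0.  Returns -inf
    when rt <= t0 (no decision time remains).
    """
    td = trial.rt - p.t0
    if td <= 0:
        return -np.inf
    winner = p.accumulator(trial.choice)
    loser = p.accumulator("false" if trial.choice == "true" else "true")
    f = lba_fpt_pdf(td, winner)
    surv = 1.0 - lba_fpt_cdf(td, loser)
    # guard against underflow of either factor
    return float(np.log(max(f, 1e-300)) + np.log(max(surv, 1e-300)))


def dataset_loglik(rt, is_true, A, B, v_true, v_false, sv, t0, *, renormalize=False):
    """Vectorised joint log-likelihood of one participant's trials.

    Parameters may be scalars or 1-d arrays over candidate parameter vectors
    (e.g. MCMC chains); ``rt`` and ``is_true`` are 1-d over trials.  Returns
    an array of shape ``(n_candidates,)`` (or a scalar if all parameters are
    scalars).  Trials with rt <= t0 contribute a large negative penalty, and
    the total is floored at ``LOGLIK_FLOOR`` so samplers remain movable.

    With ``renormalize`` the per-trial density is divided by the probability
    that at least one drift is positive, matching a simulator that redraws
    trials where both drifts are non-positive; by default the raw defective
    density is used (the event is rare at realistic parameter values).

    The boundary is parameterised through the gap ``B``: b = A + B.
    """
    rt = np.asarray(rt, dtype=float)
    is_true = np.asarray(is_true, dtype=bool)
    scalar_in = np.isscalar(A) or np.asarray(A).ndim == 0
    A, B, v_true, v_false, sv, t0 = (
        np.atleast_1d(np.asarray(x, dtype=float)) for x in (A, B, v_true, v_false, sv, t0)
    )
    n_cand = max(x.shape[0] for x in (A, B, v_true, v_false, sv, t0))
    b = A + B

    ll = np.zeros(n_cand)
    bad = (A <= 0) | (B <= 0) | (sv <= 0) | (t0 <= 0)
    for sel, vw, vl in ((is_true, v_true, v_false), (~is_true, v_false, v_true)):
        if not sel.any():
            continue
        td = rt[sel][None, :] - t0[:, None]  # (n_cand, n_sel)
        ok = td > 0
        tds = np.where(ok, td, 1.0)
        ts = tds * sv[:, None]
        # winner pdf
        z1 = np.clip((b[:, None] - tds * vw[:, None]) / ts, -Z_CLIP, Z_CLIP)
        z2 = np.clip((b[:, None] - A[:, None] - tds * vw[:, None]) / ts, -Z_CLIP, Z_CLIP)
        f = (
            -vw[:, None] * ndtr(z2)
            + sv[:, None] * np.exp(-0.5 * z2 * z2) / _SQRT2PI
            + vw[:, None] * ndtr(z1)
            - sv[:, None] * np.exp(-0.5 * z1 * z1) / _SQRT2PI
        ) / A[:, None]
        # loser survivor
        z1 = np.clip((b[:, None] - tds * vl[:, None]) / ts, -Z_CLIP, Z_CLIP)
        z2 = np.clip((b[:, None] - A[:, None] - tds * vl[:, None]) / ts, -Z_CLIP, Z_CLIP)
        F = (
            1.0
            + ((b[:, None] - A[:, None] - tds * vl[:, None]) / A[:, None]) * ndtr(z2)
            - ((b[:, None] - tds * vl[:, None]) / A[:, None]) * ndtr(z1)
            + (ts / A[:, None]) * np.exp(-0.5 * z2 * z2) / _SQRT2PI
            - (ts / A[:, None]) * np.exp(-0.5 * z1 * z1) / _SQRT2PI
        )
        dens = np.maximum(
            np.maximum(f, 1e-300) * np.maximum(1.0 - np.clip(F, 0.0, 1.0), 1e-300),
            1e-300,
        )
        term = np.where(ok, np.log(dens), -1e8)
        ll += term.sum(axis=1)
    if renormalize:
        with np.errstate(invalid="ignore"):
            p_race = 1.0 - ndtr(-v_true / sv) * ndtr(-v_false / sv)
        ll -= len(rt) * np.log(np.maximum(p_race, 1e-300))
    ll = np.where(bad, LOGLIK_FLOOR, np.maximum(ll, LOGLIK_FLOOR))
    return float(ll[0]) if scalar_in and n_cand == 1 else ll


def simulate_trials(p: ParticipantParams, n: int, seed, *, rng=None) -> list[Trial]:
    """Simulate ``n`` LBA trials for one participant.

    Per trial: start points ~ U[0, A] independently per accumulator, drifts
    ~ Normal(v_i, sv) independently; the winner is the accumulator with the
    smallest crossing time (b - start)/drift among those with positive drift,
    and rt = crossing time + t0.  Trials where both sampled drifts are <= 0
    are redrawn (the likelihood is not renormalised for this event; it is
    rare at realistic parameter values).  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    choice, rt = _simulate_arrays(p, n, rng)
    return [Trial(choice="true" if c else "false", rt=float(t)) for c, t in zip(choice, rt)]


def _simulate_arrays(p: ParticipantParams, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised simulation core; returns (is_true, rt) arrays of length n."""
    is_true = np.empty(n, dtype=bool)
    rt = np.empty(n, dtype=float)
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        starts = rng.uniform(0.0, p.A, size=(m, 2))
        drifts = np.column_stack(
            [rng.normal(p.v_true, p.sv, size=m), rng.normal(p.v_false, p.sv, size=m)]
        )
        both_neg = (drifts <= 0).all(axis=1)
        with np.errstate(divide="ignore"):
            times = np.where(drifts > 0, (p.b - starts) / drifts, np.inf)
        winner = np.argmin(times, axis=1)
        keep = ~both_neg
        idx = todo[keep]
        is_true[idx] = winner[keep] == 0
        rt[idx] = times[keep, winner[keep]] + p.t0
        todo = todo[both_neg]
    return is_true, rt
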