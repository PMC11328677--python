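"""Synthetic cohorts: individual parameter draws, the 21-configuration grid, two-group design.

Individual "true" parameters are drawn from normal distributions around
population means and then corrected into the allowable range:

* ``A`` (start-point range max), ``B`` (boundary gap, b = A + B) and
  ``v_false`` are floored at 0.05, ``v_true`` at 1.3, ``sv`` at 0.01;
* if ``v_true - v_false < 0.2`` after flooring, ``v_false`` is replaced by
  ``v_true - 0.2`` (unconditionally — the replacement may undercut the floor);
* ``t0`` is a constant (0.3 s) for every participant.

Generating SDs are 0.6 for A and B, 0.8 for the drift means and 0.4 for sv.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lba import ParticipantParams, _simulate_arrays

__all__ = [
    "GroupSpec",
    "PopulationConfig",
    "Cohort",
    "PARAM_NAMES",
    "DEFAULT_SDS",
    "DEFAULT_LOWER_BOUNDS",
    "draw_individual_params",
    "study1_grid",
    "study2_config",
    "simulate_dataset",
]

#: drawn (non-constant) generating parameters, in canonical order
PARAM_NAMES = ("A", "B", "v_true", "v_false", "sv")

DEFAULT_SDS = {"A": 0.6, "B": 0.6, "v_true": 0.8, "v_false": 0.8, "sv": 0.4}
DEFAULT_LOWER_BOUNDS = {"A": 0.05, "B": 0.05, "v_true": 1.3, "v_false": 0.05, "sv": 0.01}

#: minimum advantage of the correct drift over the incorrect one
MIN_DRIFT_GAP = 0.2


@dataclass(frozen=True)
class GroupSpec:
    """One group in a multi-group design: label, mean overrides, size."""

    label: str
    means: dict
    size: int


@dataclass(frozen=True)
class PopulationConfig:
    """Population-level generating distribution for a simulated cohort."""

    means: dict
    sds: dict = field(default_factory=lambda: dict(DEFAULT_SDS))
    lower_bounds: dict = field(default_factory=lambda: dict(DEFAULT_LOWER_BOUNDS))
    t0_fixed: float = 0.3
    n_participants: int = 100
    n_trials: int = 1000
    groups: tuple = ()

    def __post_init__(self):
        if any(sd <= 0 for sd in self.sds.values()):
            raise ValueError("all generating SDs must be positive")
        if self.groups and sum(g.size for g in self.groups) != self.n_participants:
            raise ValueError("group sizes must sum to n_participants")

    def group_means(self, label: str) -> dict:
        for g in self.groups:
            if g.label == label:
                return {**self.means, **g.means}
        raise KeyError(label)


@dataclass(frozen=True)
class Cohort:
    """True individual parameters (one row per participant) plus their config."""

    true_params: pd.DataFrame  # columns: participant, group, A, b, B, v_true, v_false, sv, t0
    config: PopulationConfig
    seed: int

    def participant(self, i: int) -> ParticipantParams:
        row = self.true_params.iloc[i]
        return ParticipantParams(
            A=row["A"], b=row["b"], v_true=row["v_true"],
            v_false=row["v_false"], sv=row["sv"], t0=row["t0"],
        )


def _correct(draws: np.ndarray, lower_bounds: dict) -> np.ndarray:
    """Apply floors then the v_false replacement, in place on a (n, 5) array."""
    for j, name in enumerate(PARAM_NAMES):
        np.maximum(draws[:, j], lower_bounds[name], out=draws[:, j])
    jt, jf = PARAM_NAMES.index("v_true"), PARAM_NAMES.index("v_false")
    gap_bad = draws[:, jt] - draws[:, jf] < MIN_DRIFT_GAP
    draws[gap_bad, jf] = draws[gap_bad, jt] - MIN_DRIFT_GAP
    return draws


def draw_individual_params(config: PopulationConfig, seed: int) -> Cohort:
    """Draw a cohort of true individual parameters from ``config``.

    Each participant gets an independent substream spawned from the master
    seed, so cohorts are extensible without reshuffling earlier participants.
    """
    master = np.random.SeedSequence(seed)
    groups = config.groups or (GroupSpec("all", {}, config.n_participants),)
    children = master.spawn(config.n_participants)
    rows = []
    pid = 0
    for g in groups:
        means = config.group_means(g.label) if config.groups else config.means
        mu = np.array([means[p] for p in PARAM_NAMES])
        sd = np.array([config.sds[p] for p in PARAM_NAMES])
        for _ in range(g.size):
            rng = np.random.default_rng(children[pid])
            draw = rng.normal(mu, sd)[None, :]
            draw = _correct(draw, config.lower_bounds)[0]
            rec = dict(zip(PARAM_NAMES, draw))
            rows.append(
                {
                    "participant": pid,
                    "group": g.label,
                    "A": rec["A"],
                    "B": rec["B"],
                    "b": rec["A"] + rec["B"],
                    "v_true": rec["v_true"],
                    "v_false": rec["v_false"],
                    "sv": rec["sv"],
                    "t0": config.t0_fixed,
                }
            )
            pid += 1
    df = pd.DataFrame(rows)
    return Cohort(true_params=df, config=config, seed=seed)


def study1_grid(n_participants: int = 100, n_trials: int = 1000) -> list[PopulationConfig]:
    """The 21 population-mean combinations of the first recovery study.

    A = 2 and mean sv = 1 throughout; boundary gap B in {2.3, 2.5, 2.7} crossed
    with v_true in {2.3, 2.5, 2.7} for v_false in {0.6, 0.8}, and B in
    {2.3, 2.5, 2.7} with v_true = 2.3 for v_false = 1 (a partial factorial).
    """
    combos = []
    for v_false in (0.6, 0.8):
        for v_true in (2.3, 2.5, 2.7):
            for B in (2.3, 2.5, 2.7):
                combos.append((B, v_true, v_false))
    for B in (2.3, 2.5, 2.7):
        combos.append((B, 2.3, 1.0))
    return [
        PopulationConfig(
            means={"A": 2.0, "B": B, "v_true": vt, "v_false": vf, "sv": 1.0},
            n_participants=n_participants,
            n_trials=n_trials,
        )
        for (B, vt, vf) in combos
    ]


def study2_config(n_per_group: int = 50, n_trials: int = 1000) -> PopulationConfig:
    """Two-group design: groups differ only in the sv generating mean (1.5 vs 0.5)."""
    shared = {"A": 2.0, "B": 2.5, "v_true": 2.5, "v_false": 0.8, "sv": 1.0}
    return PopulationConfig(
        means=shared,
        n_participants=2 * n_per_group,
        n_trials=n_trials,
        groups=(
            GroupSpec("group1", {"sv": 1.5}, n_per_group),
            GroupSpec("group2", {"sv": 0.5}, n_per_group),
        ),
    )


def simulate_dataset(cohort: Cohort, seed: int, dataset_id: str = "dataset") -> pd.DataFrame:
    """Simulate the trial table for a cohort: one row per (participant, trial).

    Columns: dataset_id, participant_id, group, trial, choice ('true'/'false'),
    rt in seconds.  Reproducible: one substream per participant spawned from
    ``seed``.
    """
    n_trials = cohort.config.n_trials
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(cohort.true_params))
    frames = []
    for i, row in cohort.true_params.iterrows():
        rng = np.random.default_rng(children[i])
        p = cohort.participant(i)
        is_true, rt = _simulate_arrays(p, n_trials, rng)
        frames.append(
            pd.DataFrame(
                {
                    "dataset_id": dataset_id,
                    "participant_id": int(row["participant"]),
                    "group": row["group"],
                    "trial": np.arange(n_trials),
                    "choice": np.where(is_true, "true", "false"),
                    "rt": np.round(rt, 6),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a trial table CSV (UTF-8, LF, 6-decimal rt, mandatory header)."""
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n", float_format="%.6f")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial table CSV, validating the mandatory columns."""
    df = pd.read_csv(path)
    required = ["dataset_id", "participant_id", "group", "trial", "choice", "rt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing column(s): {', '.join(missing)}")
    return df
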