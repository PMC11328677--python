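"""Recovery metrics against brute-force and third-party oracles."""

import numpy as np
import pandas as pd
import pytest

from lbascale.metrics import (
    dic,
    fisher_z_mean,
    filter_by_psrf,
    group_ttest,
    icc_2_1,
    pearson_recovery,
)

# a fixed 10-point "hand" dataset used by several formula oracles
TRUE_VALS = np.array([1.2, 2.1, 0.7, 3.3, 2.8, 1.9, 0.4, 2.5, 3.0, 1.1])
EST_VALS = np.array([1.0, 2.4, 0.9, 3.0, 2.6, 2.2, 0.8, 2.3, 3.4, 1.0])


class TestPearson:
    def test_perfect_recovery(self):
        r, p = pearson_recovery(TRUE_VALS, TRUE_VALS)
        assert r == pytest.approx(1.0)

    def test_location_scale_invariance(self):
        r, _ = pearson_recovery(TRUE_VALS, 2 * TRUE_VALS + 3)
        assert r == pytest.approx(1.0)

    def test_matches_brute_force_formula(self):
        x, y = TRUE_VALS, EST_VALS
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        r, p = pearson_recovery(x, y)
        assert r == pytest.approx(num / den, rel=1e-12)
        assert 0 < p < 1

    def test_zero_variance_warns_and_returns_nan(self):
        with pytest.warns(UserWarning):
            r, p = pearson_recovery(np.ones(5), EST_VALS[:5])
        assert np.isnan(r)


class TestICC21:
    def test_perfect_agreement(self):
        icc, p, (lo, hi) = icc_2_1(TRUE_VALS, TRUE_VALS + 1e-9)
        assert icc == pytest.approx(1.0, abs=1e-6)

    def test_constant_shift_penalised_below_pearson(self):
        r, _ = pearson_recovery(TRUE_VALS, TRUE_VALS + 2.0)
        icc, _, _ = icc_2_1(TRUE_VALS, TRUE_VALS + 2.0)
        assert icc < r
        assert icc < 0.6  # large shift relative to spread

    def test_matches_anova_decomposition_oracle(self):
        """ICC(2,1) from a first-principles two-way ANOVA on the hand table."""
        x, y = TRUE_VALS, EST_VALS
        n, k = len(x), 2
        data = np.column_stack([x, y])
        grand = data.mean()
        msr = k * np.sum((data.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((data.mean(axis=0) - grand) ** 2) / (k - 1)
        sse = (
            np.sum((data - grand) ** 2)
            - k * np.sum((data.mean(axis=1) - grand) ** 2)
            - n * np.sum((data.mean(axis=0) - grand) ** 2)
        )
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        icc, p, _ = icc_2_1(x, y)
        assert icc == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        n = len(TRUE_VALS)
        df = pd.DataFrame(
            {
                "targets": np.tile(np.arange(n), 2),
                "raters": np.repeat(["true", "est"], n),
                "scores": np.concatenate([TRUE_VALS, EST_VALS]),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="scores"
        ).set_index("Type")
        row = ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index else ref.loc["ICC2"]
        icc, p, (lo, hi) = icc_2_1(TRUE_VALS, EST_VALS)
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        ci = row["CI95"] if "CI95" in row.index else row["CI95%"]
        assert lo == pytest.approx(ci[0], abs=0.01)
        assert hi == pytest.approx(ci[1], abs=0.01)


class TestFisherZ:
    def test_constant_inputs_unchanged(self):
        assert fisher_z_mean([0.6, 0.6, 0.6]) == pytest.approx(0.6)

    def test_symmetry_cancels(self):
        assert fisher_z_mean([0.5, -0.5]) == pytest.approx(0.0, abs=1e-12)

    def test_two_value_closed_form(self):
        expected = np.tanh((np.arctanh(0.9) + np.arctanh(0.5)) / 2)
        assert fisher_z_mean([0.9, 0.5]) == pytest.approx(expected, rel=1e-12)

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            rs = rng.uniform(-0.95, 0.95, size=rng.integers(2, 8))
            m = fisher_z_mean(rs)
            assert rs.min() - 1e-12 <= m <= rs.max() + 1e-12

    def test_unit_correlation_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            m = fisher_z_mean([1.0, 0.0])
        assert 0 < m < 1


class TestFilterByPsrf:
    def _conv(self, flags):
        return pd.DataFrame(
            {"participant": np.arange(len(flags)), "max_psrf": 1.0, "converged": flags}
        )

    def test_all_converged_is_identity(self):
        table = pd.DataFrame({"participant": [0, 1, 2], "x": [1.0, 2.0, 3.0]})
        excluded, out = filter_by_psrf(self._conv([True, True, True]), table)
        assert excluded == []
        pd.testing.assert_frame_equal(out, table)

    def test_failed_participants_removed_everywhere(self):
        table = pd.DataFrame({"participant": np.arange(100), "x": np.arange(100.0)})
        flags = [i not in (3, 17, 44, 80, 99) for i in range(100)]
        excluded, out = filter_by_psrf(self._conv(flags), table)
        assert sorted(excluded) == [3, 17, 44, 80, 99]
        assert len(out) == 95
        assert not out["participant"].isin(excluded).any()


class TestGroupTTest:
    def test_identical_groups_give_zero(self):
        vals = np.concatenate([TRUE_VALS[:4], TRUE_VALS[:4]])
        groups = ["g1"] * 4 + ["g2"] * 4
        res = group_ttest(vals, groups)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_pooled_formula(self):
        g1 = np.array([1.1, 1.4, 0.9, 1.3])
        g2 = np.array([0.6, 0.8, 0.5, 0.7])
        res = group_ttest(np.concatenate([g1, g2]), ["a"] * 4 + ["b"] * 4)
        sp2 = ((len(g1) - 1) * g1.var(ddof=1) + (len(g2) - 1) * g2.var(ddof=1)) / (
            len(g1) + len(g2) - 2
        )
        t_expected = (g1.mean() - g2.mean()) / np.sqrt(sp2 * (1 / len(g1) + 1 / len(g2)))
        assert res["t"] == pytest.approx(t_expected, rel=1e-12)
        assert res["df"] == 6
        assert res["means"]["a"] == pytest.approx(g1.mean())

    def test_df_bookkeeping_after_exclusions(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=97)
        groups = ["g1"] * 48 + ["g2"] * 49
        assert group_ttest(vals, groups)["df"] == 95


class _DegenerateDraws:
    """Minimal stand-in for PosteriorDraws with an analytically known DIC."""

    def __init__(self, ll_draws, mean_params, pids):
        self.loglik = ll_draws  # (chains, kept, participants)
        self._mean_params = mean_params
        self.participant_ids = np.asarray(pids)

    def posterior_mean_individual(self):
        return self._mean_params


class TestDIC:
    def test_degenerate_posterior_has_zero_complexity(self):
        """All draws identical => p_D = 0 and DIC = D(theta_bar)."""
        from lbascale.cohort import PopulationConfig, draw_individual_params, simulate_dataset
        from lbascale.lba import dataset_loglik

        cfg = PopulationConfig(
            means={"A": 2.0, "B": 2.5, "v_true": 2.5, "v_false": 0.8, "sv": 1.0},
            n_participants=2, n_trials=40,
        )
        cohort = draw_individual_params(cfg, seed=1)
        data = simulate_dataset(cohort, seed=2)
        truth = cohort.true_params
        lls = []
        for _, row in truth.iterrows():
            lls.append(
                dataset_loglik(
                    data[data["participant_id"] == row["participant"]]["rt"].to_numpy(),
                    data[data["participant_id"] == row["participant"]]["choice"].to_numpy()
                    == "true",
                    row["A"], row["B"], row["v_true"], row["v_false"], row["sv"], row["t0"],
                )
            )
        ll = np.tile(np.asarray(lls)[None, None, :], (3, 10, 1))
        means = truth.rename(columns={"participant": "participant"})[
            ["participant", "A", "b", "v_true", "v_false", "sv", "t0"]
        ]
        draws = _DegenerateDraws(ll, means, truth["participant"].to_numpy())
        per, total = dic(draws, data)
        assert per["p_d"].to_numpy() == pytest.approx(0.0, abs=1e-8)
        assert total == pytest.approx(float(-2 * np.sum(lls)), rel=1e-10)

    def test_normal_toy_effective_parameters(self):
        """Gaussian mean with a flat-ish prior: p_D converges to ~1 effective
        parameter; computed from exact posterior draws."""
        rng = np.random.default_rng(3)
        n = 200
        y = rng.normal(1.0, 1.0, n)
        post_mean, post_sd = y.mean(), 1.0 / np.sqrt(n)
        theta = rng.normal(post_mean, post_sd, 4000)
        ll = -0.5 * ((y[None, :] - theta[:, None]) ** 2).sum(axis=1)
        dbar = (-2 * ll).mean()
        dhat = -2 * (-0.5 * ((y - post_mean) ** 2).sum())
        p_d = dbar - dhat
        assert p_d == pytest.approx(1.0, abs=0.15)

    def test_summed_dic_is_additive_over_participants(self):
        rng = np.random.default_rng(4)
        from lbascale.cohort import PopulationConfig, draw_individual_params, simulate_dataset
        from lbascale.lba import dataset_loglik

        cfg = PopulationConfig(
            means={"A": 2.0, "B": 2.5, "v_true": 2.5, "v_false": 0.8, "sv": 1.0},
            n_participants=3, n_trials=30,
        )
        cohort = draw_individual_params(cfg, seed=5)
        data = simulate_dataset(cohort, seed=6)
        truth = cohort.true_params
        ll = np.empty((2, 5, 3))
        for j, (_, row) in enumerate(truth.iterrows()):
            sub = data[data["participant_id"] == row["participant"]]
            base = float(
                dataset_loglik(
                    sub["rt"].to_numpy(), sub["choice"].to_numpy() == "true",
                    row["A"], row["B"], row["v_true"], row["v_false"], row["sv"], row["t0"],
                )
            )
            ll[:, :, j] = base + rng.normal(0, 0.5, size=(2, 5))
        means = truth[["participant", "A", "b", "v_true", "v_false", "sv", "t0"]]
        draws = _DegenerateDraws(ll, means, truth["participant"].to_numpy())
        per, total = dic(draws, data)
        assert total == pytest.approx(per["dic"].sum(), rel=1e-12)
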