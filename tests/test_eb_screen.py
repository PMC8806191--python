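"""Moderated statistics, the empirical-Bayes mixture, hit calling, contrasts."""

import numpy as np
import pandas as pd
import pytest

from walisar.eb_screen import (
    MixtureConfig, summary_statistic, build_screen_table, moderated_z,
    remove_outliers, fit_mixture, call_hits, run_screen, delta_delta,
)
from walisar.synthetic_data import generate_screen_scores


def manual_percentile(values, q):
    """Independent linear-interpolation percentile (textbook formula)."""
    v = sorted(values)
    rank = (len(v) - 1) * q / 100.0
    lo = int(np.floor(rank))
    frac = rank - lo
    return v[lo] if lo + 1 >= len(v) else v[lo] + frac * (v[lo + 1] - v[lo])


class TestSummaryStatistic:
    def test_hand_arithmetic(self):
        d, s = summary_statistic([0.3, 0.3, 0.3], [0.1, 0.1], [0.1, 0.1])
        assert d == pytest.approx(0.2)

    def test_equal_means_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.2, 0.01, 50)
        d, _ = summary_statistic(x, x, x)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        e, c1, c2 = rng.normal(size=(3, 30))
        d0, s0 = summary_statistic(e, c1, c2)
        d1, s1 = summary_statistic(e + 5, c1 + 5, c2 + 5)
        assert d1 == pytest.approx(d0) and s1 == pytest.approx(s0)

    def test_standard_error_formula(self):
        rng = np.random.default_rng(2)
        e, c1, c2 = rng.normal(size=(3, 40))
        _, s = summary_statistic(e, c1, c2)
        expect = np.sqrt(e.var(ddof=1) / 40 + c1.var(ddof=1) / 160
                         + c2.var(ddof=1) / 160)
        assert s == pytest.approx(expect)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            summary_statistic([0.1], [0.2, 0.3], [0.2, 0.3])


class TestModeratedZ:
    def test_constant_s_halves(self):
        table = pd.DataFrame({"orn_label": list("abcd"),
                              "d_stat": [0.1, 0.2, -0.1, 0.0],
                              "s_stat": [0.05] * 4})
        out, alpha0 = moderated_z(table)
        assert alpha0 == pytest.approx(0.05)
        assert out["z_stat"].tolist() == pytest.approx(
            [0.1 / 0.1, 0.2 / 0.1, -0.1 / 0.1, 0.0])

    def test_zero_d_gives_zero_z(self):
        table = pd.DataFrame({"d_stat": [0.0, 0.0], "s_stat": [0.1, 0.9]})
        out, _ = moderated_z(table)
        assert (out["z_stat"] == 0).all()

    def test_against_independent_percentile_oracle(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"d_stat": rng.normal(size=46),
                              "s_stat": rng.uniform(0.01, 0.2, 46)})
        out, alpha0 = moderated_z(table)
        a0 = manual_percentile(table["s_stat"], 90)
        assert alpha0 == pytest.approx(a0)
        assert out["z_stat"].to_numpy() == pytest.approx(
            (table["d_stat"] / (a0 + table["s_stat"])).to_numpy())

    def test_negative_s_rejected(self):
        with pytest.raises(ValueError):
            moderated_z(pd.DataFrame({"d_stat": [0, 0], "s_stat": [0.1, -0.1]}))


class TestRemoveOutliers:
    def test_identity_when_no_outliers(self):
        z = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        keep, removed = remove_outliers(z)
        assert keep.all() and removed.size == 0

    def test_extreme_value_removed(self):
        z = np.concatenate([np.linspace(-1, 1, 20), [100.0]])
        keep, removed = remove_outliers(z)
        assert list(removed) == [20]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        z = np.concatenate([rng.normal(size=30), [50.0, -60.0]])
        keep, _ = remove_outliers(z)
        keep2, removed2 = remove_outliers(z[keep])
        assert keep2.all() and removed2.size == 0

    def test_all_removed_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(np.array([1.0, 2.0, 3.0, 4.0]), k=0.0)


class TestMixture:
    def test_posteriors_bounded(self):
        rng = np.random.default_rng(5)
        fit = fit_mixture(rng.normal(size=80))
        assert (np.abs(fit.posteriors) <= 1).all()

    def test_pure_null_keeps_large_null_weight(self):
        rng = np.random.default_rng(6)
        fits = [fit_mixture(rng.normal(size=200)) for _ in range(5)]
        assert np.mean([f.pi_null for f in fits]) > 0.85

    def test_null_sd_recovered_within_15_percent(self):
        rng = np.random.default_rng(7)
        sds = [fit_mixture(rng.normal(0, 2.0, size=200)).null_sd
               for _ in range(5)]
        assert np.mean(sds) == pytest.approx(2.0, rel=0.15)

    def test_planted_signal_ranks_above_null(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=46)
        idx = rng.choice(46, 9, replace=False)
        z[idx] += rng.choice([-5.0, 5.0], 9)
        fit = fit_mixture(z)
        planted = np.abs(fit.posteriors[idx])
        others = np.delete(np.abs(fit.posteriors), idx)
        assert planted.min() > np.median(others)

    def test_posterior_sign_matches_z_sign(self):
        rng = np.random.default_rng(9)
        z = np.concatenate([rng.normal(size=40), [-6.0, 6.0]])
        fit = fit_mixture(z)
        assert fit.posteriors[-2] < -0.5 and fit.posteriors[-1] > 0.5

    def test_monotone_outside_null_bulk(self):
        rng = np.random.default_rng(10)
        z = np.concatenate([rng.normal(size=40), rng.normal(5, 0.3, 8)])
        fit = fit_mixture(z)
        grid = np.linspace(fit.null_mean + 2 * fit.null_sd, 8.0, 80)
        p = np.abs(fit.posterior_at(grid))
        assert np.min(np.diff(p)) > -0.02

    def test_non_convergence_reported(self):
        rng = np.random.default_rng(11)
        fit = fit_mixture(rng.normal(size=60), MixtureConfig(max_iter=1))
        assert not fit.converged and fit.n_iter == 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_mixture([0.0, 1.0])


class TestCallHits:
    def _fit_with_posteriors(self, post):
        rng = np.random.default_rng(12)
        fit = fit_mixture(rng.normal(size=20))
        return fit, np.asarray(post)

    def test_all_zero_posteriors_no_hits(self):
        fit, post = self._fit_with_posteriors(np.zeros(10))
        assert call_hits(fit, posteriors=post).sum() == 0

    def test_single_confident_orn_is_sole_hit(self):
        fit, post = self._fit_with_posteriors([0.0] * 9 + [0.99])
        hits = call_hits(fit, posteriors=post)
        assert hits.sum() == 1 and hits[-1]

    def test_average_local_fdr_of_reported_set(self):
        fit, post = self._fit_with_posteriors([0.99, 0.95, 0.8, 0.5, 0.1])
        hits = call_hits(fit, posteriors=post)
        lfdr = 1 - np.abs(post)
        assert lfdr[hits].mean() < fit.fdr_threshold


class TestRunScreen:
    def test_recovers_planted_orns(self):
        scores, truth = generate_screen_scores(n_orns=46, seed=13)
        table, fit, alpha0 = run_screen(scores)
        merged = table.merge(truth, on="orn_label")
        hits = merged[merged["hit"]]
        recall = hits["is_valent"].sum() / truth["is_valent"].sum()
        assert recall >= 0.8
        assert alpha0 > 0
        # hit signs agree with planted effect signs
        valent_hits = hits[hits["is_valent"]]
        assert (np.sign(valent_hits["true_effect"]) == valent_hits["sign"]).all()

    def test_outliers_still_scored(self):
        scores, _ = generate_screen_scores(n_orns=30, valent_fraction=0.0, seed=14)
        table, fit, _ = run_screen(scores, MixtureConfig(outlier_k=1.0))
        assert table["outlier"].any()
        assert table["posterior"].notna().all()


class TestDeltaDelta:
    def _scores(self, rng, n=30, boost=0.0):
        rows = []
        for role in ("test", "ctrl_driver", "ctrl_responder"):
            w = rng.normal(0, 0.2, n)
            rows.append(pd.DataFrame({
                "fly_id": [f"{role}{i}" for i in range(n)],
                "role": role, "wtsale": w + (boost if role == "test" else 0)}))
        return pd.concat(rows, ignore_index=True)

    def test_identical_conditions_give_zero(self):
        rng = np.random.default_rng(15)
        a = self._scores(rng)
        out = delta_delta(a, a, pairing="within_fly", bootstrap_reps=500, seed=0)
        assert out.dd_stat == 0.0
        assert out.ci_low <= 0 <= out.ci_high

    def test_wind_specific_boost_recovered(self):
        rng = np.random.default_rng(16)
        b = self._scores(rng, n=100)
        a = b.copy()
        a.loc[a["role"] == "test", "wtsale"] += 0.2
        out = delta_delta(a, b, pairing="within_fly", bootstrap_reps=500, seed=1)
        assert out.dd_stat == pytest.approx(0.2, abs=1e-12)

    def test_swap_negates(self):
        rng = np.random.default_rng(17)
        a, b = self._scores(rng, boost=0.1), self._scores(rng)
        ab = delta_delta(a, b, pairing="between_cohort", bootstrap_reps=500, seed=2)
        ba = delta_delta(b, a, pairing="between_cohort", bootstrap_reps=500, seed=2)
        assert ab.dd_stat == pytest.approx(-ba.dd_stat)

    def test_unmatched_ids_rejected(self):
        rng = np.random.default_rng(18)
        a = self._scores(rng)
        b = self._scores(rng)
        b["fly_id"] = "other_" + b["fly_id"]
        with pytest.raises(ValueError):
            delta_delta(a, b, pairing="within_fly")

    def test_between_cohort_null_ci_covers_zero(self):
        rng = np.random.default_rng(19)
        a, b = self._scores(rng, n=80), self._scores(rng, n=80)
        out = delta_delta(a, b, pairing="between_cohort",
                          bootstrap_reps=1000, seed=3)
        assert out.ci_low < 0 < out.ci_high
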