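"""Hurdle regression, Beta MLE, exact Wilcoxon, and derived statistics."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

import egalnet as eg
from egalnet.networks import Topology
from egalnet.simulate import GivingEvent, TrialLog


def brute_force_signed_rank_p(d, sidedness):
    """Enumerate all 2^n sign assignments of |d| and tally the W tails."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    W_obs = ranks[d > 0].sum()
    n = len(d)
    les = grt = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        les += w <= W_obs + 1e-9
        grt += w >= W_obs - 1e-9
    if sidedness == "less":
        return les / 2**n
    if sidedness == "greater":
        return grt / 2**n
    return min(1.0, 2 * min(les, grt) / 2**n)


class TestWilcoxon:
    @pytest.mark.parametrize("sidedness", ["less", "greater", "two-sided"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seed, sidedness):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 11)
        before = rng.integers(0, 6, n).astype(float)
        after = before + rng.integers(-3, 4, n)  # discrete: forces ties
        if (after == before).all():
            after[0] += 1
        res = eg.wilcoxon_signed_rank(before, after, sidedness)
        assert res.p == pytest.approx(brute_force_signed_rank_p(after - before, sidedness))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        before = rng.normal(size=12)
        after = before + rng.normal(size=12)
        ours = eg.wilcoxon_signed_rank(before, after, "less")
        ref = scipy.stats.wilcoxon(after, before, alternative="less", method="exact")
        assert ours.p == pytest.approx(ref.pvalue)

    def test_all_negative_seven_pairs(self):
        """Seven sessions all reducing inequality: W = 0, one-sided p = 1/128."""
        before = np.linspace(0.3, 0.4, 7)
        after = before - 0.05
        res = eg.wilcoxon_signed_rank(before, after, "less")
        assert res.W == 0.0
        assert res.p == pytest.approx(1 / 128)
        assert res.n == 7

    def test_statistic_bounds(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(2, 15)
            b = rng.normal(size=n)
            a = b + rng.normal(size=n)
            res = eg.wilcoxon_signed_rank(b, a)
            assert 0 <= res.W <= res.n * (res.n + 1) / 2

    def test_normal_approximation_branch(self):
        rng = np.random.default_rng(5)
        b = rng.normal(size=40)
        a = b + rng.normal(loc=-0.5, size=40)
        res = eg.wilcoxon_signed_rank(b, a, "less")
        ref = scipy.stats.wilcoxon(a, b, alternative="less", method="approx", correction=True)
        assert res.p == pytest.approx(ref.pvalue, rel=0.05)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            eg.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            eg.wilcoxon_signed_rank([1.0], [2.0], "sideways")


class TestFitBeta:
    def test_recovers_generating_shapes(self):
        rng = np.random.default_rng(0)
        x = rng.beta(1.27, 1.72, size=5000)
        fit = eg.fit_beta(x)
        assert fit.beta1 == pytest.approx(1.27, abs=0.15)
        assert fit.beta2 == pytest.approx(1.72, abs=0.15)
        assert fit.n == 5000

    def test_uniform_draws_give_flat_shapes(self):
        rng = np.random.default_rng(1)
        fit = eg.fit_beta(rng.uniform(size=5000))
        assert fit.beta1 == pytest.approx(1.0, abs=0.1)
        assert fit.beta2 == pytest.approx(1.0, abs=0.1)

    def test_loglik_at_estimate_beats_truth(self):
        rng = np.random.default_rng(2)
        x = rng.beta(0.8, 2.0, size=2000)
        fit = eg.fit_beta(x)
        ll_truth = scipy.stats.beta.logpdf(x, 0.8, 2.0).sum()
        assert fit.loglik >= ll_truth - 1e-6

    @pytest.mark.parametrize("bad", [[0.0] + [0.5] * 20, [0.5] * 20 + [1.0], [0.2] * 5])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            eg.fit_beta(bad)


def toy_log(events, incomes=(100, 10, 20, 30, 40), label="SF_Negative"):
    star = Topology(label, 5, ((0, 1), (0, 2), (0, 3), (0, 4)), incomes)
    rows = np.array([incomes, incomes])
    return TrialLog(
        topology=star, seed=0, incomes_by_round=rows, events=events,
        stop_reason="max_rounds", session=0,
    )


class TestRecipientPositions:
    def test_bin_midpoints(self):
        log = toy_log(
            [
                GivingEvent(1, 0, 1, 5),  # unique poorest of 4 neighbors
                GivingEvent(1, 0, 4, 5),  # unique richest of 4 neighbors
            ]
        )
        pos = eg.recipient_positions([log])
        assert pos.tolist() == [0.125, 0.875]

    def test_single_neighbor_midpoint(self):
        pair = Topology("Full", 2, ((0, 1),), (50, 60))
        log = TrialLog(
            topology=pair, seed=0,
            incomes_by_round=np.array([[50, 60], [49, 61]]),
            events=[GivingEvent(1, 0, 1, 1)], stop_reason="max_rounds",
        )
        assert eg.recipient_positions([log]).tolist() == [0.5]

    def test_strictly_inside_unit_interval(self, small_experiment):
        _, logs = small_experiment
        pos = eg.recipient_positions(logs)
        assert pos.size > 0
        assert ((pos > 0) & (pos < 1)).all()


class TestFitHurdle:
    def test_part1_points_match_plain_logit(self, small_experiment):
        records, _ = small_experiment
        fit = eg.fit_hurdle(records)
        exog = sm.add_constant(records[list(fit.prob.params.index[1:])].astype(float))
        plain = sm.Logit(records["gave"], exog).fit(disp=0)
        np.testing.assert_allclose(fit.prob.params, plain.params, rtol=1e-6)

    def test_local_inequality_power_check(self):
        """A generator driven only by L must yield a positive, significant
        fitted L coefficient in the probability part."""
        params = eg.BehaviorParams(a_p=-1.05, c_x=0, c_r=0, c_l=4.0, c_k=0)
        spec = eg.SessionSpec(n_subjects=25, sigma_subj=0.3, params=params)
        records, _ = eg.generate_sessions(3, spec, seed=8)
        fit = eg.fit_hurdle(records)
        assert fit.prob.params["L"] > 0
        assert fit.prob.pvalues["L"] < 0.05

    def test_part2_only_on_givers(self, small_experiment):
        records, _ = small_experiment
        fit = eg.fit_hurdle(records)
        assert fit.amount.nobs == int((records["amount"] > 0).sum())
        assert fit.n_clusters == records["session"].nunique() * 18

    def test_degenerate_inputs(self, never_give):
        spec = eg.SessionSpec(n_subjects=18, params=never_give, sigma_subj=0.0)
        records, _ = eg.generate_sessions(1, spec, seed=0)
        with pytest.raises(ValueError):
            eg.fit_hurdle(records)  # all gave = 0
        records2, _ = eg.generate_sessions(1, eg.SessionSpec(n_subjects=18), seed=1)
        one_cluster = records2[records2["subject"] == 0]
        with pytest.raises(ValueError):
            eg.fit_hurdle(one_cluster)


class TestGiniTableAndReverse:
    def test_never_give_table_is_flat(self, treatments, never_give):
        logs = [eg.run_trial(treatments[l], never_give, 0, session=0) for l in eg.LABELS]
        table = eg.end_round_gini_table(logs)
        assert (table["gini_end"] == table["gini_initial"]).all()
        assert len(table) == 5

    def test_egalitarian_params_reduce_gini_each_session(self):
        spec = eg.SessionSpec(n_subjects=25, sigma_subj=0.0)
        _, logs = eg.generate_sessions(4, spec, seed=21)
        het = [log for log in logs if log.label == "Lattice_Hetero"]
        for log in het:
            assert log.end_gini() < log.initial_gini()

    def test_dropped_trial_reduces_downstream_n(self, small_experiment):
        _, logs = small_experiment
        kept = eg.drop_trials(logs, 1, rng=3)
        assert len(eg.end_round_gini_table(kept)) == len(logs) - 1

    def test_reverse_share_hand_count(self):
        # 3 reverse events out of 12: recipient at least as rich as giver
        events = []
        for i in range(9):
            events.append(GivingEvent(1, 0, 1, 1))  # 100 -> 10: downward
        for i in range(3):
            events.append(GivingEvent(1, 1, 0, 1))  # 10 -> 100: reverse
        log = toy_log(events)
        records = pd.DataFrame(
            {
                "session": 0, "subject": [0, 1], "treatment": "SF_Negative",
                "round": 1, "X": [100, 10], "R": [1.0, 0.5], "L": [0.3, 0.3],
                "K": [4, 1], "gave": [1, 1], "amount": [9, 3], "received_prev": [0, 0],
            }
        )
        share, _ = eg.reverse_redistribution_stats([log], records)
        assert share == pytest.approx(3 / 12)

    def test_reverse_share_extremes(self):
        down = toy_log([GivingEvent(1, 0, 1, 2)])
        share, _ = eg.reverse_redistribution_stats([down], pd.DataFrame(
            {"session": [0], "subject": [0], "treatment": ["SF_Negative"], "round": [1],
             "X": [100], "R": [1.0], "L": [0.3], "K": [4], "gave": [1], "amount": [2],
             "received_prev": [0]}))
        assert share == 0.0
        up = toy_log([GivingEvent(1, 1, 0, 2)])
        share, _ = eg.reverse_redistribution_stats([up], pd.DataFrame(
            {"session": [0], "subject": [1], "treatment": ["SF_Negative"], "round": [1],
             "X": [10], "R": [0.5], "L": [0.3], "K": [1], "gave": [1], "amount": [2],
             "received_prev": [0]}))
        assert share == 1.0

    def test_reciprocity_fit_on_synthetic_data(self, small_experiment):
        records, logs = small_experiment
        share, recip = eg.reverse_redistribution_stats(logs, records)
        assert 0 < share < 1
        assert recip is not None
        assert "received_prev" in recip.prob.params.index


class TestTimecourse:
    def test_boundary_behaviors(self, treatments, never_give, always_give):
        logs0 = [eg.run_trial(treatments["Full"], never_give, 0, session=0)]
        rec0 = pd.concat([eg.trial_records(l) for l in logs0])
        tc0 = eg.giving_timecourse(rec0)
        assert (tc0["prop_donating"] == 0).all()
        logs1 = [eg.run_trial(treatments["Full"], always_give, 0, session=0)]
        rec1 = pd.concat([eg.trial_records(l) for l in logs1])
        tc1 = eg.giving_timecourse(rec1)
        assert tc1["prop_donating"].iloc[0] == 1.0

    def test_declines_with_inequality(self, small_experiment):
        records, _ = small_experiment
        tc = eg.giving_timecourse(records)
        assert tc["prop_donating"].iloc[-1] < tc["prop_donating"].iloc[0]
        assert tc["mean_fraction_given"].iloc[-1] < tc["mean_fraction_given"].iloc[0]
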