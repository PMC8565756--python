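"""Limited / non-limited treatment classification."""

import numpy as np
import pytest
from scipy import stats

import cndc
from cndc.classify import LIMITED, NON_LIMITED

from conftest import make_observations


def letters_group(cells, season="early", stage="TS"):
    """cells: list of (n_rate, ldm, pnc, letter) mean-level rows."""
    rows = [(r, l, p, {"sig_letter": s, "season": season, "stage": stage})
            for r, l, p, s in cells]
    return cndc.ExperimentTable(make_observations(rows, season=season,
                                                  stage=stage))


class TestLetters:
    def test_single_top_letter(self, table2):
        group = table2.subset(variety="Zhongjiazao 17", stage="TS")
        res = cndc.classify_letters(group.to_frame())
        assert res.limited_rates == [0, 75, 150]
        assert res.non_limited_rates == [225]
        assert res.usable

    def test_max_ldm_defines_top_even_with_odd_letters(self, table2):
        # max-LDM treatment carries letter 'b' shared by nobody else
        group = table2.subset(variety="Fumeizhan", stage="BS")
        res = cndc.classify_letters(group.to_frame())
        assert res.non_limited_rates == [270]
        assert res.limited_rates == [0, 90, 180]

    def test_shared_letter_with_top_is_non_limited(self):
        res = cndc.classify_letters(letters_group([
            (0, 1.0, 2.0, "c"), (75, 1.5, 1.8, "ab"),
            (150, 1.9, 1.7, "ab"), (225, 2.0, 1.6, "a")]))
        assert res.non_limited_rates == [75, 150, 225]
        assert res.limited_rates == [0]
        assert not res.usable  # only one limited treatment

    def test_all_same_letter_unusable(self):
        res = cndc.classify_letters(letters_group(
            [(r, 1.0 + i * 0.01, 2.0, "a") for i, r in
             enumerate((0, 75, 150))]))
        assert set(res.labels.values()) == {NON_LIMITED}
        assert not res.usable

    def test_missing_letters_directs_to_anova(self):
        table = cndc.ExperimentTable(make_observations(
            [(0, 1.0, 2.0), (75, 1.5, 1.8), (150, 2.0, 1.6)]))
        with pytest.raises(cndc.ValidationError, match="classify_anova"):
            cndc.classify_letters(table.to_frame())


def plateau_group(rng, low=(0.5, 1.4), top=(2.0, 2.0), reps=4, jitter=0.01):
    """Replicate-level group: two clearly limited rates, two tied on top."""
    means = {0: low[0], 60: low[1], 120: top[0], 180: top[1]}
    rows = []
    for rate, m in means.items():
        for rep in range(1, reps + 1):
            rows.append((rate, m * (1 + rng.normal(0, jitter)), 2.0,
                         {"replicate": rep}))
    return cndc.ExperimentTable(make_observations(rows))


class TestAnova:
    def test_plateau_splits_two_and_two(self):
        rng = np.random.default_rng(42)
        res = cndc.classify_anova(plateau_group(rng).to_frame())
        assert res.limited_rates == [0, 60]
        assert res.non_limited_rates == [120, 180]
        assert res.usable and res.method == "anova_posthoc"

    def test_agrees_with_pairwise_t_oracle(self):
        # brute-force two-sample t-tests against the top treatment are a
        # *more liberal* reference: anything Tukey flags, t flags too
        rng = np.random.default_rng(7)
        table = plateau_group(rng, jitter=0.02)
        res = cndc.classify_anova(table.to_frame())
        frame = table.to_frame()
        top_rate = frame.groupby("n_rate")["ldm"].mean().idxmax()
        top = frame[frame["n_rate"] == top_rate]["ldm"]
        for rate in res.limited_rates:
            vals = frame[frame["n_rate"] == rate]["ldm"]
            t, p = stats.ttest_ind(top, vals)
            assert p < 0.05 and vals.mean() < top.mean()

    def test_no_signal_all_non_limited(self):
        rows = [(r, 1.0, 2.0, {"replicate": rep})
                for r in (0, 60, 120) for rep in (1, 2, 3)]
        res = cndc.classify_anova(
            cndc.ExperimentTable(make_observations(rows)).to_frame())
        assert set(res.labels.values()) == {NON_LIMITED}
        assert not res.usable

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        table = plateau_group(rng)
        frame = table.to_frame()
        shuffled = frame.sample(frac=1.0, random_state=0)
        a = cndc.classify_anova(frame)
        b = cndc.classify_anova(shuffled)
        assert a.labels == b.labels

    def test_alpha_monotonicity(self):
        # raising alpha can only move treatments limited-ward
        rng = np.random.default_rng(11)
        for _ in range(10):
            frame = plateau_group(rng, jitter=0.05).to_frame()
            prev = set()
            for alpha in (0.001, 0.01, 0.05, 0.2):
                lim = set(cndc.classify_anova(frame, alpha=alpha).limited_rates)
                assert prev <= lim
                prev = lim

    def test_insufficient_replication_raises(self):
        rows = [(0, 1.0, 2.0, {"replicate": 1}),
                (60, 1.5, 1.8, {"replicate": 1}),
                (120, 2.0, 1.6, {"replicate": 1}),
                (120, 2.05, 1.6, {"replicate": 2})]
        with pytest.raises(cndc.InsufficientDataError):
            cndc.classify_anova(
                cndc.ExperimentTable(make_observations(rows)).to_frame())

    def test_requires_three_rate_levels(self):
        rows = [(r, m, 2.0, {"replicate": rep})
                for r, m in ((0, 1.0), (60, 2.0)) for rep in (1, 2)]
        with pytest.raises(cndc.InsufficientDataError):
            cndc.classify_anova(
                cndc.ExperimentTable(make_observations(rows)).to_frame())


class TestClassifyTable:
    def test_auto_dispatch(self, table2, synth_default):
        letters = cndc.classify_table(table2)
        assert all(r.method == "letters" for r in letters)
        assert len(letters) == 20
        anova = cndc.classify_table(synth_default[0])
        assert all(r.method == "anova_posthoc" for r in anova)
        assert len(anova) == 5

    def test_letters_and_anova_agree_on_synthetic(self, synth_default):
        # derive compact letters from the replicate data with an
        # independent Tukey implementation, then check both routes agree
        table, _ = synth_default
        frame = table.to_frame()
        for _, group in frame.groupby("stage", sort=False):
            res_anova = cndc.classify_anova(group)
            rates = sorted(group["n_rate"].unique())
            samples = [group[group["n_rate"] == r]["ldm"].to_numpy()
                       for r in rates]
            oracle = stats.tukey_hsd(*samples)
            means = {r: s.mean() for r, s in zip(rates, samples)}
            top = max(means, key=means.get)
            i_top = rates.index(top)
            expected = {}
            for i, r in enumerate(rates):
                sig_lower = (oracle.pvalue[i, i_top] < 0.05
                             and means[r] < means[top])
                expected[r] = LIMITED if sig_lower else NON_LIMITED
            assert res_anova.labels == expected
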