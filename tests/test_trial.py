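import numpy as np
import pandas as pd
import pytest

from sleepprompt.fixtures import contingency_table
from sleepprompt.trial import (
    ConsortEvents,
    EnrollmentRecord,
    PowerSpec,
    TrialOpsError,
    consort_accounting,
    inflate_for_attrition,
    pearson_chi_square,
    required_sample_size,
    stratified_block_randomize,
    stratum_label,
    two_sample_t_change,
)


def roster(n, sex="female", isi=10, prefix="P"):
    return [EnrollmentRecord(f"{prefix}{i:03d}", sex, isi) for i in range(n)]


class TestRandomization:
    def test_single_stratum_complete_blocks_balance(self):
        table = stratified_block_randomize(roster(8), seed=1)
        assert table["arm"].value_counts().to_dict() == {"SPA": 4, "control": 4}

    def test_partial_block_imbalance_bounded(self):
        for seed in range(40):
            table = stratified_block_randomize(roster(6), seed=seed)
            counts = table["arm"].value_counts()
            assert abs(counts.get("SPA", 0) - counts.get("control", 0)) <= 2

    def test_block_balance_after_every_complete_block(self):
        table = stratified_block_randomize(roster(24), seed=7)
        for b, grp in table.groupby("block_index"):
            assert grp["arm"].value_counts().to_dict() == {"SPA": 2, "control": 2}

    def test_deterministic_under_seed(self):
        t1 = stratified_block_randomize(roster(20), seed=99)
        t2 = stratified_block_randomize(roster(20), seed=99)
        pd.testing.assert_frame_equal(t1, t2)

    def test_relabeling_invariance(self):
        a = stratified_block_randomize(roster(10), seed=5)
        b = stratified_block_randomize(roster(10, prefix="Q"), seed=5)
        assert list(a["arm"]) == list(b["arm"])

    def test_strata_use_independent_streams(self):
        mixed = roster(8, sex="female") + roster(8, sex="male", prefix="M")
        t = stratified_block_randomize(mixed, seed=3)
        females_only = stratified_block_randomize(roster(8, sex="female"), seed=3)
        assert list(t[t["sex"] == "female"]["arm"]) == list(females_only["arm"])

    def test_stratum_consistency_enforced(self):
        with pytest.raises(TrialOpsError):
            EnrollmentRecord("P1", "female", 20, stratum="female:lt8")
        assert stratum_label("male", 8) == "male:s8_14"

    def test_bad_block_size_rejected(self):
        with pytest.raises(TrialOpsError):
            stratified_block_randomize(roster(4), block_size=3, seed=1)


class TestSampleSize:
    def test_trial_planning_inputs_give_fifty_per_group(self):
        assert required_sample_size(PowerSpec(delta=1.3, sd=2.3)) == 50

    def test_unit_standardized_effect(self):
        # 2 x (1.96 + 0.8416)^2 ~ 15.7 -> 16
        assert required_sample_size(PowerSpec(delta=1.0, sd=1.0)) == 16

    def test_monotone_in_effect_size(self):
        sizes = [required_sample_size(PowerSpec(delta=d, sd=2.3)) for d in (2.0, 1.3, 0.8, 0.4)]
        assert sizes == sorted(sizes)
        assert required_sample_size(PowerSpec(delta=1.3, sd=3.0)) > 50

    @pytest.mark.parametrize("n,rate,expected", [(100, 0.20, 120), (100, 0.0, 100), (101, 0.20, 122)])
    def test_attrition_inflation(self, n, rate, expected):
        assert inflate_for_attrition(n, rate) == expected

    def test_invalid_spec_rejected(self):
        with pytest.raises(TrialOpsError):
            PowerSpec(delta=0, sd=2.3)


def _chi_square_oracle(counts):
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            exp = counts[i].sum() * counts[:, j].sum() / n
            stat += (counts[i, j] - exp) ** 2 / exp
    return stat, (counts.shape[0] - 1) * (counts.shape[1] - 1)


class TestChiSquare:
    @pytest.mark.parametrize(
        "fixture,stat,df",
        [
            ("table1-isi8-alcohol", 6.81, 2),
            ("table1-isi8-smoking", 3.90, 1),
            ("table1-isi8-sleep-aid", 5.85, 1),
        ],
    )
    def test_published_baseline_statistics(self, fixture, stat, df):
        _, _, counts = contingency_table(fixture)
        res = pearson_chi_square(counts)
        assert round(res.statistic, 2) == stat
        assert res.df == df

    def test_proportional_table_is_zero(self):
        res = pearson_chi_square([[10, 20], [5, 10]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_oracle_equivalence_on_small_tables(self):
        """Matches a direct double-loop expected-count computation on random
        r x c tables up to 4 x 4 with n <= 50."""
        rng = np.random.default_rng(2021)
        for _ in range(200):
            r, c = rng.integers(2, 5, size=2)
            total = int(rng.integers(r * c, 51))
            counts = rng.multinomial(total - r * c,
                                     np.ones(r * c) / (r * c)).reshape(r, c) + 1
            res = pearson_chi_square(counts)
            stat, df = _chi_square_oracle(counts)
            assert res.statistic == pytest.approx(stat, rel=1e-12)
            assert res.df == df

    def test_zero_marginal_rejected(self):
        with pytest.raises(TrialOpsError):
            pearson_chi_square([[0, 0], [5, 10]])


class TestTTest:
    def test_identical_samples(self):
        res = two_sample_t_change([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == 0.0
        assert res.p_value < 1.0 or res.p_value == pytest.approx(1.0)

    def test_constant_shift_zero_variance(self):
        res = two_sample_t_change([5.0, 5.0], [2.0, 2.0])
        assert res.mean_difference == 3.0
        assert res.p_value == 0.0

    def test_matches_scipy_on_noisy_samples(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        a, b = rng.normal(-2.2, 4.3, 60), rng.normal(-1.5, 4.7, 56)
        res = two_sample_t_change(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.ci_low < res.mean_difference < res.ci_high

    def test_null_p_uniform(self):
        """Under a common distribution the p-value is ~uniform: moderate
        rejection-rate check at alpha=.05 over 400 simulations."""
        rng = np.random.default_rng(42)
        rejections = sum(
            two_sample_t_change(rng.normal(0, 4.3, 60), rng.normal(0, 4.3, 56)).p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.08

    def test_small_sample_rejected(self):
        with pytest.raises(TrialOpsError):
            two_sample_t_change([1.0], [1.0, 2.0])


class TestConsort:
    @staticmethod
    def _events(dropouts_spa=2):
        return ConsortEvents(
            applied=215,
            eligible=118,
            allocated={"SPA": 62, "control": 56},
            excluded_after_allocation={"SPA": dropouts_spa, "control": 0},
            analyzed={"SPA": 62 - dropouts_spa, "control": 56},
        )

    def test_dropout_rate_to_one_decimal(self):
        s = consort_accounting(self._events())
        assert s.dropout_rate_pct["SPA"] == 3.2
        assert s.dropout_rate_pct["control"] == 0.0
        assert s.analyzed["SPA"] == 60

    def test_inconsistent_counts_rejected(self):
        bad = ConsortEvents(
            applied=100, eligible=100,
            allocated={"SPA": 50}, excluded_after_allocation={"SPA": 0},
            analyzed={"SPA": 52},
        )
        with pytest.raises(TrialOpsError):
            consort_accounting(bad)
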