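"""Statistics-pipeline tests against scipy/statsmodels oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gaitcoord.stats import (
    StatsError,
    build_table1,
    build_table2,
    compare_conditions,
    correlation_screen,
    normality_screen,
)

CONDITIONS = ("usual", "fast", "slow")


def make_records(rng, n=80, means=(0.0, 0.0, 0.0), sds=(1.0, 1.0, 1.0), var="pci"):
    frames = []
    for cond, m, s in zip(CONDITIONS, means, sds):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"S{i}" for i in range(n)],
                    "condition": cond,
                    var: rng.normal(m, s, size=n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestNormalityScreen:
    def test_gaussian_accepted_skewed_rejected(self):
        rng = np.random.default_rng(3)
        records = make_records(rng, var="pci")
        records["ga"] = np.concatenate(
            [rng.exponential(1.0, 80) ** 3 for _ in CONDITIONS]
        )
        screen = normality_screen(records, variables=("pci", "ga"))
        assert (screen.loc["pci"] > 0.05).all()
        assert (screen.loc["ga"] < 0.05).all()

    def test_constant_vector_marked_missing(self):
        rng = np.random.default_rng(0)
        records = make_records(rng)
        records["pci"] = 1.0
        screen = normality_screen(records, variables=("pci",))
        assert screen.loc["pci"].isna().all()


class TestCompareConditions:
    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(3, 1, 40)
        records = pd.concat(
            [
                pd.DataFrame({"subject_id": [f"S{i}" for i in range(40)],
                              "condition": c, "pci": vals})
                for c in CONDITIONS
            ],
            ignore_index=True,
        )
        row = compare_conditions(records, "pci")
        assert row.f_stat == pytest.approx(0.0, abs=1e-9)
        assert all(p == 1.0 for p in row.pairwise_adjusted.values())

    def test_published_scale_effects_detected(self):
        rng = np.random.default_rng(2)
        records = make_records(
            rng, n=80, means=(2.87, 2.65, 3.57), sds=(0.74, 0.72, 1.05)
        )
        row = compare_conditions(records, "pci")
        assert row.p_value < 0.001

    def test_large_shift_power_sanity(self):
        rng = np.random.default_rng(4)
        records = make_records(rng, n=10, means=(0.0, 0.0, 10.0))
        row = compare_conditions(records, "pci")
        assert row.pairwise_adjusted[("usual", "slow")] < 0.001
        assert row.pairwise_adjusted[("slow", "fast")] < 0.001

    def test_bonferroni_is_triple_capped(self):
        rng = np.random.default_rng(5)
        records = make_records(rng)
        row = compare_conditions(records, "pci")
        for pair, raw in row.pairwise_raw.items():
            assert row.pairwise_adjusted[pair] == pytest.approx(min(1.0, 3 * raw))
            assert row.pairwise_adjusted[pair] >= raw

    def test_anova_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(6)
        records = make_records(rng, n=25, means=(0.0, 0.4, 0.8))
        row = compare_conditions(records, "pci")
        fit = ols("pci ~ C(condition)", data=records).fit()
        oracle = sm.stats.anova_lm(fit, typ=1)
        assert row.f_stat == pytest.approx(float(oracle["F"].iloc[0]), rel=1e-9)
        assert row.p_value == pytest.approx(float(oracle["PR(>F)"].iloc[0]), rel=1e-9)

    def test_two_group_anova_equals_squared_t(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        f, _ = sps.f_oneway(a, b)
        t, _ = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, abs=1e-9)

    def test_repeated_measures_variant(self):
        rng = np.random.default_rng(8)
        subject_effect = rng.normal(0, 2.0, 30)
        frames = []
        for cond, shift in zip(CONDITIONS, (0.0, -0.3, 0.5)):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": [f"S{i}" for i in range(30)],
                        "condition": cond,
                        "pci": 3.0 + shift + subject_effect + rng.normal(0, 0.3, 30),
                    }
                )
            )
        records = pd.concat(frames, ignore_index=True)
        paired = compare_conditions(records, "pci", repeated=True)
        independent = compare_conditions(records, "pci")
        # the between-subject spread masks the shift unless paired
        assert paired.p_value < 0.001
        assert paired.p_value < independent.p_value

    def test_missing_group_rejected(self):
        rng = np.random.default_rng(9)
        records = make_records(rng)
        with pytest.raises(StatsError):
            compare_conditions(records[records["condition"] != "slow"], "pci")


class TestCorrelationScreen:
    def _records(self, rng, n=80):
        frame = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "condition": "usual",
                "gait_speed": rng.normal(1.1, 0.05, n),
                "height": rng.normal(1.66, 0.09, n),
                "bmi": rng.normal(22.8, 3.1, n),
                "cadence": rng.normal(111.6, 6.5, n),
                "swing_time": rng.normal(0.43, 0.02, n),
                "step_length": rng.normal(0.63, 0.08, n),
                "pci": rng.normal(2.87, 0.74, n),
                "ga": rng.normal(1.27, 1.05, n),
            }
        )
        return frame

    def test_perfect_negative_correlation(self):
        rng = np.random.default_rng(10)
        records = self._records(rng)
        records["pci"] = -records["step_length"]
        screen = correlation_screen(records, "usual")
        assert screen.loc["step_length", "pci_r"] == pytest.approx(-1.0, abs=1e-12)

    def test_independent_draws_mostly_null(self):
        rng = np.random.default_rng(11)
        screen = correlation_screen(self._records(rng), "usual")
        r = screen[["pci_r", "ga_r"]].to_numpy().ravel()
        p = screen[["pci_p", "ga_p"]].to_numpy().ravel()
        assert (np.abs(r) < 0.3).all()
        assert (p > 0.05).mean() >= 0.75

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(12)
        records = self._records(rng)
        base = correlation_screen(records, "usual")
        records["step_length"] = 1000.0 * records["step_length"] - 40.0
        records["pci"] = 0.1 * records["pci"] + 7.0
        moved = correlation_screen(records, "usual")
        assert moved.loc["step_length", "pci_r"] == pytest.approx(
            base.loc["step_length", "pci_r"], abs=1e-9
        )

    def test_zero_variance_marked_undefined(self):
        rng = np.random.default_rng(13)
        records = self._records(rng)
        records["bmi"] = 22.8
        screen = correlation_screen(records, "usual")
        assert np.isnan(screen.loc["bmi", "pci_r"])


class TestTables:
    def test_noiseless_cohort_zero_sd(self):
        frames = []
        for cond in CONDITIONS:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": [f"S{i}" for i in range(5)],
                        "condition": cond,
                        "pci": 3.0,
                        "ga": 1.0,
                    }
                )
            )
        records = pd.concat(frames, ignore_index=True)
        table = build_table1(records, variables=("pci", "ga"))
        assert (table[[f"{c}_sd" for c in CONDITIONS]] == 0).all().all()

    def test_table2_layout(self):
        rng = np.random.default_rng(14)
        records = make_records(rng)
        records["ga"] = records["pci"] * 0.5 + rng.normal(0, 0.5, len(records))
        table = build_table2(records)
        assert list(table.index) == ["pci", "ga"]
        assert ((table >= 0) & (table <= 1)).all().all()
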