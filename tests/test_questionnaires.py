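import numpy as np
import pandas as pd
import pytest

from neurofatigue._stats import bh_adjust, significance_stars
from neurofatigue.questionnaires import (
    bmis_scores,
    cronbach_alpha,
    order_effect_check,
    paired_condition_tests,
    zef_scores,
)
from neurofatigue.synth import BMIS_ITEMS, ZEF_DIMENSIONS, ZEF_ITEMS
from neurofatigue.synth.questionnaire import BMIS_PLEASANT, BMIS_UNPLEASANT


def _bmis_table(values):
    rows = []
    for s, vals in enumerate(values):
        row = {"subject": s, "condition": "videoconference", "phase": "after"}
        row.update(dict(zip(BMIS_ITEMS, vals)))
        rows.append(row)
    return pd.DataFrame(rows)


def _zef_table(values):
    rows = []
    for s, vals in enumerate(values):
        row = {"subject": s, "condition": "videoconference"}
        row.update(dict(zip(ZEF_ITEMS, vals)))
        rows.append(row)
    return pd.DataFrame(rows)


class TestBmisScores:
    def test_symmetric_minimum_gives_zero(self):
        out = bmis_scores(_bmis_table([[1] * 16]))
        assert out["overall"].iloc[0] == 0

    def test_extreme_split(self):
        vals = {**{i: 4 for i in BMIS_PLEASANT}, **{i: 1 for i in BMIS_UNPLEASANT}}
        out = bmis_scores(_bmis_table([[vals[i] for i in BMIS_ITEMS]]))
        assert out["overall"].iloc[0] == 8 * 4 - 8 * 1 == 24

    def test_bounds(self, rng):
        vals = rng.integers(1, 5, (50, 16))
        out = bmis_scores(_bmis_table(vals))
        assert out["overall"].between(-24, 24).all()

    def test_item_order_invariance(self, rng):
        vals = rng.integers(1, 5, (1, 16))
        table = _bmis_table(vals)
        shuffled = table[list(np.random.default_rng(0).permutation(table.columns))]
        a = bmis_scores(table)
        b = bmis_scores(shuffled)
        assert a["overall"].iloc[0] == b["overall"].iloc[0]

    def test_missing_item_rejected(self):
        table = _bmis_table([[2] * 16]).drop(columns=["happy"])
        with pytest.raises(ValueError, match="missing items"):
            bmis_scores(table)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="lie in"):
            bmis_scores(_bmis_table([[5] * 16]))


class TestZefScores:
    def test_all_fives(self):
        out = zef_scores(_zef_table([[5] * 18]))
        assert out["overall"].iloc[0] == 5.0
        for dim in ZEF_DIMENSIONS:
            assert out[dim].iloc[0] == 5.0

    def test_all_ones(self):
        assert zef_scores(_zef_table([[1] * 18]))["overall"].iloc[0] == 1.0

    def test_dimension_construction_oracle(self):
        vals = []
        for dim_idx, items in enumerate(ZEF_DIMENSIONS.values()):
            vals += [dim_idx + 1] * len(items)
        vals += [3, 3, 3]  # unassigned block
        out = zef_scores(_zef_table([vals]))
        for dim_idx, dim in enumerate(ZEF_DIMENSIONS):
            assert out[dim].iloc[0] == dim_idx + 1
        assert np.isclose(out["overall"].iloc[0], np.mean(vals))

    def test_missing_item_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            zef_scores(_zef_table([[3] * 18]).drop(columns=["zef07"]))


class TestCronbachAlpha:
    def test_identical_items_alpha_one(self, rng):
        x = rng.standard_normal(100)
        matrix = np.column_stack([x] * 6)
        assert np.isclose(cronbach_alpha(matrix), 1.0)

    def test_independent_items_alpha_near_zero(self):
        vals = []
        for seed in range(50):
            m = np.random.default_rng(seed).standard_normal((500, 18))
            vals.append(cronbach_alpha(m))
        assert abs(np.mean(vals)) < 0.1

    def test_two_item_closed_form(self):
        # standardized two-item alpha = 2*rho / (1 + rho)
        rho = 0.5
        rng = np.random.default_rng(1)
        z = rng.standard_normal((2000, 2))
        x1 = z[:, 0]
        x2 = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        assert abs(cronbach_alpha(np.column_stack([x1, x2])) - 2 * rho / (1 + rho)) < 0.05

    def test_zero_variance_undefined(self):
        assert np.isnan(cronbach_alpha(np.ones((10, 4))))

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 1)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((2, 4)))


class TestPairedConditionTests:
    def _frames(self, a_vals, b_vals):
        a = pd.DataFrame({"subject": np.arange(len(a_vals)), "score": a_vals})
        b = pd.DataFrame({"subject": np.arange(len(b_vals)), "score": b_vals})
        return a, b

    def test_identical_conditions_nothing_significant(self, rng):
        vals = rng.standard_normal(20)
        a, b = self._frames(vals, vals)
        out = paired_condition_tests(a, b, ["score"])
        assert (out["p"] == 1.0).all()
        assert out["stars"].iloc[0] == ""

    def test_constant_shift_n35(self, rng):
        vals = rng.standard_normal(35)
        a, b = self._frames(vals + 1.0, vals)
        out = paired_condition_tests(a, b, ["score"])
        assert out["p_adj"].iloc[0] < 0.001
        assert out["stars"].iloc[0] == "***"

    def test_bh_step_up_hand_example(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)

    def test_shift_invariance(self, rng):
        vals = rng.standard_normal(25)
        diff = rng.standard_normal(25)
        a1, b1 = self._frames(vals + diff, vals)
        a2, b2 = self._frames(vals + diff + 50.0, vals + 50.0)
        p1 = paired_condition_tests(a1, b1, ["score"])["p"].iloc[0]
        p2 = paired_condition_tests(a2, b2, ["score"])["p"].iloc[0]
        assert np.isclose(p1, p2)

    def test_subject_mismatch_rejected(self):
        a = pd.DataFrame({"subject": [0, 1], "score": [1.0, 2.0]})
        b = pd.DataFrame({"subject": [0, 2], "score": [1.0, 2.0]})
        with pytest.raises(ValueError, match="same subjects"):
            paired_condition_tests(a, b, ["score"])

    def test_bh_monotone_in_rank(self, rng):
        p = rng.uniform(0, 1, 30)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,stars", [(0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.2, ""), (np.nan, "")]
    )
    def test_thresholds(self, p, stars):
        assert significance_stars(p) == stars


def _order_scores(rng, n=35, order_effect=0.0, lecture_effect=0.0, subject_sd=1.0):
    rows = []
    subj_int = subject_sd * rng.standard_normal(n)
    orders = np.array(["videoconference_first"] * (n // 2) + ["face_to_face_first"] * (n - n // 2))
    for s in range(n):
        for cond in ("videoconference", "face_to_face"):
            score = (
                subj_int[s]
                + order_effect * (orders[s] == "videoconference_first")
                + lecture_effect * (cond == "videoconference")
                + 0.5 * rng.standard_normal()
            )
            rows.append(
                dict(subject=s, condition=cond, order=orders[s], overall=score)
            )
    return pd.DataFrame(rows)


class TestOrderEffectCheck:
    def test_type_one_error(self):
        sig = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            table = order_effect_check(_order_scores(rng))
            sig += table.loc[table["term"] == "order", "p"].iloc[0] < 0.05
        assert sig / reps <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)

    def test_injected_order_effect_recovered(self):
        estimates = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            table = order_effect_check(_order_scores(rng, order_effect=1.0))
            estimates.append(table.loc[table["term"] == "order", "estimate"].iloc[0])
        estimates = np.asarray(estimates)
        assert abs(estimates.mean() - 1.0) < 3 * estimates.std(ddof=1)

    def test_specificity(self):
        lecture_sig, order_sig = 0, 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            table = order_effect_check(_order_scores(rng, lecture_effect=2.0))
            lecture_sig += table.loc[table["term"] == "condition", "p"].iloc[0] < 0.05
            order_sig += table.loc[table["term"] == "order", "p"].iloc[0] < 0.05
        assert lecture_sig >= 0.9 * reps
        assert order_sig <= 0.3 * reps

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="column"):
            order_effect_check(pd.DataFrame({"subject": [], "condition": []}))
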