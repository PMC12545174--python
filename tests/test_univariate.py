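import numpy as np
import pandas as pd
import pytest

from rnc.response_store import ResponseSet, UnivariateProfile, univariate_profile
from rnc.univariate import (
    CONDITIONS,
    UniControlCondition,
    aggregate_by_pair_group,
    build_univariate_null,
    crossval_univariate,
    profile_correlation,
    select_univariate_controls,
    stepwise_distance_grouping,
    subset_contrast,
    within_between_grouping,
)


def prof(values, area="A", participant="p1", ids=None):
    values = np.asarray(values, float)
    if ids is None:
        ids = [str(i + 1) for i in range(len(values))]
    return UnivariateProfile(participant, area, values, ids)


def brute_force_select(a, b, base_a, base_b, condition, n_select):
    """Independent oracle: explicit filter then full sort with id tie-break."""
    rows = []
    for i in range(len(a.values)):
        va, vb = a.values[i], b.values[i]
        m = condition.margin
        ok_a = va > base_a + m if condition.drive_a else va < base_a - m
        ok_b = vb > base_b + m if condition.drive_b else vb < base_b - m
        if ok_a and ok_b:
            score = va + vb if condition.aligning else va - vb
            rows.append((score, a.image_ids[i]))
    desc = condition.label in ("drive_both", "drive_A_suppress_B")
    rows.sort(key=lambda t: ((-t[0] if desc else t[0]), t[1]))
    return [iid for _, iid in rows[:n_select]]


class TestBuildUnivariateNull:
    def test_constant_profile(self):
        null = build_univariate_null(prof([2.5] * 10), 3, 100, seed=0)
        assert np.all(null.sample_scores == 2.5)
        assert null.baseline_score == 2.5

    def test_single_sample_is_baseline(self):
        p = prof(np.arange(10.0))
        null = build_univariate_null(p, 4, 1, seed=3)
        assert null.baseline_score == pytest.approx(null.sample_scores[0])
        assert len(null.baseline_image_ids) == 4

    def test_outlier_profile_baseline_avoids_outlier(self):
        p = prof([0.0] * 9 + [10.0])
        null = build_univariate_null(p, 1, 5000, seed=1)
        # null mean ~ 1; a zero image (score 0) is closer than the 10
        assert null.baseline_score == 0.0

    def test_batch_too_large(self):
        with pytest.raises(ValueError):
            build_univariate_null(prof([1.0, 2.0]), 3, 10, 0)

    def test_reproducible(self):
        p = prof(np.random.default_rng(2).normal(size=100))
        a = build_univariate_null(p, 10, 2000, seed=9)
        b = build_univariate_null(p, 10, 2000, seed=9)
        assert np.array_equal(a.sample_scores, b.sample_scores)
        assert np.array_equal(a.baseline_image_ids, b.baseline_image_ids)


class TestSelectUnivariateControls:
    A = [0.0, 1.0, 2.0, -1.0, 0.5]
    B = [0.0, -1.0, 2.0, 1.0, 0.5]

    @pytest.mark.parametrize(
        "label,expected",
        [
            ("drive_both", ["3"]),
            ("drive_A_suppress_B", ["2"]),
            ("suppress_both", ["1"]),
        ],
    )
    def test_hand_worked_example(self, label, expected):
        sol = select_univariate_controls(
            prof(self.A, "A"), prof(self.B, "B"), 0.3, 0.3,
            UniControlCondition(label), n_select=1,
        )
        assert list(sol.image_ids) == expected

    def test_equal_areas_cannot_disentangle(self):
        a = prof([0.5, 1.0, -0.2], "A")
        b = prof([0.5, 1.0, -0.2], "B")
        sol = select_univariate_controls(
            a, b, 0.0, 0.0, UniControlCondition("drive_A_suppress_B"), 2
        )
        assert sol.n_selected == 0
        assert not sol.complete

    def test_zero_margin_drive_both_is_full_sort(self, rng):
        values = rng.normal(size=50)
        a, b = prof(values, "A"), prof(rng.normal(size=50), "B")
        cond = UniControlCondition("drive_both", margin=0.0)
        sol = select_univariate_controls(a, b, -10.0, -10.0, cond, 50)
        oracle = brute_force_select(a, b, -10.0, -10.0, cond, 50)
        assert list(sol.image_ids) == oracle
        assert np.all(np.diff(sol.selection_scores) <= 0)

    @pytest.mark.parametrize("label", CONDITIONS)
    def test_matches_brute_force_oracle(self, label, rng):
        for _ in range(10):
            a = prof(rng.normal(size=200), "A")
            b = prof(rng.normal(size=200), "B")
            cond = UniControlCondition(label)
            sol = select_univariate_controls(a, b, 0.1, -0.1, cond, 25)
            assert list(sol.image_ids) == brute_force_select(a, b, 0.1, -0.1, cond, 25)

    def test_disentangle_symmetry(self, rng):
        a = prof(rng.normal(size=100), "A")
        b = prof(rng.normal(size=100), "B")
        ab = select_univariate_controls(
            a, b, 0.0, 0.0, UniControlCondition("drive_A_suppress_B"), 25
        )
        ba = select_univariate_controls(
            b, a, 0.0, 0.0, UniControlCondition("drive_B_suppress_A"), 25
        )
        assert list(ab.image_ids) == list(ba.image_ids)


class TestCrossvalUnivariate:
    def test_identical_participants_identical_folds(self):
        base = np.linspace(-1, 1, 40)
        pa = [prof(base, "A", f"s{i}") for i in range(3)]
        pb = [prof(base[::-1].copy(), "B", f"s{i}") for i in range(3)]
        folds = crossval_univariate(
            pa, pb, UniControlCondition("drive_A_suppress_B"),
            n_select=5, batch_size=5, n_null_samples=500, seed=0,
        )
        ids = [tuple(f.image_ids) for f in folds]
        assert len(set(ids)) == 1

    def test_eight_participants_eight_folds(self, rng):
        pa = [prof(rng.normal(size=30), "A", f"s{i}") for i in range(8)]
        pb = [prof(rng.normal(size=30), "B", f"s{i}") for i in range(8)]
        folds = crossval_univariate(
            pa, pb, UniControlCondition("drive_both"),
            n_select=5, batch_size=5, n_null_samples=200, seed=0,
        )
        assert len(folds) == 8
        assert sorted(f.fold for f in folds) == [f"s{i}" for i in range(8)]

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            crossval_univariate(
                [prof([1.0, 2.0, 3.0])], [prof([1.0, 2.0, 3.0], "B")],
                UniControlCondition("drive_both"),
            )

    def test_heldout_control_generalizes_on_hierarchy(self, small_chain):
        """Disentangling V1 vs V4 holds up in held-out participants."""
        cfg, sets, _ = small_chain
        participants = sorted({p for p, _ in sets})
        pa = [univariate_profile(sets[(p, "V1")]) for p in participants]
        pb = [univariate_profile(sets[(p, "V4")]) for p in participants]
        folds = crossval_univariate(
            pa, pb, UniControlCondition("drive_A_suppress_B"),
            n_select=25, batch_size=25, n_null_samples=3000, seed=1,
        )
        hits = sum(
            f.eval["A"] > f.eval["baseline_A"] and f.eval["B"] < f.eval["baseline_B"]
            for f in folds
        )
        assert hits >= len(folds) - 1


class TestProfileCorrelation:
    def test_identity_and_negation(self, rng):
        p = prof(rng.normal(size=10))
        q = prof(-p.values, "B")
        assert profile_correlation(p, p) == pytest.approx(1.0)
        assert profile_correlation(p, q) == pytest.approx(-1.0)

    def test_hand_pearson(self):
        r = profile_correlation(prof([1, 2, 3]), prof([1, 2, 4], "B"))
        assert r == pytest.approx(0.981981, abs=1e-6)

    def test_zero_variance_nan_with_warning(self):
        with pytest.warns(UserWarning):
            r = profile_correlation(prof([1, 1, 1]), prof([1, 2, 3], "B"))
        assert np.isnan(r)

    def test_shared_image_subset(self):
        p = prof([1, 2, 3, 4], ids=["a", "b", "c", "d"])
        q = prof([1, 2, 3], "B", ids=["b", "c", "d"])
        assert profile_correlation(p, q) == pytest.approx(1.0)


class TestAggregation:
    def test_chain_grouping_sizes(self):
        g = stepwise_distance_grouping(["V1", "V2", "V3", "V4"])
        sizes = pd.Series(list(g.values())).value_counts().to_dict()
        assert sizes == {1: 3, 2: 2, 3: 1}

    def test_within_between_membership(self):
        g = within_between_grouping({"x": ("EBA", "FFA"), "y": ("PPA", "RSC")})
        within = {p for p, k in g.items() if k == "within"}
        assert within == {("EBA", "FFA"), ("PPA", "RSC")}
        assert sum(k == "between" for k in g.values()) == 4

    def test_constant_statistic(self):
        g = stepwise_distance_grouping(["V1", "V2", "V3", "V4"])
        stats = {pair: 3.25 for pair in g}
        agg = aggregate_by_pair_group(stats, g)
        assert np.allclose(agg.to_numpy(), 3.25)

    def test_unmapped_pair_raises(self):
        g = stepwise_distance_grouping(["V1", "V2"])
        with pytest.raises(ValueError, match="not mapped"):
            aggregate_by_pair_group({("V1", "V9"): 1.0}, g)

    def test_pair_order_irrelevant(self):
        g = stepwise_distance_grouping(["V1", "V2", "V3"])
        agg = aggregate_by_pair_group({("V2", "V1"): 2.0, ("V3", "V1"): 4.0}, g)
        assert agg.loc[1] == 2.0 and agg.loc[2] == 4.0


class TestSubsetContrast:
    def test_single_block_overall_mean(self, rng):
        resp = rng.normal(size=(4, 3))
        rs = ResponseSet("p", "a", resp, list("abcd"))
        out = subset_contrast(rs, ["all"] * 4, ["all"] * 3)
        assert out.loc["all", "all"] == pytest.approx(resp.mean())

    def test_two_by_two_cells(self):
        resp = np.array([[1.0, 2.0], [3.0, 4.0]])
        rs = ResponseSet("p", "a", resp, ["a", "b"])
        out = subset_contrast(rs, ["sky", "nosky"], ["lower", "upper"])
        assert out.loc["sky", "lower"] == 1.0
        assert out.loc["sky", "upper"] == 2.0
        assert out.loc["nosky", "lower"] == 3.0
        assert out.loc["nosky", "upper"] == 4.0

    def test_voxel_permutation_within_label(self, rng):
        resp = rng.normal(size=(3, 6))
        labels = np.array(["l", "u", "l", "u", "l", "u"])
        rs = ResponseSet("p", "a", resp, list("abc"))
        out1 = subset_contrast(rs, ["x"] * 3, labels)
        perm = [2, 1, 0, 3, 4, 5]  # swaps two "l" voxels
        rs2 = ResponseSet("p", "a", resp[:, perm], list("abc"))
        out2 = subset_contrast(rs2, ["x"] * 3, labels[perm])
        assert np.allclose(out1.to_numpy(), out2.to_numpy())

    def test_empty_block_nan_warning(self):
        rs = ResponseSet("p", "a", np.ones((2, 2)), ["a", "b"])
        with pytest.warns(UserWarning, match="empty block"):
            out = subset_contrast(
                rs, ["x", "x"], ["l", "u"], image_levels=["x", "y"]
            )
        assert np.isnan(out.loc["y", "l"])
        assert out.loc["x", "l"] == 1.0
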