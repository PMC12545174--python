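import itertools

import numpy as np
import pytest

from rnc.multivariate import (
    RSM,
    BatchSearchConfig,
    build_multivariate_null,
    compute_rsm,
    crossval_multivariate,
    rsa_score,
    search_controlling_batches,
)
from rnc.response_store import ResponseSet


def make_rs(responses, area="A", participant="p1"):
    responses = np.asarray(responses, float)
    ids = [f"i{k}" for k in range(responses.shape[0])]
    return ResponseSet(participant, area, responses, ids)


def exhaustive_best(rs_a, rs_b, batch_size, objective):
    """Oracle: score every possible batch with the scalar-path functions."""
    best_ids, best_key = None, np.inf
    for combo in itertools.combinations(rs_a.image_ids, batch_size):
        r = rsa_score(compute_rsm(rs_a, combo), compute_rsm(rs_b, combo)).r
        key = -r if objective == "align" else abs(r)
        if key < best_key:
            best_key, best_ids = key, combo
    return set(best_ids), best_key


class TestComputeRsm:
    def test_hand_two_voxel_patterns(self):
        rs = make_rs([[1, -1], [2, -2], [-1, 1]])
        rsm = compute_rsm(rs, rs.image_ids)
        expected = np.array([[1, 1, -1], [1, 1, -1], [-1, -1, 1]], float)
        assert np.allclose(rsm.matrix, expected)

    def test_unit_diagonal(self, rng):
        rs = make_rs(rng.normal(size=(6, 5)))
        rsm = compute_rsm(rs, rs.image_ids[:4])
        assert np.allclose(np.diag(rsm.matrix), 1.0)
        assert np.allclose(rsm.matrix, rsm.matrix.T)

    def test_duplicate_in_batch_rejected(self, rng):
        rs = make_rs(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError, match="duplicate"):
            compute_rsm(rs, ["i0", "i0", "i1"])

    def test_zero_variance_pattern_rejected(self):
        rs = make_rs([[1.0, 1.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            compute_rsm(rs, rs.image_ids)

    def test_voxel_permutation_invariance(self, rng):
        resp = rng.normal(size=(5, 6))
        a = compute_rsm(make_rs(resp), [f"i{k}" for k in range(5)])
        b = compute_rsm(
            make_rs(resp[:, rng.permutation(6)]), [f"i{k}" for k in range(5)]
        )
        assert np.allclose(a.matrix, b.matrix)

    def test_image_batch_permutation_equivariance(self, rng):
        rs = make_rs(rng.normal(size=(5, 4)))
        batch = list(rs.image_ids)
        perm = [3, 0, 4, 1, 2]
        a = compute_rsm(rs, batch)
        b = compute_rsm(rs, [batch[i] for i in perm])
        assert np.allclose(b.matrix, a.matrix[np.ix_(perm, perm)])


class TestRsaScore:
    def test_identical_rsms(self, rng):
        rs = make_rs(rng.normal(size=(6, 4)))
        rsm = compute_rsm(rs, rs.image_ids)
        assert rsa_score(rsm, rsm).r == pytest.approx(1.0)

    def test_hand_anticorrelated_triangles(self):
        ids = np.array(["a", "b", "c"], object)
        m1 = np.array([[1, 1, -1], [1, 1, -1], [-1, -1, 1]], float)
        m2 = np.array([[1, -1, 1], [-1, 1, 1], [1, 1, 1]], float)
        r = rsa_score(RSM(ids, m1), RSM(ids, m2)).r
        assert r == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self, rng):
        a = compute_rsm(make_rs(rng.normal(size=(6, 4))), [f"i{k}" for k in range(6)])
        b = compute_rsm(
            make_rs(rng.normal(size=(6, 4)), "B"), [f"i{k}" for k in range(6)]
        )
        assert rsa_score(a, b).r == pytest.approx(rsa_score(b, a).r)

    def test_degenerate_batch_of_two(self):
        ids = np.array(["a", "b"], object)
        m = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.warns(UserWarning, match="constant"):
            r = rsa_score(RSM(ids, m), RSM(ids, m)).r
        assert np.isnan(r)


class TestBuildMultivariateNull:
    def test_identical_areas_score_one(self, rng):
        resp = rng.normal(size=(20, 5))
        null = build_multivariate_null(
            make_rs(resp, "A"), make_rs(resp, "B"), 5, 50, seed=0
        )
        assert np.allclose(null.sample_scores, 1.0)
        assert null.baseline_score == pytest.approx(1.0)

    def test_single_sample_is_baseline(self, rng):
        null = build_multivariate_null(
            make_rs(rng.normal(size=(10, 4))),
            make_rs(rng.normal(size=(10, 4)), "B"),
            4, 1, seed=5,
        )
        assert null.baseline_score == pytest.approx(null.sample_scores[0])

    def test_null_mean_matches_exhaustive_enumeration(self, rng):
        rs_a = make_rs(rng.normal(size=(6, 4)))
        rs_b = make_rs(rng.normal(size=(6, 4)), "B")
        exhaustive = [
            rsa_score(compute_rsm(rs_a, c), compute_rsm(rs_b, c)).r
            for c in itertools.combinations(rs_a.image_ids, 3)
        ]
        null = build_multivariate_null(rs_a, rs_b, 3, 4000, seed=2)
        assert null.null_mean == pytest.approx(np.mean(exhaustive), abs=0.05)

    def test_reproducible(self, rng):
        rs_a = make_rs(rng.normal(size=(12, 4)))
        rs_b = make_rs(rng.normal(size=(12, 4)), "B")
        a = build_multivariate_null(rs_a, rs_b, 4, 300, seed=7)
        b = build_multivariate_null(rs_a, rs_b, 4, 300, seed=7)
        assert np.array_equal(a.baseline_image_ids, b.baseline_image_ids)


def small_cfg(objective, generations=10, seed=0):
    return BatchSearchConfig(
        population=80, batch_size=4, n_elite=10,
        mutation_counts=(1, 2, 3), n_random=40,
        generations=generations, objective=objective, seed=seed,
    )


class TestSearchControllingBatches:
    def test_identical_areas_align_immediately(self, rng):
        resp = rng.normal(size=(12, 5))
        _, score, trace = search_controlling_batches(
            make_rs(resp, "A"), make_rs(resp, "B"), small_cfg("align", 1)
        )
        assert score == pytest.approx(1.0)

    def test_trace_monotone_both_objectives(self, rng):
        rs_a = make_rs(rng.normal(size=(15, 5)))
        rs_b = make_rs(rng.normal(size=(15, 5)), "B")
        _, _, t_align = search_controlling_batches(
            rs_a, rs_b, small_cfg("align", 12)
        )
        assert np.all(np.diff(t_align) >= 0)
        _, _, t_dis = search_controlling_batches(
            rs_a, rs_b, small_cfg("disentangle", 12)
        )
        assert np.all(np.diff(np.abs(t_dis)) <= 0)

    def test_finds_exhaustive_optimum_small_pool(self, rng):
        rs_a = make_rs(rng.normal(size=(10, 5)))
        rs_b = make_rs(rng.normal(size=(10, 5)), "B")
        oracle_ids, _ = exhaustive_best(rs_a, rs_b, 4, "align")
        batch, score, _ = search_controlling_batches(
            rs_a, rs_b, small_cfg("align", 15, seed=3)
        )
        assert set(batch) == oracle_ids

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError, match="population"):
            BatchSearchConfig(population=100, n_elite=10, n_random=10,
                              mutation_counts=(1, 2), batch_size=4)

    def test_deterministic_given_seed(self, rng):
        rs_a = make_rs(rng.normal(size=(12, 5)))
        rs_b = make_rs(rng.normal(size=(12, 5)), "B")
        b1, s1, _ = search_controlling_batches(rs_a, rs_b, small_cfg("align", 5, 1))
        b2, s2, _ = search_controlling_batches(rs_a, rs_b, small_cfg("align", 5, 1))
        assert list(b1) == list(b2) and s1 == s2


class TestCrossvalMultivariate:
    def test_identical_participants_eval_equals_train(self, rng):
        resp_a, resp_b = rng.normal(size=(12, 5)), rng.normal(size=(12, 5))
        sets_a = [make_rs(resp_a, "A", f"s{i}") for i in range(3)]
        sets_b = [make_rs(resp_b, "B", f"s{i}") for i in range(3)]
        folds = crossval_multivariate(sets_a, sets_b, small_cfg("align", 5))
        for f in folds:
            assert f["eval_score"] == pytest.approx(f["train_score"], abs=1e-9)

    def test_fold_count_matches_participants(self, rng):
        sets_a = [make_rs(rng.normal(size=(10, 4)), "A", f"s{i}") for i in range(4)]
        sets_b = [make_rs(rng.normal(size=(10, 4)), "B", f"s{i}") for i in range(4)]
        folds = crossval_multivariate(sets_a, sets_b, small_cfg("align", 3))
        assert [f["fold"] for f in folds] == [f"s{i}" for i in range(4)]

    def test_too_few_participants(self, rng):
        with pytest.raises(ValueError):
            crossval_multivariate(
                [make_rs(rng.normal(size=(8, 3)))],
                [make_rs(rng.normal(size=(8, 3)), "B")],
                small_cfg("align", 2),
            )

    def test_align_beats_baseline_on_grouped_cortex(self, grouped_cortex):
        """Aligned batches beat the random-batch baseline in held-out data."""
        _, sets, _ = grouped_cortex
        participants = sorted({p for p, _ in sets})
        sets_a = [sets[(p, "EBA")] for p in participants]
        sets_b = [sets[(p, "PPA")] for p in participants]
        cfg = BatchSearchConfig(
            population=80, batch_size=25, n_elite=10,
            mutation_counts=(1, 5, 12), n_random=40,
            generations=8, objective="align", seed=2,
        )
        folds = crossval_multivariate(sets_a, sets_b, cfg, null_samples=300)
        hits = sum(
            f["eval_score"] > f["baseline_eval_score"] for f in folds
        )
        assert hits == len(folds)
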