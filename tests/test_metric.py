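import numpy as np
import pytest
from scipy import stats

from otfrm import (
    FeatureSpace,
    OTConfig,
    SyntheticSpaceSpec,
    TaskEmbeddingSet,
    adaptability_correlation,
    generate_feature_space,
    generate_stage_snapshots,
    inter_task_similarity,
    intra_task_similarity,
    otfrm_report,
    otfrm_score,
    pairwise_distance_matrix,
    rank_transfer_sources,
    spearman_rho,
    stage_comparison,
    wasserstein_p,
    simulate_adaptation_outcomes,
)
from otfrm.exceptions import IllConditionedRatioError, UndefinedStatisticError

S2 = np.sqrt(2) / 2


class TestIntraTaskSimilarity:
    def test_identical_vectors_give_one(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        assert intra_task_similarity(X) == pytest.approx(1.0)

    def test_two_orthogonal_vectors_give_zero(self):
        assert intra_task_similarity(np.eye(2)) == pytest.approx(0.0, abs=1e-12)

    def test_three_vector_enumeration(self):
        # pairs: (e1,e2)=0, (e1,diag)=s2, (e2,diag)=s2 -> mean = 2*s2/3
        X = np.array([[1.0, 0.0], [0.0, 1.0], [S2, S2]])
        assert intra_task_similarity(X) == pytest.approx(2 * S2 / 3, abs=1e-9)

    def test_single_sample_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            intra_task_similarity(np.array([[1.0, 0.0]]))

    def test_bounded_in_unit_interval(self, rng):
        v = intra_task_similarity(rng.standard_normal((30, 6)))
        assert -1.0 <= v <= 1.0


class TestInterTaskSimilarity:
    def test_identical_tasks_give_one(self, rng, exact_cfg):
        X = rng.standard_normal((5, 3))
        fs = FeatureSpace(
            [
                TaskEmbeddingSet(task_id="a", embeddings=X),
                TaskEmbeddingSet(task_id="b", embeddings=X.copy()),
            ]
        )
        assert inter_task_similarity("a", fs, exact_cfg) == pytest.approx(1.0, abs=1e-9)

    def test_singleton_orthogonal_tasks_give_zero(self, tri_space, exact_cfg):
        fs = FeatureSpace(tri_space.tasks[:2])
        assert inter_task_similarity("task1", fs, exact_cfg) == pytest.approx(0.0, abs=1e-12)

    def test_three_singleton_tasks_average(self, tri_space, exact_cfg):
        # task3 at 45 deg from both: mean OT similarity = s2
        assert inter_task_similarity("task3", tri_space, exact_cfg) == pytest.approx(S2, abs=1e-9)

    def test_single_task_space_is_undefined(self):
        fs = FeatureSpace([TaskEmbeddingSet(task_id="a", embeddings=[[1.0, 0.0]])])
        with pytest.raises(UndefinedStatisticError):
            inter_task_similarity("a", fs)


class TestOTFRMScore:
    def test_duplicated_points_and_45_degree_neighbours(self, exact_cfg):
        # task3 holds two copies of the diagonal vector: intra = 1;
        # inter = s2 (45 degrees to both axes tasks) -> score = 1/s2
        fs = FeatureSpace(
            [
                TaskEmbeddingSet(task_id="task1", embeddings=[[1.0, 0.0]]),
                TaskEmbeddingSet(task_id="task2", embeddings=[[0.0, 1.0]]),
                TaskEmbeddingSet(task_id="task3", embeddings=[[S2, S2], [S2, S2]]),
            ]
        )
        assert otfrm_score("task3", fs, exact_cfg) == pytest.approx(1 / S2, abs=1e-9)

    def test_identical_tasks_score_one(self, rng, exact_cfg):
        X = rng.standard_normal((4, 3)) + 0.5
        fs = FeatureSpace(
            [TaskEmbeddingSet(task_id=f"t{k}", embeddings=X.copy()) for k in range(3)]
        )
        assert otfrm_score("t0", fs, exact_cfg) == pytest.approx(
            intra_task_similarity(X) / 1.0, abs=1e-9
        )

    def test_near_zero_denominator_raises_with_components(self, exact_cfg):
        fs = FeatureSpace(
            [
                TaskEmbeddingSet(task_id="a", embeddings=[[1.0, 0.0], [1.0, 0.0]]),
                TaskEmbeddingSet(task_id="b", embeddings=[[0.0, 1.0]]),
            ]
        )
        with pytest.raises(IllConditionedRatioError) as err:
            otfrm_score("a", fs, exact_cfg)
        assert err.value.numerator == pytest.approx(1.0)
        assert err.value.denominator == pytest.approx(0.0, abs=1e-12)


class TestPairwiseDistances:
    def test_identical_tasks_all_zero(self, rng, exact_cfg):
        X = rng.standard_normal((4, 3))
        fs = FeatureSpace(
            [TaskEmbeddingSet(task_id=f"t{k}", embeddings=X.copy()) for k in range(2)]
        )
        np.testing.assert_allclose(pairwise_distance_matrix(fs, exact_cfg), 0.0, atol=1e-9)

    def test_singleton_orthogonal_tasks(self, tri_space, exact_cfg):
        fs = FeatureSpace(tri_space.tasks[:2])
        D = pairwise_distance_matrix(fs, exact_cfg)
        np.testing.assert_allclose(D, [[0.0, 1.0], [1.0, 0.0]], atol=1e-12)

    def test_matrix_matches_elementwise_recomputation(self, exact_cfg):
        spec = SyntheticSpaceSpec(K=3, m=6, d=4, delta=1.5, seed=3)
        fs = generate_feature_space(spec)
        D = pairwise_distance_matrix(fs, exact_cfg)
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
        for k in range(3):
            for l in range(3):
                expected = (
                    0.0
                    if k == l
                    else wasserstein_p(
                        fs.tasks[k].embeddings, fs.tasks[l].embeddings, exact_cfg
                    )
                )
                assert D[k, l] == pytest.approx(expected, abs=1e-9)

    def test_report_consistent_with_components(self, small_space, exact_cfg):
        report = otfrm_report(small_space, exact_cfg)
        D = report.pairwise_distance
        assert np.allclose(D, D.T, atol=1e-8)
        for k, tid in enumerate(report.task_ids):
            entry = report.per_task[tid]
            assert -1.0 <= entry["intra_sim"] <= 1.0
            assert -1.0 <= entry["inter_sim"] <= 1.0
            inter = float(np.mean(np.delete(1.0 - D[k], k)))
            assert entry["inter_sim"] == pytest.approx(inter, abs=1e-12)
            assert entry["otfrm"] == pytest.approx(entry["intra_sim"] / inter, abs=1e-9)


class TestStageComparison:
    def test_identical_snapshots_give_unit_ratios(self, default_spec):
        fs = generate_feature_space(default_spec)
        snaps = {s: fs for s in ("randomly_initialized", "pretrained", "fine_tuned")}
        comparison = stage_comparison(snaps)
        for entry in comparison.per_task.values():
            assert entry["ratio_PT_over_RI"] == pytest.approx(1.0)
            assert entry["ratio_FT_over_PT"] == pytest.approx(1.0)

    def test_monotone_under_growing_separation(self):
        # m large enough that sampling noise does not swamp the 0 -> 1
        # separation signal in the intra/inter estimates
        spec = SyntheticSpaceSpec(K=4, m=40, d=16, seed=5)
        snaps = generate_stage_snapshots(spec, (0.0, 1.0, 4.0))
        comparison = stage_comparison(snaps)
        for entry in comparison.per_task.values():
            assert entry["otfrm_RI"] <= entry["otfrm_PT"] <= entry["otfrm_FT"]

    def test_missing_stage_is_an_input_error(self, default_spec):
        fs = generate_feature_space(default_spec)
        with pytest.raises(ValueError, match="fine_tuned"):
            stage_comparison({"randomly_initialized": fs, "pretrained": fs})

    def test_mismatched_task_sets_rejected(self, default_spec):
        fs = generate_feature_space(default_spec)
        other = FeatureSpace(fs.tasks[:-1])
        with pytest.raises(ValueError, match="task_ids"):
            stage_comparison(
                {"randomly_initialized": fs, "pretrained": fs, "fine_tuned": other}
            )


class TestSpearman:
    def test_perfect_anti_monotone(self):
        d = np.array([0.1, 0.5, 0.9, 1.4])
        assert spearman_rho(d, -2 * d + 1) == pytest.approx(-1.0)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    @pytest.mark.parametrize("seed", [0, 2, 9])
    def test_matches_scipy_with_and_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=25).astype(float)  # forces ties
        y = rng.standard_normal(25)
        expected = stats.spearmanr(x, y).statistic
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)

    def test_simulated_adaptation_matches_brute_force_ranks(self):
        rng = np.random.default_rng(2)
        distances = rng.uniform(0, 2, size=30)
        deltas = simulate_adaptation_outcomes(distances, slope=-1.0, noise_sd=0.1, seed=2)
        rho, n = adaptability_correlation(distances, deltas)
        assert n == 30
        # brute-force: sort-based ranks (no ties here), Pearson on ranks
        rx = np.argsort(np.argsort(distances)).astype(float)
        ry = np.argsort(np.argsort(deltas)).astype(float)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(brute, abs=1e-12)
        assert rho < -0.9  # low noise, strong negative slope


class TestSourceRanking:
    def test_two_task_space_returns_the_other(self, rng):
        fs = FeatureSpace(
            [
                TaskEmbeddingSet(task_id="a", embeddings=rng.standard_normal((3, 2))),
                TaskEmbeddingSet(task_id="b", embeddings=rng.standard_normal((3, 2))),
            ]
        )
        assert rank_transfer_sources("a", fs) == ["b"]

    def test_distance_sorted_order(self, tri_space, exact_cfg):
        # distances from task1: task3 at 1-s2 (~0.29), task2 at 1.0
        assert rank_transfer_sources("task1", tri_space, exact_cfg) == ["task3", "task2"]

    def test_order_equals_argsort_of_distance_row(self, exact_cfg):
        spec = SyntheticSpaceSpec(K=4, m=8, d=6, delta=2.0, seed=9)
        fs = generate_feature_space(spec)
        D = pairwise_distance_matrix(fs, exact_cfg)
        target_idx = 0
        others = np.delete(np.arange(fs.K), target_idx)
        expected = [fs.task_ids[i] for i in others[np.argsort(D[target_idx][others], kind="stable")]]
        assert rank_transfer_sources(fs.task_ids[target_idx], fs, exact_cfg) == expected

    def test_unknown_target_rejected(self, tri_space):
        with pytest.raises(KeyError):
            rank_transfer_sources("nope", tri_space)
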