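"""Latent-trajectory clustering, scree/covariance diagnostics, CP-ALS
comparator, cluster overlap and clinical ANOVA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from pdmdc import (
    ClinicalTable,
    ResponseTensor,
    compute_shared_basis,
    extract_state_trajectories,
    fit_shared_latent,
    generate_population,
    preset,
    standardize_per_diet,
    subtract_baseline,
)
from pdmdc.metabotyping import (
    CPModel,
    SimilarityMatrix,
    StateTrajectorySet,
    anova_association,
    check_two_factor_degeneracy,
    cluster_cp_scores,
    cluster_overlap,
    cluster_similarity,
    cosine_similarity_matrix,
    cp_als,
    cp_reconstruct,
    dynamical_class_profiles,
    profile_correlation,
    scree_inflection,
)


@pytest.fixture(scope="module")
def two_cluster_case():
    """Small two-cluster population with its shared-basis trajectories."""
    spec = preset("metabotype-100", M=25, I=30, seed=2)
    tensor, diets, gt = generate_population(spec)
    proc = subtract_baseline(tensor)
    proc, _ = standardize_per_diet(proc)
    basis = compute_shared_basis(proc, 4)
    models = fit_shared_latent(proc, diets, basis)
    ts = extract_state_trajectories(models, diets, proc.n_times)
    return ts, gt


class TestCosineSimilarity:
    def test_trajectory_array_shape_matches_design(self, two_cluster_case):
        ts, _ = two_cluster_case
        assert ts.trajectories.shape == (4, 8, 30, 3)

    def test_identical_and_negated_trajectories(self):
        base = np.array([1.0, 2.0, 0.5, -1.0])
        traj = np.zeros((1, 4, 3, 1))
        traj[0, :, 0, 0] = base
        traj[0, :, 1, 0] = base
        traj[0, :, 2, 0] = -base
        ts = StateTrajectorySet(traj, ["a", "b", "c"], ["d"])
        sim = cosine_similarity_matrix(ts, 0, 0)
        assert sim.values[0, 1] == pytest.approx(1.0)
        assert sim.values[0, 2] == pytest.approx(-1.0)

    def test_hand_computed_pair(self):
        traj = np.zeros((1, 2, 2, 1))
        traj[0, :, 0, 0] = [1.0, 0.0]
        traj[0, :, 1, 0] = [1.0, 1.0]
        ts = StateTrajectorySet(traj, ["a", "b"], ["d"])
        sim = cosine_similarity_matrix(ts, 0, 0)
        assert sim.values[0, 1] == pytest.approx(0.70710678, abs=1e-8)

    def test_zero_norm_trajectory_named(self):
        traj = np.ones((1, 3, 2, 1))
        traj[0, :, 1, 0] = 0.0
        ts = StateTrajectorySet(traj, ["a", "b"], ["d"])
        with pytest.raises(ValueError, match="'b'"):
            cosine_similarity_matrix(ts, 0, 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_structural_invariants_on_random_trajectories(self, seed):
        rng = np.random.default_rng(seed)
        traj = rng.standard_normal((2, 6, 5, 2))
        ts = StateTrajectorySet(traj, [f"i{k}" for k in range(5)], ["a", "b"])
        sim = cosine_similarity_matrix(ts, rng.integers(2), rng.integers(2))
        np.testing.assert_allclose(sim.values, sim.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)
        assert np.all(np.abs(sim.values) <= 1 + 1e-12)


class TestClusterSimilarity:
    def test_block_diagonal_similarity_recovered(self):
        sim_values = np.full((6, 6), 0.05)
        sim_values[:3, :3] = 0.95
        sim_values[3:, 3:] = 0.95
        np.fill_diagonal(sim_values, 1.0)
        sim = SimilarityMatrix(sim_values, 0, "d", [f"i{k}" for k in range(6)])
        labels = cluster_similarity(sim, 2)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_k_equal_to_I_gives_singletons(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(-0.5, 0.5, (4, 4))
        values = np.clip((raw + raw.T) / 2, -1, 1)
        np.fill_diagonal(values, 1.0)
        sim = SimilarityMatrix(values, 0, "d", list("abcd"))
        assert sorted(cluster_similarity(sim, 4)) == [0, 1, 2, 3]

    def test_planted_clusters_fully_recovered(self, two_cluster_case):
        ts, gt = two_cluster_case
        aris = []
        for s in range(ts.S):
            for d in range(len(ts.diet_ids)):
                labels = cluster_similarity(cosine_similarity_matrix(ts, s, d), 2)
                aris.append(adjusted_rand_score(gt.cluster_labels, labels))
        assert max(aris) == 1.0

    def test_k_above_I_rejected(self):
        sim = SimilarityMatrix(np.eye(3), 0, "d", list("abc"))
        with pytest.raises(ValueError):
            cluster_similarity(sim, 5)


def brute_force_knee(spectrum):
    """Independent scan: index of the largest second difference of the
    normalized spectrum."""
    s = np.asarray(spectrum) / spectrum[0]
    best, arg = -np.inf, None
    for k in range(1, len(s) - 1):
        d2 = s[k - 1] - 2 * s[k] + s[k + 1]
        if d2 > best:
            best, arg = d2, k
    return arg


class TestScreeInflection:
    def test_worked_spectrum_gives_four(self):
        S, _ = scree_inflection(np.array([10, 8, 6, 4, 0.1, 0.09, 0.08]))
        assert S == 4

    def test_exact_rank_spectrum(self):
        S, _ = scree_inflection(np.array([3.0, 2.0, 1.0, 0.0, 0.0, 0.0]))
        assert S == 3

    def test_geometric_decay_warns_weak_and_matches_bruteforce(self):
        spectrum = 10.0 * 0.9 ** np.arange(12)
        with pytest.warns(UserWarning, match="weak inflection"):
            S, info = scree_inflection(spectrum)
        assert info["weak_inflection"]
        assert S == brute_force_knee(spectrum)

    def test_short_spectrum_rejected(self):
        with pytest.raises(ValueError):
            scree_inflection(np.array([2.0, 1.0]))


class TestDynamicalClasses:
    def _template_tensor(self, rng, n_per=6):
        t = np.arange(8.0)
        templates = np.vstack([np.exp(-t / 2.0), np.sin(t / 2.0)])
        rows = []
        for tpl in templates:
            for _ in range(n_per):
                rows.append(tpl * rng.uniform(0.5, 2.0) + 1e-4 * rng.standard_normal(8))
        values = np.asarray(rows)[:, :, None, None]
        return ResponseTensor(values, [f"m{k}" for k in range(len(rows))],
                              range(8), ["i"], ["d"]), len(templates), templates

    def test_template_metabolites_grouped_exactly(self, rng):
        tensor, S, _ = self._template_tensor(rng)
        labels, _ = dynamical_class_profiles(tensor, S)
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_group_means_correlate_with_templates(self, rng):
        tensor, S, templates = self._template_tensor(rng)
        labels, profiles = dynamical_class_profiles(tensor, S)
        for tpl in templates:
            assert max(profile_correlation(tpl, pr) for pr in profiles) > 0.99

    def test_single_group_returns_grand_mean_profile(self, rng):
        tensor, _, _ = self._template_tensor(rng)
        labels, profiles = dynamical_class_profiles(tensor, 1)
        assert set(labels) == {0}
        np.testing.assert_allclose(profiles[0], tensor.values.mean(axis=(2, 3)).mean(axis=0))

    def test_constant_profile_rejected(self):
        values = np.ones((2, 5, 1, 1))
        values[0, :, 0, 0] = np.arange(5.0)
        tensor = ResponseTensor(values, ["m0", "mflat"], range(5), ["i"], ["d"])
        with pytest.raises(ValueError, match="mflat"):
            dynamical_class_profiles(tensor, 2)


class TestProfileCorrelation:
    def test_self_correlation_is_one(self, rng):
        a = rng.standard_normal(8)
        assert profile_correlation(a, a) == pytest.approx(1.0)

    def test_negative_affine_map_gives_minus_one(self, rng):
        a = rng.standard_normal(8)
        assert profile_correlation(a, -2.0 * a + 3.0) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        rho = profile_correlation(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0]))
        assert rho == pytest.approx(0.98198, abs=1e-5)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            profile_correlation(np.ones(4), np.arange(4.0))


def _planted_cp_tensor(rng, F, shape=(6, 5, 4, 3)):
    factors = [rng.standard_normal((dim, F)) for dim in shape]
    return cp_reconstruct(factors), factors


def _congruence(est, true):
    """Best per-mode factor match (absolute cosine) after greedy
    permutation alignment on the combined congruence."""
    F = true[0].shape[1]
    norm = lambda f: f / np.linalg.norm(f, axis=0)
    prod = np.ones((F, F))
    for e, t in zip(est, true):
        prod *= norm(e).T @ norm(t)
    from scipy.optimize import linear_sum_assignment
    rows, cols = linear_sum_assignment(-np.abs(prod))
    return np.abs(prod[rows, cols])


class TestCPALS:
    def test_rank1_tensor_recovered(self, rng):
        tensor, factors = _planted_cp_tensor(rng, 1)
        model = cp_als(tensor, 1, n_starts=2, seed=0)
        assert model.explained_variance > 0.99999
        assert _congruence(model.factors, factors).min() > 0.9999

    def test_rank2_tensor_factor_congruence(self, rng):
        tensor, factors = _planted_cp_tensor(rng, 2)
        model = cp_als(tensor, 2, n_starts=4, seed=0)
        assert _congruence(model.factors, factors).min() > 0.99

    def test_objective_monotone_nonincreasing(self, rng):
        tensor = rng.standard_normal((5, 4, 3, 3))
        model = cp_als(tensor, 2, n_starts=1, max_iter=40, seed=1)
        hist = model.objective_history
        assert np.all(np.diff(hist) <= 1e-12)

    def test_explained_variance_in_unit_interval(self, rng):
        tensor = rng.standard_normal((4, 4, 3, 2))
        model = cp_als(tensor, 2, n_starts=1, seed=2)
        assert 0.0 <= model.explained_variance <= 1.0


def _model_from_factors(factors):
    return CPModel(factors[0], factors[1], factors[2], factors[3],
                   F=factors[0].shape[1], explained_variance=1.0,
                   converged=True, objective_history=np.zeros(1))


class TestDegeneracyCheck:
    def _orthogonal_model(self, rng):
        factors = [np.linalg.qr(rng.standard_normal((6, 2)))[0] for _ in range(4)]
        return _model_from_factors(factors)

    def _degenerate_model(self, rng, triple=-0.95):
        """Two components with per-mode cosines whose product is `triple`."""
        mag = (-triple) ** (1 / 4)  # |cosine| per mode; one mode negative
        factors = []
        for mode in range(4):
            c = -mag if mode == 0 else mag
            u = np.zeros(6)
            u[0] = 1.0
            v = np.zeros(6)
            v[0], v[1] = c, np.sqrt(1 - c * c)
            factors.append(np.column_stack([u, v]))
        return _model_from_factors(factors)

    def test_orthogonal_factors_not_degenerate(self, rng):
        assert not check_two_factor_degeneracy(self._orthogonal_model(rng))

    def test_constructed_degenerate_pair_detected(self, rng):
        model = self._degenerate_model(rng)
        assert check_two_factor_degeneracy(model, threshold=0.85)

    def test_threshold_one_never_fires(self, rng):
        assert not check_two_factor_degeneracy(self._degenerate_model(rng), threshold=1.0)

    def test_single_component_never_degenerate(self, rng):
        factors = [rng.standard_normal((5, 1)) for _ in range(4)]
        assert not check_two_factor_degeneracy(_model_from_factors(factors))


class TestClusterCPScores:
    def test_separated_blobs_recovered(self, rng):
        scores = np.vstack([rng.normal(0, 0.1, (8, 2)), rng.normal(5, 0.1, (7, 2))])
        model = _model_from_factors([rng.standard_normal((4, 2)),
                                     rng.standard_normal((5, 2)),
                                     scores,
                                     rng.standard_normal((3, 2))])
        labels = cluster_cp_scores(model, 2, seed=0)
        truth = np.array([0] * 8 + [1] * 7)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_one_single_label(self, rng):
        model = _model_from_factors([rng.standard_normal((3, 2)) for _ in range(4)])
        assert set(cluster_cp_scores(model, 1)) == {0}

    def test_planted_population_scores_recover_ground_truth(self):
        spec = preset("metabotype-100", M=25, I=30, seed=2)
        tensor, diets, gt = generate_population(spec)
        proc = subtract_baseline(tensor)
        proc, _ = standardize_per_diet(proc)
        M = proc.n_metabolites
        scaled = proc.values / proc.values.reshape(M, -1).std(
            axis=1, ddof=1)[:, None, None, None]
        model = cp_als(scaled, 5, n_starts=3, seed=2)
        labels = cluster_cp_scores(model, 2, seed=2, normalize=True)
        assert adjusted_rand_score(gt.cluster_labels, labels) == 1.0


class TestClusterOverlap:
    def test_identical_labelings(self):
        labels = np.array([0, 0, 1, 1, 2])
        assert cluster_overlap(labels, labels)["percent"] == 100.0

    def test_renamed_labels_still_full_overlap(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([2, 2, 0, 0, 1, 1])
        out = cluster_overlap(a, b)
        assert out["percent"] == 100.0 and out["ari"] == 1.0

    def test_single_disagreement_among_17(self):
        a = np.array([0] * 9 + [1] * 8)
        b = a.copy()
        b[0] = 1
        assert cluster_overlap(a, b)["percent"] == pytest.approx(100 * 16 / 17)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_overlap(np.zeros(3), np.zeros(4))

    def test_invariant_to_relabeling_both_sides(self, rng):
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        base = cluster_overlap(a, b)["percent"]
        assert cluster_overlap((a + 1) % 3, b)["percent"] == pytest.approx(base)


class TestAnovaAssociation:
    def _table(self, values, names=None):
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        names = names or [f"c{k}" for k in range(values.shape[1])]
        return ClinicalTable(values, names, [f"i{k}" for k in range(values.shape[0])])

    def test_identical_groups_give_F0_p1(self):
        labels = np.array([0, 0, 1, 1])
        out = anova_association(labels, self._table([5.0, 5.0, 5.0, 5.0]))
        assert out[0]["F"] == 0.0 and out[0]["p"] == 1.0

    def test_strongly_separated_groups_highly_significant(self, rng):
        g0 = rng.normal(0.0, 1.0, 8)
        g1 = rng.normal(10.0, 1.0, 8)
        labels = np.array([0] * 8 + [1] * 8)
        out = anova_association(labels, self._table(np.concatenate([g0, g1])))
        assert out[0]["p"] < 1e-6
        # closed-form F oracle
        from scipy.stats import f_oneway
        F_ref, p_ref = f_oneway(g0, g1)
        assert out[0]["F"] == pytest.approx(F_ref)
        assert out[0]["p"] == pytest.approx(p_ref)

    def test_measure_missing_in_one_cluster_skipped(self, rng):
        labels = np.array([0, 0, 0, 1, 1, 1])
        values = rng.standard_normal((6, 2))
        values[3:, 1] = np.nan
        with pytest.warns(UserWarning, match="skipped"):
            out = anova_association(labels, self._table(values, ["ok", "gone"]))
        assert [r["measure"] for r in out] == ["ok"]
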