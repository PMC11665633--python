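import numpy as np
import pytest

from ldamark import (
    AbundanceTable,
    EffectRecord,
    LDAFit,
    MarkerResult,
    PipelineConfig,
    SampleGroups,
    ValidationError,
    bootstrap_lda_reference,
    compute_effect_sizes,
    filter_degenerate,
    find_markers,
    fit_two_class_lda,
    normalize_per_million,
    score_and_threshold,
)
from ldamark.lda_effect import SingularScatterError


def _pair(values, n_a, n_b, **kwargs):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = [f"s{j}" for j in range(values.shape[1])]
    table = AbundanceTable(values, [f"f{i}" for i in range(values.shape[0])], ids)
    groups = SampleGroups(ids, ["A"] * n_a + ["B"] * n_b, **kwargs)
    return table, groups


class TestNormalize:
    def test_proportional_rescale(self):
        table = AbundanceTable([[0.2], [0.8]], ["f1", "f2"], ["s1"])
        out = normalize_per_million(table)
        np.testing.assert_allclose(out.values[:, 0], [200000.0, 800000.0])

    def test_columns_sum_to_constant(self):
        rng = np.random.default_rng(0)
        table = AbundanceTable(
            rng.lognormal(size=(20, 10)),
            [f"f{i}" for i in range(20)],
            [f"s{j}" for j in range(10)],
        )
        out = normalize_per_million(table)
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_column_named(self):
        table = AbundanceTable([[1.0, 0.0]], ["f1"], ["good", "bad"])
        with pytest.raises(ValidationError, match="bad"):
            normalize_per_million(table)


class TestFilterDegenerate:
    def test_all_zero_dropped(self):
        table = AbundanceTable(
            [[0.0, 0.0], [1.0, 2.0]], ["dead", "alive"], ["s1", "s2"]
        )
        out, dropped = filter_degenerate(table)
        assert dropped == ["dead"]
        assert out.feature_ids == ["alive"]

    def test_constant_dropped(self):
        table = AbundanceTable(
            [[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]], ["const", "varies"], ["s1", "s2", "s3"]
        )
        _, dropped = filter_degenerate(table)
        assert dropped == ["const"]

    def test_duplicate_keeps_first(self):
        table = AbundanceTable(
            [[1.0, 2.0], [1.0, 2.0], [2.0, 1.0]], ["first", "second", "other"], ["s1", "s2"]
        )
        out, dropped = filter_degenerate(table)
        assert dropped == ["second"]
        assert out.feature_ids == ["first", "other"]

    def test_full_rank_unchanged(self):
        table = AbundanceTable([[1.0, 2.0], [2.0, 1.0]], ["f1", "f2"], ["s1", "s2"])
        out, dropped = filter_degenerate(table)
        assert dropped == []
        np.testing.assert_array_equal(out.values, table.values)

    def test_all_dropped_is_error(self):
        table = AbundanceTable([[1.0, 1.0]], ["f1"], ["s1", "s2"])
        with pytest.raises(ValidationError, match="all features"):
            filter_degenerate(table)


class TestFitTwoClassLDA:
    def test_closed_form_2d(self):
        # class0 = {(1,0),(-1,0),(0,1),(0,-1)} + 1, class1 = {(5,0),(3,0),(4,1),(4,-1)} + 1
        # (shift keeps values nonnegative; scatter and mean difference unchanged)
        vals = np.array(
            [[1, -1, 0, 0, 5, 3, 4, 4], [0, 0, 1, -1, 0, 0, 1, -1]], dtype=float
        ) + 1.0
        table, groups = _pair(vals, 4, 4)
        fit = fit_two_class_lda(table, groups)
        np.testing.assert_allclose(np.abs(fit.w_unit), [1.0, 0.0], atol=1e-12)
        assert fit.delta_ld == pytest.approx(4.0, abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(size=(3, 12))
        table, groups = _pair(vals, 6, 6)
        _, swapped = _pair(vals, 6, 6, reference_level="B")
        fit1 = fit_two_class_lda(table, groups)
        fit2 = fit_two_class_lda(table, swapped)
        np.testing.assert_allclose(np.abs(fit1.w_unit), np.abs(fit2.w_unit), atol=1e-10)
        assert fit1.delta_ld == pytest.approx(fit2.delta_ld, abs=1e-10)

    def test_single_feature(self):
        table, groups = _pair([[1, 2, 3, 7, 8, 9]], 3, 3)
        fit = fit_two_class_lda(table, groups)
        assert abs(fit.w_unit[0]) == pytest.approx(1.0, abs=1e-12)
        assert fit.delta_ld == pytest.approx(6.0, abs=1e-12)

    def test_matches_direct_solve_oracle(self):
        """Unit coefficients match S_w^-1 (mu1-mu0) (up to sign) within 1e-8."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = int(rng.integers(2, 6))
            n = int(rng.integers(p + 3, 15))
            vals = rng.lognormal(size=(p, 2 * n))
            table, groups = _pair(vals, n, n)
            fit = fit_two_class_lda(table, groups)
            x = vals.T
            mu0, mu1 = x[:n].mean(axis=0), x[n:].mean(axis=0)
            c0, c1 = x[:n] - mu0, x[n:] - mu1
            w = np.linalg.solve(c0.T @ c0 + c1.T @ c1, mu1 - mu0)
            w /= np.linalg.norm(w)
            if w @ fit.w_unit < 0:
                w = -w
            np.testing.assert_allclose(fit.w_unit, w, atol=1e-8)

    def test_singular_scatter_reports_features(self):
        base = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        vals = np.vstack([base, 2 * base])  # exactly collinear, not duplicates
        table, groups = _pair(vals, 3, 3)
        with pytest.raises(SingularScatterError) as exc:
            fit_two_class_lda(table, groups)
        assert exc.value.features  # candidate collinear features reported

    def test_too_few_samples(self):
        table, groups = _pair([[1, 2, 3]], 1, 2)
        with pytest.raises(ValidationError, match="at least 2"):
            fit_two_class_lda(table, groups)


def _fit(w, mu0, mu1):
    w = np.asarray(w, float)
    w_unit = w / np.linalg.norm(w)
    mu0, mu1 = np.asarray(mu0, float), np.asarray(mu1, float)
    return LDAFit(
        w_unit=w_unit,
        delta_ld=float(abs(w_unit @ (mu1 - mu0))),
        class_feature_means=np.vstack([mu0, mu1]),
        feature_ids=[f"f{i}" for i in range(w.size)],
        class_levels=("A", "B"),
    )


class TestEffectSizes:
    def test_projection_from_2d_example(self):
        fit = _fit([1.0, 0.0], [0.0, 0.0], [4.0, 0.0])
        raw = [e.raw_effect for e in compute_effect_sizes(fit, "projection")]
        np.testing.assert_allclose(raw, [4.0, 0.0], atol=1e-12)

    def test_projection_arithmetic(self):
        # w=(0.6,0.8), delta_ld=10, both means higher in class 1 -> (+6,+8)
        fit = LDAFit(
            w_unit=np.array([0.6, 0.8]),
            delta_ld=10.0,
            class_feature_means=np.array([[0.0, 0.0], [5.0, 5.0]]),
            feature_ids=["f0", "f1"],
            class_levels=("A", "B"),
        )
        raw = [e.raw_effect for e in compute_effect_sizes(fit, "projection")]
        np.testing.assert_allclose(raw, [6.0, 8.0], atol=1e-12)

    def test_averaged_from_2d_example(self):
        # |mu1-mu0| = (4, 0): averaged gives ((4+4)/2, (0+0)/2)
        fit = _fit([1.0, 0.0], [0.0, 0.0], [4.0, 0.0])
        raw = [e.raw_effect for e in compute_effect_sizes(fit, "averaged")]
        np.testing.assert_allclose(raw, [4.0, 0.0], atol=1e-12)

    def test_sign_follows_mean_difference(self):
        fit = _fit([0.6, -0.8], [10.0, 10.0], [14.0, 4.0])
        effects = compute_effect_sizes(fit, "projection")
        assert effects[0].raw_effect > 0  # higher in non-reference class
        assert effects[1].raw_effect < 0

    def test_unknown_mode(self):
        fit = _fit([1.0], [0.0], [1.0])
        with pytest.raises(ValidationError):
            compute_effect_sizes(fit, "magic")


class TestScoreAndThreshold:
    def test_effect_100_scores_two(self):
        result = score_and_threshold([EffectRecord("f1", 100.0)], 2.0)
        assert result.features == ["f1"]
        assert result.scores[0] == 2.0  # exactly at the default threshold

    def test_negative_effect(self):
        result = score_and_threshold([EffectRecord("f1", -1000.0)], 2.0)
        assert result.scores == [-3.0]

    def test_effect_50_excluded_at_default(self):
        assert len(score_and_threshold([EffectRecord("f1", 50.0)], 2.0)) == 0

    def test_zero_effect_excluded(self):
        assert len(score_and_threshold([EffectRecord("f1", 0.0)], 0.0)) == 0

    def test_ordering_descending_with_id_ties(self):
        effects = [
            EffectRecord("b", 1000.0),
            EffectRecord("a", 1000.0),
            EffectRecord("c", -10000.0),
        ]
        result = score_and_threshold(effects, 2.0)
        assert result.features == ["a", "b", "c"]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        effects = [
            EffectRecord(f"f{i}", float(s))
            for i, s in enumerate(rng.uniform(-1e5, 1e5, size=50))
        ]
        previous = None
        for thr in (0.0, 1.0, 2.0, 3.0, 4.0):
            selected = set(score_and_threshold(effects, thr).features)
            if previous is not None:
                assert selected <= previous
            previous = selected


class TestPipeline:
    def test_recovers_spiked_features_with_sign(self, spiked_dataset):
        table, groups, truth = spiked_dataset
        result = find_markers(table, groups)
        scores = dict(zip(result.features, result.scores))
        for fid, direction in truth.items():
            assert fid in scores
            assert np.sign(scores[fid]) == direction

    def test_deterministic_under_poisoned_global_seed(self, spiked_dataset):
        table, groups, _ = spiked_dataset
        np.random.seed(123)
        r1 = find_markers(table, groups)
        np.random.seed(99999)
        r2 = find_markers(table, groups)
        assert r1.features == r2.features
        assert r1.scores == r2.scores

    def test_scale_invariance(self, spiked_dataset):
        table, groups, _ = spiked_dataset
        scaled = AbundanceTable(
            table.values * 137.0, table.feature_ids, table.sample_ids
        )
        r1 = find_markers(table, groups)
        r2 = find_markers(scaled, groups)
        assert r1.features == r2.features
        np.testing.assert_allclose(r1.scores, r2.scores, rtol=1e-9)

    def test_sample_and_feature_permutation_invariance(self, spiked_dataset):
        table, groups, _ = spiked_dataset
        rng = np.random.default_rng(0)
        s_perm = list(rng.permutation(table.sample_ids))
        f_perm = list(rng.permutation(table.feature_ids))
        permuted = table.select_features(f_perm).select_samples(s_perm)
        r1 = find_markers(table, groups)
        r2 = find_markers(permuted, groups)
        assert r1.features == r2.features
        np.testing.assert_allclose(r1.scores, r2.scores, rtol=1e-9)

    def test_pure_null_yields_few_markers(self):
        from scipy.stats import binom

        from ldamark import SyntheticSpec, generate_synthetic
        from ldamark.stat_screen import kruskal_wallis_screen

        spec = SyntheticSpec(
            n_features=100, n_samples_per_class=(20, 20), n_spiked=0, seed=5
        )
        table, groups, _ = generate_synthetic(spec)
        filtered, _ = filter_degenerate(normalize_per_million(table))
        screen = kruskal_wallis_screen(filtered, groups, 0.05)
        n_retained = sum(r.retained for r in screen)
        lo, hi = binom.ppf([0.005, 0.995], 100, 0.05)
        assert lo <= n_retained <= hi

    def test_empty_result_not_error(self):
        rng = np.random.default_rng(21)
        vals = rng.lognormal(size=(10, 8))
        ids = [f"s{j}" for j in range(8)]
        table = AbundanceTable(vals, [f"f{i}" for i in range(10)], ids)
        groups = SampleGroups(ids, ["A"] * 4 + ["B"] * 4)
        result = find_markers(
            table, groups, PipelineConfig(kruskal_threshold=1e-6)
        )
        assert isinstance(result, MarkerResult)
        assert len(result) == 0


class TestBootstrapReference:
    def test_defaults(self, spiked_dataset):
        table, groups, truth = spiked_dataset
        filtered, _ = filter_degenerate(normalize_per_million(table))
        sub = filtered.select_features(sorted(truth))
        boot = bootstrap_lda_reference(sub, groups, seed=1)
        assert boot.n_boot == 30
        assert boot.fraction == pytest.approx(2.0 / 3.0)
        assert boot.coefficients.shape == (30, sub.n_features)

    def test_full_fraction_degenerates_to_direct(self, spiked_dataset):
        table, groups, truth = spiked_dataset
        filtered, _ = filter_degenerate(normalize_per_million(table))
        sub = filtered.select_features(sorted(truth))
        boot = bootstrap_lda_reference(sub, groups, n_boot=5, fraction=1.0, seed=1)
        for row in boot.coefficients:
            np.testing.assert_allclose(row, boot.direct.w_unit, atol=1e-12)
        np.testing.assert_allclose(boot.mean_coefficients, boot.direct.w_unit, atol=1e-12)

    def test_mean_approaches_direct(self, spiked_dataset):
        table, groups, truth = spiked_dataset
        filtered, _ = filter_degenerate(normalize_per_million(table))
        sub = filtered.select_features(sorted(truth))
        dev = {}
        for n_boot in (10, 1000):
            boot = bootstrap_lda_reference(sub, groups, n_boot=n_boot, seed=2)
            dev[n_boot] = np.abs(boot.mean_coefficients - boot.direct.w_unit).mean()
        assert dev[1000] < dev[10]

    def test_explicit_seed_reproducible(self, spiked_dataset):
        table, groups, truth = spiked_dataset
        filtered, _ = filter_degenerate(normalize_per_million(table))
        sub = filtered.select_features(sorted(truth))
        b1 = bootstrap_lda_reference(sub, groups, n_boot=10, seed=77)
        b2 = bootstrap_lda_reference(sub, groups, n_boot=10, seed=77)
        np.testing.assert_array_equal(b1.coefficients, b2.coefficients)

    def test_invalid_fraction(self, spiked_dataset):
        table, groups, _ = spiked_dataset
        with pytest.raises(ValidationError):
            bootstrap_lda_reference(table, groups, fraction=0.0, seed=1)
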