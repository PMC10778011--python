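"""Diagnostic-accuracy engine: confusion building, one-vs-rest collapse,
kappa (value, marginals identity, CI), micro-averaging identities, MSE,
and the marginal-reconstruction utility."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from msibreslow.classify import CATEGORIES, BreslowCategory
from msibreslow.errors import InputError, ReconciliationError, UndefinedMetricError
from msibreslow.evaluate import (
    ConfusionMatrix3,
    ReconstructedMarginals,
    build_confusion,
    class_metrics,
    cohen_kappa,
    cohen_kappa_counts,
    cohen_kappa_from_marginals,
    complete_confusion,
    confusion_from_class_metrics,
    kappa_ci,
    kappa_ci_counts,
    kappa_se_counts,
    micro_average,
    mse_by_category,
    one_vs_rest,
)


def random_matrix(rng, n_max=60):
    counts = rng.integers(0, n_max, size=(3, 3))
    if counts.sum() == 0:
        counts[0, 0] = 1
    return ConfusionMatrix3(counts)


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        cats = [BreslowCategory.LT1] * 3 + [BreslowCategory.MID] * 2 + [BreslowCategory.GT2]
        cm = build_confusion(cats, cats)
        assert np.array_equal(cm.counts, np.diag([3, 2, 1]))

    def test_single_lesion_unit_count(self):
        cm = build_confusion([BreslowCategory.LT1], [BreslowCategory.GT2])
        expected = np.zeros((3, 3), int)
        expected[0, 2] = 1
        assert np.array_equal(cm.counts, expected)

    def test_counts_conserved(self):
        rng = np.random.default_rng(4)
        t = [CATEGORIES[i] for i in rng.integers(0, 3, 500)]
        p = [CATEGORIES[i] for i in rng.integers(0, 3, 500)]
        assert build_confusion(t, p).total == 500

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            build_confusion([BreslowCategory.LT1], [])


class TestOneVsRest:
    def test_diagonal_has_no_errors(self):
        cm = ConfusionMatrix3(np.diag([5, 6, 7]))
        for k in range(3):
            tp, fn, fp, tn = one_vs_rest(cm, k)
            assert fn == 0 and fp == 0

    def test_reconstructed_hfus_thin_class(self):
        # diagonal/marginals recovered from the published per-class rows
        marg = confusion_from_class_metrics(
            [56, 15, 27], [0.982, 0.800, 0.852], [0.952, 0.940, 0.986]
        )
        cm = complete_confusion(marg)
        assert one_vs_rest(cm, 0) == (55, 1, 2, 40)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            cm = random_matrix(rng)
            # expand to raw label pairs and recount
            pairs = [
                (i, j)
                for i in range(3)
                for j in range(3)
                for _ in range(int(cm.counts[i, j]))
            ]
            for k in range(3):
                tp = sum(1 for t, p in pairs if t == k and p == k)
                fn = sum(1 for t, p in pairs if t == k and p != k)
                fp = sum(1 for t, p in pairs if t != k and p == k)
                tn = sum(1 for t, p in pairs if t != k and p != k)
                assert one_vs_rest(cm, k) == (tp, fn, fp, tn)


class TestClassMetrics:
    def test_published_thin_row_hfus(self):
        m = class_metrics(55, 1, 2, 40)
        assert m.sensitivity == pytest.approx(0.982, abs=5e-4)
        assert m.specificity == pytest.approx(0.952, abs=5e-4)
        assert m.ppv == pytest.approx(0.965, abs=5e-4)
        assert m.npv == pytest.approx(0.976, abs=5e-4)
        assert m.kappa == pytest.approx(0.937, abs=1e-3)

    def test_published_mid_row_msi(self):
        assert class_metrics(9, 6, 27, 57).kappa == pytest.approx(0.177, abs=1e-3)

    def test_perfect_test(self):
        m = class_metrics(12, 0, 0, 30)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.kappa) == (1, 1, 1, 1, 1)

    def test_empty_stratum_rejected(self):
        with pytest.raises(UndefinedMetricError):
            class_metrics(0, 0, 3, 5)


class TestMicroAverage:
    def test_diagonal_is_perfect(self):
        assert micro_average(ConfusionMatrix3(np.diag([5, 6, 7]))) == (1, 1, 1, 1)

    def test_reconstructed_hfus_totals(self):
        marg = confusion_from_class_metrics(
            [56, 15, 27], [0.982, 0.800, 0.852], [0.952, 0.940, 0.986]
        )
        sens, spec, ppv, npv = micro_average(complete_confusion(marg))
        assert sens == pytest.approx(90 / 98)

    def test_micro_identities_equal_accuracy(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            cm = random_matrix(rng)
            sens, spec, ppv, npv = micro_average(cm)
            accuracy = np.trace(cm.counts) / cm.total
            assert sens == pytest.approx(accuracy, abs=1e-12)
            assert ppv == pytest.approx(accuracy, abs=1e-12)
            assert spec == pytest.approx(npv, abs=1e-12)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa(ConfusionMatrix3(np.diag([10, 10, 10]))) == 1.0

    def test_independence_is_zero(self):
        assert cohen_kappa(ConfusionMatrix3(np.full((3, 3), 4))) == pytest.approx(0.0)

    def test_published_overall_from_marginals(self):
        k = cohen_kappa_from_marginals((55, 12, 23), (56, 15, 27), (57, 17, 24))
        assert k == pytest.approx(0.858, abs=1e-3)

    def test_marginals_identity_fuzz(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            cm = random_matrix(rng)
            diag = np.diag(cm.counts)
            k1 = cohen_kappa(cm)
            k2 = cohen_kappa_from_marginals(
                diag, cm.counts.sum(axis=1), cm.counts.sum(axis=0)
            )
            assert k1 == pytest.approx(k2, abs=1e-12)

    def test_matches_sklearn_on_label_pairs(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            t = rng.integers(0, 3, 80)
            p = rng.integers(0, 3, 80)
            cm = build_confusion([CATEGORIES[i] for i in t], [CATEGORIES[i] for i in p])
            assert cohen_kappa(cm) == pytest.approx(cohen_kappa_score(t, p), abs=1e-12)

    def test_invariant_under_uniform_scaling(self):
        rng = np.random.default_rng(9)
        cm = random_matrix(rng)
        scaled = ConfusionMatrix3(cm.counts * 7)
        assert cohen_kappa(cm) == pytest.approx(cohen_kappa(scaled), abs=1e-12)

    def test_degenerate_marginals_rejected(self):
        counts = np.zeros((3, 3), int)
        counts[1, 1] = 40
        with pytest.raises(UndefinedMetricError):
            cohen_kappa(ConfusionMatrix3(counts))


class TestKappaCI:
    def test_perfect_agreement_ci_collapses(self):
        cm = ConfusionMatrix3(np.diag([10, 10, 10]))
        assert kappa_ci(cm) == (1.0, 1.0)

    def test_doubling_counts_shrinks_width_by_sqrt2(self):
        rng = np.random.default_rng(14)
        cm = random_matrix(rng)
        lo1, hi1 = kappa_ci_counts(cm.counts)
        lo2, hi2 = kappa_ci_counts(cm.counts * 2)
        assert (hi2 - lo2) / (hi1 - lo1) == pytest.approx(1 / np.sqrt(2), abs=1e-9)

    def test_asymptotic_se_close_to_bootstrap(self):
        """Multinomial bootstrap of the reconstructed ultrasound matrix
        cross-checks the asymptotic SE, and the CI half-width lands within
        25% of the published interval half-width."""
        marg = confusion_from_class_metrics(
            [56, 15, 27], [0.982, 0.800, 0.852], [0.952, 0.940, 0.986]
        )
        cm = complete_confusion(marg)
        n = cm.total
        p = (cm.counts / n).ravel()
        rng = np.random.default_rng(101)
        boots = rng.multinomial(n, p, size=10_000).reshape(-1, 3, 3)
        kappas = []
        for b in boots:
            bp = b / n
            po = np.trace(bp)
            pe = bp.sum(1) @ bp.sum(0)
            if pe < 1:
                kappas.append((po - pe) / (1 - pe))
        boot_se = np.std(kappas)
        asym_se = kappa_se_counts(cm.counts)
        assert asym_se == pytest.approx(boot_se, rel=0.15)
        lo, hi = kappa_ci(cm)
        published_half = (0.952 - 0.763) / 2
        assert (hi - lo) / 2 == pytest.approx(published_half, rel=0.25)

    def test_small_sample_rejected(self):
        with pytest.raises(InputError):
            kappa_ci(ConfusionMatrix3(np.diag([1, 1, 1])))


class TestMse:
    def test_exact_estimates_zero(self):
        t = [0.5, 1.5, 3.0]
        cats = [BreslowCategory.LT1, BreslowCategory.MID, BreslowCategory.GT2]
        out = mse_by_category(t, t, cats)
        assert all(out[c] == 0.0 for c in CATEGORIES) and out["overall"] == 0.0

    def test_constant_offset(self):
        t = np.array([0.5, 0.7, 1.5, 1.8, 3.0, 4.0])
        cats = [BreslowCategory.LT1] * 2 + [BreslowCategory.MID] * 2 + [BreslowCategory.GT2] * 2
        out = mse_by_category(t, t + 0.3, cats)
        for c in CATEGORIES:
            assert out[c] == pytest.approx(0.09)

    def test_hand_listed_example_direct_sum(self):
        t = [0.4, 0.8, 1.2, 1.9, 2.5, 5.0]
        e = [0.5, 0.6, 1.5, 1.5, 3.5, 4.0]
        cats = [BreslowCategory.LT1] * 2 + [BreslowCategory.MID] * 2 + [BreslowCategory.GT2] * 2
        out = mse_by_category(t, e, cats)
        assert out[BreslowCategory.LT1] == pytest.approx((0.01 + 0.04) / 2)
        assert out[BreslowCategory.MID] == pytest.approx((0.09 + 0.16) / 2)
        assert out[BreslowCategory.GT2] == pytest.approx((1.0 + 1.0) / 2)
        assert out["overall"] == pytest.approx((0.01 + 0.04 + 0.09 + 0.16 + 2.0) / 6)

    def test_empty_category_reported_absent(self):
        out = mse_by_category([0.5], [0.6], [BreslowCategory.LT1])
        assert out[BreslowCategory.GT2] is None


class TestReconstruction:
    def test_ultrasound_rows(self):
        marg = confusion_from_class_metrics(
            [56, 15, 27], [0.982, 0.800, 0.852], [0.952, 0.940, 0.986]
        )
        assert marg.diagonal == (55, 12, 23)
        assert marg.col_sums == (57, 17, 24)
        fp = sum(c - d for c, d in zip(marg.col_sums, marg.diagonal))
        fn = sum(r - d for r, d in zip(marg.row_sums, marg.diagonal))
        assert fp == fn == 8

    def test_multispectral_rows(self):
        marg = confusion_from_class_metrics(
            [56, 15, 28], [0.554, 0.600, 0.786], [0.930, 0.679, 0.901]
        )
        assert marg.diagonal == (31, 9, 22)
        assert marg.col_sums == (34, 36, 29)

    def test_perfect_metrics(self):
        marg = confusion_from_class_metrics([10, 20, 30], [1, 1, 1], [1, 1, 1])
        assert marg.diagonal == (10, 20, 30) and marg.col_sums == (10, 20, 30)

    def test_inconsistent_rows_raise_named_error(self):
        with pytest.raises(ReconciliationError, match="sum"):
            confusion_from_class_metrics([10, 10, 10], [0.9, 1, 1], [1, 1, 1])

    def test_round_trip_from_any_matrix(self):
        """Feeding a matrix's own per-class (n, sens, spec) back recovers its
        diagonal and marginals exactly when no rounding occurs."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            cm = random_matrix(rng)
            if np.any(cm.counts.sum(axis=1) == 0):
                continue
            ns, sens, spec = [], [], []
            for k in range(3):
                tp, fn, fp, tn = one_vs_rest(cm, k)
                if tp + fn == 0 or fp + tn == 0:
                    break
                ns.append(tp + fn)
                sens.append(tp / (tp + fn))
                spec.append(tn / (tn + fp))
            else:
                marg = confusion_from_class_metrics(ns, sens, spec)
                assert marg.diagonal == tuple(np.diag(cm.counts))
                assert marg.row_sums == tuple(cm.counts.sum(axis=1))
                assert marg.col_sums == tuple(cm.counts.sum(axis=0))

    def test_completion_matches_marginals(self):
        marg = ReconstructedMarginals((31, 9, 22), (56, 15, 28), (34, 36, 29))
        cm = complete_confusion(marg)
        assert tuple(np.diag(cm.counts)) == marg.diagonal
        assert tuple(cm.counts.sum(axis=1)) == marg.row_sums
        assert tuple(cm.counts.sum(axis=0)) == marg.col_sums
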