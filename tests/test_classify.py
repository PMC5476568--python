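"""Feature construction, repeated-holdout SVM, ROC, Hotelling's T2."""

import numpy as np
import pandas as pd
import pytest

from infoshare.classify import (
    ClassificationReport,
    FeatureSpec,
    build_features,
    hotelling_t2,
    roc_auc,
    svm_repeated_holdout,
)


def _labels(n_pat, n_ctl):
    return ["patient"] * n_pat + ["control"] * n_ctl


@pytest.fixture
def cnv_spec(m1020):
    return FeatureSpec(
        range_features=(
            ("cnv_lf_distance", "R1", 0.0, 1.45),
            ("cnv_rf_distance", "R2", 0.6, 1.45),
        ),
        set_features=(
            ("cnv_rf_rt", m1020.roi_channels("R2"), m1020.roi_channels("R3")),
            ("cnv_rf_lp", m1020.roi_channels("R2"), m1020.roi_channels("R5")),
            ("cnv_lf_rt", m1020.roi_channels("R1"), m1020.roi_channels("R3")),
            ("cnv_lf_lp", m1020.roi_channels("R1"), m1020.roi_channels("R5")),
        ),
        npv_columns=("score_a", "score_b"),
    )


class TestBuildFeatures:
    def test_mode_column_counts(self, m1020, cnv_spec, rng):
        npv = pd.DataFrame(
            rng.standard_normal((4, 2)), columns=["score_a", "score_b"],
            index=list("wxyz"),
        )
        conn = {s: np.ones((20, 20)) for s in npv.index}
        assert build_features(npv, conn, m1020, cnv_spec, "NPV").shape[1] == 2
        assert build_features(npv, conn, m1020, cnv_spec, "CNV").shape[1] == 6
        both = build_features(npv, conn, m1020, cnv_spec, "BOTH")
        assert both.shape[1] == 8

    def test_hand_computed_cnv_values(self, m1020, cnv_spec):
        npv = pd.DataFrame(index=["s1"])
        conn = {"s1": np.full((20, 20), 0.25)}
        feats = build_features(npv, conn, m1020, cnv_spec, "CNV")
        assert np.allclose(feats.loc["s1"], 0.25)

    def test_missing_npv_column_rejected(self, m1020, cnv_spec):
        npv = pd.DataFrame({"score_a": [1.0]}, index=["s1"])
        with pytest.raises(ValueError):
            build_features(npv, None, None, cnv_spec, "NPV")

    def test_cnv_requires_six_variables(self, m1020):
        spec = FeatureSpec(range_features=(("one", "R1", 0.0, 2.0),))
        with pytest.raises(ValueError):
            build_features(pd.DataFrame(index=["s"]),
                           {"s": np.ones((20, 20))}, m1020, spec, "CNV")


class TestHoldoutProtocol:
    def test_separable_features_perfect_rates(self, rng):
        X = np.vstack([rng.standard_normal((10, 3)) + 10,
                       rng.standard_normal((12, 3)) - 10])
        rep = svm_repeated_holdout(X, _labels(10, 12), n_repeats=50, seed=0)
        assert rep.summary["sensitivity_mean"] == 1.0
        assert rep.summary["specificity_mean"] == 1.0
        assert rep.classification_rate == 1.0

    def test_study_sized_test_sets(self, rng):
        """13 patients/25 controls with 7+7 trained leaves 6+18 held out."""
        X = rng.standard_normal((38, 4))
        rep = svm_repeated_holdout(X, _labels(13, 25), n_repeats=25, seed=1)
        per_repeat = rep.pooled_labels.reshape(25, 24)
        assert (per_repeat.sum(axis=1) == 6).all()
        assert per_repeat.shape[1] == 24

    def test_chance_level_on_permuted_labels(self, rng):
        X = rng.standard_normal((38, 5))
        labels = np.array(_labels(13, 25))
        rng.shuffle(labels)
        rep = svm_repeated_holdout(X, labels, n_repeats=500, seed=2)
        assert abs(rep.classification_rate - 0.5) < 0.05

    def test_reproducible_under_seed(self, rng):
        X = rng.standard_normal((20, 3))
        r1 = svm_repeated_holdout(X, _labels(9, 11), n_repeats=20, seed=9)
        r2 = svm_repeated_holdout(X, _labels(9, 11), n_repeats=20, seed=9)
        pd.testing.assert_frame_equal(r1.per_repeat, r2.per_repeat)
        assert np.array_equal(r1.pooled_scores, r2.pooled_scores)

    def test_too_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            svm_repeated_holdout(
                rng.standard_normal((12, 2)), _labels(6, 6), seed=0
            )


class TestRoc:
    def _report(self, scores, labels):
        return ClassificationReport(
            per_repeat=pd.DataFrame(
                {"sensitivity": [1.0, 1.0], "specificity": [1.0, 1.0],
                 "accuracy": [1.0, 1.0], "balanced_accuracy": [1.0, 1.0]}
            ),
            pooled_scores=np.asarray(scores, dtype=float),
            pooled_labels=np.asarray(labels),
            n_train_per_group=7,
        )

    def test_perfect_and_reversed_ranking(self):
        rep = self._report([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc_auc(rep)[1] == 1.0
        rep = self._report([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert roc_auc(rep)[1] == 0.0

    def test_random_scores_near_half(self, rng):
        rep = self._report(rng.standard_normal(2000),
                           rng.integers(0, 2, 2000))
        assert abs(roc_auc(rep)[1] - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(self._report([0.1, 0.2], [1, 1]))


class TestHotelling:
    def test_identical_samples_null(self, rng):
        a = rng.standard_normal((30, 2))
        t2, f, p = hotelling_t2(a, a.copy())
        assert t2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_tiny_p(self, rng):
        a = rng.standard_normal((50, 2))
        b = rng.standard_normal((50, 2)) + 5.0
        assert hotelling_t2(a, b)[2] < 1e-6

    def test_univariate_rejected(self, rng):
        with pytest.raises(ValueError):
            hotelling_t2(rng.standard_normal((10, 1)),
                         rng.standard_normal((10, 1)))

    def test_matches_independent_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a = rng.standard_normal((20, 2))
        b = rng.standard_normal((25, 2)) + 0.3
        t2, f, p = hotelling_t2(a, b)
        ref = pingouin.multivariate_ttest(a, b)
        assert t2 == pytest.approx(float(ref["T2"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-9)


class TestCohortLevelInvariants:
    """Slower checks tying the classifier to the synthetic ground truth."""

    def _cnv_accuracy(self, drop, seed):
        from infoshare.montage import build_montage
        from infoshare.simulate import CohortDesign, simulate_cohort
        from infoshare.topo import roi_pair_means  # noqa: F401 (doc pointer)
        from infoshare.pipeline import (
            LEFT_FRONTAL_RANGE, RIGHT_FRONTAL_RANGE, compute_connectivity,
        )

        design = CohortDesign(
            coupling_drop=drop, seed=seed,
            epochs_per_subject=30, epoch_len_s=1.0,
        )
        cohort = simulate_cohort(design)
        conn = compute_connectivity(cohort)
        m = cohort.montage
        spec = FeatureSpec(
            range_features=(
                ("cnv_lf_distance",) + LEFT_FRONTAL_RANGE,
                ("cnv_rf_distance",) + RIGHT_FRONTAL_RANGE,
            ),
            set_features=(
                ("rf_rt", m.roi_channels("R2"), m.roi_channels("R3")),
                ("rf_lp", m.roi_channels("R2"), m.roi_channels("R5")),
                ("lf_rt", m.roi_channels("R1"), m.roi_channels("R3")),
                ("lf_lp", m.roi_channels("R1"), m.roi_channels("R5")),
            ),
        )
        feats = build_features(cohort.npv, conn, m, spec, "CNV")
        labels = [cohort.groups[s] for s in feats.index]
        rep = svm_repeated_holdout(feats, labels, n_repeats=60, seed=seed)
        return rep.classification_rate

    def test_accuracy_monotone_in_injected_drop(self):
        """A larger injected coupling drop never hurts CNV classification
        (3-point grid, paired cohort seeds, averaged)."""
        seeds = (301, 302, 303, 304)
        means = [
            np.mean([self._cnv_accuracy(drop, s) for s in seeds])
            for drop in (0.0, 0.25, 0.5)
        ]
        assert means[0] <= means[1] + 0.02
        assert means[1] <= means[2] + 0.02

    def test_both_mode_at_least_matches_single_modes(self):
        """With score shifts and connectivity drops both present, combining
        feature families does not lose discrimination."""
        from infoshare.pipeline import PipelineConfig, run_pipeline
        from infoshare.simulate import CohortDesign

        config = PipelineConfig(
            design=CohortDesign(seed=61, epochs_per_subject=30,
                                epoch_len_s=1.0),
            n_perm=150, n_repeats=100, seed=61,
        )
        res = run_pipeline(config)
        rates = {m: r.classification_rate for m, r in res.reports.items()}
        assert rates["BOTH"] >= max(rates["NPV"], rates["CNV"]) - 0.02
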