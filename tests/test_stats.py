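"""Rank-sum inference, FDR, permutation tests, seed analysis, demographics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infoshare.stats import (
    SEED_SCORE_THRESHOLD,
    chisq_2x2,
    cohens_d,
    compare_demographics,
    fdr_bh,
    permutation_profile_test,
    ranksum_test,
    reference_demographics,
    roi_pair_comparison,
    second_stage_seeds,
    seed_analysis,
    summary_ttest,
)


def enumerate_ranksum_p(a, b):
    """Oracle: full enumeration of the two-sided rank-sum permutation p."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na = len(a)
    ew = na * (len(pooled) + 1) / 2.0
    obs = abs(ranks[:na].sum() - ew)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), na):
        total += 1
        hits += abs(ranks[list(comb)].sum() - ew) >= obs - 1e-12
    return hits / total


class TestRankSum:
    def test_textbook_exact_values(self):
        assert ranksum_test([1, 2], [3, 4]).p == pytest.approx(1 / 3)
        assert ranksum_test([1, 2, 3], [10, 11, 12]).p == pytest.approx(0.1)

    def test_identical_multisets_null(self):
        r = ranksum_test([1, 2], [1, 2])
        assert r.sign == 0 and r.p == 1.0

    def test_sign_convention(self):
        assert ranksum_test([5, 6, 7], [1, 2, 3]).sign == 1
        assert ranksum_test([1, 2, 3], [5, 6, 7]).sign == -1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=6), min_size=2, max_size=5),
        st.lists(st.integers(min_value=0, max_value=6), min_size=2, max_size=5),
    )
    def test_exact_p_matches_enumeration_oracle(self, a, b):
        r = ranksum_test(a, b)
        assert r.exact
        assert r.p == pytest.approx(enumerate_ranksum_p(a, b), abs=1e-12)

    def test_large_sample_close_to_scipy(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(25) + 0.5
        from scipy.stats import ranksums

        r = ranksum_test(a, b)
        assert not r.exact
        assert r.p == pytest.approx(ranksums(a, b).pvalue, rel=1e-10)

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            ranksum_test([1], [2, 3])


class TestFdr:
    def test_all_small_all_rejected(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05).all()

    def test_all_ones_none_rejected(self):
        assert not fdr_bh([1.0, 1.0, 1.0]).any()

    def test_single_boundary_p(self):
        assert fdr_bh([0.049], q=0.05)[0]

    def test_empty_input(self):
        assert fdr_bh([]).size == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 50))
        mask = fdr_bh(p, q=0.05)
        # brute force: largest i with p_(i) <= i*q/m, reject all smaller
        order = np.argsort(p)
        m = len(p)
        thresh = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= i * 0.05 / m:
                thresh = i
        expected = np.zeros(m, dtype=bool)
        expected[order[:thresh]] = True
        assert (mask == expected).all()


class TestEffectSize:
    def test_unit_shift(self, rng):
        a = rng.standard_normal(2000)
        b = rng.standard_normal(2000) + 1.0
        assert cohens_d(a, b) == pytest.approx(-1.0, abs=0.1)

    def test_identical_and_hand_case(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_degenerate_flagged(self):
        assert np.isnan(cohens_d([1, 1], [2, 2]))


class TestPermutationProfile:
    def test_huge_separation_hits_floor(self, rng):
        a = rng.standard_normal((10, 3))
        b = rng.standard_normal((10, 3)) + 50.0
        out = permutation_profile_test(a, b, n_perm=5000, seed=0)
        assert np.allclose(out["p"], 1 / 5001)

    def test_two_sided_symmetry(self, rng):
        a = rng.standard_normal((8, 3))
        b = rng.standard_normal((12, 3))
        p1 = permutation_profile_test(a, b, n_perm=500, seed=3)["p"]
        p2 = permutation_profile_test(b, a, n_perm=500, seed=3)["p"]
        assert np.allclose(p1, p2)

    def test_monotone_transform_invariance(self, rng):
        """Order-preserving rescaling of a bin leaves its p unchanged."""
        a = rng.standard_normal((9, 2))
        b = rng.standard_normal((11, 2)) + 0.4
        base = permutation_profile_test(a, b, n_perm=400, seed=5)["p"]
        scaled = permutation_profile_test(
            3.0 * a + 7.0, 3.0 * b + 7.0, n_perm=400, seed=5
        )["p"]
        assert np.allclose(base, scaled)

    def test_rejects_few_permutations(self, rng):
        with pytest.raises(ValueError):
            permutation_profile_test(
                rng.standard_normal((5, 2)), rng.standard_normal((5, 2)),
                n_perm=50,
            )

    def test_bootstrap_variant_runs(self, rng):
        out = permutation_profile_test(
            rng.standard_normal((6, 2)), rng.standard_normal((6, 2)),
            n_perm=200, seed=1, bootstrap=True,
        )
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()


def _toy_cohort_vectors(rng, shift=0.0, n_pat=8, n_ctl=10):
    cols = [f"R{a}-R{b}" for a, b in itertools.combinations(range(1, 8), 2)]
    pat = pd.DataFrame(
        rng.standard_normal((n_pat, 21)) - shift,
        columns=cols, index=[f"P{i}" for i in range(n_pat)],
    )
    ctl = pd.DataFrame(
        rng.standard_normal((n_ctl, 21)),
        columns=cols, index=[f"C{i}" for i in range(n_ctl)],
    )
    vectors = pd.concat([pat, ctl])
    groups = pd.Series(
        ["patient"] * n_pat + ["control"] * n_ctl, index=vectors.index
    )
    return vectors, groups


class TestRoiPairComparison:
    def test_structure_and_flags(self, rng):
        vectors, groups = _toy_cohort_vectors(rng, shift=3.0)
        out = roi_pair_comparison(vectors, groups)
        assert len(out) == 21
        assert out["fdr_significant"].all()
        assert (out["sign"] == 1).all()  # controls above patients
        assert (out["cohens_d"] > 0).all()

    def test_fdr_flags_subset_of_raw(self, rng):
        vectors, groups = _toy_cohort_vectors(rng, shift=0.3)
        out = roi_pair_comparison(vectors, groups)
        assert (out["fdr_significant"] <= out["raw_significant"]).all()

    def test_single_subject_group_rejected(self, rng):
        vectors, groups = _toy_cohort_vectors(rng, n_pat=1)
        with pytest.raises(ValueError):
            roi_pair_comparison(vectors, groups)


def _stacked_matrices(rng, m, n_pat, n_ctl, deficit_pairs=(), delta=1.0):
    """Symmetric random matrices; patient deficit on the given label pairs."""
    n = n_pat + n_ctl
    mats = rng.standard_normal((n, m.n_channels, m.n_channels))
    mats = (mats + mats.transpose(0, 2, 1)) / 2
    for a, b in deficit_pairs:
        i, j = m.index(a), m.index(b)
        mats[:n_pat, i, j] -= delta
        mats[:n_pat, j, i] -= delta
    groups = np.array(["patient"] * n_pat + ["control"] * n_ctl)
    return mats, groups


class TestSeedAnalysis:
    def test_hypoconnectivity_scores_positive(self, m1020, rng):
        deficit = [("Fp1", "T8"), ("F3", "T8"), ("F7", "T8")]
        mats, groups = _stacked_matrices(
            rng, m1020, 10, 12, deficit_pairs=deficit, delta=2.5
        )
        smap = seed_analysis(mats, groups, m1020, "R1")
        assert smap.per_electrode.loc["T8", "signed_score"] > \
            SEED_SCORE_THRESHOLD
        # score/threshold coupling: crossing 1.3 iff median p < 0.05
        per = smap.per_electrode
        assert (
            (per["signed_score"].abs() > SEED_SCORE_THRESHOLD)
            == (per["median_p"] < 0.05)
        ).all()

    def test_patients_above_controls_gives_negative_signs(self, m1020, rng):
        mats, groups = _stacked_matrices(rng, m1020, 10, 12)
        mats[groups == "patient"] += 5.0
        smap = seed_analysis(mats, groups, m1020, "R2")
        assert (smap.per_electrode["sign"] == -1).all()

    def test_fdr_counts_bounded_by_seed_count(self, m1020, rng):
        mats, groups = _stacked_matrices(rng, m1020, 8, 8)
        smap = seed_analysis(mats, groups, m1020, "R1")
        n_seeds = len(smap.seeds)
        assert (smap.per_electrode["n_significant"] <= n_seeds).all()

    def test_explicit_seed_list_and_errors(self, m1020, rng):
        mats, groups = _stacked_matrices(rng, m1020, 8, 8)
        smap = seed_analysis(mats, groups, m1020, ["Fz", "Cz"])
        assert len(smap.per_electrode) == 18
        with pytest.raises(ValueError):
            seed_analysis(mats, groups, m1020, [])
        with pytest.raises(ValueError):
            seed_analysis(mats, groups, m1020, list(m1020.labels))


class TestSecondStage:
    def test_top_five_selection_and_tie_break(self, m1020, rng):
        deficit = [(s, e) for s in ("Fp1", "F3", "F7", "Fp2", "F4", "F8")
                   for e in ("T8", "P8", "P3", "O1", "P7", "P4")]
        mats, groups = _stacked_matrices(
            rng, m1020, 10, 12, deficit_pairs=deficit, delta=3.0
        )
        left = seed_analysis(mats, groups, m1020, "R1")
        right = seed_analysis(mats, groups, m1020, "R2")
        chosen = second_stage_seeds(left, right, m1020, top_n=5)
        assert chosen  # at least one region significant
        for roi, chans in chosen.items():
            assert len(chans) <= 5
            assert all(m1020.roi_of[c] == roi for c in chans)

    def test_null_maps_select_nothing(self, m1020, rng):
        mats, groups = _stacked_matrices(rng, m1020, 8, 8)
        left = seed_analysis(mats, groups, m1020, "R1")
        right = seed_analysis(mats, groups, m1020, "R2")
        # with pure-noise matrices hotspots are rare; selection must then
        # be empty rather than inventing regions
        chosen = second_stage_seeds(left, right, m1020, threshold=10.0)
        assert chosen == {}


class TestDemographics:
    def test_pooled_t_from_summary(self):
        t, df, p = summary_ttest(69.31, 10.55, 13, 70.40, 5.22, 25)
        assert df == 36
        assert p == pytest.approx(0.67, abs=0.005)
        assert summary_ttest(5, 1, 10, 5, 1, 10)[2] == 1.0

    def test_chi_squared_cases(self):
        chi2, p = chisq_2x2([[10, 10], [20, 20]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        chi2, p = chisq_2x2([[5, 0], [0, 5]])
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(0.00157, abs=1e-5)
        with pytest.raises(ValueError):
            chisq_2x2([[1, 0], [1, 0]])

    def test_reference_tables_reproduce_published_p(self):
        res = {
            arm: compare_demographics(tab).set_index("variable")
            for arm, tab in reference_demographics().items()
        }
        assert res["bvftd"].loc["age", "p_display"] == "0.67"
        assert res["bvftd"].loc["education", "p_display"] == "0.10"
        assert res["bvftd"].loc["ravlt_delayed", "p_display"] == "0.002"
        assert res["ad"].loc["age", "p_display"] == "0.20"
        assert res["ad"].loc["sex", "p_display"] == "0.26"

    def test_empty_and_malformed_rows(self):
        assert compare_demographics(pd.DataFrame(columns=["variable", "kind"])
                                    ).empty
        bad = pd.DataFrame([{"variable": "x", "kind": "continuous"}])
        out = compare_demographics(bad)
        assert out.loc[0, "error"] != ""


def test_second_stage_rank_tie_breaks_by_label(m1020):
    """Equal scores at the cutoff rank resolve by channel-label order."""
    import pandas as pd
    from infoshare.stats import SeedMap

    externals = [e for e in m1020.labels if m1020.roi_of[e] not in ("R1", "R2")]

    def flat_map(score):
        per = pd.DataFrame(
            {"median_p": 0.01, "sign": 1, "signed_score": score,
             "n_significant": 0},
            index=pd.Index(externals, name="external"),
        )
        return SeedMap(seeds=("Fp1",), per_electrode=per,
                       connections=pd.DataFrame())

    chosen = second_stage_seeds(flat_map(2.0), flat_map(2.0), m1020, top_n=5)
    # every region tied at 2.0: selection must be the alphabetically first
    # labels of each region, deterministically
    for roi, chans in chosen.items():
        members = sorted(e for e in externals if m1020.roi_of[e] == roi)
        assert list(chans) == members[:5]
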