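"""CPM training: screening, strengths, cross-validation, permutation, partials."""

import numpy as np
import pytest
import scipy.stats as st

from mindcpm.core import (
    CPMModel,
    EdgeMask,
    PermutationConfig,
    SelectionConfig,
    edge_presence,
    edge_screen,
    finalize_model,
    fit_strength_model,
    network_strength,
    partial_correlation,
    permutation_pvalue,
    permutation_test,
    run_cv,
    select_models,
)
from conftest import site_slice


def brute_force_screen(X, y, threshold):
    """Oracle: per-edge scipy pearsonr with sign/threshold logic."""
    pos = np.zeros(X.shape[1], bool)
    neg = np.zeros(X.shape[1], bool)
    for e in range(X.shape[1]):
        if X[:, e].std() == 0:
            continue
        r, p = st.pearsonr(X[:, e], y)
        if p < threshold:
            if r > 0:
                pos[e] = True
            elif r < 0:
                neg[e] = True
    return pos, neg


class TestEdgeScreen:
    def test_matches_scipy_oracle(self, rng):
        X = rng.standard_normal((30, 150))
        y = rng.standard_normal(30)
        y = y + X[:, 0]  # ensure at least one real hit
        pos, neg, r, p = edge_screen(X, y, 0.05)
        o_pos, o_neg = brute_force_screen(X, y, 0.05)
        assert np.array_equal(pos.member, o_pos)
        assert np.array_equal(neg.member, o_neg)
        for e in range(0, 150, 17):
            rr, pp = st.pearsonr(X[:, e], y)
            assert r[e] == pytest.approx(rr, abs=1e-12)
            assert p[e] == pytest.approx(pp, rel=1e-9)

    def test_edge_equal_to_scores_is_positive(self, rng):
        y = rng.standard_normal(20)
        X = rng.standard_normal((20, 5))
        X[:, 2] = y
        pos, neg, r, p = edge_screen(X, y, 0.01)
        assert pos.member[2] and not neg.member[2]
        assert p[2] == pytest.approx(0.0, abs=1e-30)

    def test_minimal_significant_r_at_n188(self):
        # |r| passing p<0.01 at n=188 is r* = t/sqrt(t^2+df), t = qt(0.995, 186)
        t_crit = st.t.ppf(0.995, 186)
        r_star = t_crit / np.sqrt(t_crit**2 + 186)
        assert r_star == pytest.approx(0.187, abs=0.001)
        rng = np.random.default_rng(0)
        # an edge engineered to have exactly r slightly above/below r*
        n = 188
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std()
        for target, expect in ((r_star * 1.02, True), (r_star * 0.98, False)):
            y = rng.standard_normal(n)
            y = (y - y.mean()) / y.std()
            y = y - (y @ z) / n * z  # orthogonalize
            y = y / y.std()
            edge = target * y + np.sqrt(1 - target**2) * z
            pos, _, _, _ = edge_screen(
                np.column_stack([edge, rng.standard_normal(n)]), y, 0.01
            )
            assert bool(pos.member[0]) is expect

    def test_null_selection_rate_near_alpha(self, rng):
        X = rng.standard_normal((200, 1000))
        y = rng.standard_normal(200)
        pos, neg, _, _ = edge_screen(X, y, 0.01)
        frac = (pos.size + neg.size) / 1000
        assert 0.003 <= frac <= 0.02  # ~1% type-I rate

    def test_zero_variance_scores_error(self, rng):
        with pytest.raises(ValueError, match="zero variance"):
            edge_screen(rng.standard_normal((10, 4)), np.ones(10), 0.01)

    def test_zero_variance_edge_ineligible(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 7.0
        pos, neg, r, p = edge_screen(X, rng.standard_normal(20), 0.5)
        assert not pos.member[1] and not neg.member[1]
        assert r[1] == 0.0 and p[1] == 1.0


class TestNetworkStrength:
    def test_hand_example(self):
        X = np.array([[0.2, 0.3, 0.1]])
        pos = EdgeMask("positive", [True, True, False])
        neg = EdgeMask("negative", [False, False, True])
        s = network_strength(X, pos, neg)
        assert s.loc[0, "pos_sum"] == pytest.approx(0.5)
        assert s.loc[0, "neg_sum"] == pytest.approx(0.1)
        assert s.loc[0, "combined"] == pytest.approx(0.4)

    def test_empty_masks_give_zero(self, rng):
        X = rng.standard_normal((5, 8))
        z = EdgeMask("positive", np.zeros(8, bool))
        zn = EdgeMask("negative", np.zeros(8, bool))
        s = network_strength(X, z, zn)
        assert (s == 0).all().all()

    def test_matches_loop_oracle(self, rng):
        X = rng.standard_normal((25, 60))
        pos = EdgeMask("positive", rng.random(60) < 0.3)
        neg = EdgeMask("negative", (rng.random(60) < 0.3) & ~pos.member)
        s = network_strength(X, pos, neg)
        for i in range(25):
            ps = sum(X[i, e] for e in range(60) if pos.member[e])
            ns = sum(X[i, e] for e in range(60) if neg.member[e])
            assert s.loc[i, "pos_sum"] == pytest.approx(ps, abs=1e-10)
            assert s.loc[i, "combined"] == pytest.approx(ps - ns, abs=1e-10)


class TestFitStrengthModel:
    def test_exact_line(self):
        beta, c = fit_strength_model([1.0, 2.0], [2.0, 4.0])
        assert beta == pytest.approx(2.0) and c == pytest.approx(0.0)

    def test_constant_scores(self):
        beta, c = fit_strength_model([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert beta == 0.0 and c == 5.0

    def test_constant_strength_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_strength_model([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_recovers_planted_line_within_3se(self, rng):
        s = rng.standard_normal(500)
        y = 3.0 * s + 1.5 + rng.normal(0, 2.0, 500)
        beta, c = fit_strength_model(s, y)
        se = 2.0 / (np.sqrt(500) * s.std())
        assert abs(beta - 3.0) < 3 * se


class TestRunCV:
    def test_exact_single_edge_signal(self, rng):
        n = 40
        X = rng.standard_normal((n, 30))
        y = 2.0 * X[:, 7] + 1.0
        cv = run_cv(X, y, SelectionConfig())
        # a few spurious edges can enter at n=40, mildly diluting the signal
        assert cv.r["combined"] > 0.95

    def test_loocv_fast_path_equals_explicit_folds(self, rng):
        X = rng.standard_normal((25, 80))
        y = rng.standard_normal(25) + 0.5 * X[:, 3]
        cfg = SelectionConfig(edge_p_threshold=0.1)
        cv = run_cv(X, y, cfg)
        for i in range(25):
            train = np.ones(25, bool)
            train[i] = False
            pos, neg, _, _ = edge_screen(X[train], y[train], cfg.edge_p_threshold)
            assert np.array_equal(cv.fold_positive[i], pos.member)
            assert np.array_equal(cv.fold_negative[i], neg.member)
            s_tr = network_strength(X[train], pos, neg)["combined"].to_numpy()
            s_te = network_strength(X[i : i + 1], pos, neg)["combined"].to_numpy()
            try:
                beta, c = fit_strength_model(s_tr, y[train])
                expect = beta * s_te[0] + c
            except ValueError:
                expect = y[train].mean()
            assert cv.predicted["combined"][i] == pytest.approx(expect, abs=1e-8)

    def test_null_data_gives_nonpositive_mean_r(self):
        rs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 100))
            y = rng.standard_normal(60)
            rs.append(run_cv(X, y, SelectionConfig()).r["combined"])
        assert np.mean(rs) < 0.05

    def test_kfold_partitions_each_subject_once(self, rng):
        X = rng.standard_normal((37, 50))
        y = rng.standard_normal(37) + X[:, 0]
        cfg = SelectionConfig(cv_scheme="kfold", k=10, rng_seed=3)
        cv = run_cv(X, y, cfg)
        assert cv.fold_of_subject.shape == (37,)
        assert set(cv.fold_of_subject) == set(range(10))
        sizes = np.bincount(cv.fold_of_subject)
        assert sizes.max() - sizes.min() <= 1

    def test_planted_cohort_prediction_is_strong(self, two_site_cohort):
        X, ph = site_slice(two_site_cohort, "train")
        cv = run_cv(X, ph["total"].to_numpy(), SelectionConfig())
        assert cv.r["combined"] > 0.5

    def test_determinism(self, rng):
        X = rng.standard_normal((30, 40))
        y = rng.standard_normal(30)
        cfg = SelectionConfig(cv_scheme="kfold", k=5, rng_seed=9)
        a = run_cv(X, y, cfg)
        b = run_cv(X, y, cfg)
        assert np.array_equal(a.predicted["combined"], b.predicted["combined"])
        assert a.r == b.r


class TestPermutation:
    def test_pvalue_definition(self):
        null = np.concatenate([np.full(17, 0.5), np.full(983, -0.1)])
        assert permutation_pvalue(null, 0.3) == 0.017
        assert permutation_pvalue(np.full(10, -1.0), 0.2) == 0.0
        assert permutation_pvalue(np.array([0.4]), 0.4) == 1.0  # identity permutation
        assert permutation_pvalue(null, 0.3, add_one=True) == pytest.approx(18 / 1001)

    def test_null_and_p_consistent_and_deterministic(self, rng):
        X = rng.standard_normal((20, 30))
        y = rng.standard_normal(20)
        cfg = SelectionConfig()
        pcfg = PermutationConfig(n_perm=30, rng_seed=4)
        obs = run_cv(X, y, cfg).r["combined"]
        null1, p1 = permutation_test(X, y, cfg, pcfg, observed_r=obs)
        null2, p2 = permutation_test(X, y, cfg, pcfg, observed_r=obs)
        assert np.array_equal(null1, null2) and p1 == p2
        assert p1 == pytest.approx((null1 >= obs).mean())

    def test_signal_has_small_p(self, rng):
        X = rng.standard_normal((40, 30))
        y = 2 * X[:, 3] + rng.normal(0, 0.5, 40)
        cfg = SelectionConfig()
        null, p = permutation_test(X, y, cfg, PermutationConfig(n_perm=50, rng_seed=0))
        assert p == 0.0


class TestPartialCorrelation:
    def test_orthogonal_covariate_leaves_r(self, rng):
        n = 300
        z = rng.standard_normal(n)
        z = (z - z.mean()) / z.std()
        x = rng.standard_normal(n)
        x -= (x @ z) / n * z  # exactly orthogonal to z in sample
        y = 0.5 * x + rng.standard_normal(n)
        y -= (y @ z) / n * z
        r_plain = st.pearsonr(x, y).statistic
        r_part, _ = partial_correlation(x, y, z.reshape(-1, 1))
        assert r_part == pytest.approx(r_plain, abs=1e-10)

    def test_closed_form_half_correlations(self, rng):
        # with r_xy=0.5, r_xz=r_yz=0.5 the partial is (0.5-0.25)/0.75 = 1/3
        n = 400
        m = rng.standard_normal((n, 3))
        q, _ = np.linalg.qr(m - m.mean(axis=0))  # zero-mean orthonormal basis
        e1, e2, e3 = q[:, 0], q[:, 1], q[:, 2]
        z = e1
        x = 0.5 * e1 + np.sqrt(0.75) * e2
        a = 0.25 / np.sqrt(0.75)
        y = 0.5 * e1 + a * e2 + np.sqrt(1 - 0.25 - a**2) * e3
        r, _ = partial_correlation(x, y, z.reshape(-1, 1))
        assert r == pytest.approx(1 / 3, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        n = 80
        x = rng.standard_normal(n)
        z = 0.4 * x + rng.standard_normal(n)
        y = 0.3 * x + 0.5 * z + rng.standard_normal(n)
        r, p = partial_correlation(x, y, z.reshape(-1, 1))
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)

    def test_covariate_equal_to_x_errors(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        with pytest.raises(ValueError, match="residual variance"):
            partial_correlation(x, y, x.reshape(-1, 1))

    def test_collinear_covariates_error(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        z = rng.standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(x, y, np.column_stack([z, 2 * z]))


class TestFinalizeAndPresence:
    def test_exact_linear_single_edge(self, rng):
        X = rng.standard_normal((50, 21))
        y = 3.0 * X[:, 5] + 2.0
        model = finalize_model(X, y, SelectionConfig(), "total")
        assert model.positive_mask.member[5]
        beta = model.coefficients["combined"]["beta"]
        # combined strength includes edge 5 plus possible false positives;
        # with only edge 5 selected the line is recovered exactly
        if model.positive_mask.size == 1 and model.negative_mask.size == 0:
            assert beta == pytest.approx(3.0)
            assert model.coefficients["combined"]["c"] == pytest.approx(2.0)
        cv = run_cv(X, y, SelectionConfig())
        presence = edge_presence(cv, model)
        assert presence["positive"] == pytest.approx(100.0, abs=1.0)

    def test_planted_masks_recovered(self, two_site_cohort):
        X, ph = site_slice(two_site_cohort, "train")
        model = finalize_model(X, ph["total"].to_numpy(), SelectionConfig(), "total")
        truth = two_site_cohort.truth
        pos = np.flatnonzero(model.positive_mask.member)
        neg = np.flatnonzero(model.negative_mask.member)
        hit = len(set(pos) & set(truth["planted_positive"])) + len(
            set(neg) & set(truth["planted_negative"])
        )
        assert hit / 30 >= 0.8

    def test_null_cohort_mask_size_near_alpha(self, rng):
        X = rng.standard_normal((200, 1953))
        y = rng.standard_normal(200)
        model = finalize_model(X, y, SelectionConfig(), "null")
        frac = (model.positive_mask.size + model.negative_mask.size) / 1953
        assert 0.003 <= frac <= 0.02

    def test_masks_disjoint_and_presence_fixture(self, rng):
        X = rng.standard_normal((40, 66))
        y = rng.standard_normal(40) + X[:, 0] - X[:, 1]
        model = finalize_model(X, y, SelectionConfig(edge_p_threshold=0.1), "t")
        assert not np.any(model.positive_mask.member & model.negative_mask.member)
        # constructed fixture: edge present in 93 of 100 folds -> 93.0%
        fold_masks = np.zeros((100, 66), bool)
        fold_masks[:93, 0] = True
        cv = run_cv(X, y, SelectionConfig(edge_p_threshold=0.1))
        single = CPMModel(
            positive_mask=EdgeMask("positive", np.eye(66, dtype=bool)[0]),
            negative_mask=EdgeMask("negative", np.zeros(66, bool)),
            coefficients={v: {"beta": 1.0, "c": 0.0} for v in ("combined", "pos_only", "neg_only")},
            target_name="t",
            n_train=40,
            edge_p_threshold=0.1,
            n_nodes=12,
        )
        cv.fold_positive = fold_masks
        assert edge_presence(cv, single)["positive"] == pytest.approx(93.0)
        assert edge_presence(cv, single)["negative"] is None

    def test_model_round_trip(self, tmp_path, rng):
        X = rng.standard_normal((40, 45))  # 45 edges = 10 nodes
        y = rng.standard_normal(40) + X[:, 2] - X[:, 11]
        model = finalize_model(X, y, SelectionConfig(edge_p_threshold=0.2), "AA")
        model.save(tmp_path / "m")
        back = CPMModel.load(tmp_path / "m")
        assert np.array_equal(back.positive_mask.member, model.positive_mask.member)
        assert np.array_equal(back.negative_mask.member, model.negative_mask.member)
        assert back.coefficients == model.coefficients
        assert back.target_name == "AA" and back.n_train == 40


class TestSelectModels:
    def test_printed_p_values_select_aa_and_nj(self):
        assert select_models({"AA": 0.017, "NJ": 0.025, "O": 0.31}) == ["AA", "NJ"]

    def test_boundary_and_empty(self):
        assert select_models({"AA": 0.05}) == []
        assert select_models({"AA": 0.9, "NJ": 0.06}) == []

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            select_models({"AA": 1.2})
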