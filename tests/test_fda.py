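import numpy as np
import pytest
from scipy import linalg

from focm_screen import fda
from focm_screen.fda import (
    FitError,
    Standardizer,
    criterion,
    fit_fda,
    loo_scores,
    project_external,
    project_scores,
    scatter_matrices,
)
from focm_screen.synthetic import SyntheticConfig, generate_cohorts

from conftest import TOY_VARS, make_dataset


def brute_force_direction(X, labels, resolution_deg=0.1):
    """Oracle: maximize J over a dense grid of unit directions (2-D only)."""
    S_B, S_W = scatter_matrices(X, labels)
    angles = np.deg2rad(np.arange(0.0, 180.0, resolution_deg))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    num = np.einsum("ij,jk,ik->i", dirs, S_B, dirs)
    den = np.einsum("ij,jk,ik->i", dirs, S_W, dirs)
    J = num / den
    return dirs[np.argmax(J)]


class TestFitFDA:
    def test_1d_toy_perfect_separation(self, toy_1d):
        m = fit_fda(toy_1d, ("Methionine",), ("ASD", "NEU"))
        # orientation: ASD (values 0,1) must score higher, so w = -1 here
        assert m.w.shape == (1,)
        assert abs(abs(m.w[0]) - 1.0) < 1e-12
        assert m.class_score_means["ASD"] > m.class_score_means["NEU"]
        assert m.fit.J > 10

    def test_2d_matches_brute_force_grid_within_one_degree(self):
        rng = np.random.default_rng(11)
        n = 4
        X = np.vstack(
            [
                rng.normal([0, 0], [1.0, 1.0], (n, 2)),
                rng.normal([4, 0], [1.0, 1.0], (n, 2)),
            ]
        )
        labels = ["ASD"] * n + ["NEU"] * n
        ds = make_dataset(X, labels, ("SAM", "SAH"))
        m = fit_fda(ds, ("SAM", "SAH"), standardize=False)
        w_star = brute_force_direction(X, labels)
        cos = abs(float(m.w @ w_star))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_criterion_scale_invariant(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        m = fit_fda(ds, ("8-OHG", "GSSG"))
        J1 = criterion(m.w, m.fit.S_B, m.fit.S_W)
        J2 = criterion(3.7 * m.w, m.fit.S_B, m.fit.S_W)
        assert J1 == pytest.approx(J2, rel=1e-12)

    def test_scatter_matrices_symmetric_psd(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        m = fit_fda(ds, TOY_VARS[:4])
        assert np.allclose(m.fit.S_B, m.fit.S_B.T)
        assert np.allclose(m.fit.S_W, m.fit.S_W.T)
        assert np.linalg.eigvalsh(m.fit.S_W).min() > -1e-8
        # two classes: S_B has rank <= 1
        assert np.linalg.matrix_rank(m.fit.S_B, tol=1e-8) <= 1

    def test_empty_class_errors(self, toy_1d):
        with pytest.raises(FitError):
            fit_fda(toy_1d, ("Methionine",), ("ASD", "SIB"))

    def test_degenerate_scatter_errors(self):
        X = np.ones((6, 2))
        ds = make_dataset(X, ["ASD"] * 3 + ["NEU"] * 3, ("SAM", "SAH"))
        with pytest.raises(FitError, match="degenerate"):
            fit_fda(ds, ("SAM", "SAH"))

    def test_closed_form_matches_generalized_eigensolution(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = 12
            p = 3
            X = rng.standard_normal((2 * n, p))
            X[:n] += rng.normal(0, 1, p)
            labels = ["ASD"] * n + ["NEU"] * n
            ds = make_dataset(X, labels, ("SAM", "SAH", "tGSH"))
            m = fit_fda(ds, ("SAM", "SAH", "tGSH"))
            vals, vecs = linalg.eigh(m.fit.S_B, m.fit.S_W)
            v = vecs[:, np.argmax(vals)]
            v = v / np.linalg.norm(v)
            cos = abs(float(m.w @ v))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_model_json_round_trip(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        m = fit_fda(ds, ("8-OHG", "GSSG"))
        m2 = fda.DiscriminantModel.from_json(m.to_json())
        np.testing.assert_allclose(m2.w, m.w)
        np.testing.assert_allclose(m2.standardizer.center, m.standardizer.center)
        assert m2.classes == m.classes


class TestProjectScores:
    def test_declared_standardizer_arithmetic(self):
        std = Standardizer(np.array([5.5]), np.array([5.244]))
        z = std(np.array([[10.0]]))
        assert z[0, 0] == pytest.approx((10 - 5.5) / 5.244)
        assert z[0, 0] == pytest.approx(0.858, abs=1e-3)

    def test_projected_class_mean_equals_stored_mean(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        vars_ = ("8-OHG", "GSSG")
        m = fit_fda(ds, vars_)
        mean_asd = ds.cohort_matrix("ASD", vars_).mean(axis=0)
        score = (m.standardizer(mean_asd[None, :]) @ m.w)[0]
        assert score == pytest.approx(m.class_score_means["ASD"], abs=1e-12)

    def test_orientation_mean_asd_above_neu(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        m = fit_fda(ds, TOY_VARS)
        s_asd = project_scores(m, ds.subset_cohorts(["ASD"]))
        s_neu = project_scores(m, ds.subset_cohorts(["NEU"]))
        assert s_asd.mean() > s_neu.mean()


class TestLooScores:
    def test_six_sample_manual_fold(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 2)) + np.array([[2, 0]] * 3 + [[0, 0]] * 3)
        labels = ["ASD"] * 3 + ["NEU"] * 3
        ds = make_dataset(X, labels, ("SAM", "SAH"))
        cv = loo_scores(ds, ("SAM", "SAH"))
        assert len(cv.scores) == 6
        # manual single fold: drop sample 0, fit, project it
        ds_rest = make_dataset(X[1:], labels[1:], ("SAM", "SAH"))
        m = fit_fda(ds_rest, ("SAM", "SAH"))
        manual = (m.standardizer(X[0][None, :]) @ m.w)[0]
        assert cv.scores[0] == pytest.approx(manual, abs=1e-10)

    def test_matches_naive_refit_loop(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        vars_ = ("8-OHG", "GSSG", "SAM")
        cv = loo_scores(ds, vars_)
        sub = ds.subset_cohorts(("ASD", "NEU"))
        X = sub.matrix(vars_)
        labels = np.asarray([s.cohort for s in sub.samples])
        mask = np.ones(len(labels), dtype=bool)
        for j in range(0, len(labels), 17):  # spot-check folds
            mask[j] = False
            m = fda._fit_arrays(X[mask], labels[mask], ("ASD", "NEU"), vars_)
            expected = (m.standardizer(X[j][None, :]) @ m.w)[0]
            assert cv.scores[j] == pytest.approx(expected, abs=1e-10)
            mask[j] = True

    def test_deterministic(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        a = loo_scores(ds, ("8-OHG",)).scores
        b = loo_scores(ds, ("8-OHG",)).scores
        np.testing.assert_array_equal(a, b)

    def test_permutation_invariant(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        cv = loo_scores(ds, ("8-OHG", "GSSG"))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ds.subset_cohorts(("ASD", "NEU"))))
        sub = ds.subset_cohorts(("ASD", "NEU"))
        shuffled = make_dataset(
            sub.matrix(("8-OHG", "GSSG"))[perm],
            [sub.samples[i].cohort for i in perm],
            ("8-OHG", "GSSG"),
            ids=[sub.samples[i].id for i in perm],
        )
        cv2 = loo_scores(shuffled, ("8-OHG", "GSSG"))
        by_id = dict(zip(cv2.ids, cv2.scores))
        for i, sid in enumerate(cv.ids):
            assert by_id[sid] == pytest.approx(cv.scores[i], abs=1e-10)

    def test_affine_rescaling_leaves_scores_unchanged(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        vars_ = ("8-OHG", "GSSG")
        cv = loo_scores(ds, vars_)
        sub = ds.subset_cohorts(("ASD", "NEU"))
        X = sub.matrix(vars_).copy()
        X[:, 0] = X[:, 0] * 1000.0  # unit change on one variable
        scaled = make_dataset(
            X, [s.cohort for s in sub.samples], vars_, ids=[s.id for s in sub.samples]
        )
        cv2 = loo_scores(scaled, vars_)
        np.testing.assert_allclose(cv2.scores, cv.scores, atol=1e-8)

    def test_too_few_samples_errors(self):
        ds = make_dataset(
            [[0.0], [1.0], [10.0], [11.0]], ["ASD", "ASD", "NEU", "NEU"], ("SAM",)
        )
        with pytest.raises(FitError, match=">= 3"):
            loo_scores(ds, ("SAM",))

    def test_overlapping_classes_give_overlapping_scores(self, null_two_cohorts):
        cv = loo_scores(null_two_cohorts, ("SAM", "SAH"))
        a = cv.by_cohort("ASD")
        n = cv.by_cohort("NEU")
        # heavy overlap: each cohort's median falls inside the other's range
        assert n.min() < np.median(a) < n.max()
        assert a.min() < np.median(n) < a.max()

    def test_planted_direction_concentrates(self):
        cfg = SyntheticConfig(
            n_asd=400,
            n_sib=0,
            n_neu=400,
            variables=TOY_VARS,
            delta={"8-OHG": 2.0},
            rho=0.0,
            vineland_link=None,
            seed=9,
        )
        ds, _ = generate_cohorts(cfg)
        m = fit_fda(ds, TOY_VARS)
        i = m.variables.index("8-OHG")
        assert abs(m.w[i]) > 0.9


class TestProjectExternal:
    def test_training_cohort_matches_project_scores(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        m = fit_fda(ds, TOY_VARS)
        ext = dict(project_external(m, ds, "NEU"))
        direct = project_scores(m, ds.subset_cohorts(["NEU"]))
        ids = [s.id for s in ds.samples if s.cohort == "NEU"]
        for sid, val in zip(ids, direct):
            assert ext[sid] == pytest.approx(val, abs=1e-12)

    def test_absent_cohort_errors(self, planted_two_cohorts):
        ds, _ = planted_two_cohorts
        m = fit_fda(ds, TOY_VARS)
        with pytest.raises(FitError, match="SIB"):
            project_external(m, ds, "SIB")

    def test_neu_like_sib_classified_mostly_neu(self):
        cfg = SyntheticConfig(
            n_asd=80,
            n_sib=40,
            n_neu=80,
            variables=TOY_VARS,
            delta={"8-OHG": 2.0, "GSSG": 2.0},
            sib_mixing=0.1,
            vineland_link=None,
            seed=21,
        )
        ds, _ = generate_cohorts(cfg)
        m = fit_fda(ds, TOY_VARS)
        sib = np.array([s for _, s in project_external(m, ds, "SIB")])
        midpoint = 0.5 * (
            m.class_score_means["ASD"] + m.class_score_means["NEU"]
        )
        assert np.mean(sib <= midpoint) > 0.5
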