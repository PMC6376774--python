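"""Multinomial GEE solver: link, score identities, oracles, covariances."""

import numpy as np
import pandas as pd
import pytest

from landmarkdpo.data import build_landmark_dataset
from landmarkdpo.model import (
    LandmarkGEE,
    PredictionModel,
    fit_fixed_landmark,
    fit_supermodel,
    inverse_glogit,
)
from landmarkdpo.pseudo import compute_dpos, dpo_aj, stack_dpos
from landmarkdpo.simulate import Scenario, simulate_cohort

from conftest import make_rows


class TestInverseGlogit:
    def test_symmetry(self):
        assert inverse_glogit([0.0, 0.0]) == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_closed_form(self):
        assert inverse_glogit([np.log(2.0)]) == pytest.approx([1 / 3, 2 / 3])

    def test_reference_limit(self):
        p = inverse_glogit([-50.0, -50.0])
        assert p[0] == pytest.approx(1.0)

    def test_overflow_guard(self):
        p = inverse_glogit([1000.0, 0.0])
        assert np.isfinite(p).all()
        assert p == pytest.approx([0.0, 1.0, 0.0], abs=1e-12)

    def test_sums_to_one_batch(self, rng):
        eta = rng.normal(size=(20, 3)) * 5
        assert inverse_glogit(eta).sum(axis=1) == pytest.approx(np.ones(20))


def _covariate_frame(rows, rng, binary=True):
    ids = [r.subject_id for r in rows]
    x = rng.integers(0, 2, len(ids)) if binary else rng.normal(size=len(ids))
    return pd.DataFrame({"id": ids, "x": x.astype(float)})


class TestFixedLandmark:
    @pytest.mark.parametrize("terminal_mode, lambda0D", [("absent", 0.0), ("present", 0.4)])
    @pytest.mark.parametrize("working", ["multinomial", "binary"])
    def test_intercept_only_recovers_column_means(self, terminal_mode, lambda0D, working):
        rows, _ = make_rows(seed=1, n=80, lambda0D=lambda0D, lambda_c=0.7, terminal_mode=terminal_mode)
        dpo = dpo_aj(rows, 1.0, 2, terminal_mode)
        res = fit_fixed_landmark(dpo, working=working)
        fitted = res.predict({}, 0.0)["prob"].to_numpy()
        assert fitted == pytest.approx(dpo.column_means(), abs=1e-8)

    def test_uncensored_two_category_equals_logistic_regression(self, rng):
        import statsmodels.api as sm

        rows, _ = make_rows(seed=2, n=120, lambda_c=0.0, k_max=1)
        dpo = dpo_aj(rows, 1.0, 1)
        cov = _covariate_frame(rows, rng)
        res = fit_fixed_landmark(dpo, cov, columns=["x"])
        y = np.round(dpo.theta[:, 1])  # exact indicators without censoring
        x = sm.add_constant(cov["x"].to_numpy())
        logit = sm.Logit(y, x).fit(disp=0)
        assert res.params == pytest.approx(logit.params, abs=1e-6)

    def test_group_fit_matches_joint_saturated_fit(self, rng):
        rows, _ = make_rows(seed=3, n=100, lambda_c=0.5)
        dpo = dpo_aj(rows, 1.0, 2)
        cov = _covariate_frame(rows, rng)
        joint = fit_fixed_landmark(dpo, cov, columns=["x"])
        for level in (0.0, 1.0):
            mask = np.isin(dpo.subject_ids, cov.loc[cov["x"] == level, "id"])
            sub = type(dpo)(
                landmark_time=dpo.landmark_time,
                subject_ids=[s for s, m in zip(dpo.subject_ids, mask) if m],
                theta=dpo.theta[mask],
                estimator=dpo.estimator,
                window=dpo.window,
                k_max=dpo.k_max,
                terminal_mode=dpo.terminal_mode,
            )
            sep = fit_fixed_landmark(sub)
            p_joint = joint.predict({"x": level}, 0.0)["prob"].to_numpy()
            p_sep = sep.predict({}, 0.0)["prob"].to_numpy()
            assert p_joint == pytest.approx(p_sep, abs=1e-7)

    def test_relabeling_invariance(self, rng):
        # permuting the non-reference categories permutes predictions with them
        rows, _ = make_rows(seed=4, n=80, lambda0D=0.4, lambda_c=0.5, terminal_mode="present")
        dpo = dpo_aj(rows, 1.0, 2, "present")
        res = fit_fixed_landmark(dpo)
        perm = [0, 2, 3, 1]  # keep reference, cycle the rest
        permuted = type(dpo)(
            landmark_time=dpo.landmark_time,
            subject_ids=dpo.subject_ids,
            theta=dpo.theta[:, perm],
            estimator=dpo.estimator,
            window=dpo.window,
            k_max=dpo.k_max,
            terminal_mode=dpo.terminal_mode,
        )
        stacked = permuted.to_frame()
        model = LandmarkGEE(
            theta=dpo.theta[:, perm],
            exog=np.empty((len(dpo.subject_ids), 0)),
            subject_ids=np.array(dpo.subject_ids),
            landmarks=np.zeros(len(dpo.subject_ids)),
            categories=[dpo.categories[i] for i in perm],
            cov_names=[],
        )
        res_perm = model.fit()
        p = res.predict({}, 0.0).set_index("category")["prob"]
        p_perm = res_perm.predict({}, 0.0).set_index("category")["prob"]
        for cat in p.index:
            assert p_perm[cat] == pytest.approx(p[cat], abs=1e-8)


def _stacked_setup(seed=0, n=250, grid=(0.0, 0.4, 0.8), max_events=4, lambda0D=0.3):
    scenario = Scenario(
        frailty="gamma", lambda01=0.9, lambda02=1.2, lambda0D=lambda0D, lambda_c=0.25,
        n=n, max_events=max_events,
    )
    hists, _ = simulate_cohort(scenario, seed)
    ds = build_landmark_dataset(hists, list(grid), 1.0, 2, scenario.terminal_mode)
    dpos = compute_dpos(ds, "aj")
    stacked = stack_dpos(dpos)
    frame = ds.to_frame()
    cov = frame[["id", "landmark"]].copy()
    cov["prior_recurrence"] = (frame["prior_events"] >= 1).astype(float)
    return stacked, cov, ds


class TestSupermodel:
    def test_degree_zero_equals_pooled_fixed_fit(self):
        stacked, cov, _ = _stacked_setup()
        sup = fit_supermodel(stacked, cov, smoother_degree=0, columns=["prior_recurrence"])
        theta_cols = [c for c in stacked.columns if c.startswith("theta_")]
        merged = stacked.merge(cov, on=["id", "landmark"])
        pooled = LandmarkGEE(
            theta=merged[theta_cols].to_numpy(),
            exog=merged[["prior_recurrence"]].to_numpy(),
            subject_ids=merged["id"].to_numpy(),
            landmarks=np.zeros(len(merged)),
            categories=[c[len("theta_"):] for c in theta_cols],
            cov_names=["prior_recurrence"],
        ).fit()
        assert sup.params == pytest.approx(pooled.params, abs=1e-7)

    def test_saturated_supermodel_matches_fixed_fits(self):
        # intercept-only, 2 landmarks, degree 1: the basis is saturated, so
        # the supermodel solves each per-landmark score separately
        stacked, cov, ds = _stacked_setup(grid=(0.0, 0.5))
        sup = fit_supermodel(stacked, None, smoother_degree=1, columns=[])
        dpos = compute_dpos(ds, "aj")
        for dpo, s in zip(dpos, ds.grid):
            fixed = fit_fixed_landmark(dpo)
            p_sup = sup.predict({}, s)["prob"].to_numpy()
            p_fix = fixed.predict({}, s)["prob"].to_numpy()
            assert p_sup == pytest.approx(p_fix, abs=1e-6)

    def test_parameter_counts_match_application_layout(self, rng):
        # 3 binary covariates, cubic smoothers: 3 categories x 4 bases x 4
        # columns = 48 with terminal; 2 x 4 x 4 = 32 without
        stacked, cov, _ = _stacked_setup(grid=(0.0, 0.3, 0.6, 0.9, 1.2, 1.5), n=400)
        cov = cov.copy()
        ids = cov["id"].unique()
        draws = pd.DataFrame({
            "id": ids,
            "z1": rng.integers(0, 2, len(ids)).astype(float),
            "z2": rng.integers(0, 2, len(ids)).astype(float),
        })
        cov = cov.merge(draws, on="id")
        cols = ["prior_recurrence", "z1", "z2"]
        model = LandmarkGEE.from_stacked(stacked, cov, columns=cols, smoother_degree=3)
        assert model.n_params == 48
        no_term = stacked.drop(columns=["theta_D"]).copy()
        theta_cols = [c for c in no_term.columns if c.startswith("theta_")]
        no_term[theta_cols] = no_term[theta_cols].div(no_term[theta_cols].sum(axis=1), axis=0)
        model2 = LandmarkGEE.from_stacked(no_term, cov, columns=cols, smoother_degree=3)
        assert model2.n_params == 32

    def test_sandwich_matches_brute_force(self):
        stacked, cov, _ = _stacked_setup()
        model = LandmarkGEE.from_stacked(
            stacked, cov, columns=["prior_recurrence"], smoother_degree=1
        )
        res = model.fit()
        g_rows, a = model._score_pieces(res.params)
        ids = model.subject_ids
        bread = np.linalg.pinv(a)
        meat = np.zeros((model.n_params, model.n_params))
        for sid in pd.unique(ids):
            g = g_rows[ids == sid].sum(axis=0)
            meat += np.outer(g, g)
        assert res.cov_params == pytest.approx(bread @ meat @ bread, abs=1e-10)

    def test_prediction_probabilities_sum_to_one(self):
        stacked, cov, _ = _stacked_setup(grid=(0.0, 0.3, 0.6, 0.9))
        res = fit_supermodel(stacked, cov, smoother_degree=2, columns=["prior_recurrence"])
        for s in (0.0, 0.33, 0.8):
            p = res.predict({"prior_recurrence": 1.0}, s)
            assert p["prob"].sum() == pytest.approx(1.0)
            assert (p["ci_low"] >= 0).all() and (p["ci_high"] <= 1).all()

    def test_errors(self):
        stacked, cov, _ = _stacked_setup()
        one = stacked[stacked["landmark"] == 0.0]
        with pytest.raises(ValueError, match="at least 2 landmarks"):
            fit_supermodel(one, cov, smoother_degree=1, columns=["prior_recurrence"])
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_supermodel(stacked, cov, smoother_degree=3, columns=["prior_recurrence"])
        with pytest.raises(ValueError, match="missing covariate column"):
            fit_supermodel(stacked, cov, smoother_degree=1, columns=["nope"])
        res = fit_supermodel(stacked, cov, smoother_degree=1, columns=["prior_recurrence"])
        with pytest.raises(ValueError, match="refusing to extrapolate"):
            res.predict({"prior_recurrence": 0.0}, 5.0)

    def test_rank_deficiency_names_columns(self):
        stacked, cov, _ = _stacked_setup()
        cov = cov.copy()
        cov["dup"] = cov["prior_recurrence"]
        with pytest.raises(ValueError, match="collinear"):
            fit_supermodel(stacked, cov, smoother_degree=1, columns=["prior_recurrence", "dup"])

    def test_raw_scale_coefficients_reproduce_centered_predictions(self):
        stacked, cov, _ = _stacked_setup(grid=(0.0, 0.3, 0.6, 0.9))
        res = fit_supermodel(stacked, cov, smoother_degree=2, columns=["prior_recurrence"])
        raw = res.coef_table(scale="raw")
        s, xval = 0.4, 1.0
        eta = {}
        for cat, grp in raw.groupby("category"):
            val = 0.0
            for _, row in grp.iterrows():
                term_val = 1.0 if row["term"] == "Intercept" else xval
                val += row["estimate"] * term_val * s ** row["degree"]
            eta[cat] = val
        cats = res.model.categories
        probs = inverse_glogit([eta[c] for c in cats[1:]])
        expected = res.predict({"prior_recurrence": xval}, s)["prob"].to_numpy()
        assert probs == pytest.approx(expected, abs=1e-10)

    def test_save_load_round_trip(self, tmp_path):
        stacked, cov, _ = _stacked_setup()
        res = fit_supermodel(stacked, cov, smoother_degree=1, columns=["prior_recurrence"])
        res.save(tmp_path / "model.json")
        back = PredictionModel.load(tmp_path / "model.json")
        a = res.predict({"prior_recurrence": 1.0}, 0.4)
        b = back.predict({"prior_recurrence": 1.0}, 0.4)
        pd.testing.assert_frame_equal(a, b)

    def test_summary_mentions_convergence(self):
        stacked, cov, _ = _stacked_setup()
        res = fit_supermodel(stacked, cov, smoother_degree=1, columns=["prior_recurrence"])
        text = res.summary()
        assert "converged" in text and "robust" in text
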