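"""Landmark regression models on dynamic pseudo-observations.

The pseudo-observation vector of each at-risk subject is treated as a
multinomial outcome and related to landmark covariates through a generalized
logit link.  Coefficients solve the quasi-score estimating equation

    U(beta) = sum_i D_i^T V_i^{-1} (theta_hat_i - theta_i(beta)) = 0,

with ``D_i = d theta_i / d beta`` and ``V_i`` the multinomial covariance at
the current fit.  Two model flavours share one solver:

* **fixed-landmark model** — one landmark, one coefficient vector per
  non-reference category, model-based covariance ``(sum D^T V^{-1} D)^{-1}``;
* **supermodel** — pseudo-observations stacked over a landmark grid with
  coefficients varying as ``beta(s) = f(s) . beta`` for a polynomial basis
  ``f(s) = (1, s, ..., s^h)``, working independence across a subject's
  landmark blocks, and a robust sandwich covariance clustered by subject.

Landmark times are centered at the grid midpoint before powers are taken
(configurable); an un-centering expansion reports raw-scale coefficients.

Usage follows the Model/Results pattern::

    model = LandmarkGEE.from_stacked(stacked, covariates, columns=[...], smoother_degree=3)
    res = model.fit()
    res.summary()
    res.predict({"prior_recurrence": 1, ...}, s=2.0)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LandmarkGEE",
    "LandmarkGEEResults",
    "PredictionModel",
    "inverse_glogit",
    "fit_fixed_landmark",
    "fit_supermodel",
    "predict_probabilities",
]

_PROB_FLOOR = 1e-10


def inverse_glogit(eta) -> np.ndarray:
    """Map per-category linear predictors to probabilities, reference first.

    ``p_c = exp(eta_c) / (1 + sum exp(eta))`` and
    ``p_ref = 1 / (1 + sum exp(eta))``; overflow is guarded by a max-shift.
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    single = eta.ndim == 1
    if single:
        eta = eta[None, :]
    m = np.maximum(eta.max(axis=-1, keepdims=True), 0.0)
    num = np.exp(eta - m)
    denom = np.exp(-m) + num.sum(axis=-1, keepdims=True)
    probs = np.concatenate([np.exp(-m) / denom, num / denom], axis=-1)
    return probs[0] if single else probs


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LandmarkGEE:
    """Multinomial GEE model for dynamic pseudo-observations.

    Parameters
    ----------
    theta
        (N, C) pseudo-observation matrix including the reference (zero-event)
        column first.
    exog
        (N, p) numeric covariate matrix, without intercept.
    subject_ids
        Length-N cluster labels; a subject repeated over landmarks forms one
        cluster for the sandwich covariance.
    landmarks
        Length-N landmark times.
    categories
        C category labels, reference first.
    cov_names
        p covariate names.
    smoother_degree
        ``None`` for the fixed-landmark model (single landmark); an integer
        ``h >= 0`` for the supermodel polynomial basis.
    working
        ``"multinomial"`` (full multinomial working covariance) or
        ``"binary"`` (diagonal working covariance; the per-category binary
        workaround, giving the same point estimates in practice).
    """

    theta: np.ndarray
    exog: np.ndarray
    subject_ids: np.ndarray
    landmarks: np.ndarray
    categories: list
    cov_names: list
    smoother_degree: int | None = None
    working: str = "multinomial"
    center_landmarks: bool = True
    landmark_center: float = field(init=False, default=0.0)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.exog = np.asarray(self.exog, dtype=float)
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.working not in ("multinomial", "binary"):
            raise ValueError("working must be 'multinomial' or 'binary'")
        if np.isnan(self.exog).any():
            bad = np.argwhere(np.isnan(self.exog))[0]
            raise ValueError(
                f"missing covariate value: column '{self.cov_names[bad[1]]}' "
                f"for subject {self.subject_ids[bad[0]]}"
            )
        distinct = np.unique(self.landmarks)
        if self.smoother_degree is None:
            if distinct.size != 1:
                raise ValueError("fixed-landmark model requires a single landmark; use smoother_degree")
            self._degree = 0
            self.landmark_center = 0.0
        else:
            h = int(self.smoother_degree)
            if h < 0:
                raise ValueError("smoother_degree must be >= 0")
            if distinct.size < 2:
                raise ValueError("supermodel requires at least 2 landmarks")
            if h >= distinct.size:
                raise ValueError(
                    f"smoother degree {h} is unidentifiable with {distinct.size} landmarks"
                )
            self._degree = h
            self.landmark_center = (
                (distinct.min() + distinct.max()) / 2.0 if self.center_landmarks else 0.0
            )
        self._landmark_range = (float(distinct.min()), float(distinct.max()))
        self._design = self._row_design(self.exog, self.landmarks)
        self._check_rank()
        codes, self._clusters = pd.factorize(self.subject_ids)
        self._cluster_codes = codes

    # -- design ------------------------------------------------------------

    @property
    def n_categories(self) -> int:
        return self.theta.shape[1]

    @property
    def term_names(self) -> list:
        return ["Intercept", *self.cov_names]

    def _basis(self, s: np.ndarray) -> np.ndarray:
        sc = np.asarray(s, dtype=float) - self.landmark_center
        return np.vander(sc, self._degree + 1, increasing=True)

    def _row_design(self, exog: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Per-row within-category design: kron(basis(s), (1, x))."""
        z = np.column_stack([np.ones(len(exog)), exog])
        f = self._basis(s)
        return np.einsum("nb,nq->nbq", f, z).reshape(len(exog), -1)

    @property
    def n_params(self) -> int:
        return (self.n_categories - 1) * self._design.shape[1]

    def _check_rank(self):
        d = self._design
        rank = np.linalg.matrix_rank(d)
        if rank < d.shape[1]:
            # name the dependent columns via pivoted QR
            from scipy.linalg import qr

            _, _, piv = qr(d, mode="economic", pivoting=True)
            bad = sorted(piv[rank:])
            q = len(self.term_names)
            names = [f"{self.term_names[j % q]}*s^{j // q}" for j in bad]
            raise ValueError(f"rank-deficient design; collinear columns: {names}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dpo(cls, dpo, covariates=None, columns=None, **kwargs) -> "LandmarkGEE":
        """Fixed-landmark model from a single DPO matrix plus a covariate table."""
        stacked = dpo.to_frame()
        return cls.from_stacked(stacked, covariates, columns=columns, smoother_degree=None, **kwargs)

    @classmethod
    def from_stacked(
        cls,
        stacked: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        columns=None,
        smoother_degree: int | None = None,
        **kwargs,
    ) -> "LandmarkGEE":
        """Model from a stacked DPO table (see :func:`landmarkdpo.pseudo.stack_dpos`).

        ``covariates`` is joined by ``id`` (and by ``landmark`` too when it
        has such a column, for landmark-varying covariates).
        """
        theta_cols = [c for c in stacked.columns if c.startswith("theta_")]
        categories = [c[len("theta_"):] for c in theta_cols]
        merged = stacked
        if covariates is not None:
            cov = covariates.copy()
            cov["id"] = cov["id"].astype(str)
            merged = merged.copy()
            merged["id"] = merged["id"].astype(str)
            keys = ["id", "landmark"] if "landmark" in cov.columns else ["id"]
            merged = merged.merge(cov, on=keys, how="left", validate="many_to_one")
        if columns is None:
            reserved = {"id", "landmark", "estimator", *theta_cols}
            columns = [c for c in merged.columns if c not in reserved]
        missing = [c for c in columns if c not in merged.columns]
        if missing:
            raise ValueError(f"missing covariate column(s): {missing}")
        exog = merged[list(columns)].to_numpy(dtype=float)
        return cls(
            theta=merged[theta_cols].to_numpy(dtype=float),
            exog=exog,
            subject_ids=merged["id"].to_numpy(),
            landmarks=merged["landmark"].to_numpy(dtype=float),
            categories=categories,
            cov_names=list(columns),
            smoother_degree=smoother_degree,
            **kwargs,
        )

    # -- estimation --------------------------------------------------------

    def _mu(self, beta: np.ndarray) -> np.ndarray:
        cm1 = self.n_categories - 1
        b = beta.reshape(cm1, -1)
        eta = self._design @ b.T  # (N, C-1)
        probs = inverse_glogit(eta)
        return probs[:, 1:]  # non-reference means

    def _score_pieces(self, beta: np.ndarray):
        d = self._design
        mu = self._mu(beta)
        mu_f = np.clip(mu, _PROB_FLOOR, None)
        v = np.einsum("nc,cd->ncd", mu_f, np.eye(mu.shape[1])) - np.einsum(
            "nc,nd->ncd", mu_f, mu_f
        )
        r = self.theta[:, 1:] - mu
        if self.working == "multinomial":
            # V_i^{-1} cancels against D_i = V_i Z_i*: score rows are Z_i*^T r_i
            g_rows = np.einsum("nc,nb->ncb", r, d)
            a = np.einsum("ncd,nb,ne->cbde", v, d, d)
        else:
            w_inv = 1.0 / np.clip(mu_f * (1.0 - mu_f), _PROB_FLOOR, None)
            g_rows = np.einsum("ncd,nc,nc,ne->nde", v, w_inv, r, d)
            a = np.einsum("nca,nc,ncb,ne,nf->aebf", v, w_inv, v, d, d)
        p = self.n_params
        return g_rows.reshape(len(d), p), a.reshape(p, p)

    def fit(self, maxiter: int = 100, score_tol: float = 1e-8, param_tol: float = 1e-10) -> "LandmarkGEEResults":
        """Fisher scoring with step-halving from a zero start."""
        p = self.n_params
        beta = np.zeros(p)
        g_rows, a = self._score_pieces(beta)
        u = g_rows.sum(axis=0)
        unorm = np.max(np.abs(u))
        n_iter = 0
        converged = unorm < score_tol
        while not converged and n_iter < maxiter:
            n_iter += 1
            step = np.linalg.lstsq(a, u, rcond=None)[0]
            lam = 1.0
            while True:
                cand = beta + lam * step
                g_new, a_new = self._score_pieces(cand)
                u_new = g_new.sum(axis=0)
                unorm_new = np.max(np.abs(u_new))
                if unorm_new <= unorm or lam < 1.0 / 1024.0:
                    break
                lam *= 0.5
            delta = np.max(np.abs(cand - beta)) / max(1.0, np.max(np.abs(beta)))
            beta, g_rows, a, u, unorm = cand, g_new, a_new, u_new, unorm_new
            if np.max(np.abs(beta)) > 1e6:
                raise ConvergenceError(
                    "coefficients diverging; an outcome category is likely (near-)empty "
                    "for some covariate stratum (separation)"
                )
            if unorm < score_tol or delta < param_tol:
                converged = True
        if not converged:
            raise ConvergenceError(f"Fisher scoring did not converge; last score norm {unorm:.3e}")

        a_inv = np.linalg.pinv(a)
        if self.smoother_degree is None:
            cov = a_inv
            cov_type = "model"
        else:
            # sandwich clustered by subject
            n_clusters = len(self._clusters)
            scores = np.zeros((n_clusters, p))
            np.add.at(scores, self._cluster_codes, g_rows)
            b_mat = scores.T @ scores
            cov = a_inv @ b_mat @ a_inv
            cov_type = "robust"
        cov = (cov + cov.T) / 2.0
        return LandmarkGEEResults(
            model=self,
            params=beta,
            cov_params=cov,
            cov_type=cov_type,
            n_iter=n_iter,
            score_norm=float(unorm),
            converged=converged,
        )


@dataclass
class LandmarkGEEResults:
    """Fit results: coefficients, covariance, diagnostics, prediction."""

    model: LandmarkGEE
    params: np.ndarray
    cov_params: np.ndarray
    cov_type: str
    n_iter: int
    score_norm: float
    converged: bool

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    def _param_index(self):
        cats = self.model.categories[1:]
        terms = self.model.term_names
        degrees = range(self.model._degree + 1)
        q = len(terms)
        idx = []
        for c in cats:
            for b in degrees:
                for t in terms:
                    idx.append((c, t, b))
        return idx

    def coef_table(self, scale: str = "centered") -> pd.DataFrame:
        """Tidy coefficient table (category, term, degree, estimate, se).

        ``scale="raw"`` re-expands the centered polynomial so coefficients
        refer to powers of the raw landmark time (standard errors are only
        reported on the centered scale on which the fit was run).
        """
        idx = self._param_index()
        tab = pd.DataFrame(idx, columns=["category", "term", "degree"])
        tab["estimate"] = self.params
        tab["se"] = self.bse
        if scale == "raw" and self.model.landmark_center != 0.0:
            c = self.model.landmark_center
            out = tab.copy()
            out["estimate"] = 0.0
            out["se"] = np.nan
            h = self.model._degree
            for (cat, term), grp in tab.groupby(["category", "term"], sort=False):
                beta_c = grp.sort_values("degree")["estimate"].to_numpy()
                raw = np.zeros(h + 1)
                for b in range(h + 1):
                    for bp in range(b + 1):
                        raw[bp] += beta_c[b] * comb(b, bp) * (-c) ** (b - bp)
                sel = (out["category"] == cat) & (out["term"] == term)
                out.loc[sel, "estimate"] = raw
            return out
        return tab

    def summary(self) -> str:
        kind = "fixed landmark" if self.model.smoother_degree is None else (
            f"supermodel (degree {self.model._degree})"
        )
        lines = [
            "Landmark multinomial GEE on dynamic pseudo-observations",
            f"  model:        {kind}",
            f"  categories:   {self.model.categories} (reference '{self.model.categories[0]}')",
            f"  observations: {len(self.model.theta)}  clusters: {len(self.model._clusters)}",
            f"  covariance:   {self.cov_type}",
            f"  converged:    {self.converged} in {self.n_iter} iterations "
            f"(score norm {self.score_norm:.2e})",
            "",
            self.coef_table().to_string(index=False, float_format=lambda x: f"{x: .4f}"),
        ]
        return "\n".join(lines)

    # -- prediction --------------------------------------------------------

    def to_prediction_model(self) -> "PredictionModel":
        """Detach a lightweight, serialisable predictor from the fit."""
        return PredictionModel(
            params=self.params.copy(),
            cov_params=self.cov_params.copy(),
            categories=list(self.model.categories),
            cov_names=list(self.model.cov_names),
            degree=self.model._degree,
            landmark_center=self.model.landmark_center,
            landmark_range=self.model._landmark_range,
            is_fixed=self.model.smoother_degree is None,
            cov_type=self.cov_type,
        )

    def predict(self, covariates, s: float, alpha: float = 0.05) -> pd.DataFrame:
        """Per-category probabilities with delta-method SEs and Wald CIs.

        ``covariates`` is a mapping or single-row frame of covariate values;
        CIs are on the probability scale, truncated to [0, 1].
        """
        return self.to_prediction_model().predict(covariates, s, alpha=alpha)

    predict_probabilities = predict

    def save(self, path) -> None:
        self.to_prediction_model().save(path)


@dataclass
class PredictionModel:
    """Everything needed to turn covariates and a landmark time into
    probabilities: coefficients, their covariance, and the link metadata."""

    params: np.ndarray
    cov_params: np.ndarray
    categories: list
    cov_names: list
    degree: int
    landmark_center: float
    landmark_range: tuple
    is_fixed: bool
    cov_type: str

    def _design_point(self, x: np.ndarray, s: float) -> np.ndarray:
        lo, hi = self.landmark_range
        if self.is_fixed:
            if not np.isclose(s, lo):
                raise ValueError(f"fixed-landmark fit is only valid at s={lo}")
        elif not (lo <= s <= hi):
            raise ValueError(
                f"s={s} outside the fitted landmark range [{lo}, {hi}]; refusing to extrapolate"
            )
        f = (s - self.landmark_center) ** np.arange(self.degree + 1)
        z = np.concatenate([[1.0], x])
        return np.kron(f, z)

    def predict(self, covariates, s: float, alpha: float = 0.05) -> pd.DataFrame:
        if isinstance(covariates, pd.DataFrame):
            covariates = covariates.iloc[0].to_dict()
        x = np.array([float(covariates[name]) for name in self.cov_names])
        d = self._design_point(x, float(s))
        n_cat = len(self.categories)
        eta = self.params.reshape(n_cat - 1, -1) @ d
        probs = inverse_glogit(eta)
        # dp/deta for the full vector (reference first): dp_c/deta_k = p_c (I(c=k) - p_k)
        dp_deta = probs[:, None] * (np.eye(n_cat)[:, 1:] - probs[None, 1:])
        jac = np.einsum("ck,b->ckb", dp_deta, d).reshape(n_cat, -1)
        var = jac @ self.cov_params @ jac.T
        se = np.sqrt(np.clip(np.diag(var), 0.0, None))
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "category": self.categories,
                "prob": probs,
                "se": se,
                "ci_low": np.clip(probs - z * se, 0.0, 1.0),
                "ci_high": np.clip(probs + z * se, 0.0, 1.0),
            }
        )

    def save(self, path) -> None:
        import json

        payload = {
            "params": self.params.tolist(),
            "cov_params": self.cov_params.tolist(),
            "categories": self.categories,
            "cov_names": self.cov_names,
            "degree": self.degree,
            "landmark_center": self.landmark_center,
            "landmark_range": list(self.landmark_range),
            "is_fixed": self.is_fixed,
            "cov_type": self.cov_type,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "PredictionModel":
        import json

        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            params=np.asarray(payload["params"]),
            cov_params=np.asarray(payload["cov_params"]),
            categories=payload["categories"],
            cov_names=payload["cov_names"],
            degree=int(payload["degree"]),
            landmark_center=float(payload["landmark_center"]),
            landmark_range=tuple(payload["landmark_range"]),
            is_fixed=bool(payload["is_fixed"]),
            cov_type=payload["cov_type"],
        )


# -- thin functional wrappers mirroring the operation surface ---------------


def fit_fixed_landmark(dpo, covariates=None, columns=None, working: str = "multinomial") -> LandmarkGEEResults:
    """Fit the fixed-landmark multinomial model to one DPO matrix."""
    return LandmarkGEE.from_dpo(dpo, covariates, columns=columns, working=working).fit()


def fit_supermodel(
    stacked,
    covariates=None,
    smoother_degree: int = 1,
    columns=None,
    working: str = "multinomial",
    center_landmarks: bool = True,
) -> LandmarkGEEResults:
    """Fit the polynomial-smoother supermodel to stacked DPOs."""
    return LandmarkGEE.from_stacked(
        stacked,
        covariates,
        columns=columns,
        smoother_degree=smoother_degree,
        working=working,
        center_landmarks=center_landmarks,
    ).fit()


def predict_probabilities(results: LandmarkGEEResults, covariates, s: float) -> pd.DataFrame:
    return results.predict(covariates, s)
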