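"""Edge-wise confound modelling and harmonization.

Technical and biological covariates (acquisition batch, sex, TSPO-binding
genotype, age, injected dose over body weight) each shift similarity edges.
A linear model per edge, fitted on healthy controls only, estimates those
shifts; subtracting the full prediction from every scan harmonizes the
cohort without touching disease-related variance that is absent in the
controls. The distribution of standardized coefficients across edges,
summarized as Cohen's d against zero, gives the global direction of each
covariate's effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ConfoundRegressor", "EffectSummary", "fit_confound_model",
    "residualize", "effect_size_summary",
]

DEFAULT_TERMS = ("batch", "sex", "genotype", "age", "dose_over_weight")

_SEX_CODE = {"F": 0.0, "M": 1.0}
_GENOTYPE_CODE = {"HAB": 0.0, "MAB": 1.0}


class ConfoundRegressor(TransformerMixin, BaseEstimator):
    """Per-edge ordinary least squares confound model.

    Parameters
    ----------
    terms : tuple of str
        Covariates to include; any subset of ``batch``, ``sex``,
        ``genotype``, ``age``, ``dose_over_weight``. Batch is one-hot
        encoded against the lexicographically first level; sex is coded
        F=0/M=1 and genotype HAB=0/MAB=1 so a positive coefficient means
        higher similarity in males / mixed-affinity binders.
    standardized_beta : bool
        If True, z-score the outcome and every predictor within the fit
        sample before fitting, yielding comparable standardized
        coefficients (for effect-size summaries, not residualization).
    zscore_residuals : bool
        If True, :meth:`transform` scales residuals by the mean/SD of the
        training-sample residuals per edge.

    Attributes
    ----------
    coef_ : ndarray [n_edges x p]
        Fitted coefficients, columns named in ``design_columns_``.
    batch_levels_ : tuple
        Batch levels seen at fit time (first = reference).
    residual_mean_, residual_std_ : ndarray [n_edges]
        Training-residual scaling parameters.
    train_ids_ : tuple
        Index labels of the training scans.
    """

    def __init__(self, terms=DEFAULT_TERMS, standardized_beta=False,
                 zscore_residuals=True):
        self.terms = terms
        self.standardized_beta = standardized_beta
        self.zscore_residuals = zscore_residuals

    # -- design ---------------------------------------------------------
    def _design(self, covariates: pd.DataFrame, fit: bool):
        cols = [np.ones(len(covariates))]
        names = ["intercept"]
        for term in self.terms:
            if term == "batch":
                batches = covariates["batch"].astype(str)
                if fit:
                    self.batch_levels_ = tuple(sorted(batches.unique()))
                    if len(self.batch_levels_) < 2:
                        raise ValueError(
                            "batch term requested but only one batch level "
                            f"present: {self.batch_levels_}")
                unseen = sorted(set(batches) - set(self.batch_levels_))
                if unseen:
                    raise ValueError(f"batch level(s) {unseen} unseen at fit time")
                for lvl in self.batch_levels_[1:]:
                    cols.append((batches == lvl).to_numpy(float))
                    names.append(f"batch:{lvl}")
            elif term == "sex":
                bad = sorted(set(covariates["sex"]) - set(_SEX_CODE))
                if bad:
                    raise ValueError(f"unknown sex token(s) {bad}")
                cols.append(covariates["sex"].map(_SEX_CODE).to_numpy(float))
                names.append("sex")
            elif term == "genotype":
                bad = sorted(set(covariates["genotype"]) - set(_GENOTYPE_CODE))
                if bad:
                    raise ValueError(
                        f"genotype term requested but level(s) {bad} are not "
                        "codable (drop the term for first-generation-tracer "
                        "cohorts)")
                cols.append(covariates["genotype"].map(_GENOTYPE_CODE).to_numpy(float))
                names.append("genotype")
            elif term in ("age", "dose_over_weight"):
                cols.append(covariates[term].to_numpy(float))
                names.append(term)
            else:
                raise ValueError(f"unknown confound term {term!r}")
        return np.column_stack(cols), names

    @staticmethod
    def _check_rank(X, names):
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, r, piv = qr(X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            tol = diag.max() * max(X.shape) * np.finfo(float).eps
            bad = sorted(names[piv[i]] for i in range(len(diag)) if diag[i] <= tol)
            raise ValueError(f"rank-deficient confound design; collinear "
                             f"column(s): {bad}")

    # -- estimator API --------------------------------------------------
    def fit(self, X, covariates: pd.DataFrame):
        """Fit per-edge OLS on the given (training, typically HC-only)
        scans.

        ``X`` is [n_scans x n_edges]; ``covariates`` is a DataFrame aligned
        row-wise with X (``manifest_to_frame`` output works).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("edge table must be 2-D [scans x edges]")
        if len(covariates) != X.shape[0]:
            raise ValueError("covariates and edge table row counts disagree")
        design, names = self._design(covariates, fit=True)
        self._check_rank(design, names)
        if X.shape[0] < design.shape[1] + 2:
            raise ValueError(f"need at least p+2 = {design.shape[1] + 2} "
                             f"training scans, got {X.shape[0]}")
        y = X
        if self.standardized_beta:
            ym = y.mean(axis=0)
            ys = y.std(axis=0, ddof=1)
            ys = np.where(ys > 0, ys, 1.0)
            y = (y - ym) / ys
            d = design.copy()
            for j in range(1, d.shape[1]):
                sd = d[:, j].std(ddof=1)
                d[:, j] = (d[:, j] - d[:, j].mean()) / (sd if sd > 0 else 1.0)
            design = d
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.coef_ = beta.T                      # [n_edges x p]
        self.design_columns_ = tuple(names)
        resid = y - design @ beta
        self.residual_mean_ = resid.mean(axis=0)
        sd = resid.std(axis=0, ddof=1)
        self.residual_std_ = np.where(sd > 0, sd, 1.0)
        self.train_ids_ = tuple(covariates.index.astype(str))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, covariates: pd.DataFrame):
        """Residualize scans: observed minus full linear prediction
        (optionally z-scored with training-sample statistics)."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError("edge count differs from the fitted model")
        design, _ = self._design(covariates, fit=False)
        resid = X - design @ self.coef_.T
        if self.zscore_residuals:
            resid = (resid - self.residual_mean_) / self.residual_std_
        return resid

    def coefficients(self, covariate: str) -> np.ndarray:
        """Per-edge coefficient vector for one design column (e.g. ``sex``
        or ``batch:SITE2``)."""
        check_is_fitted(self, "coef_")
        if covariate not in self.design_columns_:
            raise KeyError(f"{covariate!r} not in fitted design "
                           f"{self.design_columns_}")
        return self.coef_[:, self.design_columns_.index(covariate)]


def fit_confound_model(edges, covariates: pd.DataFrame, *, hc_only=True,
                       terms=DEFAULT_TERMS, standardized_beta=False,
                       zscore_residuals=True) -> ConfoundRegressor:
    """Convenience wrapper: fit a :class:`ConfoundRegressor`, restricting
    the training sample to healthy controls when ``hc_only`` (the leakage
    guard used before disease classification)."""
    edges = np.asarray(edges, dtype=float)
    if hc_only:
        mask = (covariates["group"] == "HC").to_numpy()
        if mask.sum() == 0:
            raise ValueError("no healthy-control scans to fit on")
        edges = edges[mask]
        covariates = covariates.loc[mask]
    model = ConfoundRegressor(terms=terms, standardized_beta=standardized_beta,
                              zscore_residuals=zscore_residuals)
    return model.fit(edges, covariates)


def residualize(edges, model: ConfoundRegressor, covariates: pd.DataFrame,
                zscore: bool | None = None) -> np.ndarray:
    """Apply a fitted confound model to any set of scans (``zscore``
    overrides the model's own residual-scaling setting)."""
    check_is_fitted(model, "coef_")
    X = np.asarray(edges, dtype=float)
    if X.shape[1] != model.coef_.shape[0]:
        raise ValueError("edge count differs from the fitted model")
    design, _ = model._design(covariates, fit=False)
    resid = X - design @ model.coef_.T
    if zscore if zscore is not None else model.zscore_residuals:
        resid = (resid - model.residual_mean_) / model.residual_std_
    return resid


@dataclass
class EffectSummary:
    covariate: str
    beta: np.ndarray
    cohen_d: float
    ci_low: float
    ci_high: float
    n_boot: int


def effect_size_summary(model: ConfoundRegressor, covariate: str,
                        n_boot: int = 1000, seed: int = 0) -> EffectSummary:
    """Cohen's d of a covariate's per-edge coefficient distribution
    against zero, with a percentile bootstrap CI over edges."""
    beta = model.coefficients(covariate)
    if beta.size < 2:
        raise ValueError("need at least 2 edges")
    sd = beta.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate coefficient distribution (zero spread)")
    d = float(beta.mean() / sd)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, beta.size, size=(n_boot, beta.size))
    samples = beta[idx]
    sds = samples.std(axis=1, ddof=1)
    ds = np.where(sds > 0, samples.mean(axis=1) / np.where(sds > 0, sds, 1.0), np.nan)
    lo, hi = np.nanpercentile(ds, [2.5, 97.5])
    return EffectSummary(covariate=covariate, beta=beta, cohen_d=d,
                         ci_low=float(lo), ci_high=float(hi), n_boot=n_boot)
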