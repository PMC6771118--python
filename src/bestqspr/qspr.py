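"""Linear structure-pathogenicity regression with LOO-validated outlier removal.

The model regresses per-variant mean severity (BDSI, percent) on the
modulus of the relative dimerization energy |ddE_dim| (kcal/mol) by
unweighted ordinary least squares. Model validation is leave-one-out
(LOO): each point is predicted by the line refitted without it, and a
point is an outlier when its LOO residual exceeds ``threshold`` (default
2) times the standard deviation of all LOO residuals.

Outlier deletion is iterative but deliberately conservative: flagged
points are removed and the model refitted only while the current model
is still inadequate, i.e. while both the training R^2 is below
``r2_adequate`` (default 0.75) and the LOO cross-validated R^2 (q^2,
the PRESS-based predicted R^2) is below ``q2_adequate`` (default 0.70).
Iterating the 2-SD rule to full convergence keeps deleting ~2-sigma
points from perfectly well-behaved data (with ~20 points the largest of
n Gaussian LOO residuals exceeds twice their SD about half the time);
stopping at adequacy removes gross outliers and nothing else. A
cumulative cap (``max_removal_fraction``, default 25% of the initial
points) bounds the deletion on pathological data.

:class:`QsprRegressor` is a scikit-learn estimator (``fit(X, y)`` /
``predict``); the module-level functions mirror it on
:class:`QsprDataset` inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import VariantEnergyRecord

__all__ = [
    "QsprDataset",
    "QsprModel",
    "QsprRegressor",
    "SingularFitError",
    "fit_ols",
    "loo_residuals",
    "flag_outliers",
    "fit_with_outlier_removal",
    "model_statistics",
]


class SingularFitError(ValueError):
    """Degenerate design (all x equal) or too few points to fit a line."""


@dataclass
class QsprDataset:
    """(|ddE_dim|, mean BDSI) points with stable identifiers."""

    ids: list[str]
    x: np.ndarray  # |ddE_dim|, kcal/mol, >= 0
    y: np.ndarray  # mean BDSI, percent
    provenance: str = "fixture"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and equal length")
        if len(self.ids) != len(self.x):
            raise ValueError("ids must match the number of points")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("point ids must be unique")
        if (self.x < 0).any():
            raise ValueError("x is a modulus and must be >= 0")
        if ((self.y < 0) | (self.y > 100)).any():
            raise ValueError("y (BDSI) must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_energy_records(
        cls, records: list[VariantEnergyRecord], provenance: str = "fixture"
    ) -> "QsprDataset":
        """Keep the non-truncating records with both an energy and a severity."""
        ids, xs, ys = [], [], []
        for r in records:
            if r.variant.truncating or r.dde_dim is None or r.mean_bdsi is None:
                continue
            ids.append(r.point_id or r.variant.canonical)
            xs.append(abs(r.dde_dim))
            ys.append(r.mean_bdsi)
        return cls(ids=ids, x=np.array(xs), y=np.array(ys), provenance=provenance)

    def subset(self, keep: np.ndarray) -> "QsprDataset":
        return QsprDataset(
            ids=[i for i, k in zip(self.ids, keep) if k],
            x=self.x[keep],
            y=self.y[keep],
            provenance=self.provenance,
        )


@dataclass
class QsprModel:
    """A fitted line with its validation statistics."""

    slope: float
    intercept: float
    r2: float
    r2_xv: float
    f_stat: float
    n_used: int
    outlier_ids: list[str] = field(default_factory=list)
    loo_residuals: list[float] = field(default_factory=list)
    significant: bool = True

    def predict(self, abs_dde_dim) -> np.ndarray:
        return self.slope * np.asarray(abs_dde_dim, dtype=float) + self.intercept

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "r2": self.r2,
                "r2_xv": self.r2_xv,
                "f_stat": self.f_stat,
                "n_used": self.n_used,
                "outlier_ids": self.outlier_ids,
                "significant": self.significant,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "QsprModel":
        d = json.loads(text)
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            r2=d.get("r2", float("nan")),
            r2_xv=d.get("r2_xv", float("nan")),
            f_stat=d.get("f_stat", float("nan")),
            n_used=d.get("n_used", 0),
            outlier_ids=list(d.get("outlier_ids", [])),
            significant=bool(d.get("significant", True)),
        )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 2:
        raise SingularFitError(f"need at least 2 points, got {len(x)}")
    if np.ptp(x) == 0:
        raise SingularFitError("all x values equal; slope is undefined")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(slope), float(intercept)


def _loo_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOO residuals via the leverage shortcut r_i = e_i / (1 - h_ii).

    Algebraically identical to n drop-one refits for linear least
    squares (verified against the brute-force oracle in the test suite).
    """
    n = len(x)
    if n < 4:
        raise SingularFitError(f"LOO validation needs >= 4 points, got {n}")
    slope, intercept = _ols_line(x, y)
    e = y - (slope * x + intercept)
    xbar = x.mean()
    h = 1.0 / n + (x - xbar) ** 2 / ((x - xbar) ** 2).sum()
    if np.any(h >= 1.0):
        raise SingularFitError("a point has full leverage; LOO undefined")
    return e / (1.0 - h)


class QsprRegressor(RegressorMixin, BaseEstimator):
    """OLS of severity on |ddE_dim| with LOO validation and outlier deletion.

    Parameters
    ----------
    remove_outliers : bool, default True
        Run the iterative flag-and-refit deletion described in the
        module docstring. With False the model is a plain OLS fit.
    threshold : float, default 2.0
        Flag a point when |LOO residual| strictly exceeds ``threshold``
        times the SD of the LOO residuals.
    ddof : {0, 1}, default 1
        Degrees-of-freedom convention for that SD (1 = sample SD).
    r2_adequate, q2_adequate : float
        Adequacy levels at which deletion stops; see module docstring.
    max_removal_fraction : float, default 0.25
        Cumulative cap on deleted points, as a fraction of the initial n.
    max_iter : int, default 10
        Hard cap on flag-remove-refit rounds.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted line (percent per kcal/mol; percent).
    coef_ : ndarray of shape (1,)
        ``[slope_]``, scikit-learn convention.
    r2_, r2_xv_, f_stat_, f_pvalue_, significant_ :
        Survivor-set statistics; ``r2_xv_`` is the PRESS-based LOO
        predicted R^2, ``f_stat_ = r2/(1-r2)*(n-2)``.
    n_used_ : int
        Survivors; ``n_used_ + len(outlier_ids_) == n initial``.
    outlier_ids_ : list of str
        Cumulatively deleted point ids, in removal order.
    inlier_mask_ : ndarray of bool
        True for survivors, aligned with the fit input.
    loo_residuals_ : ndarray
        LOO residuals of the survivor set.
    n_iter_ : int
        Deletion rounds actually performed.
    """

    def __init__(
        self,
        remove_outliers: bool = True,
        threshold: float = 2.0,
        ddof: int = 1,
        r2_adequate: float = 0.75,
        q2_adequate: float = 0.70,
        max_removal_fraction: float = 0.25,
        max_iter: int = 10,
    ):
        self.remove_outliers = remove_outliers
        self.threshold = threshold
        self.ddof = ddof
        self.r2_adequate = r2_adequate
        self.q2_adequate = q2_adequate
        self.max_removal_fraction = max_removal_fraction
        self.max_iter = max_iter

    # -- internal ------------------------------------------------------
    @staticmethod
    def _as_x(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("expected a single feature |ddE_dim|")
            x = x[:, 0]
        return x

    def _stats(self, x: np.ndarray, y: np.ndarray):
        slope, intercept = _ols_line(x, y)
        e = y - (slope * x + intercept)
        sstot = ((y - y.mean()) ** 2).sum()
        if sstot == 0:
            raise SingularFitError("response is constant; R^2 undefined")
        r2 = 1.0 - (e**2).sum() / sstot
        loo = _loo_residuals(x, y) if len(x) >= 4 else np.full_like(y, np.nan)
        r2_xv = 1.0 - np.nansum(loo**2) / sstot
        return slope, intercept, r2, r2_xv, loo

    # -- estimator API -------------------------------------------------
    def fit(self, X, y, ids: list[str] | None = None) -> "QsprRegressor":
        """Fit on moduli ``X`` (shape (n,) or (n, 1)) and severities ``y``."""
        x = self._as_x(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("X and y lengths differ")
        n0 = len(x)
        if n0 < 3:
            raise SingularFitError(f"need at least 3 points, got {n0}")
        if ids is None:
            ids = [str(i) for i in range(n0)]
        if not (0 <= self.max_removal_fraction < 1):
            raise ValueError("max_removal_fraction must be in [0, 1)")

        keep = np.ones(n0, dtype=bool)
        removed: list[str] = []
        cap = int(math.floor(self.max_removal_fraction * n0)) if self.remove_outliers else 0
        n_iter = 0
        if self.remove_outliers:
            for _ in range(self.max_iter):
                idx = np.flatnonzero(keep)
                if len(idx) < 5:  # flagging needs >= 5 points
                    break
                xs, ys = x[idx], y[idx]
                _, _, r2, r2_xv, loo = self._stats(xs, ys)
                if r2 >= self.r2_adequate or r2_xv >= self.q2_adequate:
                    break  # model already adequate: stop deleting
                sd = float(np.std(loo, ddof=self.ddof))
                flagged = np.abs(loo) > self.threshold * sd  # strict: "more than"
                if not flagged.any():
                    break
                order = np.argsort(-np.abs(loo[flagged]))
                candidates = list(idx[flagged][order])
                room = cap - len(removed)
                candidates = candidates[:room]
                if not candidates:
                    break
                n_iter += 1
                for i in candidates:
                    keep[i] = False
                    removed.append(ids[i])
            if keep.sum() < 3:
                raise SingularFitError(
                    "outlier removal left fewer than 3 points; refusing to fit"
                )

        xs, ys = x[keep], y[keep]
        slope, intercept, r2, r2_xv, loo = self._stats(xs, ys)
        n_used = int(keep.sum())
        if r2 >= 1.0:
            f_stat, f_pvalue = float("inf"), 0.0
        else:
            f_stat = r2 / (1.0 - r2) * (n_used - 2)
            f_pvalue = float(stats.f.sf(f_stat, 1, n_used - 2))

        self.slope_ = slope
        self.intercept_ = intercept
        self.coef_ = np.array([slope])
        self.r2_ = float(r2)
        self.r2_xv_ = float(r2_xv)
        self.f_stat_ = float(f_stat)
        self.f_pvalue_ = f_pvalue
        self.significant_ = bool(f_pvalue < 0.05)
        self.n_used_ = n_used
        self.outlier_ids_ = removed
        self.inlier_mask_ = keep
        self.loo_residuals_ = loo
        self.n_iter_ = n_iter
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        return self.slope_ * self._as_x(X) + self.intercept_

    def to_model(self) -> QsprModel:
        """Freeze the fitted state into a portable :class:`QsprModel`."""
        check_is_fitted(self, "slope_")
        return QsprModel(
            slope=self.slope_,
            intercept=self.intercept_,
            r2=self.r2_,
            r2_xv=self.r2_xv_,
            f_stat=self.f_stat_,
            n_used=self.n_used_,
            outlier_ids=list(self.outlier_ids_),
            loo_residuals=list(np.asarray(self.loo_residuals_, dtype=float)),
            significant=self.significant_,
        )


# -- functional wrappers over QsprDataset -----------------------------------


def fit_ols(dataset: QsprDataset) -> QsprModel:
    """Plain unweighted OLS on the dataset, no outlier handling."""
    est = QsprRegressor(remove_outliers=False)
    est.fit(dataset.x, dataset.y, ids=dataset.ids)
    return est.to_model()


def loo_residuals(dataset: QsprDataset) -> np.ndarray:
    """Leave-one-out residuals y_i - yhat_(-i) for every point."""
    return _loo_residuals(dataset.x, dataset.y)


def flag_outliers(
    dataset: QsprDataset, threshold: float = 2.0, ddof: int = 1
) -> set[str]:
    """Single-pass flags: ids with |LOO residual| > threshold * SD(LOO residuals)."""
    if len(dataset) < 5:
        raise SingularFitError("outlier flagging needs >= 5 points")
    loo = loo_residuals(dataset)
    sd = float(np.std(loo, ddof=ddof))
    # an exact fit leaves only rounding noise; nothing to flag
    if sd <= 1e-10 * max(1.0, float(np.abs(dataset.y).max())):
        return set()
    return {i for i, r in zip(dataset.ids, loo) if abs(r) > threshold * sd}


def fit_with_outlier_removal(
    dataset: QsprDataset, max_iter: int = 10, **params
) -> QsprModel:
    """Iterative flag-remove-refit with the adequacy stopping rule."""
    est = QsprRegressor(remove_outliers=True, max_iter=max_iter, **params)
    est.fit(dataset.x, dataset.y, ids=dataset.ids)
    return est.to_model()


def model_statistics(
    model: QsprModel,
) -> tuple[float, float, float, bool]:
    """(R^2, LOO R^2_xv, F, significant-at-95%) of a fitted model."""
    return model.r2, model.r2_xv, model.f_stat, model.significant
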