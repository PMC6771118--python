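"""Predicted mean visual acuity (PMVA) and pathogenicity classification.

The fitted severity line ``BDSI = slope * |ddE_dim| + intercept`` is
inverted back to the logMAR scale and projected to a chosen age A:

    PMVA = (2.6 / 200) * [slope * |ddE_dim| + intercept] * exp(+A/100)

i.e. the predicted two-eye mean BCVA (logMAR) of a carrier at age A.
Note the age exponent is positive - the severity index discounts late
observation, so the forward prediction re-inflates with age. A variant
is called likely pathogenic when its PMVA at the reference age of 40
years reaches the 0.5 logMAR WHO low-vision cut; operationally the
comparison uses PMVA rounded to 2 decimals (half-up), which with the
bundled coefficients makes the smallest pathogenic integer modulus
77 kcal/mol (exact arithmetic at 77 gives 0.4997, rounding to 0.50).

Stop-gain (truncating) variants have no molecular-mechanics energies
and are reported as not scorable rather than classified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .bdsi import FULL_SCALE_LOGMAR
from .cohort import VariantEnergyRecord
from .qspr import QsprModel, QsprRegressor
from .variants import ProteinVariant

__all__ = [
    "REFERENCE_MODEL",
    "REFERENCE_AGE",
    "PMVA_CUT",
    "LIKELY_PATHOGENIC",
    "LIKELY_NON_PATHOGENIC",
    "NOT_SCORABLE",
    "PmvaPrediction",
    "PmvaPredictor",
    "predict_pmva",
    "classify_pathogenicity",
    "pathogenic_energy_threshold",
    "bcva_progression",
    "classify_energy_record",
]

#: Bundled reference coefficients of the severity line (percent per
#: kcal/mol; percent), as calibrated on the reference BVMD cohort.
REFERENCE_MODEL = QsprModel(
    slope=0.24935,
    intercept=6.56527,
    r2=0.854,
    r2_xv=0.809,
    f_stat=76.164,
    n_used=15,
    outlier_ids=["P31", "P27", "P25", "P13", "P24"],
)

#: Age (years) at which pathogenicity is classified.
REFERENCE_AGE = 40.0

#: WHO low-vision cut on the logMAR scale.
PMVA_CUT = 0.5

LIKELY_PATHOGENIC = "likely-pathogenic"
LIKELY_NON_PATHOGENIC = "likely-non-pathogenic"
NOT_SCORABLE = "not-scorable"

# logMAR percent-scale factor: 2.6 two-eye full scale / (100% * 2 eyes).
_SCALE = FULL_SCALE_LOGMAR / 200.0


def _round_half_up(value: float, decimals: int) -> float:
    f = 10.0**decimals
    return math.floor(value * f + 0.5) / f


@dataclass(frozen=True)
class PmvaPrediction:
    """One variant's acuity prediction and classification."""

    variant: ProteinVariant | None
    abs_dde_dim: float | None
    age_years: float
    pmva: float | None
    classification: str


def predict_pmva(
    abs_dde_dim: float,
    age_years: float = REFERENCE_AGE,
    model: QsprModel | None = None,
) -> float:
    """Predicted two-eye mean BCVA (logMAR) at the given age."""
    if abs_dde_dim < 0:
        raise ValueError(f"|ddE_dim| must be >= 0, got {abs_dde_dim}")
    m = model or REFERENCE_MODEL
    return _SCALE * (m.slope * abs_dde_dim + m.intercept) * math.exp(age_years / 100.0)


def classify_pathogenicity(
    abs_dde_dim: float,
    model: QsprModel | None = None,
    age_years: float = REFERENCE_AGE,
    pmva_cut: float = PMVA_CUT,
    decimals: int = 2,
) -> str:
    """Likely pathogenic iff PMVA at the reference age, rounded to
    ``decimals`` places, reaches ``pmva_cut``."""
    v = _round_half_up(predict_pmva(abs_dde_dim, age_years, model), decimals)
    return LIKELY_PATHOGENIC if v >= pmva_cut else LIKELY_NON_PATHOGENIC


def pathogenic_energy_threshold(
    model: QsprModel | None = None,
    age_years: float = REFERENCE_AGE,
    pmva_cut: float = PMVA_CUT,
    decimals: int = 2,
) -> tuple[float, int]:
    """Invert the PMVA line for the pathogenicity bound on |ddE_dim|.

    Returns the exact real solution of ``PMVA == pmva_cut`` and the
    smallest integer modulus classified pathogenic under the rounding
    rule (the two differ because e.g. 0.4997 rounds up to 0.50).
    """
    m = model or REFERENCE_MODEL
    if m.slope <= 0:
        raise ValueError("slope must be positive to define an energy threshold")
    gain = _SCALE * math.exp(age_years / 100.0)
    real_root = (pmva_cut / gain - m.intercept) / m.slope
    # smallest integer whose rounded PMVA reaches the cut: the rounding
    # rule admits values down to cut - 0.5*10^-decimals
    effective_cut = pmva_cut - 0.5 * 10.0**-decimals
    lo = max(0, math.floor((effective_cut / gain - m.intercept) / m.slope) - 1)
    k = lo
    while classify_pathogenicity(float(k), m, age_years, pmva_cut, decimals) != LIKELY_PATHOGENIC:
        k += 1
    return real_root, k


def bcva_progression(
    abs_dde_dim: float,
    ages: list[float],
    model: QsprModel | None = None,
) -> list[tuple[float, float]]:
    """PMVA along a grid of ages; strictly increasing for fixed modulus."""
    if any(a < 0 for a in ages):
        raise ValueError("ages must be non-negative")
    if list(ages) != sorted(ages):
        raise ValueError("ages must be sorted ascending")
    return [(a, predict_pmva(abs_dde_dim, a, model)) for a in ages]


def classify_energy_record(
    record: VariantEnergyRecord,
    model: QsprModel | None = None,
    age_years: float = REFERENCE_AGE,
) -> PmvaPrediction:
    """Score one variant record; truncating variants are not scorable."""
    if record.variant.truncating or record.dde_dim is None:
        return PmvaPrediction(
            variant=record.variant,
            abs_dde_dim=None,
            age_years=age_years,
            pmva=None,
            classification=NOT_SCORABLE,
        )
    x = abs(record.dde_dim)
    return PmvaPrediction(
        variant=record.variant,
        abs_dde_dim=x,
        age_years=age_years,
        pmva=predict_pmva(x, age_years, model),
        classification=classify_pathogenicity(x, model, age_years),
    )


class PmvaPredictor(ClassifierMixin, BaseEstimator):
    """Pathogenicity classifier over |ddE_dim| moduli.

    With ``slope``/``intercept`` left as None, :meth:`fit` calibrates
    the severity line from training data via :class:`QsprRegressor`
    (X = moduli, y = mean BDSI); otherwise the given (or bundled
    reference) coefficients are used and ``fit`` only validates input.

    ``predict`` returns string labels; :meth:`predict_acuity` returns
    the underlying PMVA values (logMAR).
    """

    classes_ = np.array([LIKELY_NON_PATHOGENIC, LIKELY_PATHOGENIC])

    def __init__(
        self,
        slope: float | None = None,
        intercept: float | None = None,
        age_years: float = REFERENCE_AGE,
        pmva_cut: float = PMVA_CUT,
        decimals: int = 2,
    ):
        self.slope = slope
        self.intercept = intercept
        self.age_years = age_years
        self.pmva_cut = pmva_cut
        self.decimals = decimals

    def fit(self, X=None, y=None) -> "PmvaPredictor":
        if self.slope is not None and self.intercept is not None:
            self.model_ = QsprModel(
                slope=self.slope,
                intercept=self.intercept,
                r2=float("nan"),
                r2_xv=float("nan"),
                f_stat=float("nan"),
                n_used=0,
            )
        elif X is not None and y is not None:
            reg = QsprRegressor().fit(X, y)
            self.model_ = reg.to_model()
        else:
            self.model_ = REFERENCE_MODEL
        self.n_features_in_ = 1
        return self

    def predict_acuity(self, X, age_years: float | None = None) -> np.ndarray:
        check_is_fitted(self, "model_")
        age = self.age_years if age_years is None else age_years
        x = np.atleast_1d(np.asarray(X, dtype=float)).ravel()
        return np.array([predict_pmva(v, age, self.model_) for v in x])

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        x = np.atleast_1d(np.asarray(X, dtype=float)).ravel()
        return np.array(
            [
                classify_pathogenicity(
                    v, self.model_, self.age_years, self.pmva_cut, self.decimals
                )
                for v in x
            ]
        )
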