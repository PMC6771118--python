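"""Age-adjusted Best's Disease Severity Index (BDSI).

For proband *i* with per-eye best-corrected visual acuities
``logMAR_LE,i`` and ``logMAR_RE,i`` and age ``A_i`` (years at last
clinical evaluation), the index is

    BDSI_i = (logMAR_LE,i + logMAR_RE,i) / 2.6 * 100% * exp(-A_i / 100)

and the per-variant value is the arithmetic mean over the N probands
sharing the variant. The 2.6 normalizer is the two-eye logMAR sum of a
completely blind individual (1.3 per eye), so the index reads as percent
loss of vision; the exponential factor discounts severity observed late
in life (f = exp(-A/100), ~0.368 at age 100).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .cohort import ProbandRecord

__all__ = [
    "FULL_SCALE_LOGMAR",
    "BdsiValue",
    "MissingDataError",
    "age_adjustment_factor",
    "proband_bdsi",
    "mean_bdsi",
]

logger = logging.getLogger(__name__)

#: Two-eye logMAR sum corresponding to complete blindness (1.3 per eye).
FULL_SCALE_LOGMAR = 2.6


class MissingDataError(ValueError):
    """An operation needed BCVA or energy values that are absent."""


@dataclass(frozen=True)
class BdsiValue:
    """Per-variant mean severity with its provenance."""

    value: float
    n_probands: int
    contributing_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 100.0):
            raise ValueError(f"BDSI {self.value} outside [0, 100]")
        if self.n_probands != len(self.contributing_ids) or self.n_probands < 1:
            raise ValueError("n_probands must equal len(contributing_ids) >= 1")


def age_adjustment_factor(age_years: float) -> float:
    """The time factor ``f = exp(-age/100)``, strictly decreasing in age."""
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    return math.exp(-age_years / 100.0)


def proband_bdsi(bcva_le: float | None, bcva_re: float | None, age_years: float) -> float:
    """Severity index of a single proband, percent in [0, 100].

    Raises
    ------
    MissingDataError
        If either eye's BCVA is missing. Records with missing acuity
        must be excluded upstream, never silently scored as zero.
    """
    if bcva_le is None or bcva_re is None:
        raise MissingDataError("BCVA missing for at least one eye")
    if bcva_le < 0 or bcva_re < 0:
        raise ValueError("BCVA cannot be negative")
    total = bcva_le + bcva_re
    if total > FULL_SCALE_LOGMAR:
        logger.warning(
            "two-eye logMAR sum %.2f exceeds the %.1f full scale; clamping",
            total,
            FULL_SCALE_LOGMAR,
        )
        total = FULL_SCALE_LOGMAR
    return total / FULL_SCALE_LOGMAR * 100.0 * age_adjustment_factor(age_years)


def mean_bdsi(group: list[ProbandRecord]) -> BdsiValue:
    """Mean severity over the BCVA-complete probands of one variant group.

    Probands with any missing eye are dropped (and should appear in the
    cohort validation report); a group with no usable proband raises
    :class:`MissingDataError`, mirroring the ``NA`` severity cells of
    the reference energy table.
    """
    if not group:
        raise ValueError("empty proband group")
    usable = [r for r in group if r.has_bcva]
    if not usable:
        raise MissingDataError(
            "no proband in group has BCVA for both eyes: "
            + ", ".join(r.proband_id for r in group)
        )
    values = [proband_bdsi(r.bcva_le, r.bcva_re, r.age_years) for r in usable]
    return BdsiValue(
        value=sum(values) / len(values),
        n_probands=len(usable),
        contributing_ids=tuple(r.proband_id for r in usable),
    )
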