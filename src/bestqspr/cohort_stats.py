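"""Cohort-level descriptive statistics: test positivity and penetrance.

Penetrance is the fraction of variant carriers expressing the disease
phenotype. Probands are counted as affected carriers alongside affected
relatives; unaffected carriers come from family segregation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CarrierCounts", "positivity_rate", "penetrance"]


@dataclass(frozen=True)
class CarrierCounts:
    """Affected/unaffected variant-carrier tallies, optionally by sex."""

    affected_carriers: int
    unaffected_carriers: int
    by_sex: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.affected_carriers < 0 or self.unaffected_carriers < 0:
            raise ValueError("carrier counts must be non-negative")
        if self.by_sex is not None:
            aff = sum(a for a, _ in self.by_sex.values())
            unaff = sum(u for _, u in self.by_sex.values())
            if (aff, unaff) != (self.affected_carriers, self.unaffected_carriers):
                raise ValueError(
                    "per-sex counts do not sum to the overall totals: "
                    f"({aff}, {unaff}) != "
                    f"({self.affected_carriers}, {self.unaffected_carriers})"
                )

    @property
    def total(self) -> int:
        return self.affected_carriers + self.unaffected_carriers


def positivity_rate(positive: int, tested: int) -> float:
    """Percent of tested individuals carrying a variant (exact value;
    round at presentation)."""
    if tested <= 0:
        raise ValueError("tested must be positive")
    if not 0 <= positive <= tested:
        raise ValueError(f"positive must lie in [0, {tested}], got {positive}")
    return 100.0 * positive / tested


def penetrance(counts: CarrierCounts) -> tuple[float, dict[str, float] | None]:
    """Overall percent of carriers affected, plus per-sex values when
    per-sex tallies are present."""
    if counts.total == 0:
        raise ValueError("no carriers: penetrance undefined")
    overall = 100.0 * counts.affected_carriers / counts.total
    by_sex = None
    if counts.by_sex is not None:
        by_sex = {}
        for sex, (aff, unaff) in counts.by_sex.items():
            if aff + unaff == 0:
                continue
            by_sex[sex] = 100.0 * aff / (aff + unaff)
    return overall, by_sex
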