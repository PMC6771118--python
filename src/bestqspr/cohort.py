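"""Cohort and per-variant energy tables: parsing, validation, grouping.

The cohort table has one row per proband with age at last clinical
evaluation, per-eye best-corrected visual acuity (BCVA, logMAR scale)
and the protein-level *BEST1* variant. The energy table has one row per
distinct amino-acid replacement with the relative dimerization and
calcium-binding energies (kcal/mol) and, where computable, the mean
age-adjusted severity index of the probands sharing that variant.

Missing cells are any of ``NA``, ``-`` or empty on input and are written
back as ``NA``. Numeric cells may use a decimal comma (``"12,85"``) when
``decimal=","`` is requested; the bundled fixtures use decimal points.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .variants import ProteinVariant, parse_protein_variant

__all__ = [
    "ProbandRecord",
    "VariantEnergyRecord",
    "CohortValidationReport",
    "CohortParseError",
    "load_cohort_table",
    "write_cohort_table",
    "load_energy_table",
    "group_by_variant",
    "validate_cohort",
    "records_to_json",
]

logger = logging.getLogger(__name__)

#: Strings treated as missing on input.
NA_VALUES = ["NA", "", "-"]

#: Upper bound accepted for a single eye's logMAR BCVA. Blindness is
#: defined at >= 1.3 but larger values occur clinically.
BCVA_MAX = 2.6

_COHORT_COLUMNS = ["proband_id", "age_years", "amino_acid_change", "bcva_le", "bcva_re"]
_ENERGY_COLUMNS = ["amino_acid_change", "dde_dim", "dde_cabin"]


class CohortParseError(ValueError):
    """A table-level or row-level parsing failure (the message carries the row)."""


@dataclass
class ProbandRecord:
    """One clinically evaluated individual."""

    proband_id: str
    age_years: float
    variant: ProteinVariant
    bcva_le: float | None = None
    bcva_re: float | None = None
    stage_le: int | None = None
    stage_re: int | None = None
    allele_state: str = "heterozygous"
    sex: str | None = None
    exon: str | None = None
    nucleotide_change: str | None = None
    second_variant: ProteinVariant | None = None
    family_study: bool = False

    def __post_init__(self) -> None:
        if not self.age_years > 0:
            raise CohortParseError(
                f"proband {self.proband_id}: age must be positive, got {self.age_years}"
            )
        for eye, v in (("LE", self.bcva_le), ("RE", self.bcva_re)):
            if v is not None and not (0.0 <= v <= BCVA_MAX):
                raise CohortParseError(
                    f"proband {self.proband_id}: BCVA {eye}={v} outside [0, {BCVA_MAX}]"
                )
        for eye, s in (("LE", self.stage_le), ("RE", self.stage_re)):
            if s is not None and s not in range(6):
                raise CohortParseError(
                    f"proband {self.proband_id}: stage {eye}={s} outside 0..5"
                )

    @property
    def has_bcva(self) -> bool:
        """True when both eyes have a BCVA value (required for the severity index)."""
        return self.bcva_le is not None and self.bcva_re is not None

    @property
    def partially_missing(self) -> bool:
        """Exactly one eye recorded - flagged, not silently accepted."""
        return (self.bcva_le is None) != (self.bcva_re is None)


@dataclass
class VariantEnergyRecord:
    """One protein variant with its relative molecular-mechanics energies.

    ``dde_dim`` and ``dde_cabin`` are the variant-minus-native changes in
    subunit dimerization energy and per-calcium binding energy (kcal/mol).
    Truncating variants carry no energies.
    """

    variant: ProteinVariant
    dde_dim: float | None
    dde_cabin: float | None
    mean_bdsi: float | None = None
    pmva: float | None = None
    location_labels: list[str] = field(default_factory=list)
    point_id: str | None = None
    proband_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, v in (("dde_dim", self.dde_dim), ("dde_cabin", self.dde_cabin)):
            if v is not None and not math.isfinite(v):
                raise CohortParseError(f"{self.variant}: {name} is not finite")
        if self.mean_bdsi is not None and not (0.0 <= self.mean_bdsi <= 100.0):
            raise CohortParseError(
                f"{self.variant}: mean_bdsi={self.mean_bdsi} outside [0, 100]"
            )

    @property
    def abs_dde_dim(self) -> float | None:
        return None if self.dde_dim is None else abs(self.dde_dim)


@dataclass
class CohortValidationReport:
    """Summary emitted after loading a cohort table."""

    n_rows: int
    n_bcva_complete: int
    missing_bcva_ids: list[str]
    partially_missing_ids: list[str]
    warnings: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [
            f"probands: {self.n_rows}",
            f"BCVA complete (both eyes): {self.n_bcva_complete}",
            f"missing BCVA: {', '.join(self.missing_bcva_ids) or 'none'}",
        ]
        if self.partially_missing_ids:
            lines.append(
                "one-eyed BCVA (excluded from severity index): "
                + ", ".join(self.partially_missing_ids)
            )
        lines.extend(self.warnings)
        return "\n".join(lines)


def _opt_float(value) -> float | None:
    return None if pd.isna(value) else float(value)


def _opt_int(value) -> int | None:
    return None if pd.isna(value) else int(value)


def load_cohort_table(
    path: str | Path, *, decimal: str = "."
) -> list[ProbandRecord]:
    """Read a delimited cohort table into proband records.

    The delimiter is sniffed between comma, semicolon and tab; with
    ``decimal=","`` numeric cells like ``"12,85"`` parse as 12.85 (such
    files must use a non-comma delimiter).
    """
    sep = None if decimal != "," else ";"
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            engine="python",
            decimal=decimal,
            na_values=NA_VALUES,
            keep_default_na=False,
            skipinitialspace=True,
        )
    except pd.errors.EmptyDataError as exc:
        raise CohortParseError(f"{path}: empty file without header") from exc
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing mandatory columns {missing}")
    if df.empty:
        logger.warning("%s: header only, no proband rows", path)
        return []

    records: list[ProbandRecord] = []
    for i, row in df.iterrows():
        try:
            variant = parse_protein_variant(str(row["amino_acid_change"]))
            second = row.get("second_amino_acid_change")
            allele = str(row.get("allele_state", "HET")).strip().upper()
            records.append(
                ProbandRecord(
                    proband_id=str(row["proband_id"]),
                    age_years=float(row["age_years"]),
                    variant=variant,
                    bcva_le=_opt_float(row["bcva_le"]),
                    bcva_re=_opt_float(row["bcva_re"]),
                    stage_le=_opt_int(row.get("stage_le")),
                    stage_re=_opt_int(row.get("stage_re")),
                    allele_state="homozygous" if allele == "HOM" else "heterozygous",
                    sex=None if pd.isna(row.get("sex")) else str(row.get("sex")),
                    exon=None if pd.isna(row.get("exon")) else str(row.get("exon")),
                    nucleotide_change=(
                        None
                        if pd.isna(row.get("nucleotide_change"))
                        else str(row.get("nucleotide_change"))
                    ),
                    second_variant=(
                        None if pd.isna(second) else parse_protein_variant(str(second))
                    ),
                    family_study=str(row.get("family_study", "false")).strip().lower()
                    in {"true", "1", "yes"},
                )
            )
        except (ValueError, TypeError) as exc:
            raise CohortParseError(f"{path}: row {i}: {exc}") from exc
    return records


def validate_cohort(records: list[ProbandRecord]) -> CohortValidationReport:
    """Build the missing-BCVA validation report for a parsed cohort."""
    missing = [r.proband_id for r in records if not r.has_bcva]
    partial = [r.proband_id for r in records if r.partially_missing]
    return CohortValidationReport(
        n_rows=len(records),
        n_bcva_complete=sum(r.has_bcva for r in records),
        missing_bcva_ids=missing,
        partially_missing_ids=partial,
    )


def write_cohort_table(records: list[ProbandRecord], path: str | Path) -> None:
    """Write proband records back to CSV (missing cells as ``NA``)."""
    rows = []
    for r in records:
        rows.append(
            {
                "proband_id": r.proband_id,
                "sex": r.sex,
                "age_years": r.age_years,
                "exon": r.exon,
                "nucleotide_change": r.nucleotide_change,
                "amino_acid_change": r.variant.canonical,
                "second_amino_acid_change": (
                    r.second_variant.canonical if r.second_variant else None
                ),
                "allele_state": "HOM" if r.allele_state == "homozygous" else "HET",
                "family_study": "true" if r.family_study else "false",
                "stage_le": r.stage_le,
                "stage_re": r.stage_re,
                "bcva_le": r.bcva_le,
                "bcva_re": r.bcva_re,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA")


def load_energy_table(path: str | Path, *, decimal: str = ".") -> list[VariantEnergyRecord]:
    """Read a per-variant energy table into :class:`VariantEnergyRecord` rows."""
    sep = None if decimal != "," else ";"
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python",
        decimal=decimal,
        na_values=NA_VALUES,
        keep_default_na=False,
        skipinitialspace=True,
    )
    missing = [c for c in _ENERGY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing mandatory columns {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            loc = row.get("location")
            records.append(
                VariantEnergyRecord(
                    variant=parse_protein_variant(str(row["amino_acid_change"])),
                    dde_dim=_opt_float(row["dde_dim"]),
                    dde_cabin=_opt_float(row["dde_cabin"]),
                    mean_bdsi=_opt_float(row.get("mean_bdsi")),
                    pmva=_opt_float(row.get("pmva")),
                    location_labels=(
                        [] if pd.isna(loc) else [t for t in str(loc).split(";") if t]
                    ),
                    point_id=(
                        None if pd.isna(row.get("point_id")) else str(row["point_id"])
                    ),
                    proband_ids=(
                        []
                        if pd.isna(row.get("proband_ids"))
                        else str(row["proband_ids"]).split(";")
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CohortParseError(f"{path}: row {i}: {exc}") from exc
    return records


def group_by_variant(
    records: list[ProbandRecord],
) -> dict[ProteinVariant, list[ProbandRecord]]:
    """Group probands by the canonical protein change.

    The key is the (ref, position, alt) triple, not the nucleotide
    change, so e.g. c.888C>G and c.888C>A both land in the p.(Asn296Lys)
    group. The grouping is a partition of the input records.
    """
    groups: dict[ProteinVariant, list[ProbandRecord]] = {}
    for r in records:
        key = ProteinVariant(
            r.variant.ref_residue, r.variant.position, r.variant.alt_residue
        )
        groups.setdefault(key, []).append(r)
    return groups


def records_to_json(records: list[ProbandRecord]) -> str:
    """JSON export of parsed proband records."""
    out = []
    for r in records:
        out.append(
            {
                "proband_id": r.proband_id,
                "age_years": r.age_years,
                "variant": r.variant.canonical,
                "truncating": r.variant.truncating,
                "bcva_le": r.bcva_le,
                "bcva_re": r.bcva_re,
                "stage_le": r.stage_le,
                "stage_re": r.stage_re,
                "allele_state": r.allele_state,
            }
        )
    return json.dumps(out, indent=2)
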