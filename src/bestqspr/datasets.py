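"""Bundled reference tables of the BVMD calibration cohort.

Two fixtures ship with the package: the clinical cohort (36 probands of
an Italian BVMD case series: age, per-eye BCVA, protein variant) and the
per-variant energy table (relative dimerization and calcium-binding
energies with the printed per-variant mean severity). The severity
values in the energy table are the published per-variant means and are
used verbatim for the regression dataset; recomputing them from the
cohort's BCVA and ages reproduces them to ~0.1 percent-point (ages at
evaluation evidently differ marginally between the two tables).
"""

from __future__ import annotations

from importlib import resources

from .cohort import (
    ProbandRecord,
    VariantEnergyRecord,
    load_cohort_table,
    load_energy_table,
)
from .qspr import QsprDataset

__all__ = [
    "load_reference_cohort",
    "load_reference_energies",
    "load_reference_qspr",
    "REFERENCE_OUTLIERS",
]

#: Point ids deleted by the validated reference regression.
REFERENCE_OUTLIERS = frozenset({"P13", "P24", "P25", "P27", "P31"})


def _data_path(name: str):
    return resources.files("bestqspr.data").joinpath(name)


def load_reference_cohort() -> list[ProbandRecord]:
    """The 36-proband clinical cohort (27 with BCVA for both eyes)."""
    with resources.as_file(_data_path("reference_cohort.csv")) as p:
        return load_cohort_table(p)


def load_reference_energies() -> list[VariantEnergyRecord]:
    """The 25 grouped variants with relative energies; the stop gain
    p.(Arg200*) carries no energies."""
    with resources.as_file(_data_path("reference_energies.csv")) as p:
        return load_energy_table(p)


def load_reference_qspr() -> QsprDataset:
    """The 20-point (|ddE_dim|, mean BDSI) regression dataset."""
    return QsprDataset.from_energy_records(
        load_reference_energies(), provenance="fixture"
    )
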