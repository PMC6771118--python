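"""Relative dimerization and calcium-binding energy algebra.

The inputs are total molecular-mechanics energies of the hydrated
bestrophin-1 species (monomers A and B, dimer AB, dimer with two bound
Ca2+) produced by an external minimization protocol; this module only
evaluates the defining differences, in kcal/mol:

    dE_dim   = E_tot{AB} - E_tot{A} - E_tot{B}
    ddE_dim  = dE_dim(variant) - dE_dim(native)
    dE_Cabin = 1/2 [E_tot{AB,2Ca} - E_tot{AB} - 2 E_sol{Ca2+}]
    ddE_Cabin = dE_Cabin(variant) - dE_Cabin(native)

``dE_Cabin`` is a per-calcium binding energy (two ions per dimer). Both
relative energies vanish when variant equals native and are invariant
under a constant offset added to every total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .bdsi import MissingDataError
from .cohort import NA_VALUES, VariantEnergyRecord
from .variants import parse_protein_variant

__all__ = [
    "EnergyComponents",
    "dimerization_energy",
    "relative_dimerization_energy",
    "ca_binding_energy",
    "relative_ca_binding_energy",
    "load_energy_components",
    "energy_records_from_components",
]


@dataclass(frozen=True)
class EnergyComponents:
    """Raw molecular-mechanics totals for one species set (kcal/mol)."""

    e_tot_dimer: float
    e_tot_monomer_a: float
    e_tot_monomer_b: float
    e_tot_dimer_2ca: float | None = None
    e_sol_ca: float | None = None
    label: str = "native"

    def __post_init__(self) -> None:
        for name in ("e_tot_dimer", "e_tot_monomer_a", "e_tot_monomer_b"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise MissingDataError(f"{self.label}: {name} missing or non-finite")
        if self.e_tot_dimer_2ca is not None and self.e_sol_ca is None:
            raise MissingDataError(
                f"{self.label}: e_sol_ca required whenever e_tot_dimer_2ca is present"
            )

    @property
    def has_ca(self) -> bool:
        return self.e_tot_dimer_2ca is not None and self.e_sol_ca is not None


def dimerization_energy(c: EnergyComponents) -> float:
    """Dimer-minus-monomers binding energy of the AB pair."""
    return c.e_tot_dimer - c.e_tot_monomer_a - c.e_tot_monomer_b


def relative_dimerization_energy(
    variant: EnergyComponents, native: EnergyComponents
) -> float:
    """Variant-minus-native change in dimerization energy (antisymmetric)."""
    return dimerization_energy(variant) - dimerization_energy(native)


def ca_binding_energy(c: EnergyComponents) -> float:
    """Per-calcium binding energy of the dimer."""
    if not c.has_ca:
        raise MissingDataError(
            f"{c.label}: calcium components (e_tot_dimer_2ca, e_sol_ca) missing"
        )
    return 0.5 * (c.e_tot_dimer_2ca - c.e_tot_dimer - 2.0 * c.e_sol_ca)


def relative_ca_binding_energy(
    variant: EnergyComponents, native: EnergyComponents
) -> float:
    """Variant-minus-native change in per-calcium binding energy."""
    return ca_binding_energy(variant) - ca_binding_energy(native)


def load_energy_components(
    path: str | Path, *, decimal: str = "."
) -> dict[str, EnergyComponents]:
    """Read a component-energy table keyed by the ``label`` column.

    Columns: ``label`` (``native`` or a ``p.(RefPosAlt)`` variant),
    ``e_tot_dimer``, ``e_tot_monomer_a``, ``e_tot_monomer_b`` and
    optionally ``e_tot_dimer_2ca``, ``e_sol_ca``.
    """
    df = pd.read_csv(
        path,
        sep=None if decimal != "," else ";",
        engine="python",
        decimal=decimal,
        na_values=NA_VALUES,
        keep_default_na=False,
    )
    required = ["label", "e_tot_dimer", "e_tot_monomer_a", "e_tot_monomer_b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    out: dict[str, EnergyComponents] = {}
    for _, row in df.iterrows():
        label = str(row["label"])

        def opt(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        out[label] = EnergyComponents(
            e_tot_dimer=float(row["e_tot_dimer"]),
            e_tot_monomer_a=float(row["e_tot_monomer_a"]),
            e_tot_monomer_b=float(row["e_tot_monomer_b"]),
            e_tot_dimer_2ca=opt("e_tot_dimer_2ca"),
            e_sol_ca=opt("e_sol_ca"),
            label=label,
        )
    if "native" not in out:
        raise ValueError(f"{path}: no 'native' reference row")
    return out


def energy_records_from_components(
    components: dict[str, EnergyComponents],
) -> list[VariantEnergyRecord]:
    """Evaluate the relative energies of every variant against ``native``."""
    native = components["native"]
    records = []
    for label, comp in components.items():
        if label == "native":
            continue
        dde_cabin = (
            relative_ca_binding_energy(comp, native)
            if comp.has_ca and native.has_ca
            else None
        )
        records.append(
            VariantEnergyRecord(
                variant=parse_protein_variant(label),
                dde_dim=relative_dimerization_energy(comp, native),
                dde_cabin=dde_cabin,
            )
        )
    return records
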