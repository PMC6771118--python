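"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator inverts the analysis: a per-variant target severity is
drawn as ``slope * |ddE_dim| + intercept + noise`` (plus a gross offset
for planted outliers), then per-proband eye acuities are constructed so
that recomputing the severity index from the synthetic cohort recovers
the target exactly (the per-eye split carries cosmetic jitter that
cancels in the two-eye sum). Noise therefore enters at the mean-severity
level, where the regression model operates, not per eye.

All randomness flows from ``numpy.random.default_rng(config.seed)``
(PCG64); a fixed seed gives byte-identical tables on any platform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .bdsi import FULL_SCALE_LOGMAR
from .cohort import ProbandRecord, VariantEnergyRecord
from .variants import AMINO_ACIDS_3, ProteinVariant

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_energies",
    "simulate_cohort",
    "make_fixture_structure",
]

logger = logging.getLogger(__name__)

_AA = sorted(AMINO_ACIDS_3)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults mirror the reference analysis: the bundled severity-line
    coefficients, signed ddE_dim uniform on [-100, 100] kcal/mol so the
    moduli span the observed range, ages uniform on the cohort's 9-85
    year range, and 1-3 probands per variant.
    """

    n_variants: int = 20
    probands_per_variant: tuple[int, int] = (1, 3)
    slope: float = 0.24935
    intercept: float = 6.56527
    noise_sd: float = 3.0
    outlier_fraction: float = 0.0
    outlier_offset: float = 40.0
    dde_range: tuple[float, float] = (-100.0, 100.0)
    age_range: tuple[float, float] = (9.0, 85.0)
    eye_jitter_sd: float = 0.05
    eye_max_logmar: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.dde_range[0] > self.dde_range[1]:
            raise ValueError("dde_range must be ordered")
        if not 0 < self.age_range[0] <= self.age_range[1]:
            raise ValueError("age_range must be positive and ordered")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    slope: float
    intercept: float
    outlier_ids: list[str]
    target_bdsi: dict[str, float]
    energies: list[VariantEnergyRecord] = field(default_factory=list)
    n_regenerated: int = 0


def _variant_name(rng: np.random.Generator, position: int) -> ProteinVariant:
    ref = _AA[rng.integers(len(_AA))]
    alt = _AA[rng.integers(len(_AA))]
    while alt == ref:
        alt = _AA[rng.integers(len(_AA))]
    return ProteinVariant(ref_residue=ref, position=position, alt_residue=alt)


def simulate_energies(config: SimulationConfig) -> list[VariantEnergyRecord]:
    """Draw per-variant relative energies: signed ddE_dim uniform on
    ``dde_range``; ddE_Cabin independent (not used by the fitted model)."""
    rng = np.random.default_rng(config.seed)
    return _simulate_energies(config, rng)


def _simulate_energies(
    config: SimulationConfig, rng: np.random.Generator
) -> list[VariantEnergyRecord]:
    lo, hi = config.dde_range
    pool_top = max(367, config.n_variants + 1)
    positions = rng.choice(
        np.arange(1, pool_top), size=config.n_variants, replace=False
    )
    records = []
    for k in range(config.n_variants):
        records.append(
            VariantEnergyRecord(
                variant=_variant_name(rng, int(positions[k])),
                dde_dim=float(rng.uniform(lo, hi)),
                dde_cabin=float(rng.uniform(lo, hi)),
                point_id=f"V{k + 1}",
            )
        )
    return records


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[ProbandRecord], SimulationTruth]:
    """Generate a proband cohort whose recomputed per-variant mean
    severity equals the planted linear model plus noise.

    For each variant, a target severity is drawn and every proband of
    the group receives eye acuities summing to
    ``target/100 * 2.6 * exp(age/100)``; the recomputed index is then
    exactly the target regardless of the per-eye jitter. Ages implying a
    per-eye acuity above ``eye_max_logmar`` are redrawn (counted in the
    truth record); an infeasible target at the youngest age is clamped
    with a warning.
    """
    rng = np.random.default_rng(config.seed)
    energies = _simulate_energies(config, rng)
    n_out = int(round(config.outlier_fraction * config.n_variants))
    outlier_idx = set(
        rng.choice(config.n_variants, size=n_out, replace=False).tolist()
    )

    records: list[ProbandRecord] = []
    truth = SimulationTruth(
        slope=config.slope,
        intercept=config.intercept,
        outlier_ids=sorted(energies[i].point_id for i in outlier_idx),
        target_bdsi={},
        energies=energies,
    )
    lo_n, hi_n = config.probands_per_variant
    proband_no = 0
    for k, rec in enumerate(energies):
        target = (
            config.slope * abs(rec.dde_dim)
            + config.intercept
            + rng.normal(0.0, config.noise_sd)
        )
        if k in outlier_idx:
            target += config.outlier_offset
        # a severity index is a percentage; redraw noise outside [0, 100]
        attempts = 0
        while not 0.0 <= target <= 100.0 and attempts < 1000:
            target = (
                config.slope * abs(rec.dde_dim)
                + config.intercept
                + rng.normal(0.0, config.noise_sd)
                + (config.outlier_offset if k in outlier_idx else 0.0)
            )
            truth.n_regenerated += 1
            attempts += 1
        target = float(np.clip(target, 0.0, 100.0))
        truth.target_bdsi[rec.point_id] = target
        rec.mean_bdsi = target

        group_ids = []
        for _ in range(int(rng.integers(lo_n, hi_n + 1))):
            proband_no += 1
            pid = f"S{proband_no}"
            group_ids.append(pid)
            age, le, re_ = _eyes_for_target(target, config, rng, truth)
            records.append(
                ProbandRecord(
                    proband_id=pid,
                    age_years=age,
                    variant=rec.variant,
                    bcva_le=le,
                    bcva_re=re_,
                )
            )
        rec.proband_ids = group_ids
    return records, truth


def _eyes_for_target(
    target: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: SimulationTruth,
) -> tuple[float, float, float]:
    """Draw (age, bcva_le, bcva_re) reproducing the target severity."""
    cap = config.eye_max_logmar
    for _ in range(1000):
        age = float(rng.uniform(*config.age_range))
        half = target / 100.0 * FULL_SCALE_LOGMAR * math.exp(age / 100.0) / 2.0
        if half > cap:
            truth.n_regenerated += 1
            continue
        jitter = float(rng.normal(0.0, config.eye_jitter_sd))
        jitter = float(np.clip(jitter, -min(half, cap - half), min(half, cap - half)))
        return age, half + jitter, half - jitter
    logger.warning("infeasible severity target %.1f%%; clamping eyes to cap", target)
    age = config.age_range[0]
    return age, cap, cap


# -- toy multimer fixture ----------------------------------------------------


def make_fixture_structure(
    n_chains: int = 5,
    seed: int = 0,
    path: str | Path | None = None,
) -> tuple[str, dict]:
    """Write a synthetic ring multimer (PDB text) with planted ions and
    a known ground-truth label table.

    Each chain is a vertical column of residues on a ring about the z
    axis plus a pore-facing residue near the axis and an "arm" residue
    reaching the next chain; Ca2+ is planted 2.5 A from residue 3 but
    owned by the neighbouring chain (mimicking the inter-subunit calcium
    clasp), K+ 2.5 A from residue 5, one Cl- on the axis. Returns the
    PDB text and a truth dict with per-(chain, seqid) expected labels
    (for cutoffs interface 5 A, ion 8 A, pore 12 A, membrane band
    (5, 25) on the axial coordinate).

    The geometry is deterministic; ``seed`` only jitters atom positions
    by < 0.05 A so files differ across seeds without changing any label.
    """
    rng = np.random.default_rng(seed)
    col_r, pore_r, arm_gap_deg = 16.0, 4.5, 12.5
    sector = 360.0 / n_chains
    st = gemmi.Structure()
    st.name = "synthetic ring multimer"
    model = gemmi.Model("1")
    truth: dict = {"membrane_band": (5.0, 25.0), "labels": {}}

    def add_residue(chain, seqid, name, center, element="C", single=False):
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        offsets = [0.0] if single else [-0.7, 0.0, 0.7]
        names = ["CA"] if single else ["N", "CA", "C"]
        for off, aname in zip(offsets, names):
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element(element)
            jitterxyz = rng.normal(0.0, 0.015, size=3)
            atom.pos = gemmi.Position(
                center[0] + jitterxyz[0],
                center[1] + jitterxyz[1],
                center[2] + off + jitterxyz[2],
            )
            res.add_atom(atom)
        chain.add_residue(res)

    def ring_xy(radius, angle_deg):
        a = math.radians(angle_deg)
        return radius * math.cos(a), radius * math.sin(a)

    chain_ids = [chr(ord("A") + k) for k in range(n_chains)]
    ion_plan: list[tuple[str, int, str, str, tuple[float, float, float]]] = []
    for k, cid in enumerate(chain_ids):
        chain = gemmi.Chain(cid)
        theta = k * sector
        nxt = chain_ids[(k + 1) % n_chains]
        prev = chain_ids[(k - 1) % n_chains]
        labels = {}
        # residue 1: pore-facing, near the axial chloride
        x, y = ring_xy(pore_r, theta)
        add_residue(chain, 1, "ALA", (x, y, 0.0))
        labels[1] = {"pore-lining", "near-Cl-site"}
        # for many chains the pore ring tightens into inter-chain contact
        if n_chains > 1 and 2.0 * pore_r * math.sin(math.pi / n_chains) <= 5.0:
            labels[1] |= {f"interface:{nxt}", f"interface:{prev}"}
        # residues 2-6: the column
        for j, z in enumerate((-20.0, -10.0, 0.0, 10.0, 20.0), start=2):
            x, y = ring_xy(col_r, theta)
            add_residue(chain, j, "ALA", (x, y, z))
        labels[2] = {"other"}
        labels[3] = {f"near-Ca-site:{nxt}"}
        labels[4] = {f"interface:{prev}"} if n_chains > 1 else {"other"}
        labels[5] = {"membrane-facing", f"near-K-site:{cid}"}
        labels[6] = {"membrane-facing"}
        # residue 7: arm reaching the next chain's column
        x, y = ring_xy(col_r, theta + sector - arm_gap_deg)
        add_residue(chain, 7, "ALA", (x, y, 0.0))
        labels[7] = {f"interface:{nxt}"} if n_chains > 1 else {"other"}
        # calcium clasp: placed by this chain's residue 3, owned by the
        # next chain; potassium near residue 5, owned by this chain
        x, y = ring_xy(col_r - 2.5, theta)
        ion_plan.append((nxt, 101 + k, "CA", "Ca", (x, y, -10.0)))
        ion_plan.append((cid, 121 + k, "K", "K", (x, y, 10.0)))
        truth["labels"][cid] = labels
        model.add_chain(chain)
    # single chloride on the axis, attached to the first chain
    ion_plan.append((chain_ids[0], 199, "CL", "Cl", (0.0, 0.0, 0.0)))
    by_name = {c.name: c for c in model}
    for owner, seqid, name, element, pos in ion_plan:
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        atom = gemmi.Atom()
        atom.name = name
        atom.element = gemmi.Element(element)
        atom.pos = gemmi.Position(*pos)
        res.add_atom(atom)
        by_name[owner].add_residue(res)

    st.add_model(model)
    pdb_text = st.make_pdb_string()
    if path is not None:
        Path(path).write_text(pdb_text)
    return pdb_text, truth
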