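"""Residue-location annotation in a multimeric channel structure.

Reduced-scope, distance-heuristic reimplementation of the qualitative
"location of variant residue" labels: a residue can sit at an
inter-subunit interface, near a bound Ca2+/K+/Cl- ion, line the channel
pore (close to the five-fold symmetry axis), or face the membrane band.
The pore axis is approximated by the first principal axis of the
assembly's heavy-atom cloud; all cutoffs are configuration, not
constants of nature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .variants import ProteinVariant

__all__ = [
    "Residue",
    "Ion",
    "ChannelModel",
    "ResidueLocation",
    "LocationCutoffs",
    "SiteProximity",
    "OutOfModelError",
    "ION_SPECIES",
    "load_structure",
    "interface_residues",
    "site_proximity",
    "classify_variant_location",
]

logger = logging.getLogger(__name__)

#: Controlled ion species and the residue names they are read from.
ION_SPECIES = {"CA": "Ca2+", "K": "K+", "CL": "Cl-"}

#: Static pairing of location labels with the structural consequence
#: they suggest for channel function.
CONSEQUENCE_BY_LABEL = {
    "interface": "channel formation and stability",
    "near-Ca-site": "channel activation",
    "near-K-site": "channel activation",
    "near-Cl-site": "chloride ion throughput or ion selectivity",
    "pore-lining": "conformational changes, channel gating",
    "membrane-facing": "channel embedding in cell membrane",
    "other": "unclassified",
}


class OutOfModelError(ValueError):
    """Variant position falls outside the modelled residue range."""


@dataclass
class Residue:
    chain: str
    seqid: int
    name: str
    coords: np.ndarray  # heavy atoms only, shape (n_atoms, 3), angstrom


@dataclass
class Ion:
    species: str  # one of ION_SPECIES values
    position: np.ndarray  # shape (3,)
    chain: str


@dataclass
class ChannelModel:
    """Parsed multi-subunit channel with ions and a pore axis."""

    chains: dict[str, list[Residue]]
    ions: list[Ion]
    axis_direction: np.ndarray  # unit vector
    axis_anchor: np.ndarray
    membrane_band: tuple[float, float] | None = None

    def residue(self, chain: str, seqid: int) -> Residue:
        for r in self.chains[chain]:
            if r.seqid == seqid:
                return r
        raise OutOfModelError(f"residue {seqid} not in chain {chain}")

    def residues_at(self, seqid: int) -> list[Residue]:
        return [r for rs in self.chains.values() for r in rs if r.seqid == seqid]

    def axial_radial(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Axial coordinate and radial distance of points w.r.t. the pore axis."""
        rel = np.atleast_2d(points) - self.axis_anchor
        axial = rel @ self.axis_direction
        radial = np.linalg.norm(rel - np.outer(axial, self.axis_direction), axis=1)
        return axial, radial


@dataclass(frozen=True)
class LocationCutoffs:
    """Distance cutoffs (angstrom) for the location heuristics."""

    interface: float = 5.0
    ion: float = 8.0
    pore: float = 12.0


@dataclass
class SiteProximity:
    applicable: bool
    within: bool = False
    distance: float = float("inf")
    owning_chain: str | None = None


@dataclass
class ResidueLocation:
    labels: set[str] = field(default_factory=set)
    distances: dict[str, float] = field(default_factory=dict)

    @property
    def consequences(self) -> list[str]:
        out = []
        for label in sorted(self.labels):
            kind = label.split(":")[0]
            c = CONSEQUENCE_BY_LABEL.get(kind, "unclassified")
            if c not in out:
                out.append(c)
        return out


def load_structure(
    path: str | Path, membrane_band: tuple[float, float] | None = None
) -> ChannelModel:
    """Read a PDB/mmCIF file into a :class:`ChannelModel`.

    Waters are dropped; single-atom residues named CA/K/CL become ions
    (unknown ion-like species are ignored with a warning); the pore axis
    is the first principal axis of all protein heavy atoms.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0 or len(st[0]) == 0:
        raise OSError(f"{path}: no chains found")
    chains: dict[str, list[Residue]] = {}
    ions: list[Ion] = []
    for chain in st[0]:
        for res in chain:
            if res.is_water():
                continue
            heavy = np.array(
                [
                    [a.pos.x, a.pos.y, a.pos.z]
                    for a in res
                    if a.element.name != "H"
                ]
            )
            if heavy.size == 0:
                continue
            upper = res.name.strip().upper()
            if len(res) == 1 and upper in ION_SPECIES:
                ions.append(
                    Ion(
                        species=ION_SPECIES[upper],
                        position=heavy[0],
                        chain=chain.name,
                    )
                )
                continue
            if len(res) == 1 and (
                res[0].element.is_metal or upper in {"BR", "IOD", "F", "NA"}
            ):
                logger.warning("ignoring unknown ion species %r", res.name)
                continue
            chains.setdefault(chain.name, []).append(
                Residue(
                    chain=chain.name, seqid=res.seqid.num, name=res.name, coords=heavy
                )
            )
    if not chains:
        raise OSError(f"{path}: no protein chains found")
    cloud = np.vstack([r.coords for rs in chains.values() for r in rs])
    anchor = cloud.mean(axis=0)
    _, _, vt = np.linalg.svd(cloud - anchor, full_matrices=False)
    direction = vt[0] / np.linalg.norm(vt[0])
    # SVD leaves the sign arbitrary; canonicalize so results are stable
    if direction[int(np.argmax(np.abs(direction)))] < 0:
        direction = -direction
    return ChannelModel(
        chains=chains,
        ions=ions,
        axis_direction=direction,
        axis_anchor=anchor,
        membrane_band=membrane_band,
    )


def interface_residues(
    model: ChannelModel, chain_a: str, chain_b: str, cutoff: float = 5.0
) -> set[int]:
    """Residues of ``chain_a`` with any heavy atom within ``cutoff`` of
    ``chain_b``'s heavy atoms (seqid set)."""
    for c in (chain_a, chain_b):
        if c not in model.chains:
            raise KeyError(f"unknown chain {c!r}")
    if cutoff <= 0:
        return set()
    tree = cKDTree(np.vstack([r.coords for r in model.chains[chain_b]]))
    out = set()
    for r in model.chains[chain_a]:
        d, _ = tree.query(r.coords, k=1)
        if np.min(d) <= cutoff:
            out.add(r.seqid)
    return out


def site_proximity(
    model: ChannelModel,
    residue: tuple[str, int],
    species: str,
    cutoff: float = 8.0,
) -> SiteProximity:
    """Min heavy-atom distance from a (chain, seqid) residue to the
    nearest ion of a species; not-applicable when the species is absent."""
    r = model.residue(*residue)
    candidates = [i for i in model.ions if i.species == species]
    if not candidates:
        return SiteProximity(applicable=False)
    dists = [
        float(np.min(np.linalg.norm(r.coords - i.position, axis=1)))
        for i in candidates
    ]
    k = int(np.argmin(dists))
    return SiteProximity(
        applicable=True,
        within=dists[k] <= cutoff,
        distance=dists[k],
        owning_chain=candidates[k].chain,
    )


def classify_variant_location(
    model: ChannelModel,
    variant: ProteinVariant,
    config: LocationCutoffs = LocationCutoffs(),
    chain: str | None = None,
) -> ResidueLocation:
    """Union of interface, ion-proximity, pore-axis and membrane-band labels
    for the residue at the variant's position.

    The residue is taken from ``chain`` (default: first chain in name
    order). Deterministic for a fixed configuration; labels only grow
    when any cutoff grows.
    """
    chain_id = chain or sorted(model.chains)[0]
    try:
        res = model.residue(chain_id, variant.position)
    except (KeyError, OutOfModelError) as exc:
        raise OutOfModelError(
            f"position {variant.position} outside the modelled range of chain {chain_id}"
        ) from exc

    loc = ResidueLocation()
    # inter-subunit interfaces
    for other in sorted(model.chains):
        if other == chain_id:
            continue
        other_atoms = np.vstack([r.coords for r in model.chains[other]])
        d = float(
            np.min(np.linalg.norm(res.coords[:, None, :] - other_atoms[None], axis=2))
        )
        loc.distances[f"interface:{other}"] = d
        if d <= config.interface and config.interface > 0:
            loc.labels.add(f"interface:{other}")
    # ion proximity
    for species, suffix in (("Ca2+", "near-Ca-site"), ("K+", "near-K-site")):
        prox = site_proximity(model, (chain_id, res.seqid), species, config.ion)
        if prox.applicable:
            loc.distances[f"{suffix}:{prox.owning_chain}"] = prox.distance
            if prox.within:
                loc.labels.add(f"{suffix}:{prox.owning_chain}")
    prox = site_proximity(model, (chain_id, res.seqid), "Cl-", config.ion)
    if prox.applicable:
        loc.distances["near-Cl-site"] = prox.distance
        if prox.within:
            loc.labels.add("near-Cl-site")
    # pore lining: radial distance to the symmetry axis
    _, radial = model.axial_radial(res.coords)
    loc.distances["pore-lining"] = float(radial.min())
    if radial.min() <= config.pore:
        loc.labels.add("pore-lining")
    # membrane band: axial coordinate of the residue centroid
    if model.membrane_band is not None:
        axial, _ = model.axial_radial(res.coords.mean(axis=0))
        lo, hi = sorted(model.membrane_band)
        loc.distances["membrane-axial"] = float(axial[0])
        if lo <= axial[0] <= hi:
            loc.labels.add("membrane-facing")
    if not loc.labels:
        loc.labels.add("other")
    return loc
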