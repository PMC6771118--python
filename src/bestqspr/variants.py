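"""Protein-level variant notation.

Variants are carried in the three-letter HGVS-like protein form
``p.(RefPosAlt)``, e.g. ``p.(Thr2Ile)`` for a threonine-to-isoleucine
replacement at residue 2 of bestrophin-1. Stop gains are written with a
``*`` as the alternate residue, e.g. ``p.(Arg200*)``; they truncate the
protein and cannot be scored by the energy-based pathogenicity model.

Nucleotide-level (c.) notation is never parsed, only carried verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "AMINO_ACIDS_3",
    "STOP",
    "ProteinVariant",
    "VariantParseError",
    "parse_protein_variant",
]

#: The 20 standard residues, three-letter codes.
AMINO_ACIDS_3 = frozenset(
    {
        "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    }
)

#: Symbol used for a stop gain in the alternate-residue slot.
STOP = "*"

_VARIANT_RE = re.compile(
    r"^p\.\(?(?P<ref>[A-Za-z]{3})(?P<pos>\d+)(?P<alt>[A-Za-z]{3}|\*)\)?$"
)


class VariantParseError(ValueError):
    """Raised when a protein-variant string cannot be parsed."""


@dataclass(frozen=True)
class ProteinVariant:
    """A single amino-acid replacement or stop gain.

    Attributes
    ----------
    ref_residue : str
        Three-letter code of the native residue.
    position : int
        1-based residue index in the protein sequence.
    alt_residue : str
        Three-letter code of the replacement residue, or ``"*"`` for a
        stop gain.
    raw : str
        The string the variant was parsed from.
    """

    ref_residue: str
    position: int
    alt_residue: str
    raw: str = ""

    def __post_init__(self) -> None:
        if self.ref_residue not in AMINO_ACIDS_3:
            raise VariantParseError(
                f"unknown reference residue code {self.ref_residue!r}"
            )
        if self.alt_residue != STOP and self.alt_residue not in AMINO_ACIDS_3:
            raise VariantParseError(
                f"unknown alternate residue code {self.alt_residue!r}"
            )
        if self.position < 1:
            raise VariantParseError(
                f"residue position must be >= 1, got {self.position}"
            )
        if not self.raw:
            object.__setattr__(self, "raw", self.canonical)

    @property
    def truncating(self) -> bool:
        """True for stop-gain variants, which truncate the protein."""
        return self.alt_residue == STOP

    @property
    def canonical(self) -> str:
        """Canonical ``p.(RefPosAlt)`` form."""
        return f"p.({self.ref_residue}{self.position}{self.alt_residue})"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical


def parse_protein_variant(text: str) -> ProteinVariant:
    """Parse ``p.(RefPosAlt)`` notation into a :class:`ProteinVariant`.

    Parameters
    ----------
    text : str
        For example ``"p.(Thr2Ile)"`` or ``"p.(Arg200*)"``.

    Raises
    ------
    VariantParseError
        If the notation is malformed, a residue code is unknown, or the
        position is zero. The message names the offending token.
    """
    if not text or not text.strip():
        raise VariantParseError("empty variant string")
    token = text.strip()
    m = _VARIANT_RE.match(token)
    if m is None:
        raise VariantParseError(f"malformed protein-variant notation {token!r}")
    ref = m.group("ref").capitalize()
    alt = m.group("alt")
    if alt != STOP:
        alt = alt.capitalize()
    pos = int(m.group("pos"))
    if pos < 1:
        raise VariantParseError(f"residue position 0 in {token!r}")
    return ProteinVariant(ref_residue=ref, position=pos, alt_residue=alt, raw=token)
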