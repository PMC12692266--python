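"""Feature-level representation of IgG N-glycans and Oxford-style naming.

A glycan is described by the features that distinguish the species handled by
the Golgi processing model: the mannose count of the trimmed core, the presence
of a beta-1,2-GlcNAc antenna on each core mannose arm, a bisecting GlcNAc, core
fucose, and per-arm galactose and sialic acid (with its alpha-2,3 or alpha-2,6
linkage).  A feature record — rather than a full tree — is sufficient because
the modelled species set is small and arm/linkage features fully separate it.

Naming follows Oxford notation: ``F`` core fucose, ``A<n>`` antenna count,
``B`` bisecting GlcNAc, ``G<n>`` galactoses, ``S<n>`` sialic acids, with the
sialyl linkage written as a digit after the antenna count (``A23.. / A26..``
for alpha-2,3 / alpha-2,6).  The oligomannose precursor is ``M5`` and its
GnT I product (a hybrid structure) ``M5A1``.

Arm-isomer convention: for biantennary structures a single galactose sits on
the alpha-1,6 arm (the dominant isomer in IgG), and a single sialic acid sits
on the alpha-1,6-arm galactose; names therefore collapse arm isomers, and
``parse_glycan_name`` returns the canonical isomer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "GlycanStructure",
    "M5",
    "parse_glycan_name",
    "canonical_name",
    "GlycanNameError",
]

#: sialyl linkage tags
A23 = "a23"
A26 = "a26"

_LINKAGE_DIGIT = {A23: "3", A26: "6"}
_DIGIT_LINKAGE = {v: k for k, v in _LINKAGE_DIGIT.items()}


class GlycanNameError(ValueError):
    """Raised when a glycan label cannot be parsed."""


@dataclass(frozen=True, order=True)
class GlycanStructure:
    """One N-glycan, described by its processing-relevant features.

    Attributes
    ----------
    mannose_count:
        Mannoses of the (possibly trimmed) core: 5 for oligomannose/hybrid
        species, 3 once Man II has trimmed the alpha-1,3/alpha-1,6 mannoses.
    glcnac_13, glcnac_16:
        beta-1,2-GlcNAc antenna on the alpha-1,3 / alpha-1,6 mannose arm.
    bisecting:
        beta-1,4-GlcNAc on the core beta-mannose.
    core_fucose:
        alpha-1,6-fucose on the innermost GlcNAc.
    gal_13, gal_16:
        beta-1,4-galactose capping the respective antenna.
    sia_13, sia_16:
        N-acetylneuraminic acid on the respective galactose.
    sia_linkage:
        ``"a23"`` or ``"a26"``; set iff any sialic acid is present.  All
        sialic acids of one structure share a linkage (mixed-linkage species
        are outside the modelled set).
    """

    mannose_count: int = 3
    glcnac_13: int = 0
    glcnac_16: int = 0
    bisecting: int = 0
    core_fucose: int = 0
    gal_13: int = 0
    gal_16: int = 0
    sia_13: int = 0
    sia_16: int = 0
    sia_linkage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mannose_count not in (3, 4, 5):
            raise ValueError(f"mannose_count must be 3..5, got {self.mannose_count}")
        for f in ("glcnac_13", "glcnac_16", "bisecting", "core_fucose",
                  "gal_13", "gal_16", "sia_13", "sia_16"):
            if getattr(self, f) not in (0, 1):
                raise ValueError(f"{f} must be 0 or 1")
        if self.gal_13 and not self.glcnac_13:
            raise ValueError("gal_13 requires glcnac_13")
        if self.gal_16 and not self.glcnac_16:
            raise ValueError("gal_16 requires glcnac_16")
        if self.sia_13 and not self.gal_13:
            raise ValueError("sia_13 requires gal_13")
        if self.sia_16 and not self.gal_16:
            raise ValueError("sia_16 requires gal_16")
        if self.mannose_count == 5 and self.glcnac_16:
            raise ValueError("five-mannose structures cannot carry an alpha-1,6 antenna")
        has_sia = bool(self.sia_13 or self.sia_16)
        if has_sia and self.sia_linkage not in (A23, A26):
            raise ValueError("sialylated structure requires sia_linkage 'a23' or 'a26'")
        if not has_sia and self.sia_linkage is not None:
            raise ValueError("sia_linkage set without sialic acid")

    # -- derived counts -------------------------------------------------
    @property
    def antennae(self) -> int:
        return self.glcnac_13 + self.glcnac_16

    @property
    def gal_count(self) -> int:
        return self.gal_13 + self.gal_16

    @property
    def sia_count(self) -> int:
        return self.sia_13 + self.sia_16

    @property
    def residue_count(self) -> int:
        """Total monosaccharides incl. the two core GlcNAc."""
        return (2 + self.mannose_count + self.antennae + self.bisecting
                + self.core_fucose + self.gal_count + self.sia_count)

    @property
    def name(self) -> str:
        return canonical_name(self)

    def with_features(self, **changes) -> "GlycanStructure":
        return replace(self, **changes)


#: the oligomannose seed species Man5GlcNAc2
M5 = GlycanStructure(mannose_count=5)


def canonical_name(structure: GlycanStructure) -> str:
    """Oxford-style label for *structure* (see module docstring for grammar)."""
    s = structure
    parts = []
    if s.core_fucose:
        parts.append("F")
    if s.mannose_count == 5:
        parts.append("M5")
        if s.glcnac_13:
            parts.append("A1")
    else:
        parts.append(f"A{s.antennae}")
        if s.sia_count:
            parts.append(_LINKAGE_DIGIT[s.sia_linkage])
    if s.bisecting:
        parts.append("B")
    if s.gal_count:
        parts.append(f"G{s.gal_count}")
    if s.sia_count:
        parts.append(f"S{s.sia_count}")
    return "".join(parts)


_NAME_RE = re.compile(
    r"^(?P<fuc>F)?(?P<m5>M5)?(?:A(?P<ant>[0-2])(?P<link>[36])?)?"
    r"(?P<bis>B)?(?:G(?P<gal>[12]))?(?:S(?P<sia>[12]))?$"
)


def parse_glycan_name(name: str) -> GlycanStructure:
    """Parse an Oxford-style glycan label into its canonical structure.

    Inverse of :func:`canonical_name` on the modelled species set; arm isomers
    collapsed by the naming convention are resolved to the canonical arm
    (alpha-1,6 first for galactose and sialic acid on biantennary glycans).
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        # locate the offending fragment for the error message
        for i in range(len(name), 0, -1):
            if _NAME_RE.match(name[:i].strip()) is not None:
                raise GlycanNameError(
                    f"cannot parse glycan name {name!r}: unknown token at {name[i:]!r}")
        raise GlycanNameError(f"cannot parse glycan name {name!r}")
    fuc = 1 if m.group("fuc") else 0
    man5 = m.group("m5") is not None
    ant = int(m.group("ant")) if m.group("ant") else 0
    link = m.group("link")
    bis = 1 if m.group("bis") else 0
    gal = int(m.group("gal")) if m.group("gal") else 0
    sia = int(m.group("sia")) if m.group("sia") else 0

    if not man5 and m.group("ant") is None:
        raise GlycanNameError(f"cannot parse glycan name {name!r}: no antenna or M5 core")
    if man5 and ant > 1:
        raise GlycanNameError(f"cannot parse glycan name {name!r}: M5 core admits at most one antenna")
    if gal > ant:
        raise GlycanNameError(f"cannot parse glycan name {name!r}: more galactoses than antennae")
    if sia > gal:
        raise GlycanNameError(f"cannot parse glycan name {name!r}: more sialic acids than galactoses")
    if sia and link is None:
        raise GlycanNameError(f"cannot parse glycan name {name!r}: sialylated name needs linkage digit 3 or 6")
    if not sia and link is not None:
        raise GlycanNameError(f"cannot parse glycan name {name!r}: linkage digit without sialic acid")

    glcnac_13 = 1 if ant >= 1 else 0
    glcnac_16 = 1 if ant == 2 else 0
    # single galactose: alpha-1,6 arm if present, else the alpha-1,3 arm
    gal_16 = 1 if (gal == 2 or (gal == 1 and glcnac_16)) else 0
    gal_13 = 1 if (gal == 2 or (gal == 1 and not glcnac_16)) else 0
    # single sialic acid goes on the alpha-1,6-arm galactose first
    sia_16 = 1 if (sia == 2 or (sia == 1 and gal_16)) else 0
    sia_13 = 1 if (sia == 2 or (sia == 1 and not gal_16)) else 0
    try:
        return GlycanStructure(
            mannose_count=5 if man5 else 3,
            glcnac_13=glcnac_13,
            glcnac_16=glcnac_16,
            bisecting=bis,
            core_fucose=fuc,
            gal_13=gal_13,
            gal_16=gal_16,
            sia_13=sia_13,
            sia_16=sia_16,
            sia_linkage=_DIGIT_LINKAGE[link] if sia else None,
        )
    except ValueError as exc:
        raise GlycanNameError(f"invalid glycan name {name!r}: {exc}") from exc
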