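"""Enzyme specificity rules for Golgi N-glycan processing.

Seven enzymes act on the glycan substrate; sialylation is carried out by one
enzyme (SiaT) with two catalytic activities distinguished by the linkage it
forms (alpha-2,3 vs alpha-2,6), so there are eight catalytic activities in
total:

* **GnT I** adds a beta-1,2-GlcNAc to the alpha-1,3 mannose of M5.
* **Man II** trims the alpha-1,3- and alpha-1,6-linked mannoses (both removed
  in one catalytic event); it requires the GnT I product and is blocked by a
  bisecting GlcNAc.
* **GnT II** adds a beta-1,2-GlcNAc to the alpha-1,6 mannose; it requires the
  trimmed (three-mannose) core and is blocked by bisecting GlcNAc and by
  galactosylation.
* **GnT III** adds the bisecting beta-1,4-GlcNAc to the core beta-mannose of
  complex (trimmed) structures; blocked by sialylation.
* **FucT** adds the alpha-1,6 core fucose; blocked by bisecting GlcNAc and by
  galactose on the alpha-1,3 arm.
* **GalT** caps a free antenna GlcNAc with beta-1,4-galactose (either arm).
* **SiaT** adds Neu5Ac to an arm galactose via alpha-2,3 or alpha-2,6 linkage;
  within one glycan all sialic acids share the linkage.

These precedence constraints follow the established rule set for the human
N-glycosylation network; the shipped reaction network is their closure over
the modelled species whitelist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .structures import A23, A26, GlycanStructure

__all__ = [
    "EnzymeRule",
    "ENZYMES",
    "ACTIVITIES",
    "ACTIVITY_ENZYME",
    "DEFAULT_RULES",
    "apply_rule",
    "factor_group",
    "FACTOR_GROUPS",
]

#: enzyme identifiers (concentration carriers), in canonical order
ENZYMES: Tuple[str, ...] = (
    "GnTI", "GnTII", "GnTIII", "ManII", "FucT", "GalT", "SiaT",
)

#: catalytic activities (kf carriers); SiaT has one per linkage
ACTIVITIES: Tuple[str, ...] = (
    "GnTI", "GnTII", "GnTIII", "ManII", "FucT", "GalT", "SiaT23", "SiaT26",
)

#: activity -> enzyme whose concentration drives it
ACTIVITY_ENZYME: Dict[str, str] = {a: a for a in ACTIVITIES[:6]}
ACTIVITY_ENZYME["SiaT23"] = "SiaT"
ACTIVITY_ENZYME["SiaT26"] = "SiaT"


@dataclass(frozen=True)
class EnzymeRule:
    """One site-specific catalytic event.

    ``required_features`` / ``forbidden_features`` are exact-value predicates
    on :class:`~glycoforge.structures.GlycanStructure` fields; ``transform``
    gives the new field values of the product.  ``linkage`` (sialylation
    rules only) must be compatible with the substrate's existing linkage tag.
    """

    rule_id: str
    enzyme_id: str          # concentration carrier, one of ENZYMES
    activity: str           # kinetic-constant carrier, one of ACTIVITIES
    required_features: Dict[str, int] = field(default_factory=dict)
    forbidden_features: Dict[str, int] = field(default_factory=dict)
    transform: Dict[str, int] = field(default_factory=dict)
    linkage: Optional[str] = None

    def applicable(self, s: GlycanStructure) -> bool:
        for f, v in self.required_features.items():
            if getattr(s, f) != v:
                return False
        for f, v in self.forbidden_features.items():
            if getattr(s, f) == v:
                return False
        if self.linkage is not None and s.sia_linkage not in (None, self.linkage):
            return False
        return True


def apply_rule(rule: EnzymeRule, s: GlycanStructure) -> Optional[GlycanStructure]:
    """Apply *rule* to *s*; return the product, or ``None`` if not applicable."""
    if not rule.applicable(s):
        return None
    changes = dict(rule.transform)
    if rule.linkage is not None:
        changes["sia_linkage"] = rule.linkage
    return s.with_features(**changes)


def _sia_rules(linkage: str) -> Tuple[EnzymeRule, EnzymeRule]:
    tag = {A23: "23", A26: "26"}[linkage]
    act = f"SiaT{tag}"
    return (
        EnzymeRule(
            rule_id=f"siat{tag}_16",
            enzyme_id="SiaT", activity=act, linkage=linkage,
            required_features={"gal_16": 1, "sia_16": 0},
            transform={"sia_16": 1},
        ),
        EnzymeRule(
            rule_id=f"siat{tag}_13",
            enzyme_id="SiaT", activity=act, linkage=linkage,
            required_features={"gal_13": 1, "sia_13": 0},
            transform={"sia_13": 1},
        ),
    )


DEFAULT_RULES: Tuple[EnzymeRule, ...] = (
    EnzymeRule(
        rule_id="gnt1", enzyme_id="GnTI", activity="GnTI",
        required_features={"mannose_count": 5, "glcnac_13": 0},
        transform={"glcnac_13": 1},
    ),
    # Man II removes both outer mannoses in one rule application
    EnzymeRule(
        rule_id="man2", enzyme_id="ManII", activity="ManII",
        required_features={"mannose_count": 5, "glcnac_13": 1, "bisecting": 0},
        transform={"mannose_count": 3},
    ),
    EnzymeRule(
        rule_id="gnt2", enzyme_id="GnTII", activity="GnTII",
        required_features={"mannose_count": 3, "glcnac_13": 1, "glcnac_16": 0,
                           "bisecting": 0, "gal_13": 0, "gal_16": 0},
        transform={"glcnac_16": 1},
    ),
    EnzymeRule(
        rule_id="gnt3", enzyme_id="GnTIII", activity="GnTIII",
        required_features={"mannose_count": 3, "glcnac_13": 1, "bisecting": 0,
                           "sia_13": 0, "sia_16": 0},
        transform={"bisecting": 1},
    ),
    EnzymeRule(
        rule_id="fuct", enzyme_id="FucT", activity="FucT",
        required_features={"glcnac_13": 1, "core_fucose": 0, "bisecting": 0,
                           "gal_13": 0},
        transform={"core_fucose": 1},
    ),
    EnzymeRule(
        rule_id="galt_16", enzyme_id="GalT", activity="GalT",
        required_features={"glcnac_16": 1, "gal_16": 0},
        transform={"gal_16": 1},
    ),
    EnzymeRule(
        rule_id="galt_13", enzyme_id="GalT", activity="GalT",
        required_features={"mannose_count": 3, "glcnac_13": 1, "gal_13": 0},
        transform={"gal_13": 1},
    ),
    *_sia_rules(A23),
    *_sia_rules(A26),
)


def factor_group(rule: EnzymeRule, substrate: GlycanStructure) -> str:
    """Correction-factor group of the reaction (rule, substrate).

    Reactions producing glycans of similar structure share one kf correction
    factor; the default grouping yields 22 groups over the 61 reactions.
    """
    rid = rule.rule_id
    if rid in ("gnt1", "man2", "gnt2"):
        return rid
    if rid == "gnt3":
        g = substrate.gal_count
        return "gnt3_agal" if g == 0 else (f"gnt3_g{g}")
    if rid == "fuct":
        if substrate.mannose_count == 5:
            return "fuct_hybrid"
        if substrate.glcnac_16 == 0:
            return "fuct_mono"
        if substrate.gal_count == 0:
            return "fuct_agal"
        return "fuct_g1" if substrate.sia_count == 0 else "fuct_g1s1"
    if rid.startswith("galt"):
        if substrate.glcnac_16 == 0:
            return "galt_mono"
        if rid == "galt_16":
            return "galt_first"
        if substrate.sia_count == 0:
            return "galt_second"
        return "galt_s1_b" if substrate.bisecting else "galt_s1"
    if rid.startswith("siat"):
        tag = "23" if rule.activity == "SiaT23" else "26"
        if substrate.gal_count == 1:
            return f"siat{tag}_g1"
        return f"siat{tag}_first" if substrate.sia_count == 0 else f"siat{tag}_second"
    raise ValueError(f"unknown rule {rid}")


#: the 22 correction-factor groups of the default configuration
FACTOR_GROUPS: Tuple[str, ...] = (
    "gnt1", "man2", "gnt2",
    "gnt3_agal", "gnt3_g1", "gnt3_g2",
    "fuct_hybrid", "fuct_mono", "fuct_agal", "fuct_g1", "fuct_g1s1",
    "galt_mono", "galt_first", "galt_second", "galt_s1", "galt_s1_b",
    "siat23_g1", "siat23_first", "siat23_second",
    "siat26_g1", "siat26_first", "siat26_second",
)
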