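"""Reaction-network construction for the Golgi glycosylation model.

The network is the breadth-first closure of the enzyme rules starting from M5,
restricted to the modelled species whitelist (the glycans observed in IgG
chromatographic peaks plus their obligatory processing intermediates).  With
the default whitelist and rule set this yields exactly 45 species and 61
enzymatic reactions.

Species ordering is deterministic: lexicographic on (total residue count,
name).  Reactions are ordered by (substrate index, product index, activity).

The stoichiometric matrix ``N`` is oriented species x reactions (45 x 61):
column ``r`` has −1 at the substrate row and +1 at the product row, so the
concentration dynamics read ``dC/dt = N @ v``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np

from .rules import DEFAULT_RULES, EnzymeRule, apply_rule, factor_group
from .structures import GlycanStructure, M5, parse_glycan_name

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "PeakTable",
    "generate_network",
    "build_stoichiometry",
    "DEFAULT_WHITELIST",
    "DEFAULT_PEAKS",
    "PEAK_IDS",
]


#: the 45 modelled glycan species (Oxford-style names)
DEFAULT_WHITELIST: Tuple[str, ...] = (
    # oligomannose / hybrid intermediates
    "M5", "M5A1", "FM5A1",
    # mono-antennary
    "A1", "FA1", "A1B", "FA1B", "A1G1", "FA1G1",
    # biantennary agalactosylated
    "A2", "FA2", "A2B", "FA2B",
    # monogalactosylated
    "A2G1", "FA2G1", "A2BG1", "FA2BG1",
    # digalactosylated
    "A2G2", "FA2G2", "A2BG2", "FA2BG2",
    # monogalactosylated, monosialylated
    "A23G1S1", "A26G1S1", "FA23G1S1", "FA26G1S1",
    "A23BG1S1", "A26BG1S1", "FA23BG1S1", "FA26BG1S1",
    # digalactosylated, monosialylated
    "A23G2S1", "A26G2S1", "FA23G2S1", "FA26G2S1",
    "A23BG2S1", "A26BG2S1", "FA23BG2S1", "FA26BG2S1",
    # digalactosylated, disialylated
    "A23G2S2", "A26G2S2", "FA23G2S2", "FA26G2S2",
    "A23BG2S2", "A26BG2S2", "FA23BG2S2", "FA26BG2S2",
)

#: retained chromatographic peaks (GP3 and GP20 are excluded from analysis)
PEAK_IDS: Tuple[str, ...] = tuple(
    f"GP{i}" for i in range(1, 25) if i not in (3, 20)
)

#: default peak-membership table: peak id -> member glycan names
DEFAULT_PEAKS: Dict[str, Tuple[str, ...]] = {
    "GP1": ("FA1",),
    "GP2": ("A2",),
    "GP4": ("FA2",),
    "GP5": ("M5",),
    "GP6": ("FA2B",),
    "GP7": ("A2G1",),
    "GP8": ("FA2G1",),
    "GP9": ("A2BG1",),
    "GP10": ("FA2BG1",),
    "GP11": ("A2G2",),
    "GP12": ("A2BG2",),
    "GP13": ("FA2BG2",),
    "GP14": ("FA2G2",),
    "GP15": ("A23G1S1", "A26G1S1"),
    "GP16": ("FA23G1S1", "FA26G1S1"),
    "GP17": ("A23G2S1", "A26G2S1"),
    "GP18": ("A23BG2S1", "A26BG2S1", "FA23G2S1", "FA26G2S1"),
    "GP19": ("FA23BG2S1", "FA26BG2S1"),
    "GP21": ("A23G2S2", "A26G2S2"),
    "GP22": ("A23BG2S2", "A26BG2S2"),
    "GP23": ("FA23G2S2", "FA26G2S2"),
    "GP24": ("FA23BG2S2", "FA26BG2S2"),
}


@dataclass(frozen=True)
class Reaction:
    """One enzymatic conversion substrate -> product."""

    substrate: int          # species index
    product: int            # species index
    enzyme_id: str          # concentration carrier
    activity: str           # kinetic-constant carrier
    rule_id: str
    factor_group: str       # kf correction-factor group

    def renamed(self, names: Sequence[str]) -> Tuple[str, str, str]:
        return (names[self.substrate], names[self.product], self.activity)


class ReactionNetwork:
    """Ordered species list plus the enzymatic reactions connecting them."""

    def __init__(self, species: Sequence[GlycanStructure],
                 reactions: Sequence[Reaction]):
        self.species: Tuple[GlycanStructure, ...] = tuple(species)
        self.names: Tuple[str, ...] = tuple(s.name for s in self.species)
        self.reactions: Tuple[Reaction, ...] = tuple(reactions)
        self.index: Dict[str, int] = {n: i for i, n in enumerate(self.names)}
        if len(self.index) != len(self.names):
            raise ValueError("duplicate species names in network")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (self.names == other.names
                and [ (r.substrate, r.product, r.activity, r.factor_group)
                      for r in self.reactions ]
                == [ (r.substrate, r.product, r.activity, r.factor_group)
                     for r in other.reactions ])

    def __repr__(self) -> str:
        return (f"ReactionNetwork({self.n_species} species, "
                f"{self.n_reactions} reactions)")


def _sort_key(s: GlycanStructure) -> tuple:
    return (s.residue_count, s.name)


def generate_network(
    seed: GlycanStructure = M5,
    rules: Sequence[EnzymeRule] = DEFAULT_RULES,
    whitelist: Iterable[str] = DEFAULT_WHITELIST,
) -> ReactionNetwork:
    """Breadth-first closure of *rules* from *seed*, restricted to *whitelist*.

    Raises
    ------
    ValueError
        If the seed is not whitelisted, or whitelist species are unreachable
        from the seed under the rule set (the error lists them).
    """
    wl_structs = {parse_glycan_name(n) for n in whitelist}
    if seed not in wl_structs:
        raise ValueError(f"seed {seed.name!r} not in whitelist")

    visited = {seed}
    frontier: List[GlycanStructure] = [seed]
    edges: List[Tuple[GlycanStructure, GlycanStructure, EnzymeRule]] = []
    while frontier:
        nxt: List[GlycanStructure] = []
        for s in frontier:
            for rule in rules:
                p = apply_rule(rule, s)
                if p is None or p not in wl_structs:
                    continue
                edges.append((s, p, rule))
                if p not in visited:
                    visited.add(p)
                    nxt.append(p)
        frontier = nxt

    missing = sorted(s.name for s in wl_structs - visited)
    if missing:
        raise ValueError(
            f"whitelist species unreachable from {seed.name!r}: {', '.join(missing)}")

    species = sorted(visited, key=_sort_key)
    index = {s: i for i, s in enumerate(species)}
    reactions = [
        Reaction(
            substrate=index[s], product=index[p],
            enzyme_id=rule.enzyme_id, activity=rule.activity,
            rule_id=rule.rule_id, factor_group=factor_group(rule, s),
        )
        for s, p, rule in edges
    ]
    reactions.sort(key=lambda r: (r.substrate, r.product, r.activity))
    return ReactionNetwork(species, reactions)


def build_stoichiometry(network: ReactionNetwork) -> np.ndarray:
    """Species x reactions stoichiometric matrix (entries −1, 0, +1)."""
    N = np.zeros((network.n_species, network.n_reactions), dtype=int)
    for j, r in enumerate(network.reactions):
        N[r.substrate, j] = -1
        N[r.product, j] = 1
    return N


class PeakTable:
    """Membership of glycan species in chromatographic peaks.

    Each retained peak (GP1..GP24 excluding GP3, GP20) groups the co-eluting
    glycans whose summed abundance it measures; a glycan belongs to at most
    one peak, and some processing intermediates belong to none.
    """

    def __init__(self, members: Mapping[str, Sequence[str]],
                 network: ReactionNetwork):
        self.peak_ids: Tuple[str, ...] = tuple(members)
        self.members: Dict[str, Tuple[str, ...]] = {
            p: tuple(g) for p, g in members.items()
        }
        seen: Dict[str, str] = {}
        for p, glycans in self.members.items():
            if p not in PEAK_IDS:
                raise ValueError(f"unknown peak id {p!r}")
            for g in glycans:
                if g not in network.index:
                    raise ValueError(f"peak {p} references unknown species {g!r}")
                if g in seen:
                    raise ValueError(f"species {g!r} in peaks {seen[g]} and {p}")
                seen[g] = p
        if set(self.peak_ids) != set(PEAK_IDS):
            missing = set(PEAK_IDS) - set(self.peak_ids)
            raise ValueError(f"peak table missing peaks: {sorted(missing)}")
        # indicator matrix: peaks x species
        self.indicator = np.zeros((len(self.peak_ids), network.n_species))
        for i, p in enumerate(self.peak_ids):
            for g in self.members[p]:
                self.indicator[i, network.index[g]] = 1.0

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakTable):
            return NotImplemented
        return self.members == other.members
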