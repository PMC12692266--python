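"""Model container: kinetics, enzyme distribution, compartment layout, I/O.

The Golgi is modelled as four sequential well-mixed compartments (cis-,
medial-, trans-cisternae and the trans-Golgi network) of equal volume, with a
glycan residence time of tau = 10 min per compartment (40 min total transit).
Each of the seven enzymes has a total concentration (uM) distributed over the
four compartments by fixed fractions; each of the eight catalytic activities
has a turnover constant kf (1/min) and a Michaelis constant Km (uM), the two
SiaT activities sharing one Km — 15 base kinetic parameters.  Per-reaction
correction factors (22 groups over the 61 reactions) multiply kf to absorb
structure-dependent deviations, for 37 kinetic parameters in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Tuple, Union

import numpy as np

from .network import (DEFAULT_PEAKS, PeakTable, ReactionNetwork,
                      build_stoichiometry, generate_network)
from .rules import ACTIVITIES, ACTIVITY_ENZYME, ENZYMES

__all__ = [
    "KineticParams",
    "EnzymeDistribution",
    "GolgiModel",
    "default_model",
    "read_model",
    "write_model",
    "DEFAULT_KF",
    "DEFAULT_KM",
    "DEFAULT_FACTORS",
    "DEFAULT_DISTRIBUTION",
    "DEFAULT_TOTALS",
    "DEFAULT_BOUNDS",
    "FITTED_ENZYMES",
]

SCHEMA_VERSION = 1

#: enzymes whose totals are fitted per individual (Man II stays common)
FITTED_ENZYMES: Tuple[str, ...] = ("GnTI", "GnTII", "GnTIII", "GalT", "FucT", "SiaT")

# ---------------------------------------------------------------------------
# Default parameter values.
#
# Turnover and Michaelis constants are literature-plausible values for the
# Golgi glycosyltransferases acting on an IgG-scale substrate pool (C0 =
# 1000 uM), chosen so the median simulation produces a realistic IgG glycan
# profile; correction factors refine individual reaction classes.
# ---------------------------------------------------------------------------

#: turnover constants kf (1/min) per catalytic activity
DEFAULT_KF: Dict[str, float] = {
    "GnTI": 1500.0,
    "GnTII": 2200.0,
    "GnTIII": 420.0,
    "ManII": 6000.0,
    "FucT": 1000.0,
    "GalT": 330.0,
    "SiaT23": 18.0,
    "SiaT26": 110.0,
}

#: Michaelis constants Km (uM) per enzyme (SiaT linkages share one Km)
DEFAULT_KM: Dict[str, float] = {
    "GnTI": 260.0,
    "GnTII": 190.0,
    "GnTIII": 180.0,
    "ManII": 110.0,
    "FucT": 170.0,
    "GalT": 130.0,
    "SiaT": 120.0,
}

#: kf correction factors per reaction group (dimensionless)
DEFAULT_FACTORS: Dict[str, float] = {
    "gnt1": 1.0,
    "man2": 1.0,
    "gnt2": 1.0,
    "gnt3_agal": 1.0,
    "gnt3_g1": 0.35,
    "gnt3_g2": 0.2,
    "fuct_hybrid": 0.6,
    "fuct_mono": 0.8,
    "fuct_agal": 1.0,
    "fuct_g1": 0.25,
    "fuct_g1s1": 0.1,
    "galt_mono": 0.05,
    "galt_first": 1.0,
    "galt_second": 0.65,
    "galt_s1": 0.45,
    "galt_s1_b": 0.45,
    "siat23_g1": 0.45,
    "siat23_first": 1.0,
    "siat23_second": 0.8,
    "siat26_g1": 0.45,
    "siat26_first": 1.0,
    "siat26_second": 0.8,
}

#: fraction of each enzyme's total in compartments I..IV (rows sum to 1)
DEFAULT_DISTRIBUTION: Dict[str, Tuple[float, float, float, float]] = {
    "GnTI":   (0.55, 0.35, 0.07, 0.03),
    "GnTII":  (0.10, 0.50, 0.30, 0.10),
    "GnTIII": (0.05, 0.40, 0.40, 0.15),
    "ManII":  (0.45, 0.45, 0.08, 0.02),
    "FucT":   (0.10, 0.45, 0.35, 0.10),
    "GalT":   (0.02, 0.13, 0.45, 0.40),
    "SiaT":   (0.01, 0.04, 0.25, 0.70),
}

#: median total enzyme concentrations (uM)
DEFAULT_TOTALS: Dict[str, float] = {
    "GnTI": 0.55,
    "GnTII": 0.50,
    "GnTIII": 0.09,
    "ManII": 0.50,
    "FucT": 0.55,
    "GalT": 0.42,
    "SiaT": 0.23,
}

#: per-enzyme search bounds (uM) for personalization; the GnT I upper bound
#: is 1.1 uM, the documented ceiling of its search range
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "GnTI": (0.0, 1.1),
    "GnTII": (0.0, 1.1),
    "GnTIII": (0.0, 1.1),
    "GalT": (0.0, 1.1),
    "FucT": (0.0, 1.1),
    "SiaT": (0.0, 1.1),
}


@dataclass(frozen=True)
class KineticParams:
    """kf/Km base constants plus per-group kf correction factors."""

    kf: Dict[str, float]          # per activity, 1/min
    km: Dict[str, float]          # per enzyme, uM
    factors: Dict[str, float]     # per correction-factor group

    def __post_init__(self) -> None:
        if set(self.kf) != set(ACTIVITIES):
            raise ValueError("kf must be given for all eight catalytic activities")
        if set(self.km) != set(ENZYMES):
            raise ValueError("Km must be given for all seven enzymes")
        for d, label in ((self.kf, "kf"), (self.km, "Km"), (self.factors, "factor")):
            for k, v in d.items():
                if not v > 0:
                    raise ValueError(f"{label}[{k}] must be > 0, got {v}")

    @property
    def n_parameters(self) -> int:
        """Base kf/Km count (SiaT Km shared) plus correction factors."""
        return len(self.kf) + len(self.km) + len(self.factors)

    def km_of_activity(self, activity: str) -> float:
        return self.km[ACTIVITY_ENZYME[activity]]


class EnzymeDistribution:
    """Fractions of each enzyme's total concentration per Golgi compartment."""

    def __init__(self, fractions: Mapping[str, Tuple[float, ...]],
                 renormalize: bool = True, atol: float = 1e-9):
        if set(fractions) != set(ENZYMES):
            raise ValueError("distribution must cover all seven enzymes")
        mat = np.array([fractions[e] for e in ENZYMES], dtype=float)
        if mat.shape != (7, 4):
            raise ValueError("each enzyme needs four compartment fractions")
        if (mat < 0).any() or (mat > 1).any():
            raise ValueError("fractions must lie in [0, 1]")
        sums = mat.sum(axis=1)
        if renormalize:
            # absorb rounding in transcribed tables
            mat = mat / sums[:, None]
        elif not np.allclose(sums, 1.0, atol=atol):
            bad = [ENZYMES[i] for i in np.nonzero(~np.isclose(sums, 1.0, atol=atol))[0]]
            raise ValueError(f"fractions do not sum to 1 for: {bad}")
        self.matrix = mat  # 7 enzymes x 4 compartments

    def compartment_concentrations(self, totals: Mapping[str, float]) -> np.ndarray:
        """Per-compartment enzyme concentrations U (7 x 4, uM)."""
        t = np.array([totals[e] for e in ENZYMES], dtype=float)
        if (t < 0).any():
            raise ValueError("enzyme totals must be non-negative")
        return self.matrix * t[:, None]

    def as_dict(self) -> Dict[str, Tuple[float, ...]]:
        # rounded so serialization round-trips are stable under renormalization
        return {e: tuple(round(float(v), 12) for v in self.matrix[i])
                for i, e in enumerate(ENZYMES)}

    def __eq__(self, other) -> bool:
        if not isinstance(other, EnzymeDistribution):
            return NotImplemented
        return np.allclose(self.matrix, other.matrix, atol=1e-12)


@dataclass(frozen=True)
class GolgiModel:
    """Complete model: network, peaks, kinetics, distribution, layout."""

    network: ReactionNetwork
    peaks: PeakTable
    kinetics: KineticParams
    distribution: EnzymeDistribution
    totals: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TOTALS))
    tau: float = 10.0               # residence time per compartment, min
    c0_total: float = 1000.0        # M5 input concentration, uM
    bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not self.c0_total > 0:
            raise ValueError("c0_total must be positive")
        groups = {r.factor_group for r in self.network.reactions}
        missing = groups - set(self.kinetics.factors)
        if missing:
            raise ValueError(f"no correction factor for groups: {sorted(missing)}")
        for e, (lo, hi) in self.bounds.items():
            if not (0 <= lo < hi):
                raise ValueError(f"bad bounds for {e}: ({lo}, {hi})")

    @property
    def stoichiometry(self) -> np.ndarray:
        return build_stoichiometry(self.network)

    def with_totals(self, totals: Mapping[str, float]) -> "GolgiModel":
        merged = dict(self.totals)
        merged.update(totals)
        return replace(self, totals=merged)

    def with_factors(self, factors: Mapping[str, float]) -> "GolgiModel":
        merged = dict(self.kinetics.factors)
        merged.update(factors)
        return replace(self, kinetics=replace(self.kinetics, factors=merged))

    def initial_condition(self) -> np.ndarray:
        """All input mass as M5 entering compartment I (uM)."""
        c0 = np.zeros(self.network.n_species)
        c0[self.network.index["M5"]] = self.c0_total
        return c0

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        names = self.network.names
        return {
            "schema_version": SCHEMA_VERSION,
            "species": list(names),
            "reactions": [
                {
                    "substrate": names[r.substrate],
                    "product": names[r.product],
                    "enzyme": r.enzyme_id,
                    "activity": r.activity,
                    "rule": r.rule_id,
                    "factor_group": r.factor_group,
                }
                for r in self.network.reactions
            ],
            "peaks": {p: list(g) for p, g in self.peaks.members.items()},
            "kinetics": {
                "kf": dict(self.kinetics.kf),
                "km": dict(self.kinetics.km),
                "factors": dict(self.kinetics.factors),
            },
            "distribution": {e: list(v) for e, v in self.distribution.as_dict().items()},
            "totals": dict(self.totals),
            "tau": self.tau,
            "c0_total": self.c0_total,
            "bounds": {e: list(b) for e, b in self.bounds.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GolgiModel":
        version = data.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema version {version!r}; "
                f"this build reads version {SCHEMA_VERSION}")
        from .structures import parse_glycan_name
        from .network import Reaction

        species = [parse_glycan_name(n) for n in data["species"]]
        names = [s.name for s in species]
        index = {n: i for i, n in enumerate(names)}
        reactions = []
        for r in data["reactions"]:
            for endpoint in ("substrate", "product"):
                if r[endpoint] not in index:
                    raise ValueError(
                        f"reaction references unknown species {r[endpoint]!r}")
            reactions.append(Reaction(
                substrate=index[r["substrate"]], product=index[r["product"]],
                enzyme_id=r["enzyme"], activity=r["activity"],
                rule_id=r["rule"], factor_group=r["factor_group"],
            ))
        network = ReactionNetwork(species, reactions)
        peaks = PeakTable({p: tuple(g) for p, g in data["peaks"].items()}, network)
        kin = KineticParams(
            kf=dict(data["kinetics"]["kf"]),
            km=dict(data["kinetics"]["km"]),
            factors=dict(data["kinetics"]["factors"]),
        )
        dist = EnzymeDistribution({e: tuple(v) for e, v in data["distribution"].items()})
        return cls(
            network=network, peaks=peaks, kinetics=kin, distribution=dist,
            totals=dict(data["totals"]), tau=float(data["tau"]),
            c0_total=float(data["c0_total"]),
            bounds={e: tuple(b) for e, b in data["bounds"].items()},
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GolgiModel):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def default_model() -> GolgiModel:
    """The shipped model: rule-generated network + default parameters."""
    network = generate_network()
    peaks = PeakTable(DEFAULT_PEAKS, network)
    kin = KineticParams(kf=dict(DEFAULT_KF), km=dict(DEFAULT_KM),
                        factors=dict(DEFAULT_FACTORS))
    dist = EnzymeDistribution(DEFAULT_DISTRIBUTION)
    return GolgiModel(network=network, peaks=peaks, kinetics=kin, distribution=dist)


def write_model(model: GolgiModel, path: Union[str, Path]) -> None:
    path = Path(path)
    text = json.dumps(model.to_dict(), indent=1)
    path.write_text(text + "\n")


def read_model(path: Union[str, Path]) -> GolgiModel:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml
        data = yaml.safe_load(path.read_text())
    else:
        data = json.loads(path.read_text())
    return GolgiModel.from_dict(data)
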