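"""Stoichiometry and flux algebra of the *Lactobacillus reuteri* Pdu pathway.

The propanediol-utilisation (Pdu) pathway of *L. reuteri* dehydrates glycerol
to the branch-point aldehyde 3-hydroxypropionaldehyde (3HPA, reuterin) and
partitions it between a reductive branch yielding 1,3-propanediol (1,3PDO)
and an oxidative branch yielding 3-hydroxypropionic acid (3HP).  Four net
specific fluxes describe the system in resting (non-growing) cells:

* ``v1`` — glycerol → 3HPA, the B12-dependent glycerol/diol dehydratase
  (PduCDE) step; a consumption flux, stored negative.
* ``v2`` — 3HPA + NADH → 1,3PDO + NAD+, the 1,3-propanediol oxidoreductase
  (PduQ) reductive branch.
* ``v3`` — 3HPA + NAD+ → 3HP + NADH + ATP, the lumped three-step oxidative
  branch (PduP, PduL, PduW) with 3HP-CoA and 3HP-phosphate as internal
  intermediates; CoA cycles internally and nets to zero.
* ``v4`` — net accumulation of free 3HPA, a bookkeeping pseudo-flux defined
  by the node balance ``v4 = |v1| − v2 − v3``.

Because the two branches exchange a single NAD+/NADH pair, a closed redox
balance forces ``v2 = v3`` once any cofactor carried over from the growth
phase has been drained — the "rigid node" that yields equimolar 3HP and
1,3PDO.

Specific fluxes are carried in mmol per g cell dry weight per hour
(mmol/g_CDW.h); mass rates (mg/g_CDW.h) convert through the molar mass of
the species each flux is conventionally expressed in (v1: glycerol, v2:
1,3PDO, v3: 3HP, v4: 3HPA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
import yaml

__all__ = [
    "MOLAR_MASS",
    "FLUX_SPECIES",
    "Metabolite",
    "PduNetwork",
    "FluxVector",
    "UnknownSpeciesError",
    "UndefinedSplitError",
    "InfeasibleFluxError",
    "MissingFluxError",
    "build_pdu_network",
    "mass_to_molar",
    "molar_to_mass",
    "node_balance_residual",
    "redox_residual",
    "split_ratio",
    "infer_branch_fluxes",
]

#: Standard molar masses, g/mol, to two decimals.
MOLAR_MASS: dict[str, float] = {
    "glycerol": 92.09,
    "3hpa": 74.08,
    "3hp": 90.08,
    "13pdo": 76.09,
    "carbohydrazide": 90.09,
    # The 3HPA-carbohydrazide complex is carried in 3HPA mass equivalents.
    "3hpa_complex": 74.08,
}

#: Species each flux is conventionally expressed in for mass rates.
FLUX_SPECIES: dict[str, str] = {
    "v1": "glycerol",
    "v2": "13pdo",
    "v3": "3hp",
    "v4": "3hpa",
}

#: C3-backbone species (those carrying the glycerol carbon skeleton).
C3_SPECIES = (
    "glycerol",
    "3hpa",
    "3hpa_complex",
    "3hp",
    "13pdo",
    "3hp_coa",
    "3hp_phosphate",
)

ROLES = ("substrate", "intermediate", "product", "cofactor", "scavenger", "complex")


class UnknownSpeciesError(KeyError):
    """A species id is not part of the network / molar-mass table."""


class UndefinedSplitError(ValueError):
    """Split ratio requested with zero total branch flux (0/0)."""


class InfeasibleFluxError(ValueError):
    """Node balance cannot be satisfied with non-negative branch fluxes."""


class MissingFluxError(ValueError):
    """A flux required by a balance computation is absent."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species of the network with its molar mass (g/mol)."""

    id: str
    molar_mass: float
    role: str

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass of {self.id!r} must be > 0")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.id!r}")


@dataclass(frozen=True)
class PduNetwork:
    """Signed stoichiometric matrix of the four net Pdu fluxes.

    ``stoich`` is a (metabolites x reactions) DataFrame of signed integer
    coefficients.  Documentation-only intermediates (3HP-CoA,
    3HP-phosphate) are present with zero net coefficient because the
    oxidative branch is lumped into the single net flux v3.
    """

    metabolites: tuple[Metabolite, ...]
    reactions: tuple[str, ...]
    stoich: pd.DataFrame

    def metabolite(self, species_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == species_id:
                return m
        raise UnknownSpeciesError(species_id)

    def molar_mass(self, species_id: str) -> float:
        return self.metabolite(species_id).molar_mass

    def validate(self) -> None:
        """Check structural invariants (C3 conservation, cofactor rows)."""
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolite ids")
        c3 = [s for s in C3_SPECIES if s in self.stoich.index]
        for rxn in self.reactions:
            col = self.stoich[rxn]
            consumed = sum(1 for s in c3 if col[s] < 0)
            produced = sum(1 for s in c3 if col[s] > 0)
            if rxn == "v4":
                if produced != 1 or consumed != 0 or col["3hpa"] != 1:
                    raise ValueError("v4 must touch only 3HPA (+1)")
            elif consumed != 1 or produced != 1:
                raise ValueError(f"{rxn} must move exactly one C3 unit")
        if tuple(self.stoich.loc["nadh"]) != (0, -1, 1, 0):
            raise ValueError("NADH row must be (0, -1, +1, 0)")
        if tuple(self.stoich.loc["atp"]) != (0, 0, 1, 0):
            raise ValueError("ATP row must be (0, 0, +1, 0)")
        if self.stoich.loc["coa", "v3"] != 0:
            raise ValueError("CoA must cycle internally in the lumped v3")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "metabolites": [
                {"id": m.id, "molar_mass": m.molar_mass, "role": m.role}
                for m in self.metabolites
            ],
            "reactions": list(self.reactions),
            "stoich": {
                m.id: {r: int(self.stoich.loc[m.id, r]) for r in self.reactions}
                for m in self.metabolites
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PduNetwork":
        mets = tuple(Metabolite(**m) for m in d["metabolites"])
        rxns = tuple(d["reactions"])
        stoich = pd.DataFrame(
            [[d["stoich"][m.id].get(r, 0) for r in rxns] for m in mets],
            index=[m.id for m in mets],
            columns=rxns,
            dtype=int,
        )
        net = cls(mets, rxns, stoich)
        net.validate()
        return net

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PduNetwork":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_pdu_network() -> PduNetwork:
    """Return the fixed four-flux Pdu network (deterministic)."""
    mets = (
        Metabolite("glycerol", MOLAR_MASS["glycerol"], "substrate"),
        Metabolite("3hpa", MOLAR_MASS["3hpa"], "intermediate"),
        Metabolite("3hp_coa", 857.64, "intermediate"),
        Metabolite("3hp_phosphate", 170.06, "intermediate"),
        Metabolite("3hp", MOLAR_MASS["3hp"], "product"),
        Metabolite("13pdo", MOLAR_MASS["13pdo"], "product"),
        Metabolite("carbohydrazide", MOLAR_MASS["carbohydrazide"], "scavenger"),
        Metabolite("3hpa_complex", MOLAR_MASS["3hpa_complex"], "complex"),
        Metabolite("nadh", 663.43, "cofactor"),
        Metabolite("nad", 663.43, "cofactor"),
        Metabolite("atp", 507.18, "cofactor"),
        Metabolite("adp", 427.20, "cofactor"),
        Metabolite("coa", 767.53, "cofactor"),
    )
    rxns = ("v1", "v2", "v3", "v4")
    stoich = pd.DataFrame(
        0, index=[m.id for m in mets], columns=list(rxns), dtype=int
    )
    # v1: glycerol dehydration (PduCDE); water elided.
    stoich.loc["glycerol", "v1"] = -1
    stoich.loc["3hpa", "v1"] = 1
    # v2: reductive branch (PduQ); regenerates one NAD+ per 1,3PDO.
    stoich.loc["3hpa", "v2"] = -1
    stoich.loc["nadh", "v2"] = -1
    stoich.loc["13pdo", "v2"] = 1
    stoich.loc["nad", "v2"] = 1
    # v3: lumped oxidative branch (PduP/PduL/PduW); one ATP per 3HP; CoA and
    # the acyl intermediates cycle internally (net zero).
    stoich.loc["3hpa", "v3"] = -1
    stoich.loc["nad", "v3"] = -1
    stoich.loc["3hp", "v3"] = 1
    stoich.loc["nadh", "v3"] = 1
    stoich.loc["atp", "v3"] = 1
    stoich.loc["adp", "v3"] = -1
    # v4: net accumulation of free 3HPA (bookkeeping column).
    stoich.loc["3hpa", "v4"] = 1
    net = PduNetwork(mets, rxns, stoich)
    net.validate()
    return net


def _lookup_molar_mass(species) -> float:
    if isinstance(species, Metabolite):
        return species.molar_mass
    try:
        return MOLAR_MASS[species]
    except KeyError:
        raise UnknownSpeciesError(f"unknown species id {species!r}") from None


def mass_to_molar(q_mass: float, species) -> float:
    """Convert a mass rate (mg/g_CDW.h) to molar (mmol/g_CDW.h).

    Sign is preserved; ``species`` is a :class:`Metabolite` or a species id.
    """
    return q_mass / _lookup_molar_mass(species)


def molar_to_mass(q_molar: float, species) -> float:
    """Convert a molar rate (mmol/g_CDW.h) to mass (mg/g_CDW.h)."""
    return q_molar * _lookup_molar_mass(species)


@dataclass(frozen=True)
class FluxVector:
    """Specific fluxes v1..v4 in mmol/g_CDW.h (consumption negative).

    The mass representation (mg/g_CDW.h) is derived on demand through the
    conventional species of each flux (v1 glycerol, v2 1,3PDO, v3 3HP,
    v4 3HPA), matching the column layout of published rate tables.
    """

    v1: Optional[float]
    v2: Optional[float]
    v3: Optional[float]
    v4: Optional[float] = 0.0

    @classmethod
    def from_mass(
        cls, q_s: float, q_pdo: float, q_hp: float, q_hpa: float = 0.0
    ) -> "FluxVector":
        """Build from mass rates (mg/g_CDW.h) in Table-style units."""
        return cls(
            v1=mass_to_molar(q_s, "glycerol"),
            v2=mass_to_molar(q_pdo, "13pdo"),
            v3=mass_to_molar(q_hp, "3hp"),
            v4=mass_to_molar(q_hpa, "3hpa"),
        )

    @property
    def mass(self) -> dict[str, float]:
        """Mass rates mg/g_CDW.h keyed by flux name."""
        self._require_all()
        return {
            name: molar_to_mass(getattr(self, name), FLUX_SPECIES[name])
            for name in FLUX_SPECIES
        }

    def _require_all(self, names=("v1", "v2", "v3", "v4")) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise MissingFluxError(f"flux {name} is missing")


def node_balance_residual(f: FluxVector) -> float:
    """3HPA node closure |v1| − v2 − v3 − v4, mmol/g_CDW.h (0 = perfect)."""
    f._require_all()
    return abs(f.v1) - f.v2 - f.v3 - f.v4


def redox_residual(f: FluxVector) -> float:
    """Net NADH drift v3 − v2, mmol/g_CDW.h (0 = balanced redox)."""
    f._require_all(("v2", "v3"))
    return f.v3 - f.v2


def split_ratio(f: FluxVector) -> tuple[float, float]:
    """Flux split around the 3HPA node as (mol% to 3HP, mol% to 1,3PDO).

    The two components sum to 100 exactly.
    """
    f._require_all(("v2", "v3"))
    total = f.v2 + f.v3
    if total <= 0:
        raise UndefinedSplitError("v2 + v3 must be > 0 to define a split ratio")
    to_hp = 100.0 * f.v3 / total
    return (to_hp, 100.0 - to_hp)


def infer_branch_fluxes(v1: float, v4: float = 0.0) -> tuple[float, float]:
    """Redox-constrained branch fluxes (v2, v3) from uptake and accumulation.

    With a closed NAD+/NADH cycle the two branches run equimolar, so the
    node balance has the unique solution ``v2 = v3 = (|v1| − v4)/2``.
    Inputs and outputs in mmol/g_CDW.h; ``v1`` may carry the negative
    consumption sign.
    """
    mag = abs(v1)
    if v4 < 0:
        raise InfeasibleFluxError(f"v4 must be >= 0, got {v4}")
    if v4 > mag:
        raise InfeasibleFluxError(
            f"3HPA accumulation v4={v4} exceeds glycerol uptake |v1|={mag}"
        )
    half = (mag - v4) / 2.0
    return (half, half)
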