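"""Chemical species, balanced iron-reduction reactions, and Gibbs energies.

This module represents the six microbially relevant iron-reduction redox
couples (acetate or H2 as electron donor; goethite, hematite, ferrihydrite
or aqueous Fe3+ as electron acceptor), balances them from elemental
composition, and evaluates the per-electron Gibbs free energy of reaction

    dGr = dG0r(T) + R*T*ln(Q)

at arbitrary temperature, pH and activity assumptions.  dG0r is
extrapolated away from 298.15 K with the constant-enthalpy (van 't Hoff)
approximation: dG0r(T) = dH0r(298) - T*dS0r(298), with
dS0r = (dH0r - dG0r)/298.15.  The reaction quotient treats activities as
effective concentrations (no ionic-strength correction); solids and liquid
water are assigned unit activity and a(H+) is always 10**(-pH).

Formation data live in a packaged CSV (``data/species.csv``) with per-row
provenance; the table, not the code, is the source of truth.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path

import pandas as pd
import sympy

__all__ = [
    "R_KJ",
    "T_REF",
    "CELSIUS_OFFSET",
    "DONORS",
    "ACCEPTORS",
    "MINERAL_ACCEPTORS",
    "Species",
    "SpeciesTable",
    "Reaction",
    "ActivityModel",
    "UnknownSpeciesError",
    "balance_reaction",
    "standard_delta_g",
    "delta_g_per_electron",
    "celsius_to_kelvin",
]

# Gas constant in kJ K-1 mol-1, fixed at 8.31 J K-1 mol-1 for reproducibility.
R_KJ = 8.31e-3
T_REF = 298.15
CELSIUS_OFFSET = 273.15

# donor / acceptor identifiers -> species name in the table
DONORS = {"acetate": "acetate", "hydrogen": "H2(aq)"}
ACCEPTORS = {
    "goethite": "goethite",
    "hematite": "hematite",
    "ferrihydrite": "ferrihydrite",
    "ferric-aqueous": "Fe3+",
}
MINERAL_ACCEPTORS = ("goethite", "hematite", "ferrihydrite")


class UnknownSpeciesError(KeyError):
    """A donor, acceptor or species name is absent from the species table."""


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + CELSIUS_OFFSET


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string (e.g. ``C2H3O2``) into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Species:
    """A chemical species with phase and standard-state formation properties.

    ``dGf0`` and ``dHf0`` are standard free energy and enthalpy of formation
    at 298.15 K in kJ/mol.  Solids and liquid water always take unit
    activity in quotient evaluation.
    """

    name: str
    formula: dict[str, int]
    charge: int
    phase: str  # aqueous | solid | liquid-water
    dGf0: float
    dHf0: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.phase not in ("aqueous", "solid", "liquid-water"):
            raise ValueError(f"unknown phase {self.phase!r} for {self.name}")
        if any(n < 0 or n != int(n) for n in self.formula.values()):
            raise ValueError(f"element counts must be non-negative integers: {self.name}")

    @property
    def unit_activity(self) -> bool:
        return self.phase in ("solid", "liquid-water")


class SpeciesTable:
    """Lookup table of Species, loaded from the packaged (or a user) CSV."""

    def __init__(self, species: dict[str, Species]):
        self._species = dict(species)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpeciesTable":
        df = pd.read_csv(path)
        species = {}
        for row in df.itertuples(index=False):
            species[row.name] = Species(
                name=row.name,
                formula=parse_formula(row.formula),
                charge=int(row.charge),
                phase=row.phase,
                dGf0=float(row.dGf0_kJ_mol),
                dHf0=float(row.dHf0_kJ_mol),
                source=str(row.source),
            )
        return cls(species)

    @classmethod
    def default(cls) -> "SpeciesTable":
        with resources.as_file(
            resources.files("ferrohab.data").joinpath("species.csv")
        ) as p:
            return cls.from_csv(p)

    def __getitem__(self, name: str) -> Species:
        try:
            return self._species[name]
        except KeyError:
            raise UnknownSpeciesError(
                f"species {name!r} not in species table"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._species

    def names(self) -> list[str]:
        return list(self._species)


@dataclass(frozen=True)
class Reaction:
    """A balanced redox couple with integer stoichiometry and electron count."""

    reactants: dict[str, int]
    products: dict[str, int]
    donor: str
    acceptor: str
    n_electrons: int

    def coefficient(self, name: str) -> int:
        """Signed coefficient: positive for products, negative for reactants."""
        return self.products.get(name, 0) - self.reactants.get(name, 0)

    def species_names(self) -> list[str]:
        return sorted(set(self.reactants) | set(self.products))

    def element_imbalance(self, table: SpeciesTable) -> dict[str, int]:
        """Net element counts (products minus reactants); all-zero iff balanced."""
        net: dict[str, int] = {}
        for name in self.species_names():
            sp = table[name]
            nu = self.coefficient(name)
            for el, cnt in sp.formula.items():
                net[el] = net.get(el, 0) + nu * cnt
        return {el: v for el, v in net.items() if v != 0}

    def charge_imbalance(self, table: SpeciesTable) -> int:
        return sum(self.coefficient(n) * table[n].charge for n in self.species_names())

    def scaled(self, k: int) -> "Reaction":
        return Reaction(
            reactants={n: k * c for n, c in self.reactants.items()},
            products={n: k * c for n, c in self.products.items()},
            donor=self.donor,
            acceptor=self.acceptor,
            n_electrons=k * self.n_electrons,
        )

    def reversed(self) -> "Reaction":
        return Reaction(
            reactants=dict(self.products),
            products=dict(self.reactants),
            donor=self.donor,
            acceptor=self.acceptor,
            n_electrons=self.n_electrons,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "reactants": self.reactants,
                "products": self.products,
                "donor": self.donor,
                "acceptor": self.acceptor,
                "n_electrons": self.n_electrons,
            },
            indent=2,
        )

    def __str__(self) -> str:
        def side(coeffs: dict[str, int]) -> str:
            return " + ".join(
                (f"{c} {n}" if c != 1 else n) for n, c in coeffs.items()
            )

        return f"{side(self.reactants)} = {side(self.products)}"


def balance_reaction(
    donor: str, acceptor: str, table: SpeciesTable | None = None
) -> Reaction:
    """Construct the unique balanced reaction for a donor/acceptor couple.

    Coefficients are found as the one-dimensional rational nullspace of the
    element+charge conservation matrix over the couple's participant set
    (donor, acceptor, Fe2+, H2O, H+, and HCO3- for acetate, which is taken
    to be completely oxidised).  The result is normalised to integer
    coefficients with one formula unit of the donor, oriented so that Fe2+
    is produced.  ``n_electrons`` is the number of Fe(III) -> Fe(II)
    conversions (8 for acetate, 2 for hydrogen).
    """
    if table is None:
        table = SpeciesTable.default()
    if donor not in DONORS:
        raise UnknownSpeciesError(f"unknown donor {donor!r}; expected one of {sorted(DONORS)}")
    if acceptor not in ACCEPTORS:
        raise UnknownSpeciesError(
            f"unknown acceptor {acceptor!r}; expected one of {sorted(ACCEPTORS)}"
        )

    participants = [DONORS[donor], ACCEPTORS[acceptor], "Fe2+", "H2O", "H+"]
    if donor == "acetate":
        participants.append("HCO3-")
    species = [table[n] for n in participants]

    elements = sorted({el for sp in species for el in sp.formula})
    rows = [[sp.formula.get(el, 0) for sp in species] for el in elements]
    rows.append([sp.charge for sp in species])  # charge conservation

    null = sympy.Matrix(rows).nullspace()
    if len(null) != 1:
        raise ValueError(
            f"stoichiometry for ({donor}, {acceptor}) is not uniquely determined"
        )
    vec = [Fraction(sympy.nsimplify(x)) for x in null[0]]

    # one formula unit of donor, donor on the reactant side
    vec = [v / -vec[0] for v in vec]
    denom_lcm = math.lcm(*(v.denominator for v in vec))
    coeffs = [int(v * denom_lcm) for v in vec]
    if coeffs[participants.index("Fe2+")] < 0:
        coeffs = [-c for c in coeffs]

    reactants = {n: -c for n, c in zip(participants, coeffs) if c < 0}
    products = {n: c for n, c in zip(participants, coeffs) if c > 0}
    return Reaction(
        reactants=reactants,
        products=products,
        donor=donor,
        acceptor=acceptor,
        n_electrons=products["Fe2+"],
    )


#: typical environmental activities for the aqueous species (overridable)
DEFAULT_ACTIVITIES = {
    "acetate": 1e-3,
    "HCO3-": 1e-3,
    "Fe2+": 1e-3,
    "Fe3+": 1e-3,
    "H2(aq)": 1e-4,
}


@dataclass
class ActivityModel:
    """Dimensionless activities for aqueous species.

    Solids and liquid water are forced to unit activity; a(H+) is always
    derived from pH as 10**(-pH), never from the static table.
    """

    activities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITIES)
    )

    def __post_init__(self) -> None:
        bad = {n: a for n, a in self.activities.items() if not a > 0}
        if bad:
            raise ValueError(f"activities must be strictly positive: {bad}")

    def activity(self, sp: Species, pH: float) -> float:
        if sp.unit_activity:
            return 1.0
        if sp.name == "H+":
            return 10.0 ** (-pH)
        try:
            a = self.activities[sp.name]
        except KeyError:
            raise UnknownSpeciesError(
                f"no activity configured for aqueous species {sp.name!r}"
            ) from None
        if not a > 0:
            raise ValueError(f"non-positive activity for {sp.name!r}: {a}")
        return a


def standard_delta_g(
    reaction: Reaction, T: float, table: SpeciesTable | None = None
) -> float:
    """Standard-state Gibbs free energy of reaction at temperature T (K), kJ/mol.

    Constant-enthalpy extrapolation from 298.15 K:
    dG0r(T) = dH0r(298) - T * dS0r(298) with dS0r = (dH0r - dG0r)/298.15.
    """
    if table is None:
        table = SpeciesTable.default()
    dG298 = sum(reaction.coefficient(n) * table[n].dGf0 for n in reaction.species_names())
    dH298 = sum(reaction.coefficient(n) * table[n].dHf0 for n in reaction.species_names())
    dS298 = (dH298 - dG298) / T_REF
    return dH298 - T * dS298


def ln_reaction_quotient(
    reaction: Reaction,
    pH: float,
    act: ActivityModel,
    table: SpeciesTable,
) -> float:
    return sum(
        reaction.coefficient(n) * math.log(act.activity(table[n], pH))
        for n in reaction.species_names()
    )


def delta_g_per_electron(
    reaction: Reaction,
    T: float,
    pH: float,
    act: ActivityModel | None = None,
    table: SpeciesTable | None = None,
) -> float:
    """Per-electron Gibbs free energy of reaction, kJ per electron transferred.

    Evaluates [dG0r(T) + R*T*ln(Q)] / n_electrons with T in Kelvin, Q built
    from activities (solids/water at 1, a(H+) = 10**-pH).
    """
    if table is None:
        table = SpeciesTable.default()
    if act is None:
        act = ActivityModel()
    lnQ = ln_reaction_quotient(reaction, pH, act, table)
    dg = standard_delta_g(reaction, T, table) + R_KJ * T * lnQ
    return dg / reaction.n_electrons
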