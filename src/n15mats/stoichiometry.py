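"""Balancing of chemolithotrophic sulfur-oxidation half-reactions.

Giant sulfur bacteria couple the oxidation of sulfide (HS⁻) or internally
stored elemental sulfur (S⁰) to the reduction of NO₃⁻, either to N₂
(denitrification, 5 e⁻ per N) or to NH₄⁺ (DNRA, 8 e⁻ per N).  This module
balances such donor/acceptor couples into full reactions, closing oxygen,
hydrogen and charge with H₂O and H⁺ only, and reports the bookkeeping
quantities that matter ecologically: electrons per mole, protons turned over
per NO₃⁻ reduced, and NO₃⁻ demand per mole of electron donor.

All coefficients are exact :class:`fractions.Fraction` values; decimals
appear only when rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Mapping, Tuple

__all__ = [
    "ChemicalSpecies",
    "RedoxCouple",
    "BalancedReaction",
    "SPECIES",
    "species",
    "oxidation_state",
    "electrons_per_mole",
    "balance",
    "protons_per_nitrate",
    "nitrate_per_donor",
]

# Oxidation-state bookkeeping convention.  Peroxides/superoxides, where O is
# not -2, are deliberately unsupported.
_FIXED_STATES = {"O": -2, "H": +1}


@dataclass(frozen=True)
class ChemicalSpecies:
    """A chemical species with integer element counts and a formal charge."""

    name: str
    element_counts: Mapping[str, int]
    charge: int

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        if not counts or all(v == 0 for v in counts.values()):
            raise ValueError(f"{self.name}: empty formula")
        if any(v < 0 for v in counts.values()):
            raise ValueError(f"{self.name}: negative element count")
        object.__setattr__(self, "element_counts", counts)

    def count(self, element: str) -> int:
        return self.element_counts.get(element, 0)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _sp(name: str, counts: Dict[str, int], charge: int) -> ChemicalSpecies:
    return ChemicalSpecies(name, counts, charge)


#: Registry of every species appearing in the sulfur/nitrogen reaction set.
SPECIES: Dict[str, ChemicalSpecies] = {
    s.name: s
    for s in (
        _sp("S0", {"S": 1}, 0),
        _sp("HS-", {"H": 1, "S": 1}, -1),
        _sp("SO4^2-", {"S": 1, "O": 4}, -2),
        _sp("NO3-", {"N": 1, "O": 3}, -1),
        _sp("NO2-", {"N": 1, "O": 2}, -1),
        _sp("NH4+", {"N": 1, "H": 4}, +1),
        _sp("N2", {"N": 2}, 0),
        _sp("N2O", {"N": 2, "O": 1}, +0),
        _sp("O2", {"O": 2}, 0),
        _sp("H2O", {"H": 2, "O": 1}, 0),
        _sp("H+", {"H": 1}, +1),
    )
}

# Aliases accepted by the CLI / lookups (common ASCII spellings).
_ALIASES = {
    "SO42-": "SO4^2-",
    "SO4--": "SO4^2-",
    "S": "S0",
    "HS": "HS-",
}


def species(name: str) -> ChemicalSpecies:
    """Look up a registered species by name (a few ASCII aliases accepted)."""
    key = _ALIASES.get(name, name)
    try:
        return SPECIES[key]
    except KeyError:
        raise KeyError(
            f"unknown species {name!r}; known: {sorted(SPECIES)}"
        ) from None


def oxidation_state(sp: ChemicalSpecies, element: str) -> int:
    """Oxidation state of ``element`` in ``sp`` under fixed O = −2, H = +1.

    The species must contain ``element`` and, apart from O and H, no other
    element.  O and H themselves may be the redox element (e.g. O in O₂ or
    H₂O), in which case only the remaining fixed assignments apply.
    """
    if sp.count(element) == 0:
        raise ValueError(f"element {element} absent from {sp.name}")
    others = [
        e for e in sp.element_counts
        if e != element and sp.element_counts[e] > 0 and e not in _FIXED_STATES
    ]
    if others:
        raise ValueError(
            f"{sp.name}: unsupported species (extra non-O/H elements {others})"
        )
    fixed_sum = sum(
        _FIXED_STATES[e] * n
        for e, n in sp.element_counts.items()
        if e != element and e in _FIXED_STATES
    )
    x = Fraction(sp.charge - fixed_sum, sp.count(element))
    if x.denominator != 1:
        raise ValueError(
            f"{sp.name}: non-integer mean oxidation state for {element}"
        )
    return int(x)


@dataclass(frozen=True)
class RedoxCouple:
    """A half-reaction reactant/product pair for one redox-active element.

    ``electrons_per_mole_reactant`` is signed: positive when the reactant is
    oxidised (donor couple, electrons released), negative when reduced
    (acceptor couple, electrons taken up).
    """

    reactant: ChemicalSpecies
    product: ChemicalSpecies
    redox_element: str
    electrons_per_mole_reactant: Fraction = field(init=False)

    def __post_init__(self) -> None:
        st_r = oxidation_state(self.reactant, self.redox_element)
        st_p = oxidation_state(self.product, self.redox_element)
        n_atoms = self.reactant.count(self.redox_element)
        if self.product.count(self.redox_element) == 0:
            raise ValueError(
                f"redox element {self.redox_element} absent from product "
                f"{self.product.name}"
            )
        delta = st_p - st_r
        if delta == 0:
            raise ValueError(
                f"not a redox couple: {self.reactant.name} -> "
                f"{self.product.name} leaves {self.redox_element} unchanged"
            )
        object.__setattr__(
            self, "electrons_per_mole_reactant", Fraction(delta * n_atoms)
        )

    @property
    def is_donor(self) -> bool:
        """True when the couple releases electrons (element is oxidised)."""
        return self.electrons_per_mole_reactant > 0

    @property
    def is_acceptor(self) -> bool:
        return self.electrons_per_mole_reactant < 0


def couple(reactant: str, product: str, redox_element: str | None = None) -> RedoxCouple:
    """Build a :class:`RedoxCouple` from registered species names.

    When ``redox_element`` is omitted it is inferred as the element shared by
    reactant and product, preferring S and N over O and H.
    """
    r, p = species(reactant), species(product)
    if redox_element is None:
        shared = [e for e in r.element_counts if p.count(e) > 0]
        for preferred in ("S", "N", "O", "H"):
            if preferred in shared:
                redox_element = preferred
                break
        if redox_element is None:
            raise ValueError(f"no shared element between {reactant} and {product}")
    return RedoxCouple(r, p, redox_element)


def electrons_per_mole(c: RedoxCouple) -> Tuple[Fraction, str]:
    """Electrons transferred per mole of the couple's reactant.

    Returns ``(magnitude, direction)`` with direction ``"donated"`` for a
    donor couple and ``"accepted"`` for an acceptor couple.  E.g. NO₃⁻ → ½N₂
    accepts 5 e⁻ per NO₃⁻ and NO₃⁻ → NH₄⁺ accepts 8, the efficiency gap that
    favours denitrification when electron donor is scarce.
    """
    e = c.electrons_per_mole_reactant
    return (abs(e), "donated" if e > 0 else "accepted")


@dataclass(frozen=True)
class BalancedReaction:
    """A fully balanced reaction, coefficients keyed by species name."""

    reactant_coeffs: Mapping[str, Fraction]
    product_coeffs: Mapping[str, Fraction]
    normalization: str

    def __post_init__(self) -> None:
        for side in (self.reactant_coeffs, self.product_coeffs):
            for name, coeff in side.items():
                if coeff <= 0:
                    raise ValueError(f"non-positive coefficient for {name}")
        for closure in ("H2O", "H+"):
            if closure in self.reactant_coeffs and closure in self.product_coeffs:
                raise ValueError(f"{closure} on both sides")
        imbalance = self._imbalances()
        if imbalance:
            raise ValueError(f"reaction not balanced: {imbalance}")

    def _imbalances(self) -> Dict[str, Fraction]:
        totals: Dict[str, Fraction] = {}
        charge = Fraction(0)
        for side, sign in ((self.reactant_coeffs, 1), (self.product_coeffs, -1)):
            for name, coeff in side.items():
                sp = species(name)
                charge += sign * coeff * sp.charge
                for e, n in sp.element_counts.items():
                    totals[e] = totals.get(e, Fraction(0)) + sign * coeff * n
        out = {e: v for e, v in totals.items() if v != 0}
        if charge != 0:
            out["charge"] = charge
        return out

    def coefficient(self, name: str) -> Fraction:
        """Signed coefficient: positive reactant, negative product, 0 absent."""
        if name in self.reactant_coeffs:
            return self.reactant_coeffs[name]
        if name in self.product_coeffs:
            return -self.product_coeffs[name]
        return Fraction(0)

    def __str__(self) -> str:
        def render(side: Mapping[str, Fraction]) -> str:
            parts = []
            for name, coeff in side.items():
                c = "" if coeff == 1 else f"{float(coeff):g} "
                parts.append(f"{c}{name}")
            return " + ".join(parts)

        return f"{render(self.reactant_coeffs)} -> {render(self.product_coeffs)}"

    def as_dict(self) -> Dict[str, Dict[str, float]]:
        return {
            "reactants": {k: float(v) for k, v in self.reactant_coeffs.items()},
            "products": {k: float(v) for k, v in self.product_coeffs.items()},
            "normalization": self.normalization,
        }


def balance(donor: RedoxCouple, acceptor: RedoxCouple) -> BalancedReaction:
    """Balance a donor couple against an acceptor couple.

    The reaction is normalised to 1 mol of the donor reactant.  Electrons are
    conserved (donor e⁻ = acceptor e⁻); O, H and charge are closed using H₂O
    and H⁺ only, which suffices for the S/N/O/H system.  Coefficients are
    exact rationals.
    """
    if not donor.is_donor:
        raise ValueError(f"{donor.reactant.name}->{donor.product.name} does not donate electrons")
    if not acceptor.is_acceptor:
        raise ValueError(
            f"{acceptor.reactant.name}->{acceptor.product.name} does not accept electrons"
        )

    e_donated = donor.electrons_per_mole_reactant  # > 0, per 1 mol donor
    e_accepted = -acceptor.electrons_per_mole_reactant  # > 0, per 1 mol acceptor

    lhs: Dict[str, Fraction] = {}
    rhs: Dict[str, Fraction] = {}

    def add(side: Dict[str, Fraction], sp: ChemicalSpecies, coeff: Fraction) -> None:
        if coeff != 0:
            side[sp.name] = side.get(sp.name, Fraction(0)) + coeff

    # Donor at coefficient 1; donor product keeps the redox atoms.
    add(lhs, donor.reactant, Fraction(1))
    add(
        rhs,
        donor.product,
        Fraction(donor.reactant.count(donor.redox_element),
                 donor.product.count(donor.redox_element)),
    )
    # Acceptor scaled to take up exactly the donated electrons.
    acc_coeff = e_donated / e_accepted
    add(lhs, acceptor.reactant, acc_coeff)
    add(
        rhs,
        acceptor.product,
        acc_coeff * acceptor.reactant.count(acceptor.redox_element)
        / acceptor.product.count(acceptor.redox_element),
    )

    def total(side: Dict[str, Fraction], element: str) -> Fraction:
        return sum(
            (coeff * species(name).count(element) for name, coeff in side.items()),
            Fraction(0),
        )

    # Close O with H2O, then H with H+.  Charge closes automatically because
    # electrons were conserved; the constructor re-checks everything.
    d_oxygen = total(lhs, "O") - total(rhs, "O")
    if d_oxygen > 0:
        add(rhs, SPECIES["H2O"], d_oxygen)
    elif d_oxygen < 0:
        add(lhs, SPECIES["H2O"], -d_oxygen)
    d_hydrogen = total(lhs, "H") - total(rhs, "H")
    if d_hydrogen > 0:
        add(rhs, SPECIES["H+"], d_hydrogen)
    elif d_hydrogen < 0:
        add(lhs, SPECIES["H+"], -d_hydrogen)

    # Cancel closure species that ended up on both sides (possible when a
    # couple's own product is H2O, e.g. O2 -> H2O).
    for closure in ("H2O", "H+"):
        if closure in lhs and closure in rhs:
            net = lhs[closure] - rhs[closure]
            lhs.pop(closure)
            rhs.pop(closure)
            if net > 0:
                lhs[closure] = net
            elif net < 0:
                rhs[closure] = -net

    return BalancedReaction(lhs, rhs, normalization=donor.reactant.name)


def protons_per_nitrate(rxn: BalancedReaction) -> Tuple[Fraction, Fraction]:
    """Proton turnover per mole of NO₃⁻ reduced.

    Returns ``(signed, magnitude)`` where ``signed`` is positive when H⁺ is
    consumed (appears among the reactants) and negative when produced.  The
    magnitude is the quantity usually quoted when comparing the pH footprint
    of DNRA and denitrification.
    """
    no3 = rxn.reactant_coeffs.get("NO3-")
    if no3 is None:
        raise ValueError("reaction has no NO3- reactant")
    if "H+" in rxn.reactant_coeffs:
        signed = rxn.reactant_coeffs["H+"] / no3
    elif "H+" in rxn.product_coeffs:
        signed = -rxn.product_coeffs["H+"] / no3
    else:
        signed = Fraction(0)
    return signed, abs(signed)


def nitrate_per_donor(rxn: BalancedReaction) -> Fraction:
    """NO₃⁻ demand per mole of the donor the reaction is normalised to."""
    no3 = rxn.reactant_coeffs.get("NO3-")
    if no3 is None:
        raise ValueError("reaction has no NO3- reactant")
    return no3 / rxn.reactant_coeffs[rxn.normalization]


# The donor/acceptor couples behind the reference reaction set: sulfide or
# stored S0 oxidised to S0 or sulfate, nitrate reduced by denitrification or
# DNRA, plus aerobic S0 oxidation.
REFERENCE_COUPLES: Dict[str, RedoxCouple] = {
    "S0:SO4^2-": couple("S0", "SO4^2-"),
    "HS-:S0": couple("HS-", "S0"),
    "HS-:SO4^2-": couple("HS-", "SO4^2-"),
    "NO3-:N2": couple("NO3-", "N2"),
    "NO3-:NH4+": couple("NO3-", "NH4+"),
    "O2:H2O": couple("O2", "H2O"),
}
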