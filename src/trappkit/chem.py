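"""Monoisotopic mass arithmetic for nucleotides and 4-thiouridine photo-adducts.

UVA crosslinking of 4-thiouridine (4tU)-containing RNA to protein, followed by
nuclease P1 digestion, leaves short RNA adducts (nucleoside 5'-monophosphates,
up to trinucleotides) covalently attached to peptides.  During collision-induced
dissociation the adduct partially fragments, so peptide fragment ions can retain
a characteristic set of 4tU-derived "stub" masses.  This module derives every
such mass from molecular formulas and a central atomic-mass table, so the
chemistry itself is testable, and enumerates the targeted adduct search space
(multisets of 1-3 nucleotides containing at least one 4tU, combined with a
neutral modification such as phosphate gain or H2S loss).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "MolecularFormula",
    "NucleotideSpec",
    "RnaAdduct",
    "FragmentRetentionMass",
    "NUCLEOTIDES",
    "NEUTRAL_MODIFICATIONS",
    "monoisotopic_mass",
    "retention_fragment_set",
    "adduct_precursor_mass",
    "make_adduct",
    "enumerate_targeted_adducts",
    "write_adduct_table",
    "read_adduct_table",
]

# Monoisotopic atomic masses (Da), CODATA/NIST values.  Kept central so every
# printed mass in the package is a derived artifact, never an inline literal.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

PROTON_MASS = 1.00727646688  # mass of H+ (Da)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition: element symbol -> non-negative count."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def parse(cls, formula: str) -> "MolecularFormula":
        """Parse Hill-style notation, e.g. ``C4H4N2OS``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"unparseable formula {formula!r} at offset {pos}")
            pos = match.end()
            symbol = match.group(1)
            n = int(match.group(2)) if match.group(2) else 1
            counts[symbol] = counts.get(symbol, 0) + n
        if pos != len(formula):
            raise ValueError(f"unparseable formula {formula!r} at offset {pos}")
        return cls.from_dict(counts)

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "MolecularFormula":
        for symbol, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {symbol}")
        items = tuple(sorted((s, n) for s, n in counts.items() if n > 0))
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = self.as_dict()
        for symbol, n in other.counts:
            out[symbol] = out.get(symbol, 0) + n
        return MolecularFormula.from_dict(out)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = self.as_dict()
        for symbol, n in other.counts:
            remaining = out.get(symbol, 0) - n
            if remaining < 0:
                raise ValueError(
                    f"subtraction would leave {remaining} atoms of {symbol}"
                )
            out[symbol] = remaining
        return MolecularFormula.from_dict(out)

    def __mul__(self, k: int) -> "MolecularFormula":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return MolecularFormula.from_dict({s: n * k for s, n in self.counts})

    def __str__(self) -> str:
        return "".join(f"{s}{n if n != 1 else ''}" for s, n in self.counts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Monoisotopic mass (Da) of a molecular formula.

    Raises ``KeyError`` naming the symbol for elements absent from the table.
    """
    total = 0.0
    for symbol, n in formula.counts:
        if symbol not in ELEMENT_MASSES:
            raise KeyError(f"unknown element symbol: {symbol!r}")
        total += n * ELEMENT_MASSES[symbol]
    return total


F = MolecularFormula.parse

WATER = F("H2O")
H2S = F("H2S")
HPO3 = F("HPO3")
NH3 = F("NH3")


@dataclass(frozen=True)
class NucleotideSpec:
    """A ribonucleotide: free nucleoside 5'-monophosphate and base fragment."""

    code: str
    monophosphate: MolecularFormula
    base: MolecularFormula


# Free-acid nucleoside 5'-monophosphates (the products of nuclease P1) and the
# corresponding nucleobase fragments.  4tU is uridine with O4 replaced by S.
NUCLEOTIDES: dict[str, NucleotideSpec] = {
    "A": NucleotideSpec("A", F("C10H14N5O7P"), F("C5H5N5")),
    "C": NucleotideSpec("C", F("C9H14N3O8P"), F("C4H5N3O")),
    "G": NucleotideSpec("G", F("C10H14N5O8P"), F("C5H5N5O")),
    "U": NucleotideSpec("U", F("C9H13N2O9P"), F("C4H4N2O2")),
    "4tU": NucleotideSpec(
        "4tU", F("C9H13N2O9P") - F("O") + F("S"), F("C4H4N2O2") - F("O") + F("S")
    ),
}

# Neutral modification of the whole adduct: (formulas added, formulas removed).
NEUTRAL_MODIFICATIONS: dict[str, tuple[tuple[MolecularFormula, ...], tuple[MolecularFormula, ...]]] = {
    "none": ((), ()),
    "-H2S": ((), (H2S,)),
    "-HPO3": ((), (HPO3,)),
    "-HPO3-H2S": ((), (HPO3, H2S)),
    "+HPO3": ((HPO3,), ()),
    "+HPO3-H2S": ((HPO3,), (H2S,)),
}


@dataclass(frozen=True)
class RnaAdduct:
    """An RNA adduct left on a crosslinked peptide after nuclease digestion.

    ``composition`` is a sorted multiset of base codes (size 1-3, at least one
    4tU — the photoreactive residue the crosslink forms through);
    ``modification`` is one of the neutral states in ``NEUTRAL_MODIFICATIONS``.
    """

    composition: tuple[str, ...]
    modification: str
    precursor_mass: float
    label: str
    stub_masses: tuple[float, ...] = field(default=())

    def __post_init__(self):
        if not (1 <= len(self.composition) <= 3):
            raise ValueError("adduct composition must have 1-3 nucleotides")
        if "4tU" not in self.composition:
            raise ValueError("adduct composition must contain at least one 4tU")


def _adduct_formula(composition: tuple[str, ...], modification: str) -> MolecularFormula:
    if not (1 <= len(composition) <= 3):
        raise ValueError("composition must have 1-3 nucleotides")
    if "4tU" not in composition:
        raise ValueError("composition must contain at least one 4tU")
    total = MolecularFormula.from_dict({})
    for code in composition:
        try:
            total = total + NUCLEOTIDES[code].monophosphate
        except KeyError:
            raise ValueError(f"unknown base code {code!r}") from None
    # phosphodiester condensation: an n-mer loses n-1 waters
    total = total - WATER * (len(composition) - 1)
    added, removed = NEUTRAL_MODIFICATIONS[modification]
    for f in added:
        total = total + f
    for f in removed:
        total = total - f
    return total


def adduct_precursor_mass(adduct: RnaAdduct) -> float:
    """Neutral precursor mass delta (Da) the adduct adds to a peptide."""
    return monoisotopic_mass(_adduct_formula(adduct.composition, adduct.modification))


def make_adduct(composition: tuple[str, ...] | list[str], modification: str = "none") -> RnaAdduct:
    """Build an :class:`RnaAdduct` with its precursor mass and stub set computed."""
    comp = tuple(sorted(composition))
    mass = monoisotopic_mass(_adduct_formula(comp, modification))
    label = "+".join(comp) + ("" if modification == "none" else f" {modification}")
    stubs = tuple(f.mass for f in retention_fragment_set())
    return RnaAdduct(comp, modification, mass, label, stubs)


@dataclass(frozen=True)
class FragmentRetentionMass:
    """A 4tU-derived stub mass allowed to remain on peptide fragment ions."""

    label: str
    mass: float


def retention_fragment_set() -> list[FragmentRetentionMass]:
    """The eight 4tU-derived masses retained on fragment ions after CID.

    Crosslinked nucleotides behave as cleavable molecules in the gas phase:
    the adduct can be lost entirely, or a 4tU-derived remnant (base, base-H2S,
    or the monophosphate under the six neutral states) stays attached.  Every
    mass is recomputed from formulas here.
    """
    tu = NUCLEOTIDES["4tU"]
    specs: list[tuple[str, MolecularFormula]] = [
        ("4tU base", tu.base),
        ("4tU base-H2S", tu.base - H2S),
        ("4tUMP-HPO3-H2S", tu.monophosphate - HPO3 - H2S),
        ("4tUMP-H2S", tu.monophosphate - H2S),
        ("4tUMP", tu.monophosphate),
        ("4tUMP-HPO3", tu.monophosphate - HPO3),
        ("4tUMP+HPO3-H2S", tu.monophosphate + HPO3 - H2S),
        ("4tUMP+HPO3", tu.monophosphate + HPO3),
    ]
    return [FragmentRetentionMass(label, monoisotopic_mass(f)) for label, f in specs]


def enumerate_targeted_adducts(
    max_len: int = 3,
    alphabet: tuple[str, ...] = ("A", "C", "G", "U", "4tU"),
    modifications: tuple[str, ...] = tuple(NEUTRAL_MODIFICATIONS),
) -> list[RnaAdduct]:
    """Enumerate the targeted adduct search space.

    All multisets of size 1..max_len over ``alphabet`` containing at least one
    4tU, crossed with ``modifications``.  This is the "up to trinucleotide RNA
    where at least one residue is 4tU" targeted list.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if "4tU" not in alphabet:
        raise ValueError("alphabet must contain 4tU")
    seen: set[tuple[tuple[str, ...], str]] = set()
    out: list[RnaAdduct] = []
    for k in range(1, max_len + 1):
        for combo in itertools.combinations_with_replacement(sorted(alphabet), k):
            if "4tU" not in combo:
                continue
            for mod in modifications:
                key = (combo, mod)
                if key in seen:
                    continue
                seen.add(key)
                out.append(make_adduct(combo, mod))
    return out


def write_adduct_table(adducts: list[RnaAdduct], path) -> None:
    """Write adducts as a tab-separated table."""
    with open(path, "w") as fh:
        fh.write("label\tcomposition\tmodification\tprecursor_mass_da\tretained_stub_masses\n")
        for a in adducts:
            stubs = ";".join(f"{m:.6f}" for m in a.stub_masses)
            fh.write(
                f"{a.label}\t{','.join(a.composition)}\t{a.modification}\t"
                f"{a.precursor_mass:.6f}\t{stubs}\n"
            )


def read_adduct_table(path) -> list[RnaAdduct]:
    adducts = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["label", "composition", "modification", "precursor_mass_da", "retained_stub_masses"]
        if header != expected:
            raise ValueError(f"unexpected adduct table header: {header}")
        for line in fh:
            label, comp, mod, mass, stubs = line.rstrip("\n").split("\t")
            adducts.append(
                RnaAdduct(
                    tuple(comp.split(",")),
                    mod,
                    float(mass),
                    label,
                    tuple(float(x) for x in stubs.split(";")) if stubs else (),
                )
            )
    return adducts
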