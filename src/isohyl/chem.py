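"""Elemental-composition arithmetic and the isomer-selective reaction model.

Lysine 5-hydroxylation (5-Hyl) places a hydroxyl on the delta carbon of the
lysine side chain, adjacent to the epsilon amine.  That 1,2-aminoalcohol is
cleaved by periodate between the OH- and NH2-bearing carbons, releasing
methanimine (net loss CH5N) and leaving an aldehyde.  The aldehyde condenses
with methoxyamine to an oxime ether (net gain CH5NO - H2O) or with biotin
hydrazide to a hydrazone.  The 4- and 3-hydroxy constitutional isomers lack
the vicinal amine/hydroxyl pair and are inert to periodate, which is what
makes the chemistry isomer selective.

All mass bookkeeping in the package goes through :class:`ElementalComposition`
and the fixed monoisotopic element table below.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "PROTON_MASS",
    "WATER",
    "ElementalComposition",
    "ModificationDef",
    "SmallMoleculeSpecies",
    "monoisotopic_mass",
    "mz",
    "parse_formula",
    "builtin_registry",
    "builtin_small_molecules",
    "periodate_transform",
    "conjugate_transform",
    "CONJUGATION_REAGENTS",
]

# Monoisotopic element masses (Da).  D is deuterium, listed as its own
# symbol because heavy-methoxyamine conjugates mix H and D explicitly.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.0078250319,
    "D": 2.0141017780,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Se": 79.9165218,
}

PROTON_MASS = 1.00727646688

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class UnknownElementError(ValueError):
    """Raised for an element symbol absent from the mass table."""


class ChemistryError(ValueError):
    """Raised when a transform is applied to an incompatible species."""


@dataclass(frozen=True)
class ElementalComposition:
    """A signed element-count map; the unit of all mass arithmetic.

    Negative counts are legal and represent deltas (e.g. the periodate
    cleavage is ``C-1 H-5 N-1``).  Zero counts are dropped on construction
    so equality and hashing are canonical.
    """

    counts: tuple[tuple[str, int], ...] = ()

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        items = dict(counts)
        for el, n in items.items():
            if not isinstance(n, int):
                raise TypeError(f"count for {el} must be an integer, got {n!r}")
        clean = tuple(sorted((el, n) for el, n in items.items() if n != 0))
        object.__setattr__(self, "counts", clean)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = self.as_dict()
        for el, n in other.counts:
            out[el] = out.get(el, 0) + n
        return ElementalComposition(out)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = self.as_dict()
        for el, n in other.counts:
            out[el] = out.get(el, 0) - n
        return ElementalComposition(out)

    def __neg__(self) -> "ElementalComposition":
        return ElementalComposition({el: -n for el, n in self.counts})

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def formula(self) -> str:
        """Render as a signed formula string, e.g. ``'C-1 H-5 N-1'``."""
        order = {"C": 0, "H": 1, "D": 2}
        parts = sorted(self.counts, key=lambda t: (order.get(t[0], 3), t[0]))
        return " ".join(f"{el}{n}" for el, n in parts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ElementalComposition({self.formula() or '∅'})"


def parse_formula(text: str) -> ElementalComposition:
    """Parse a formula string with optional signed counts.

    Accepts compact formulas (``"CH5NO"``) and space-separated signed
    forms (``"C-1 H-5 N-1 O1"``).  An omitted count means 1.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text.replace(" ", "")):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in ELEMENT_MASSES:
            raise UnknownElementError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(text.replace(" ", "")):
        raise ValueError(f"trailing junk in formula {text!r}")
    return ElementalComposition(counts)


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass in Da; negative for net-loss deltas."""
    total = 0.0
    for el, n in comp.counts:
        try:
            total += n * ELEMENT_MASSES[el]
        except KeyError:
            raise UnknownElementError(f"unknown element symbol {el!r}") from None
    return total


def mz(mass: float, charge: int) -> float:
    """m/z of a protonated species: ``(mass + z*proton)/z``.

    Positive-mode protonation is the only charge carrier modelled.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


WATER = parse_formula("H2O")

# Conjugation reagents: oxime formation for the methoxyamines, hydrazone
# for biotin hydrazide.  Net delta on the aldehyde is reagent - H2O.
CONJUGATION_REAGENTS: dict[str, ElementalComposition] = {
    "methoxyamine": parse_formula("CH5NO"),
    "d3_methoxyamine": parse_formula("CH2D3NO"),
    "biotin_hydrazide": parse_formula("C10H18N4O2S"),
}

PERIODATE_DELTA = -parse_formula("CH5N")  # aldehyde formation, methanimine loss


@dataclass(frozen=True)
class ModificationDef:
    """A residue modification: mass delta plus neutral-loss signatures.

    ``delta`` is relative to the unmodified residue.  ``neutral_losses``
    are compositions lost in the gas phase from modified fragment/precursor
    ions (the CH5NO loss is the diagnostic signature of the
    methoxyamine-conjugated oxidized 5-Hyl adduct).
    """

    name: str
    targets: frozenset[str]  # residue letters, or {"protein-N-term"}
    delta: ElementalComposition
    neutral_losses: tuple[ElementalComposition, ...] = ()
    fixed: bool = False
    blocks_cleavage: bool = False

    @property
    def delta_mass(self) -> float:
        return self.delta.mass


def _mod(name, targets, delta, nl=(), fixed=False, blocks=False) -> ModificationDef:
    return ModificationDef(
        name=name,
        targets=frozenset(targets),
        delta=parse_formula(delta),
        neutral_losses=tuple(parse_formula(x) for x in nl),
        fixed=fixed,
        blocks_cleavage=blocks,
    )


def builtin_registry() -> dict[str, ModificationDef]:
    """The built-in modification registry.

    ``hyl5`` is the in-vivo hydroxyl (+O); ``hyl5_ox`` its periodate
    aldehyde; ``hyl5_ox_moa`` the methoxyamine oxime, whose net delta
    relative to unmodified K collapses to +O -2H — the single composite
    modification used for database searching.
    """
    mods = [
        _mod("hyl5", "K", "O", blocks=True),
        _mod("hyl5_ox", "K", "C-1 H-5 N-1 O1", blocks=True),
        _mod("hyl5_ox_moa", "K", "O1 H-2", nl=["CH5NO"], blocks=True),
        _mod("hyl5_ox_moa_d3", "K", "O1 H-5 D3", nl=["CH2D3NO"], blocks=True),
        # same two-step algebra as the oxime: +O - CH5N + (reagent - H2O)
        _mod("hyl5_ox_biotinhz", "K", "C9 H11 N3 O2 S1", blocks=True),
        _mod("oglcnac_ox_moa", "ST", "C10H17N3O10", nl=["C10H17N3O10"]),
        _mod("hyp", "P", "O"),
        _mod("acK", "K", "C2H2O", blocks=True),
        _mod("metox", "M", "O"),
        _mod("camC", "C", "C2H3NO", fixed=True),
        _mod("nterm_acetyl", ["protein-N-term"], "C2H2O"),
    ]
    registry = {m.name: m for m in mods}
    assert len(registry) == len(mods), "duplicate modification names"
    return registry


# Maps the 5-Hyl family through the reaction stages.
_OXIDATION_STEP = {"hyl5": "hyl5_ox"}
_CONJUGATION_STEP = {
    "methoxyamine": {"hyl5_ox": "hyl5_ox_moa"},
    "d3_methoxyamine": {"hyl5_ox": "hyl5_ox_moa_d3"},
    "biotin_hydrazide": {"hyl5_ox": "hyl5_ox_biotinhz"},
}


@dataclass(frozen=True)
class SmallMoleculeSpecies:
    """A small molecule with an explicit 1,2-aminoalcohol motif flag.

    The motif flag is structural knowledge, not inferred from the formula:
    the three aminopentanol constitutional isomers share C5H13NO but only
    the 1-amino-2-ol (the 5-Hyl side-chain analog) carries the reactive
    vicinal amine/hydroxyl pair.
    """

    name: str
    composition: ElementalComposition
    has_12_aminoalcohol: bool = False
    is_aldehyde: bool = False

    def __post_init__(self):
        if self.composition.mass <= 0:
            raise ValueError(f"{self.name}: composition mass must be positive")

    @property
    def mass(self) -> float:
        return self.composition.mass

    def mh(self) -> float:
        """[M+H]+ m/z."""
        return mz(self.mass, 1)


def builtin_small_molecules() -> dict[str, SmallMoleculeSpecies]:
    """Side-chain analogs of the three hydroxylysine constitutional isomers."""
    c5 = parse_formula("C5H13NO")
    return {
        "1-aminopentan-2-ol": SmallMoleculeSpecies(
            "1-aminopentan-2-ol", c5, has_12_aminoalcohol=True
        ),
        "1-aminopentan-3-ol": SmallMoleculeSpecies("1-aminopentan-3-ol", c5),
        "5-amino-2-pentanol": SmallMoleculeSpecies("5-amino-2-pentanol", c5),
    }


def periodate_transform(species):
    """Apply periodate oxidation; identity on non-reactive isomers.

    Small molecules react iff they carry the 1,2-aminoalcohol motif,
    losing CH5N and gaining an aldehyde.  Peptides react at every hyl5
    position (replaced by hyl5_ox).  A peptide already carrying hyl5_ox
    raises, since the aldehyde cannot be oxidized again by this chemistry.
    """
    from . import peptides  # local import to avoid a cycle

    if isinstance(species, SmallMoleculeSpecies):
        if not species.has_12_aminoalcohol:
            return species  # non-reactive isomer, returned unchanged
        return replace(
            species,
            composition=species.composition + PERIODATE_DELTA,
            has_12_aminoalcohol=False,
            is_aldehyde=True,
        )
    if isinstance(species, peptides.ModifiedPeptide):
        if any(name in ("hyl5_ox",) for _, name in species.mods):
            raise ChemistryError("peptide already periodate-oxidized")
        new_mods = tuple(
            (pos, _OXIDATION_STEP.get(name, name)) for pos, name in species.mods
        )
        if new_mods == species.mods:
            return species  # no hyl5 present: nothing to oxidize
        return replace(species, mods=new_mods)
    raise TypeError(f"cannot oxidize {type(species).__name__}")


def conjugate_transform(species, reagent: str = "methoxyamine"):
    """Condense an aldehyde species with an amine/hydrazide reagent.

    Net delta is reagent − H2O (oxime or hydrazone formation with loss of
    water).  Raises on species that do not carry an aldehyde.
    """
    from . import peptides

    if reagent not in CONJUGATION_REAGENTS:
        raise ValueError(
            f"unknown reagent {reagent!r}; choose from {sorted(CONJUGATION_REAGENTS)}"
        )
    delta = CONJUGATION_REAGENTS[reagent] - WATER
    if isinstance(species, SmallMoleculeSpecies):
        if not species.is_aldehyde:
            raise ChemistryError(f"{species.name} carries no aldehyde to conjugate")
        return replace(
            species, composition=species.composition + delta, is_aldehyde=False
        )
    if isinstance(species, peptides.ModifiedPeptide):
        step = _CONJUGATION_STEP[reagent]
        new_mods = tuple((pos, step.get(name, name)) for pos, name in species.mods)
        if new_mods == species.mods:
            raise ChemistryError("peptide carries no oxidized 5-Hyl to conjugate")
        return replace(species, mods=new_mods)
    raise TypeError(f"cannot conjugate {type(species).__name__}")


def registry_to_dict(registry: Mapping[str, ModificationDef]) -> dict:
    """Serializable view of a registry (formula strings, sorted names)."""
    return {
        name: {
            "targets": sorted(m.targets),
            "delta": m.delta.formula(),
            "neutral_losses": [nl.formula() for nl in m.neutral_losses],
            "fixed": m.fixed,
            "blocks_cleavage": m.blocks_cleavage,
        }
        for name, m in sorted(registry.items())
    }


def registry_from_dict(data: Mapping[str, Mapping]) -> dict[str, ModificationDef]:
    """Inverse of :func:`registry_to_dict`."""
    out: dict[str, ModificationDef] = {}
    for name, spec in data.items():
        out[name] = ModificationDef(
            name=name,
            targets=frozenset(spec["targets"]),
            delta=parse_formula(spec["delta"]),
            neutral_losses=tuple(
                parse_formula(x) for x in spec.get("neutral_losses", [])
            ),
            fixed=bool(spec.get("fixed", False)),
            blocks_cleavage=bool(spec.get("blocks_cleavage", False)),
        )
    return out
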