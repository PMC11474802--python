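"""Modified peptides, tryptic digestion and precursor/fragment masses."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from Bio import SeqIO

from .chem import (
    PROTON_MASS,
    WATER,
    ModificationDef,
    builtin_registry,
    monoisotopic_mass,
    mz,
    parse_formula,
)

__all__ = [
    "RESIDUE_MASSES",
    "ModifiedPeptide",
    "DigestionParams",
    "digest",
    "peptide_mass",
    "fragment_ions",
    "FragmentIon",
    "parse_peptide",
    "format_peptide",
    "read_fasta",
]

# Monoisotopic residue masses of the 20 canonical amino acids (Da).
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711378,
    "S": 87.03202840,
    "P": 97.05276384,
    "V": 99.06841390,
    "T": 101.04767846,
    "C": 103.00918447,
    "L": 113.08406396,
    "I": 113.08406396,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857750,
    "K": 128.09496301,
    "E": 129.04259308,
    "M": 131.04048508,
    "H": 137.05891185,
    "F": 147.06841390,
    "R": 156.10111102,
    "Y": 163.06332852,
    "W": 186.07931294,
}

WATER_MASS = monoisotopic_mass(WATER)

_DEFAULT_REGISTRY = builtin_registry()


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications and optional charge.

    Positions are 1-based; ``"N-term"`` addresses the protein N-terminus.
    ``protein``/``start`` record where the peptide came from when it was
    produced by a digest, so site tables can map back to protein coordinates.
    """

    sequence: str
    mods: tuple[tuple[object, str], ...] = ()
    charge: Optional[int] = None
    protein: Optional[str] = None
    start: Optional[int] = None  # 1-based position in the parent protein

    def __post_init__(self):
        if not self.sequence or not all(r in RESIDUE_MASSES for r in self.sequence):
            bad = [r for r in self.sequence if r not in RESIDUE_MASSES]
            raise ValueError(f"invalid residues {bad!r} in {self.sequence!r}")
        object.__setattr__(self, "mods", tuple(self.mods))
        seen = set()
        for pos, name in self.mods:
            mod = _DEFAULT_REGISTRY.get(name)
            if pos == "N-term":
                if mod is not None and "protein-N-term" not in mod.targets:
                    raise ValueError(f"{name} does not target the protein N-terminus")
            else:
                if not (1 <= pos <= len(self.sequence)):
                    raise ValueError(f"mod position {pos} outside 1..{len(self.sequence)}")
                if mod is not None and self.sequence[pos - 1] not in mod.targets:
                    raise ValueError(
                        f"{name} targets {sorted(mod.targets)}, not "
                        f"{self.sequence[pos - 1]} at position {pos}"
                    )
            if pos in seen:
                raise ValueError(f"two modifications at position {pos}")
            seen.add(pos)
        if self.charge is not None and self.charge < 1:
            raise ValueError("charge must be >= 1")

    def mod_at(self, pos) -> Optional[str]:
        for p, name in self.mods:
            if p == pos:
                return name
        return None

    @property
    def n_variable_mods(self) -> int:
        return sum(1 for _, name in self.mods if not _DEFAULT_REGISTRY[name].fixed)

    def mass(self, registry: Mapping[str, ModificationDef] | None = None) -> float:
        return peptide_mass(self, registry)

    def mz(self, charge: Optional[int] = None,
           registry: Mapping[str, ModificationDef] | None = None) -> float:
        z = charge if charge is not None else self.charge
        if z is None:
            raise ValueError("charge not set")
        return mz(self.mass(registry), z)


@dataclass(frozen=True)
class DigestionParams:
    """Tryptic digestion settings.

    Six missed cleavages is the working default for 5-Hyl searches: the
    composite modification sits on lysine and suppresses cleavage there, so
    modified peptides necessarily retain internal K sites.
    """

    max_missed_cleavages: int = 6
    min_length: int = 6
    max_length: int = 45
    modified_K_blocks_cleavage: bool = True

    def __post_init__(self):
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length > self.max_length:
            raise ValueError("min_length > max_length")


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1 (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein_sequence: str,
    params: DigestionParams = DigestionParams(),
    blocked_positions: Iterable[int] = (),
) -> list[tuple[int, int, int]]:
    """In-silico tryptic digest.

    Returns ``(start, end, missed)`` triples, 1-based inclusive, with the
    count of missed (uncleaved internal) sites.  ``blocked_positions`` are
    1-based residue positions whose cleavage is suppressed — used for
    modified lysines when ``modified_K_blocks_cleavage`` is on.
    """
    seq = protein_sequence
    if not seq:
        return []
    blocked = set(blocked_positions) if params.modified_K_blocks_cleavage else set()
    sites = [i for i in cleavage_sites(seq) if (i + 1) not in blocked]
    bounds = [0] + [i + 1 for i in sites] + [len(seq)]
    out = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + params.max_missed_cleavages, len(bounds))):
            start, end = bounds[a], bounds[b]
            if params.min_length <= end - start <= params.max_length:
                out.append((start + 1, end, b - a - 1))
    return out


def peptide_mass(
    pep: ModifiedPeptide, registry: Mapping[str, ModificationDef] | None = None
) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    reg = registry or _DEFAULT_REGISTRY
    total = WATER_MASS + sum(RESIDUE_MASSES[r] for r in pep.sequence)
    for _, name in pep.mods:
        total += reg[name].delta_mass
    return total


@dataclass(frozen=True)
class FragmentIon:
    label: str  # e.g. "b3", "y7(2+)"
    series: str  # "b" or "y"
    index: int  # ordinal within the series
    charge: int
    mz: float
    contains_modified_site: bool


def fragment_ions(
    pep: ModifiedPeptide,
    series: Iterable[str] = ("b", "y"),
    max_fragment_charge: int = 1,
    registry: Mapping[str, ModificationDef] | None = None,
) -> list[FragmentIon]:
    """Standard b/y fragment ladder with modification deltas.

    Each ion is flagged when its residue span covers a modified position;
    the flag drives diagnostic neutral-loss generation downstream.
    """
    reg = registry or _DEFAULT_REGISTRY
    series = tuple(series)
    if not series:
        raise ValueError("series must be non-empty")
    n = len(pep.sequence)
    # cumulative residue+mod masses from the N-terminus
    prefix = [0.0]
    for i, r in enumerate(pep.sequence, start=1):
        m = RESIDUE_MASSES[r]
        name = pep.mod_at(i)
        if name:
            m += reg[name].delta_mass
        prefix.append(prefix[-1] + m)
    nterm_extra = 0.0
    if pep.mod_at("N-term"):
        nterm_extra = reg[pep.mod_at("N-term")].delta_mass
    mod_positions = sorted(p for p, _ in pep.mods if p != "N-term")

    out: list[FragmentIon] = []
    for i in range(1, n):  # split after residue i
        b_neutral = prefix[i] + nterm_extra
        y_neutral = prefix[n] - prefix[i] + WATER_MASS
        b_modded = bool(pep.mod_at("N-term")) or any(p <= i for p in mod_positions)
        y_modded = any(p > i for p in mod_positions)
        for z in range(1, max_fragment_charge + 1):
            if "b" in series:
                out.append(
                    FragmentIon(
                        label=f"b{i}" + (f"({z}+)" if z > 1 else ""),
                        series="b", index=i, charge=z,
                        mz=(b_neutral + z * PROTON_MASS) / z,
                        contains_modified_site=b_modded,
                    )
                )
            if "y" in series:
                out.append(
                    FragmentIon(
                        label=f"y{n - i}" + (f"({z}+)" if z > 1 else ""),
                        series="y", index=n - i, charge=z,
                        mz=(y_neutral + z * PROTON_MASS) / z,
                        contains_modified_site=y_modded,
                    )
                )
    return out


# Bracketed mod notation: GFPGTPGLPGFK[hyl5]GIR, optional [mod]- N-term prefix.
_PEP_TOKEN = re.compile(r"([A-Z])(?:\[([A-Za-z0-9_]+)\])?")
_NTERM_PREFIX = re.compile(r"^\[([A-Za-z0-9_]+)\]-")


def parse_peptide(text: str, charge: Optional[int] = None) -> ModifiedPeptide:
    """Parse bracketed peptide notation; inverse of :func:`format_peptide`."""
    mods: list[tuple[object, str]] = []
    m = _NTERM_PREFIX.match(text)
    if m:
        mods.append(("N-term", m.group(1)))
        text = text[m.end():]
    seq_chars: list[str] = []
    pos = 0
    for tok in _PEP_TOKEN.finditer(text):
        if tok.start() != pos:
            raise ValueError(f"cannot parse peptide notation at {text[pos:]!r}")
        pos = tok.end()
        seq_chars.append(tok.group(1))
        if tok.group(2):
            mods.append((len(seq_chars), tok.group(2)))
    if pos != len(text):
        raise ValueError(f"trailing junk in peptide notation {text!r}")
    return ModifiedPeptide("".join(seq_chars), tuple(mods), charge=charge)


def format_peptide(pep: ModifiedPeptide) -> str:
    out = []
    nterm = pep.mod_at("N-term")
    if nterm:
        out.append(f"[{nterm}]-")
    for i, r in enumerate(pep.sequence, start=1):
        out.append(r)
        name = pep.mod_at(i)
        if name:
            out.append(f"[{name}]")
    return "".join(out)


_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|(\S+)")
_GENE_FIELD = re.compile(r"\bGN=(\S+)")


def read_fasta(path) -> dict[str, dict]:
    """Read a protein FASTA into {accession: {sequence, description, gene}}.

    UniProt-style ``sp|ACC|NAME ... GN=gene`` headers are parsed; plain
    headers use the first whitespace-delimited token as the accession.
    """
    out: dict[str, dict] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        m = _UNIPROT_HEADER.match(header)
        acc = m.group(1) if m else rec.id
        g = _GENE_FIELD.search(header)
        out[acc] = {
            "sequence": str(rec.seq).upper(),
            "description": header,
            "gene": g.group(1) if g else None,
        }
    return out
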