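"""Moiety-count abstraction of molecules and reactions.

A *moiety* is a classification of a single non-hydrogen atom by its first
bonding shell: the central element, its formal charge, its attached hydrogen
count, and the multiset of (bond order, neighbor element, neighbor formal
charge) over its heavy neighbors.  A molecule becomes a sparse vector of
moiety counts; a reaction becomes the signed difference of the product and
substrate vectors (the target vector T° that any valid mechanism must sum
to).  Stereochemistry is stripped on ingestion, so molecules are compared as
constitutional isomers.
"""

from __future__ import annotations

import re
from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from typing import Iterator, Optional

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoietyId",
    "MoietyVector",
    "Molecule",
    "BalanceReport",
    "atom_environment",
    "moiety_counts",
    "reaction_delta",
    "check_balance",
    "parse_reaction_smiles",
]


class MoietyError(ValueError):
    """Raised for invalid moiety/molecule operations."""


_BOND_CHAR = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}

# El{+charge}H{n}(comma-joined neighbor descriptors); used by the
# protonation-rule validator to read charge and hydrogen count back out.
_KEY_RE = re.compile(r"^([A-Z][a-z]?|\*)([+-]\d+)H(\d+)\((.*)\)$")

_LABEL_SEP = "::"


@dataclass(frozen=True, order=True)
class MoietyId:
    """Canonical identifier of one heavy atom's first-shell environment.

    ``environment_key`` is canonical by construction: neighbor descriptors
    are sorted, so chemically identical environments map to the same key
    regardless of atom ordering in the input.  ``labeled`` marks membership
    in the catalytic set M* (residues/cofactors); labeled ids carry a
    non-empty ``label_tag`` namespace.
    """

    environment_key: str
    labeled: bool = False
    label_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.labeled and not self.label_tag:
            raise MoietyError("labeled MoietyId requires a non-empty label_tag")
        if not self.labeled and self.label_tag:
            object.__setattr__(self, "labeled", True)

    def serialize(self) -> str:
        if self.labeled:
            return f"{self.label_tag}{_LABEL_SEP}{self.environment_key}"
        return self.environment_key

    @classmethod
    def parse(cls, text: str) -> "MoietyId":
        if _LABEL_SEP in text:
            tag, key = text.split(_LABEL_SEP, 1)
            return cls(environment_key=key, labeled=True, label_tag=tag)
        return cls(environment_key=text)

    def key_fields(self) -> Optional[tuple[str, int, int, str]]:
        """(element, formal charge, H count, neighbor field) if the key is
        a chemical environment key; None for abstract/opaque keys."""
        m = _KEY_RE.match(self.environment_key)
        if m is None:
            return None
        return m.group(1), int(m.group(2)), int(m.group(3)), m.group(4)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


class MoietyVector(Mapping):
    """Sparse signed integer counts over :class:`MoietyId`.

    Represents molecules (counts >= 0), rule deltas (columns of the rule
    matrix T) and reaction targets T°.  Zero entries are never stored;
    addition and subtraction are component-wise.
    """

    __slots__ = ("_data",)

    def __init__(self, entries: Optional[Mapping[MoietyId, int]] = None):
        data: dict[MoietyId, int] = {}
        if entries:
            for k, v in entries.items():
                if not isinstance(k, MoietyId):
                    raise MoietyError(f"keys must be MoietyId, got {type(k)!r}")
                iv = int(v)
                if iv != v:
                    raise MoietyError("moiety counts must be integers")
                if iv != 0:
                    data[k] = iv
        self._data = data

    # Mapping protocol ----------------------------------------------------
    def __getitem__(self, key: MoietyId) -> int:
        return self._data.get(key, 0)

    def __iter__(self) -> Iterator[MoietyId]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, key: object) -> bool:
        return key in self._data

    # arithmetic -----------------------------------------------------------
    def __add__(self, other: "MoietyVector") -> "MoietyVector":
        out = dict(self._data)
        for k, v in other._data.items():
            out[k] = out.get(k, 0) + v
        return MoietyVector(out)

    def __sub__(self, other: "MoietyVector") -> "MoietyVector":
        out = dict(self._data)
        for k, v in other._data.items():
            out[k] = out.get(k, 0) - v
        return MoietyVector(out)

    def __neg__(self) -> "MoietyVector":
        return MoietyVector({k: -v for k, v in self._data.items()})

    def __mul__(self, coeff: int) -> "MoietyVector":
        return MoietyVector({k: v * int(coeff) for k, v in self._data.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, MoietyVector):
            return self._data == other._data
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._data.items()))

    def __bool__(self) -> bool:
        return bool(self._data)

    def __repr__(self) -> str:
        items = ", ".join(
            f"{k.serialize()}: {v:+d}" for k, v in sorted(self._data.items())
        )
        return f"MoietyVector({{{items}}})"

    # helpers ---------------------------------------------------------------
    @property
    def support(self) -> frozenset[MoietyId]:
        return frozenset(self._data)

    def is_nonnegative(self) -> bool:
        return all(v >= 0 for v in self._data.values())

    def restrict(self, keys: Iterable[MoietyId]) -> "MoietyVector":
        keep = set(keys)
        return MoietyVector({k: v for k, v in self._data.items() if k in keep})

    def without(self, keys: Iterable[MoietyId]) -> "MoietyVector":
        drop = set(keys)
        return MoietyVector({k: v for k, v in self._data.items() if k not in drop})

    def total(self) -> int:
        return sum(self._data.values())

    def signature(self) -> tuple[tuple[str, int], ...]:
        """Canonical hashable form (sorted serialized key, count)."""
        return tuple(sorted((k.serialize(), v) for k, v in self._data.items()))

    def to_text(self) -> str:
        """Tab-delimited ``moiety_key<TAB>count`` serialization."""
        return "\n".join(f"{k}\t{v}" for k, v in sorted(self.signature()))

    @classmethod
    def from_text(cls, text: str) -> "MoietyVector":
        entries: dict[MoietyId, int] = {}
        for ln, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line:
                continue
            try:
                key, count = line.split("\t")
                entries[MoietyId.parse(key)] = int(count)
            except ValueError as exc:
                raise MoietyError(f"malformed vector row at line {ln}: {line!r}") from exc
        return cls(entries)


ZERO = MoietyVector()


@dataclass(frozen=True)
class Molecule:
    """A parsed molecule: the RDKit graph, net charge and element counts.

    Stereochemical annotations are dropped at parse time, so two
    enantiomeric SMILES yield the same :class:`Molecule`.  Equality and
    hashing go through the canonical (stereo-free) SMILES.
    """

    smiles: str
    mol: Chem.Mol = field(compare=False, hash=False, repr=False)

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise MoietyError(f"could not parse SMILES: {smiles!r}")
        Chem.RemoveStereochemistry(mol)
        canonical = Chem.MolToSmiles(mol)
        return cls(smiles=canonical, mol=mol)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Molecule):
            return self.smiles == other.smiles
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.smiles)

    @property
    def net_charge(self) -> int:
        return Chem.GetFormalCharge(self.mol)

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() != 1)

    @property
    def element_counts(self) -> Counter:
        """Element → count, hydrogens included."""
        counts: Counter = Counter()
        for atom in self.mol.GetAtoms():
            counts[atom.GetSymbol()] += 1
            if atom.GetAtomicNum() != 1:
                counts["H"] += atom.GetTotalNumHs(includeNeighbors=False)
        return counts


def atom_environment(molecule: Molecule, atom_index: int) -> MoietyId:
    """Classify one non-hydrogen atom by its first bonding shell.

    The key is built from (element, formal charge, total attached hydrogens,
    sorted multiset of (bond order, neighbor element, neighbor charge) over
    heavy neighbors) and is therefore order-independent.  Aromatic bonds are
    kept as a distinct bond order (no Kekulé alternation), so resonance-
    equivalent input SMILES produce identical keys.
    """
    mol = molecule.mol
    if atom_index < 0 or atom_index >= mol.GetNumAtoms():
        raise MoietyError(f"atom index {atom_index} out of range")
    atom = mol.GetAtomWithIdx(atom_index)
    if atom.GetAtomicNum() == 1:
        raise MoietyError("hydrogen atoms are not classified as moieties")

    neighbors = []
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetAtomicNum() == 1:
            continue  # explicit H nodes count toward the H tally
        bchar = _BOND_CHAR.get(bond.GetBondType(), f"~{bond.GetBondType()}")
        neighbors.append(f"{bchar}{other.GetSymbol()}{other.GetFormalCharge():+d}")
    key = (
        f"{atom.GetSymbol()}{atom.GetFormalCharge():+d}"
        f"H{atom.GetTotalNumHs(includeNeighbors=True)}"
        f"({','.join(sorted(neighbors))})"
    )
    return MoietyId(environment_key=key)


def moiety_counts(molecule: Molecule, label_tag: Optional[str] = None) -> MoietyVector:
    """Moiety-count vector of a molecule (one count per heavy atom).

    With ``label_tag`` given, every produced id is marked as a labeled
    (catalytic, M*) moiety in that namespace.
    """
    counts: Counter = Counter()
    for atom in molecule.mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        mid = atom_environment(molecule, atom.GetIdx())
        if label_tag:
            mid = MoietyId(mid.environment_key, labeled=True, label_tag=label_tag)
        counts[mid] += 1
    return MoietyVector(counts)


Species = tuple[Molecule, int]


def _validate_side(side: Iterable[Species]) -> list[Species]:
    out = []
    for mol, coeff in side:
        if int(coeff) != coeff or coeff <= 0:
            raise MoietyError(f"stoichiometric coefficients must be positive integers, got {coeff!r}")
        out.append((mol, int(coeff)))
    return out


def reaction_delta(
    substrates: Iterable[Species],
    products: Iterable[Species],
    substrate_labels: Optional[Mapping[Molecule, str]] = None,
    product_labels: Optional[Mapping[Molecule, str]] = None,
) -> MoietyVector:
    """Net moiety change T° = Σ coeff·counts(products) − Σ coeff·counts(substrates).

    Moieties unchanged between both sides cancel exactly.  Optional label
    maps assign a catalytic namespace tag per molecule.
    """
    substrate_labels = substrate_labels or {}
    product_labels = product_labels or {}
    delta = MoietyVector()
    for mol, coeff in _validate_side(products):
        delta = delta + moiety_counts(mol, product_labels.get(mol)) * coeff
    for mol, coeff in _validate_side(substrates):
        delta = delta - moiety_counts(mol, substrate_labels.get(mol)) * coeff
    return delta


@dataclass(frozen=True)
class BalanceReport:
    elementally_balanced: bool
    charge_balanced: bool
    element_deficits: Mapping[str, int]  # products − substrates, nonzero only
    charge_deficit: int

    @property
    def balanced(self) -> bool:
        return self.elementally_balanced and self.charge_balanced


def check_balance(substrates: Iterable[Species], products: Iterable[Species]) -> BalanceReport:
    """Compare element counts (hydrogen included) and net charge of both sides."""
    elem: Counter = Counter()
    charge = 0
    for mol, coeff in _validate_side(products):
        for sym, n in mol.element_counts.items():
            elem[sym] += n * coeff
        charge += mol.net_charge * coeff
    for mol, coeff in _validate_side(substrates):
        for sym, n in mol.element_counts.items():
            elem[sym] -= n * coeff
        charge -= mol.net_charge * coeff
    deficits = {sym: n for sym, n in sorted(elem.items()) if n != 0}
    return BalanceReport(
        elementally_balanced=not deficits,
        charge_balanced=charge == 0,
        element_deficits=deficits,
        charge_deficit=charge,
    )


def parse_reaction_smiles(rxn: str) -> tuple[list[Species], list[Species]]:
    """Parse ``sub1.sub2>>prod1.prod2`` into (substrates, products).

    Repeated molecules are parsed as separate unit-coefficient species;
    callers may aggregate them.
    """
    parts = rxn.split(">>")
    if len(parts) != 2:
        raise MoietyError(f"reaction SMILES must contain exactly one '>>': {rxn!r}")
    left, right = parts
    subs = [(Molecule.from_smiles(s), 1) for s in left.split(".") if s.strip()]
    prods = [(Molecule.from_smiles(s), 1) for s in right.split(".") if s.strip()]
    if not subs or not prods:
        raise MoietyError(f"reaction needs at least one substrate and one product: {rxn!r}")
    return subs, prods
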