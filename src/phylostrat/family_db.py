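"""Protein family databases, protein lists, and presence matrices.

A protein family database partitions the proteins of all species on the tree
into evolutionarily related families.  For age estimation the only thing
that matters about a family is which species it has at least one member in,
so copy number is collapsed to a binary presence/absence profile per family
(the :class:`PresenceMatrix`, a pandas DataFrame of 0/1 with families as
rows and tree leaves as columns in the tree's canonical leaf order).

Protein lists arrive either as plain text (one ID per line) or as GAF 2.0
annotation files, from which the DB object ID (column 2) is taken as the
primary key with the symbol (column 3) kept as an alias.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import (
    CoverageError,
    EmptyInputError,
    FormatError,
    PartitionError,
    UnassignedProteinError,
)
from .species_tree import SpeciesTree

__all__ = [
    "FamilyTable",
    "ProteinList",
    "read_family_table",
    "build_presence_matrix",
    "phylogenetic_profile",
    "read_protein_list",
    "write_profiles",
]

Member = tuple[str, str]  # (species label, protein ID)


@dataclass
class FamilyTable:
    """Families as a partition of species-qualified proteins.

    ``families`` maps family ID -> set of (species, protein) members;
    ``member_index`` maps each member back to its unique family.
    """

    families: dict[str, set[Member]] = field(default_factory=dict)
    member_index: dict[Member, str] = field(default_factory=dict)

    def add(self, family: str, species: str, protein: str) -> None:
        member = (species, protein)
        prev = self.member_index.get(member)
        if prev is not None and prev != family:
            raise PartitionError(
                f"protein {protein!r} of species {species!r} appears in two "
                f"families: {prev!r} and {family!r}"
            )
        self.families.setdefault(family, set()).add(member)
        self.member_index[member] = family

    def family_of(self, species: str, protein: str) -> Optional[str]:
        return self.member_index.get((species, protein))

    def species_of_family(self, family: str) -> set[str]:
        return {sp for sp, _ in self.families[family]}

    def proteins_of_species(self, species: str) -> list[str]:
        """Protein IDs of one species, sorted for deterministic output."""
        return sorted(p for sp, p in self.member_index if sp == species)

    def all_species(self) -> set[str]:
        return {sp for sp, _ in self.member_index}

    def __len__(self) -> int:
        return len(self.families)


def read_family_table(source: str | io.TextIOBase) -> FamilyTable:
    """Read a 3-column tab-delimited family table.

    Columns: family ID, species label, protein ID.  '#'-prefixed comment
    lines and blank lines are ignored; duplicate membership lines are
    idempotent; a protein claimed by two families raises
    :class:`PartitionError`.
    """
    if isinstance(source, str):
        fh: Iterable[str] = open(source)
    else:
        fh = source
    table = FamilyTable()
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(
                f"family table line {lineno}: expected 3 tab-separated "
                f"columns (family, species, protein), got {len(parts)}"
            )
        family, species, protein = (p.strip() for p in parts)
        if not (family and species and protein):
            raise FormatError(f"family table line {lineno}: empty field")
        table.add(family, species, protein)
    if isinstance(source, str):
        fh.close()  # type: ignore[union-attr]
    if not table.families:
        raise EmptyInputError("family table contains no data lines")
    return table


def build_presence_matrix(
    fams: FamilyTable, tree: SpeciesTree, restrict_to_tree: bool = False
) -> pd.DataFrame:
    """Binary families x leaf-species matrix.

    Entry (f, s) is 1 iff family f has at least one member protein in
    species s — paralog counts are collapsed.  Columns are the tree's
    leaves in canonical order; rows are sorted family IDs.  Species in the
    family table but not on the tree raise :class:`CoverageError` unless
    ``restrict_to_tree`` is set, in which case those members are dropped
    (families left with no species on the tree are dropped entirely).
    """
    leaves = tree.leaf_labels
    leaf_set = set(leaves)
    extra = sorted(fams.all_species() - leaf_set)
    if extra and not restrict_to_tree:
        raise CoverageError(
            "family table cites species not on the tree: " + ", ".join(extra)
        )
    rows = {}
    for family in sorted(fams.families):
        present = fams.species_of_family(family) & leaf_set
        if not present:
            continue  # only reachable with restrict_to_tree
        rows[family] = [1 if s in present else 0 for s in leaves]
    if not rows:
        raise EmptyInputError("no family has members on the tree")
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=leaves)
    return matrix.astype("int8")


def phylogenetic_profile(
    matrix: pd.DataFrame, protein: Member, fams: FamilyTable
) -> pd.Series:
    """Presence/absence vector of the protein's family over the leaf panel."""
    species, pid = protein
    family = fams.family_of(species, pid)
    if family is None or family not in matrix.index:
        raise UnassignedProteinError(
            f"protein {pid!r} of species {species!r} is not in any family"
        )
    return matrix.loc[family]


def write_profiles(
    matrix: pd.DataFrame,
    fams: FamilyTable,
    species: str,
    out: io.TextIOBase,
    proteins: Optional[Iterable[str]] = None,
) -> list[str]:
    """Write per-protein profiles as TSV; returns IDs with no family."""
    if proteins is None:
        proteins = fams.proteins_of_species(species)
    out.write("protein\t" + "\t".join(matrix.columns) + "\n")
    missing = []
    for pid in proteins:
        try:
            prof = phylogenetic_profile(matrix, (species, pid), fams)
        except UnassignedProteinError:
            missing.append(pid)
            continue
        out.write(pid + "\t" + "\t".join(str(int(v)) for v in prof) + "\n")
    return missing


@dataclass
class ProteinList:
    """An ordered, de-duplicated list of protein IDs.

    ``aliases`` maps primary ID -> fallback alias (the GAF symbol column);
    empty for plain lists.  Order of first appearance is preserved so that
    reports are stable.
    """

    ids: list[str]
    species: Optional[str] = None
    aliases: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)


def _parse_plain(lines: Iterable[str]) -> ProteinList:
    seen = set()
    ids = []
    for raw in lines:
        pid = raw.strip()
        if not pid or pid.startswith("#"):
            continue
        if pid not in seen:
            seen.add(pid)
            ids.append(pid)
    return ProteinList(ids=ids)


def _parse_gaf(lines: Iterable[str]) -> ProteinList:
    seen = set()
    ids = []
    aliases = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        parts = line.split("\t")
        if len(parts) < 15:
            raise FormatError(
                f"GAF line {lineno}: expected >= 15 tab-separated columns, "
                f"got {len(parts)}"
            )
        obj_id = parts[1].strip()
        symbol = parts[2].strip()
        if not obj_id:
            raise FormatError(f"GAF line {lineno}: empty DB object ID")
        if obj_id not in seen:
            seen.add(obj_id)
            ids.append(obj_id)
            if symbol and symbol != obj_id:
                aliases[obj_id] = symbol
    return ProteinList(ids=ids, aliases=aliases)


def read_protein_list(
    source: str | io.TextIOBase, gaf: bool = False, species: Optional[str] = None
) -> ProteinList:
    """Read a protein list from plain text or a GAF 2.0 file.

    Plain mode: one ID per line, '#' comments ignored, duplicates removed
    keeping first occurrence.  GAF mode: '!' header lines skipped; the DB
    object ID (column 2) is the primary identifier and the symbol
    (column 3) is recorded as an alias for fallback lookup.  IDs are matched
    exactly — no case folding.
    """
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = list(source)
    plist = _parse_gaf(lines) if gaf else _parse_plain(lines)
    plist.species = species
    if not plist.ids:
        raise EmptyInputError("protein list is empty after parsing")
    return plist
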