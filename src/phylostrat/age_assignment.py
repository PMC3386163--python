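"""Turning reconstructions into per-protein ages.

A protein's origin is the branch on the path between its species' leaf and
the root on which its family first appeared.  Concretely, given a family's
ancestral labeling, the origin taxon is the most ancestral node N on the
leaf-to-root path such that every node from the leaf up to N is in state 1
— the top of the contiguous present segment containing the leaf.  Under
Dollo this is always the family MRCA; under Wagner with several gains it is
the gain event that actually explains this protein's presence, so members
of the same family in different species may receive different origins.

Because a family could have appeared anywhere along its origin branch, the
node age attached to the origin is a lower bound in mya.

Domain-based strategies are also supported: given per-domain ages, a
protein is assigned the age of its oldest or youngest domain; proteins with
no annotated domains are treated as specific to their own species (age 0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import (
    ArgumentError,
    FormatError,
    PhylostratError,
    TreeValidationError,
)
from .family_db import FamilyTable, ProteinList
from .reconstruction import AncestralLabeling
from .species_tree import SpeciesTree, leaf_to_root_path

__all__ = [
    "ProteinAge",
    "AgeDatabase",
    "assign_protein_ages",
    "domain_based_ages",
    "lookup_ages",
    "read_age_database",
]

NO_FAMILY = "none"


@dataclass(frozen=True)
class ProteinAge:
    """Age record for one protein: taxon of origin plus its mya lower bound."""

    protein: str
    species: str
    family: str
    origin_taxon: str
    age_mya: float
    method: str

    @property
    def no_family(self) -> bool:
        """True when the protein had no family (or no domain) and defaulted
        to a species-specific origin."""
        return self.family == NO_FAMILY


@dataclass
class AgeDatabase:
    """All ages for one species, plus the metadata needed to reproduce them."""

    species: str
    metadata: dict[str, str] = field(default_factory=dict)
    ages: dict[str, ProteinAge] = field(default_factory=dict)

    def add(self, age: ProteinAge) -> None:
        if age.species != self.species:
            raise ArgumentError(
                f"age record species {age.species!r} != database species "
                f"{self.species!r}"
            )
        self.ages[age.protein] = age

    def __len__(self) -> int:
        return len(self.ages)

    def __contains__(self, protein: str) -> bool:
        return protein in self.ages

    def write(self, out: io.TextIOBase) -> None:
        """Tab-delimited serialization; bit-exact round trip with
        :func:`read_age_database`."""
        out.write(f"# species={self.species}\n")
        for key in sorted(self.metadata):
            out.write(f"# {key}={self.metadata[key]}\n")
        out.write("protein\tspecies\tfamily\torigin_taxon\tage_mya\tmethod\n")
        for pid in sorted(self.ages):
            a = self.ages[pid]
            out.write(
                f"{a.protein}\t{a.species}\t{a.family}\t{a.origin_taxon}\t"
                f"{a.age_mya!r}\t{a.method}\n"
            )


def read_age_database(source: str | io.TextIOBase) -> AgeDatabase:
    if isinstance(source, str):
        fh: list[str] = open(source).readlines()
    else:
        fh = list(source)
    species: Optional[str] = None
    metadata: dict[str, str] = {}
    ages: dict[str, ProteinAge] = {}
    header_seen = False
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                if key == "species":
                    species = value
                else:
                    metadata[key] = value
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise FormatError(
                f"age database line {lineno}: expected 6 columns, got {len(parts)}"
            )
        pid, sp, family, origin, age_s, method = parts
        ages[pid] = ProteinAge(
            protein=pid,
            species=sp,
            family=family,
            origin_taxon=origin,
            age_mya=float(age_s),
            method=method,
        )
    if species is None:
        sps = {a.species for a in ages.values()}
        if len(sps) != 1:
            raise FormatError("age database lacks a single species annotation")
        species = sps.pop()
    db = AgeDatabase(species=species, metadata=metadata)
    for a in ages.values():
        db.add(a)
    return db


def _origin_on_path(labeling: AncestralLabeling, path) -> str:
    """Top of the contiguous state-1 segment containing the leaf."""
    leaf = path[0]
    if labeling.state.get(leaf.label) != 1:
        raise PhylostratError(
            f"labeling of family {labeling.family!r} marks leaf "
            f"{leaf.label!r} absent although it has a member there"
        )
    origin = leaf
    for node in path[1:]:
        if labeling.state.get(node.label) == 1:
            origin = node
        else:
            break
    return origin.label


def assign_protein_ages(
    labelings: Mapping[str, AncestralLabeling],
    fams: FamilyTable,
    tree: SpeciesTree,
    species: str,
    method: str,
    proteome: Optional[Iterable[str]] = None,
    metadata: Optional[Mapping[str, str]] = None,
) -> AgeDatabase:
    """Build the age database for one species from per-family labelings.

    ``labelings`` must cover every family with a member in ``species``.
    When ``proteome`` is given, proteins in it that belong to no family are
    included with a species-specific origin (their own leaf, age 0) and
    family "none", so downstream analyses can include or exclude them.
    """
    tree.leaf(species)  # validates the species label
    path = leaf_to_root_path(tree, species)
    db = AgeDatabase(species=species, metadata=dict(metadata or {}))

    for pid in fams.proteins_of_species(species):
        family = fams.family_of(species, pid)
        assert family is not None
        if family not in labelings:
            raise ArgumentError(
                f"no labeling supplied for family {family!r} "
                f"(member {pid!r} in {species!r})"
            )
        origin = _origin_on_path(labelings[family], path)
        db.add(
            ProteinAge(
                protein=pid,
                species=species,
                family=family,
                origin_taxon=origin,
                age_mya=tree.age_of(origin),
                method=method,
            )
        )

    if proteome is not None:
        for pid in proteome:
            if pid not in db:
                db.add(
                    ProteinAge(
                        protein=pid,
                        species=species,
                        family=NO_FAMILY,
                        origin_taxon=species,
                        age_mya=0.0,
                        method=method,
                    )
                )
    return db


def domain_based_ages(
    domain_ages: Mapping[str, tuple[str, float]],
    protein_domains: Mapping[str, Iterable[str]],
    strategy: str,
    tree: SpeciesTree,
    species: str,
    metadata: Optional[Mapping[str, str]] = None,
) -> AgeDatabase:
    """Assign each protein the age of its oldest or youngest domain.

    ``domain_ages`` maps domain ID -> (origin taxon, age in mya).  Ties in
    age are resolved toward the more leafward taxon on the species' path to
    the root (and lexicographically as a last resort, for taxa off the
    path).  Proteins with no annotated domains are considered specific to
    their species: origin = own leaf, age 0.
    """
    if strategy not in ("oldest", "youngest"):
        raise ArgumentError(f"strategy must be 'oldest' or 'youngest', got {strategy!r}")
    tree.leaf(species)
    path_rank = {
        n.label: i for i, n in enumerate(leaf_to_root_path(tree, species))
    }
    db = AgeDatabase(species=species, metadata=dict(metadata or {}))
    pick = max if strategy == "oldest" else min

    for pid in sorted(protein_domains):
        domains = sorted(set(protein_domains[pid]))
        if not domains:
            db.add(
                ProteinAge(
                    protein=pid,
                    species=species,
                    family=NO_FAMILY,
                    origin_taxon=species,
                    age_mya=0.0,
                    method=f"domain_{strategy}",
                )
            )
            continue
        missing = [d for d in domains if d not in domain_ages]
        if missing:
            raise ArgumentError(
                f"protein {pid!r} cites domains with no age: " + ", ".join(missing)
            )
        for dom in domains:
            taxon = domain_ages[dom][0]
            if taxon not in tree.node_index:
                raise TreeValidationError(
                    f"domain {dom!r} origin taxon {taxon!r} is not on the tree"
                )
        target_age = pick(domain_ages[d][1] for d in domains)
        candidates = [d for d in domains if domain_ages[d][1] == target_age]
        # tie-break: most leafward taxon on the species path, then lexical
        dom = min(
            candidates,
            key=lambda d: (
                path_rank.get(domain_ages[d][0], len(path_rank)),
                domain_ages[d][0],
            ),
        )
        taxon, age = domain_ages[dom]
        db.add(
            ProteinAge(
                protein=pid,
                species=species,
                family=dom,
                origin_taxon=taxon,
                age_mya=age,
                method=f"domain_{strategy}",
            )
        )
    return db


def lookup_ages(
    db: AgeDatabase, proteins: ProteinList
) -> tuple[list[ProteinAge], list[str]]:
    """Partition a protein list into matched age records and missing IDs.

    GAF-derived lists are matched on the primary ID first, then on the
    symbol alias.  Missing IDs are returned, never silently dropped.
    """
    matched: list[ProteinAge] = []
    missing: list[str] = []
    for pid in proteins:
        if pid in db.ages:
            matched.append(db.ages[pid])
            continue
        alias = proteins.aliases.get(pid)
        if alias is not None and alias in db.ages:
            matched.append(db.ages[alias])
        else:
            missing.append(pid)
    return matched, missing
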