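"""MeSH-style chemical ontology: term storage, annotation, class selection.

Terms carry dot-delimited tree numbers (e.g. ``D02.092.877``) whose depth
encodes specificity; a compound "carries" a term when any of its own tree
numbers has that term's tree number as a dot-prefix.  Non-overlapping
metabolite sets are built greedily from the most specific terms upward
until a minimum of three compounds per class is reached; each compound is
assigned at most once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .fingerprints import Fingerprint, canonical_smiles

__all__ = [
    "MeshTerm",
    "OntologyDB",
    "OntologyError",
    "ChemSet",
    "ClassAssignment",
    "load_ontology",
    "write_ontology",
    "direct_annotations",
    "select_nonoverlapping_classes",
    "MIN_CLASS_SIZE",
]

MIN_CLASS_SIZE = 3

_TREE_NUMBER_RE = re.compile(r"^[A-Z]\d+(\.\d+)*$")


class OntologyError(ValueError):
    """Malformed ontology input."""


@dataclass(frozen=True)
class MeshTerm:
    """One ontology term with its tree positions."""

    term_id: str
    name: str
    tree_numbers: frozenset[str]

    def __post_init__(self):
        if not self.tree_numbers:
            raise OntologyError(f"term {self.term_id}: no tree numbers")
        for tn in self.tree_numbers:
            if not _TREE_NUMBER_RE.match(tn):
                raise OntologyError(
                    f"term {self.term_id}: malformed tree number {tn!r}"
                )

    @property
    def specificity(self) -> int:
        """Maximum tree depth (number of dot-separated components)."""
        return max(tn.count(".") + 1 for tn in self.tree_numbers)

    def is_prefix_of(self, other: "MeshTerm") -> bool:
        """True if any tree number of ``other`` descends from this term."""
        for parent in self.tree_numbers:
            for child in other.tree_numbers:
                if child == parent or child.startswith(parent + "."):
                    return True
        return False


def _norm_name(name: str) -> str:
    return " ".join(name.casefold().split())


def _norm_key(key_type: str, key: str) -> str:
    key_type = key_type.strip().lower()
    key = key.strip()
    if key_type == "cid":
        return f"cid:{int(key)}"
    if key_type == "smiles":
        return f"smiles:{canonical_smiles(key)}"
    if key_type == "name":
        return f"name:{_norm_name(key)}"
    raise OntologyError(f"unknown key type {key_type!r}")


@dataclass
class OntologyDB:
    """Term registry plus compound-key -> term annotations."""

    terms: dict[str, MeshTerm] = field(default_factory=dict)
    annotations: dict[str, set[str]] = field(default_factory=dict)
    fingerprint_index: dict[str, Fingerprint] = field(default_factory=dict)

    def add_term(self, term: MeshTerm) -> None:
        existing = self.terms.get(term.term_id)
        if existing is not None:
            term = MeshTerm(
                term.term_id,
                existing.name,
                existing.tree_numbers | term.tree_numbers,
            )
        self.terms[term.term_id] = term

    def annotate(self, key_type: str, key: str, term_id: str) -> None:
        if term_id not in self.terms:
            raise OntologyError(f"annotation references unknown term {term_id}")
        self.annotations.setdefault(_norm_key(key_type, key), set()).add(term_id)

    def lookup(self, key_type: str, key: str) -> set[str]:
        try:
            return set(self.annotations.get(_norm_key(key_type, key), ()))
        except Exception:  # unparseable key -> no annotation
            return set()

    def without_terms(self, term_names: set[str]) -> "OntologyDB":
        """Copy with the named terms (and their annotations) removed.

        Used for hold-out experiments where a class definition is deleted
        to test rediscovery by similarity clustering.
        """
        names = {_norm_name(n) for n in term_names}
        drop = {tid for tid, t in self.terms.items() if _norm_name(t.name) in names}
        db = OntologyDB(
            terms={tid: t for tid, t in self.terms.items() if tid not in drop},
            fingerprint_index=dict(self.fingerprint_index),
        )
        for key, tids in self.annotations.items():
            kept = tids - drop
            if kept:
                db.annotations[key] = set(kept)
        return db


def load_ontology(path: str | Path) -> OntologyDB:
    """Load the ontology TSV: key_type, key, term_id, term_name, tree_number.

    One row per (compound key, term, tree number); duplicate rows collapse.
    Malformed tree numbers raise :class:`OntologyError` with the line number.
    """
    path = Path(path)
    db = OntologyDB()
    rows: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["key_type", "key", "term_id", "term_name", "tree_number"]
        if [h.strip().lower() for h in header] != expected:
            raise OntologyError(f"{path}: header must be {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise OntologyError(f"{path}:{lineno}: expected 5 columns")
            key_type, key, term_id, term_name, tree_number = (
                p.strip() for p in parts
            )
            if not _TREE_NUMBER_RE.match(tree_number):
                raise OntologyError(
                    f"{path}:{lineno}: malformed tree number {tree_number!r}"
                )
            db.add_term(MeshTerm(term_id, term_name, frozenset({tree_number})))
            rows.append((key_type, key, term_id))
    for key_type, key, term_id in rows:
        db.annotate(key_type, key, term_id)
    return db


def write_ontology(db: OntologyDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("key_type\tkey\tterm_id\tterm_name\ttree_number\n")
        for key in sorted(db.annotations):
            key_type, raw = key.split(":", 1)
            for tid in sorted(db.annotations[key]):
                term = db.terms[tid]
                for tn in sorted(term.tree_numbers):
                    fh.write(f"{key_type}\t{raw}\t{tid}\t{term.name}\t{tn}\n")


def direct_annotations(record, db: OntologyDB) -> list[MeshTerm]:
    """Ontology terms for one compound, most specific first.

    Lookup is tried by PubChem CID, then canonical SMILES, then normalized
    name; the union of hits is returned sorted by decreasing specificity
    with ties broken by term_id.  No match yields an empty list.
    """
    term_ids: set[str] = set()
    if getattr(record, "pubchem_cid", None):
        term_ids |= db.lookup("cid", str(record.pubchem_cid))
    if getattr(record, "smiles", None):
        term_ids |= db.lookup("smiles", record.smiles)
    if getattr(record, "name", None):
        term_ids |= db.lookup("name", record.name)
    terms = [db.terms[t] for t in term_ids]
    return sorted(terms, key=lambda t: (-t.specificity, t.term_id))


@dataclass
class ChemSet:
    """A named, non-overlapping group of compounds (one enrichment unit)."""

    label: str
    compound_ids: list[str]
    provenance: str = "mesh_direct"

    def __len__(self) -> int:
        return len(self.compound_ids)


PROVENANCES = (
    "mesh_direct",
    "similarity_090",
    "similarity_075",
    "lipid_rule",
    "tree_cut_new",
    "singleton",
)


@dataclass
class ClassAssignment:
    """Non-overlapping compound -> (set label, provenance) mapping."""

    assignments: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add(self, compound_id: str, label: str, provenance: str) -> None:
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        if compound_id in self.assignments:
            raise ValueError(f"compound {compound_id!r} assigned twice")
        self.assignments[compound_id] = (label, provenance)

    def label_of(self, compound_id: str) -> str | None:
        entry = self.assignments.get(compound_id)
        return entry[0] if entry else None

    def members(self, label: str) -> list[str]:
        return [
            cid
            for cid, (lab, prov) in self.assignments.items()
            if lab == label and prov != "singleton"
        ]

    def classes(self) -> dict[str, list[str]]:
        """Multi-member set labels -> ordered member lists (no singletons)."""
        out: dict[str, list[str]] = {}
        for cid, (label, prov) in self.assignments.items():
            if prov == "singleton":
                continue
            out.setdefault(label, []).append(cid)
        return out

    def singletons(self) -> dict[str, str]:
        return {
            cid: label
            for cid, (label, prov) in self.assignments.items()
            if prov == "singleton"
        }

    def relabel(self, old: str, new: str, members: list[str] | None = None) -> None:
        for cid, (label, prov) in list(self.assignments.items()):
            if label == old and (members is None or cid in members):
                self.assignments[cid] = (new, prov)

    def validate(self, min_size: int = MIN_CLASS_SIZE) -> None:
        for label, members in self.classes().items():
            if len(members) < min_size:
                raise ValueError(
                    f"class {label!r} has {len(members)} members (< {min_size})"
                )


def select_nonoverlapping_classes(
    annotations: dict[str, list[MeshTerm]],
    min_size: int = MIN_CLASS_SIZE,
) -> ClassAssignment:
    """Greedy most-specific-first selection of non-overlapping classes.

    Working from the deepest ontology level upward, a term becomes a class
    when at least ``min_size`` still-unassigned compounds carry it (directly
    or through a descendant tree number).  Ties between equally specific
    candidates are broken by larger prospective class size, then by term
    name; compounds never assigned retain their own most specific term as a
    singleton annotation.  The result is deterministic and independent of
    input ordering.
    """
    candidates: dict[str, MeshTerm] = {}
    for terms in annotations.values():
        for t in terms:
            candidates[t.term_id] = t

    def carriers(term: MeshTerm, unassigned: set[str]) -> list[str]:
        out = []
        for cid in unassigned:
            for t in annotations[cid]:
                if t.term_id == term.term_id or term.is_prefix_of(t):
                    out.append(cid)
                    break
        return sorted(out)

    assignment = ClassAssignment()
    unassigned = set(annotations)
    levels = sorted({t.specificity for t in candidates.values()}, reverse=True)
    for level in levels:
        level_terms = [t for t in candidates.values() if t.specificity == level]
        while True:
            best: tuple[int, str, MeshTerm] | None = None
            best_members: list[str] = []
            for term in level_terms:
                members = carriers(term, unassigned)
                if len(members) < min_size:
                    continue
                key = (-len(members), _norm_name(term.name))
                if best is None or key < (-len(best_members), _norm_name(best[2].name)):
                    best = (len(members), term.term_id, term)
                    best_members = members
            if best is None:
                break
            for cid in best_members:
                assignment.add(cid, best[2].name, "mesh_direct")
            unassigned -= set(best_members)

    for cid in sorted(unassigned):
        terms = annotations[cid]
        if terms:
            assignment.add(cid, terms[0].name, "singleton")
    return assignment
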