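"""Rule-based lipid classification and the saturated/unsaturated split.

Fatty acids, oxylipins (hydroxy-, epoxy- and oxo-fatty acids) and
prostaglandins are recognized directly from their structures by an
ordered, first-match-wins rule set shipped as ``data/lipid_rules.yaml``.
Lipid classes are then split into saturated and unsaturated partitions:
a class counts as unsaturated when at least three of its members contain
a carbon-carbon double bond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from rdkit import Chem

from .fingerprints import parse_smiles
from .ontology import ChemSet

__all__ = [
    "LipidRule",
    "LipidRuleSet",
    "load_rules",
    "default_rules",
    "classify_lipid",
    "has_double_bond",
    "split_saturation",
]


@dataclass(frozen=True)
class LipidRule:
    name: str
    target: str
    match: tuple[str, ...]
    exclude: tuple[str, ...] = ()
    min_carbons: int = 0


@dataclass
class LipidRuleSet:
    """Ordered lipid rules plus the class labels eligible for splitting."""

    rules: list[LipidRule]
    lipid_class_labels: list[str]
    oxylipin_targets: list[str] = field(default_factory=list)
    saturation_token: str = "C=C"
    version: int = 1

    def is_lipid_class(self, label: str) -> bool:
        base = label.removeprefix("Unsaturated_").removeprefix("Saturated_")
        wanted = {l.casefold() for l in self.lipid_class_labels}
        return base.casefold() in wanted or label.casefold() in wanted


def load_rules(path: str | Path) -> LipidRuleSet:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    rules = [
        LipidRule(
            name=r["name"],
            target=r["target"],
            match=tuple(r.get("match", ())),
            exclude=tuple(r.get("exclude", ())),
            min_carbons=int(r.get("min_carbons", 0)),
        )
        for r in raw["rules"]
    ]
    return LipidRuleSet(
        rules=rules,
        lipid_class_labels=list(raw.get("lipid_class_labels", ())),
        oxylipin_targets=list(raw.get("oxylipin_targets", ())),
        saturation_token=raw.get("saturation_token", "C=C"),
        version=int(raw.get("version", 1)),
    )


_DEFAULT: LipidRuleSet | None = None


def default_rules() -> LipidRuleSet:
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("chemrich.data").joinpath("lipid_rules.yaml")
        with resources.as_file(ref) as path:
            _DEFAULT = load_rules(path)
    return _DEFAULT


def _kekule_mol(smiles: str) -> Chem.Mol:
    mol = Chem.Mol(parse_smiles(smiles))
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


def classify_lipid(smiles: str, rules: LipidRuleSet | None = None) -> str | None:
    """Class label of the first matching lipid rule, or None.

    Patterns are evaluated on the sanitized structure in Kekule form so
    that the outcome is independent of how the input SMILES was written.
    """
    rules = rules or default_rules()
    mol = _kekule_mol(smiles)
    n_carbons = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "C")
    for rule in rules.rules:
        if n_carbons < rule.min_carbons:
            continue
        ok = all(
            mol.HasSubstructMatch(Chem.MolFromSmarts(p)) for p in rule.match
        ) and not any(
            mol.HasSubstructMatch(Chem.MolFromSmarts(p)) for p in rule.exclude
        )
        if ok:
            return rule.target
    return None


def has_double_bond(smiles: str, mode: str = "structural") -> bool:
    """Whether the molecule contains a carbon-carbon double bond.

    ``structural`` (default) inspects Kekule bond orders; ``literal``
    emulates a plain-text search for the token ``C=C`` in the canonical
    Kekule SMILES.  The two modes agree for acyl chains; they can differ
    for ring double bonds written with ring-closure digits (e.g.
    ``C1=CCCCC1``), where only the structural mode reports true.
    """
    mol = _kekule_mol(smiles)
    if mode == "literal":
        kek = Chem.MolToSmiles(mol, kekuleSmiles=True)
        return "C=C" in kek
    if mode != "structural":
        raise ValueError(f"unknown saturation mode {mode!r}")
    for bond in mol.GetBonds():
        if (
            bond.GetBondType() == Chem.BondType.DOUBLE
            and bond.GetBeginAtom().GetSymbol() == "C"
            and bond.GetEndAtom().GetSymbol() == "C"
        ):
            return True
    return False


def split_saturation(
    set_label: str,
    members: list,
    rules: LipidRuleSet | None = None,
    mode: str = "structural",
) -> list[ChemSet]:
    """Split a lipid class into saturated/unsaturated partitions.

    ``members`` are compound records (``compound_id`` + ``smiles``).  If at
    least three members carry a C=C double bond and at least one does not,
    the class is partitioned into ``Unsaturated_<label>`` and
    ``Saturated_<label>``; if at least three do and all do, the whole class
    is relabelled ``Unsaturated_<label>``.  Non-lipid classes and classes
    with fewer than three unsaturated members are returned unchanged.
    """
    rules = rules or default_rules()
    ids = [m.compound_id for m in members]
    if not rules.is_lipid_class(set_label):
        return [ChemSet(set_label, ids)]
    unsat = [m.compound_id for m in members if has_double_bond(m.smiles, mode)]
    sat = [i for i in ids if i not in set(unsat)]
    if len(unsat) < 3:
        return [ChemSet(set_label, ids)]
    if not sat:
        return [ChemSet(f"Unsaturated_{set_label}", ids)]
    return [
        ChemSet(f"Unsaturated_{set_label}", unsat),
        ChemSet(f"Saturated_{set_label}", sat),
    ]
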