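"""Binary substructure fingerprints and Tanimoto chemical similarity.

Implements the 881-position substructure fingerprint (layout defined in
:mod:`chemrich._fp_layout` and shipped as ``data/fingerprint_layout.json``)
and the pairwise Tanimoto similarity matrix used to build the chemical
similarity tree.  For two fingerprints with ``A`` and ``B`` set bits of
which ``AB`` are shared, the Tanimoto coefficient is ``AB / (A + B - AB)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from ._fp_layout import N_BITS, build_layout

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Fingerprint",
    "SimilarityMatrix",
    "SmilesParseError",
    "compute_fingerprint",
    "tanimoto",
    "similarity_matrix",
    "parse_smiles",
    "canonical_smiles",
    "read_fingerprint_cache",
    "write_fingerprint_cache",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"SMILES parse failure: {smiles!r}")


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize a SMILES string; raise :class:`SmilesParseError`."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(smiles if isinstance(smiles, str) else "")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical isomeric SMILES under the default aromaticity model."""
    return Chem.MolToSmiles(parse_smiles(smiles))


@dataclass(frozen=True)
class Fingerprint:
    """881 ordered substructure bits for one molecule."""

    bits: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.bits, dtype=bool)
        if arr.shape != (N_BITS,):
            raise ValueError(f"fingerprint must have {N_BITS} bits, got {arr.shape}")
        object.__setattr__(self, "bits", arr)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def to_hex(self) -> str:
        return np.packbits(self.bits.astype(np.uint8)).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstring: str) -> "Fingerprint":
        raw = np.frombuffer(bytes.fromhex(hexstring), dtype=np.uint8)
        bits = np.unpackbits(raw)[:N_BITS].astype(bool)
        return cls(bits)

    def __eq__(self, other) -> bool:
        return isinstance(other, Fingerprint) and bool(
            np.array_equal(self.bits, other.bits)
        )


# --- layout compilation (module-level singleton) ----------------------------

_BOND_KIND = {
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}


class _CompiledLayout:
    def __init__(self):
        layout = build_layout()
        self.version = layout["version"]
        self.element_counts: list[tuple[str, int]] = [
            (sym, thr) for sym, thr in layout["element_counts"]
        ]
        self.rings: list[tuple[str, int, int]] = []
        for desc in layout["rings"]:
            feat, size, count = desc.split(":")
            self.rings.append((feat, int(size), int(count)))
        self.pairs: list[tuple[str, str, str]] = []
        for desc in layout["atom_pairs"]:
            pair, kind = desc.split(":")
            a, b = pair.split("-")
            self.pairs.append((a, b, kind))
        self.patterns: list[tuple[Chem.Mol, int] | None] = []
        for entry in layout["patterns"]:
            if entry is None:
                self.patterns.append(None)
                continue
            smarts, count = entry
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:  # pragma: no cover - layout authoring guard
                raise ValueError(f"invalid SMARTS in layout: {smarts!r}")
            self.patterns.append((patt, int(count)))
        n = (
            len(self.element_counts)
            + len(self.rings)
            + len(self.pairs)
            + len(self.patterns)
        )
        assert n == N_BITS, n


_LAYOUT: _CompiledLayout | None = None


def _layout() -> _CompiledLayout:
    global _LAYOUT
    if _LAYOUT is None:
        _LAYOUT = _CompiledLayout()
    return _LAYOUT


# --- per-section evaluation -------------------------------------------------


def _element_bits(mol: Chem.Mol, lay: _CompiledLayout) -> list[bool]:
    counts: dict[str, int] = {}
    n_h = 0
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        n_h += atom.GetTotalNumHs()
    counts["H"] = counts.get("H", 0) + n_h
    return [counts.get(sym, 0) >= thr for sym, thr in lay.element_counts]


def _ring_profile(mol: Chem.Mol):
    info = mol.GetRingInfo()
    rings = []
    for atom_ids, bond_ids in zip(info.AtomRings(), info.BondRings()):
        atoms = [mol.GetAtomWithIdx(i) for i in atom_ids]
        bonds = [mol.GetBondWithIdx(i) for i in bond_ids]
        aromatic = all(b.GetIsAromatic() for b in bonds)
        has_multiple = any(
            b.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
            for b in bonds
        )
        rings.append(
            {
                "size": len(atom_ids),
                "carbon_only": all(a.GetSymbol() == "C" for a in atoms),
                "nitrogen": any(a.GetSymbol() == "N" for a in atoms),
                "heteroatom": any(a.GetSymbol() != "C" for a in atoms),
                "aromatic": aromatic,
                "saturated": (not aromatic) and (not has_multiple),
                "unsaturated": (not aromatic) and has_multiple,
                "fused": any(info.NumBondRings(b.GetIdx()) > 1 for b in bonds),
            }
        )
    return rings


def _ring_bits(mol: Chem.Mol, lay: _CompiledLayout) -> list[bool]:
    rings = _ring_profile(mol)
    out = []
    for feat, size, count in lay.rings:
        if feat == "total":
            n = len(rings)
        elif feat == "aromatic_total":
            n = sum(r["aromatic"] for r in rings)
        elif feat == "heteroaromatic_total":
            n = sum(r["aromatic"] and r["heteroatom"] for r in rings)
        elif feat == "fused":
            n = sum(r["fused"] for r in rings)
        elif feat == "any":
            n = sum(r["size"] == size for r in rings)
        else:
            n = sum(r["size"] == size and r[feat] for r in rings)
        out.append(n >= count)
    return out


def _pair_bits(mol: Chem.Mol, lay: _CompiledLayout) -> list[bool]:
    seen: set[tuple[str, str, str]] = set()
    for bond in mol.GetBonds():
        a, b = sorted(
            (bond.GetBeginAtom().GetSymbol(), bond.GetEndAtom().GetSymbol())
        )
        seen.add((a, b, "any"))
        for kind, btype in _BOND_KIND.items():
            if bond.GetBondType() == btype:
                seen.add((a, b, kind))
        if bond.IsInRing():
            seen.add((a, b, "ring"))
    for atom in mol.GetAtoms():
        if atom.GetTotalNumHs() > 0:
            a, b = sorted((atom.GetSymbol(), "H"))
            seen.add((a, b, "any"))
    return [pair in seen for pair in lay.pairs]


def _pattern_bits(mol: Chem.Mol, lay: _CompiledLayout) -> list[bool]:
    out = []
    for entry in lay.patterns:
        if entry is None:
            out.append(False)
            continue
        patt, count = entry
        if count == 1:
            out.append(mol.HasSubstructMatch(patt))
        else:
            matches = mol.GetSubstructMatches(
                patt, uniquify=True, maxMatches=max(count, 64)
            )
            out.append(len(matches) >= count)
    return out


def compute_fingerprint(smiles: str) -> Fingerprint:
    """Compute the 881-bit substructure fingerprint of a molecule.

    The molecule is sanitized (single aromaticity model) before pattern
    matching, so any SMILES writing of the same structure yields the
    same bits.
    """
    mol = parse_smiles(smiles)
    lay = _layout()
    bits = (
        _element_bits(mol, lay)
        + _ring_bits(mol, lay)
        + _pair_bits(mol, lay)
        + _pattern_bits(mol, lay)
    )
    return Fingerprint(np.array(bits, dtype=bool))


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient ``AB / (A + B - AB)``; 0.0 for two empty sets."""
    inter = int(np.count_nonzero(fp_a.bits & fp_b.bits))
    union = fp_a.popcount + fp_b.popcount - inter
    if union == 0:
        return 0.0
    return inter / union


class _HasIdAndSmiles(Protocol):
    compound_id: str
    smiles: str


@dataclass
class SimilarityMatrix:
    """Pairwise Tanimoto similarities over an ordered set of compounds."""

    labels: list[str]
    values: np.ndarray
    fingerprints: dict[str, Fingerprint] = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match labels")
        self.values = v

    def distance(self) -> np.ndarray:
        """Dissimilarity ``d = 1 - T`` as a dense square matrix."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, 1.0)

    def subset(self, labels: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.labels.index(l) for l in labels]
        return SimilarityMatrix(
            list(labels),
            self.values[np.ix_(idx, idx)],
            {l: self.fingerprints[l] for l in labels if l in self.fingerprints},
        )


def similarity_matrix(
    compounds: Iterable[_HasIdAndSmiles] | "object",
) -> SimilarityMatrix:
    """Pairwise Tanimoto matrix for a study table or compound sequence."""
    records = getattr(compounds, "records", compounds)
    labels, fps = [], []
    for rec in records:
        labels.append(rec.compound_id)
        fps.append(compute_fingerprint(rec.smiles))
    if not labels:
        raise ValueError("no compounds with valid SMILES")
    mat = np.stack([fp.bits for fp in fps]).astype(np.int32)
    inter = mat @ mat.T
    pop = mat.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(labels, sim, dict(zip(labels, fps)))


# --- fingerprint cache ------------------------------------------------------


def write_fingerprint_cache(path: str | Path, fps: dict[str, Fingerprint]) -> None:
    """Write a ``compound_id<TAB>hex`` cache file (one row per compound)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#chemrich fingerprint cache v1\n")
        for cid in sorted(fps):
            fh.write(f"{cid}\t{fps[cid].to_hex()}\n")


def read_fingerprint_cache(path: str | Path) -> dict[str, Fingerprint]:
    out: dict[str, Fingerprint] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, hexstring = line.split("\t")
            out[cid] = Fingerprint.from_hex(hexstring)
    return out
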