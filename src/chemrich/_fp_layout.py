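"""Frozen layout of the 881-position binary substructure fingerprint.

The fingerprint follows the published PubChem substructure fingerprint
organisation: seven sections laid out over 881 ordered positions —
hierarchic element counts, ring features, bonded atom pairs, atom
neighborhoods, and two tiers of SMARTS-style structural patterns.  The
section boundaries and the element-count thresholds follow the public
specification; the ring section is evaluated on the smallest set of
smallest rings (SSSR) rather than the original ESSSR ring ensemble, and
positions whose original pattern definition cannot be reproduced exactly
are frozen to constant zero.  Every position's definition (or its null)
is exported in machine-readable form via :func:`build_layout` and the
shipped ``data/fingerprint_layout.json``; constant-zero positions do not
affect Tanimoto similarity.

Section map (position ranges, inclusive):

======  ==========  =====================================
section positions   content
======  ==========  =====================================
1       0-114       element count thresholds
2       115-262     ring features (SSSR approximation)
3       263-326     bonded element pairs
4       327-415     atom-centred neighborhoods
5       416-459     detailed neighborhoods (hydrogen counts)
6       460-712     simple structural patterns (SMARTS)
7       713-880     complex structural patterns (SMARTS)
======  ==========  =====================================
"""

from __future__ import annotations

import itertools
import json
from typing import Any

LAYOUT_VERSION = "1.0"
N_BITS = 881

# --- section 1: element count thresholds (positions 0-114) -----------------

_THRESHOLDED = [
    ("H", (4, 8, 16, 32)),
    ("Li", (1, 2)),
    ("B", (1, 2, 4)),
    ("C", (2, 4, 8, 16, 32)),
    ("N", (1, 2, 4, 8)),
    ("O", (1, 2, 4, 8, 16)),
    ("F", (1, 2, 4)),
    ("Na", (1, 2)),
    ("Si", (1, 2)),
    ("P", (1, 2, 4)),
    ("S", (1, 2, 4, 8)),
    ("Cl", (1, 2, 4, 8)),
    ("K", (1, 2)),
    ("Br", (1, 2, 4)),
    ("I", (1, 2, 4)),
]

_SINGLE_PRESENCE = [
    "Be", "Mg", "Al", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni",
    "Cu", "Zn", "Ga", "Ge", "As", "Se", "Kr", "Rb", "Sr", "Y", "Zr", "Nb",
    "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn", "Sb", "Te", "Xe",
    "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy",
    "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt",
    "Au", "Hg", "Tl", "Pb", "Bi", "U",
]


def _element_counts() -> list[list[Any]]:
    out: list[list[Any]] = []
    for sym, thresholds in _THRESHOLDED:
        out.extend([sym, t] for t in thresholds)
    out.extend([sym, 1] for sym in _SINGLE_PRESENCE)
    return out


# --- section 2: ring features (positions 115-262) ---------------------------
#
# Descriptors are "<feature>:<size>:<min count>"; size 0 means any size.
# Features: any, carbon_only (all ring atoms C), nitrogen (>=1 N in ring),
# heteroatom (>=1 non-C ring atom), saturated (all ring bonds single,
# non-aromatic), unsaturated (non-aromatic with >=1 multiple bond),
# aromatic; plus whole-molecule features total, aromatic_total,
# heteroaromatic_total, fused (rings sharing >=1 bond).

_RING_FEATURES = (
    "any", "carbon_only", "nitrogen", "heteroatom",
    "saturated", "unsaturated", "aromatic",
)


def _ring_bits() -> list[str]:
    out: list[str] = []
    for size in range(3, 11):
        for feat in _RING_FEATURES:
            for count in (1, 2):
                out.append(f"{feat}:{size}:{count}")
    for count in range(1, 9):
        out.append(f"total:0:{count}")
    for count in range(1, 5):
        out.append(f"aromatic_total:0:{count}")
    for count in range(1, 5):
        out.append(f"heteroaromatic_total:0:{count}")
    for size in range(3, 11):
        for count in (3, 4):
            out.append(f"any:{size}:{count}")
    out.append("fused:0:1")
    out.append("fused:0:2")
    out.append("carbon_only:6:3")
    out.append("carbon_only:6:4")
    assert len(out) == 148
    return out


# --- section 3: bonded element pairs (positions 263-326) --------------------
#
# Descriptors "<elem>-<elem>:<bond>" with bond in {any, single, double,
# triple, aromatic, ring}; element order is alphabetical within the pair.

_PAIR_BITS = [
    "C-C:any", "C-N:any", "C-O:any", "C-S:any", "C-P:any", "C-F:any",
    "C-Cl:any", "C-Br:any", "C-I:any", "C-Si:any", "B-C:any", "N-N:any",
    "N-O:any", "N-S:any", "N-P:any", "O-O:any", "O-P:any", "O-S:any",
    "P-P:any", "S-S:any", "O-Si:any", "B-O:any", "Na-O:any", "K-O:any",
    "Li-O:any", "Mg-O:any", "Ca-O:any", "Fe-O:any", "O-Zn:any", "Cu-O:any",
    "Mn-O:any", "C-Se:any", "As-O:any", "Al-O:any", "C-H:any", "H-N:any",
    "H-O:any", "H-S:any", "H-Si:any", "H-P:any", "B-H:any",
    "C-C:double", "C-N:double", "C-O:double", "C-S:double", "N-N:double",
    "N-O:double", "O-S:double", "O-P:double", "C-C:triple", "C-N:triple",
    "N-N:triple",
    "C-C:aromatic", "C-N:aromatic", "C-O:aromatic", "C-S:aromatic",
    "N-N:aromatic",
    "C-C:ring", "C-N:ring", "C-O:ring",
    "C-Sn:any", "C-Pb:any", "C-Hg:any", "C-Te:any",
]


# --- sections 4-7: SMARTS patterns (positions 327-880) ----------------------
#
# Entries are [smarts, min_count] or None (frozen-zero position).  Counts
# use unique substructure matches.


def _neighborhood_smarts() -> list[list[Any]]:
    """Atom-centred neighborhood patterns (sections 4 and 5)."""
    out: list[list[Any]] = []
    # central carbon with two/three heavy neighbors drawn from {C,N,O,S}
    pool = ["#6", "#7", "#8", "#16"]
    for combo in itertools.combinations_with_replacement(pool, 2):
        out.append([f"[#6](~[{combo[0]}])~[{combo[1]}]", 1])
    for combo in itertools.combinations_with_replacement(pool, 3):
        out.append([f"[#6](~[{combo[0]}])(~[{combo[1]}])~[{combo[2]}]", 1])
    # central nitrogen / oxygen / sulfur / phosphorus neighborhoods
    for center, combos in (
        ("#7", [("#6", "#6"), ("#6", "#8"), ("#8", "#8"), ("#6", "#7")]),
        ("#8", [("#6", "#6"), ("#6", "#7"), ("#6", "#15"), ("#6", "#16")]),
        ("#16", [("#6", "#6"), ("#8", "#8")]),
        ("#15", [("#8", "#8")]),
    ):
        for a, b in combos:
            out.append([f"[{center}](~[{a}])~[{b}]", 1])
    # quaternary / branched carbon centres
    out.append(["[#6](~[#6])(~[#6])(~[#6])~[#6]", 1])
    out.append(["[#6](~[#6])(~[#6])(~[#6])~[#8]", 1])
    out.append(["[#6](~[#6])(~[#6])(~[#6])~[#7]", 1])
    # section 5 style: hydrogen-explicit neighborhoods
    for smarts in (
        "[CX4H3]", "[CX4H2]", "[CX4H1]", "[CX4H0]",
        "[CX3H1]", "[CX3H0]", "[CX2H0]",
        "[NX3H2]", "[NX3H1]", "[NX3H0]", "[NX4H0+]",
        "[OX2H1]", "[OX2H0]", "[OX1]",
        "[SX2H1]", "[SX2H0]", "[SX4]", "[SX3]",
        "[PX4]", "[PX3]",
        "[cX3H1]", "[cX3H0]", "[nX2]", "[nX3H1]", "[oX2]", "[sX2]",
    ):
        out.append([smarts, 1])
    for count in (2, 4, 6):
        out.append(["[CX4H3]", count])
    for count in (4, 8, 12, 16, 20, 24, 30):
        out.append(["[CX4H2]", count])
    for count in (2, 3, 4, 6):
        out.append(["[OX2H1]", count])
    return out


def _structural_smarts() -> list[list[Any]]:
    """Functional-group and scaffold patterns (sections 6 and 7)."""
    groups = [
        # oxygen functions
        "[CX3](=O)[OX2H1]", "[CX3](=O)[OX1-]", "[CX3](=O)[OX2][#6]",
        "[CX3H1](=O)", "[#6][CX3](=O)[#6]", "[OX2H][CX4]", "[OX2H][cX3]",
        "[OX2]([CX4])[CX4]", "[OX2]([#6])[cX3]", "C1OC1",
        "[CX4]([OX2H])[CX4][OX2H]", "[CX4H]([OX2])[OX2]",
        "[CX3](=O)[OX2][CX3](=O)",
        # nitrogen functions
        "[CX3](=O)[NX3]", "[NX3H2][CX4]", "[NX3H1]([CX4])[CX4]",
        "[NX3]([CX4])([CX4])[CX4]", "[NX4+]", "[N+](C)(C)C",
        "NC(=N)N", "NC(=O)N", "[OX2][CX3](=O)[NX3]", "C#N",
        "[NX3]~[OX1]", "[NX2]=[CX3]", "[NX2]=[NX2]",
        "[NX3][CX4][CX3](=O)[OX2H1,OX1-]",
        # sulfur / phosphorus
        "[SX2H]", "[SX2]([#6])[#6]", "[#16X4](=O)(=O)", "OS(=O)(=O)O",
        "[#6][Sv4](=O)[#6]", "S=C", "[PX4](=O)", "OP(=O)(O)O",
        "[PX4](=O)([OX2][#6])[OX2][#6]", "[#6][OX2][PX4]",
        # unsaturation
        "C=C", "C#C", "C=CC=C", "C=CCC=C", "CC=CC",
        # aromatics and heteroaromatics
        "c1ccccc1", "c1ccc2ccccc2c1", "c1ccncc1", "c1cc[nH]c1",
        "c1c[nH]cn1", "c1c[nH]c2ccccc12", "c1ccc2[nX2]cccc2c1",
        "c1ccoc1", "c1ccsc1", "c1cnccn1", "c1cncnc1", "[a;!c]",
        "[cX3][OX2H]", "[cX3][NX3]", "[cX3][F,Cl,Br,I]", "[cX3][CX3](=O)",
        # saturated carbo/heterocycles
        "[CX4]1[OX2][CX4][CX4][CX4][CX4]1", "[CX4]1[OX2][CX4][CX4][CX4]1",
        "C1CCCCC1", "C1CCCC1", "C1CCNCC1", "C1CCNC1", "C1CCOC1",
        "C1CCC2CCCCC2C1", "[C;R](=O)[O;R]", "[C;R](=O)[N;R]", "O=C1CCCC1",
        # lipid scaffolds
        "OCC(O)CO", "OCC(O)COP(=O)", "OCC(O)COP(=O)(O)OCC[N+](C)(C)C",
        "OCC[N+](C)(C)C", "C(=O)OCC(COC(=O))OC(=O)", "C(=O)NC(CO)",
        "[CX3](=O)[NX3][CX4][CX4][OX2]", "CCCCCCCCC=C",
        # carbohydrate-like
        "OCC1OC(O)C(O)C1O", "OCC1OC(O)C(O)C(O)C1O",
        "[OX2H][CX4][CX4]([OX2H])[CX4][OX2H]",
        # halogens on carbon
        "[CX4](F)(F)F", "[CX4][Cl]", "[CX4][Br]", "[CX4][I]",
    ]
    out: list[list[Any]] = [[g, 1] for g in groups]
    # vicinal diol multiplicity (sugar discriminator)
    for count in (2, 3, 4):
        out.append(["[CX4]([OX2H])[CX4][OX2H]", count])
    # double-bond multiplicity (acyl unsaturation ladder)
    for count in (2, 3, 4, 5, 6):
        out.append(["C=C", count])
    for count in (2, 3):
        out.append(["C=CCC=C", count])
    # ester multiplicity (mono- vs di- vs tri-acyl glycerides)
    for count in (2, 3, 4):
        out.append(["[CX3](=O)[OX2][#6]", count])
    # amide / amine multiplicity
    for count in (2, 3):
        out.append(["[CX3](=O)[NX3]", count])
    # linear carbon chains of increasing length
    for length in (4, 5, 6, 7, 8, 10, 12, 14, 16, 18):
        out.append(["C" * length, 1])
    # aromatic atom totals
    for count in (5, 6, 10, 12):
        out.append(["a", count])
    return out


def build_layout() -> dict[str, Any]:
    """Construct the full 881-position layout as plain JSON-able data."""
    elements = _element_counts()
    rings = _ring_bits()
    pairs = list(_PAIR_BITS)
    smarts: list[Any] = _neighborhood_smarts() + _structural_smarts()
    n_named = len(elements) + len(rings) + len(pairs) + len(smarts)
    if n_named > N_BITS:  # pragma: no cover - layout authoring guard
        raise AssertionError(f"layout overfull: {n_named} > {N_BITS}")
    smarts = smarts + [None] * (N_BITS - n_named)
    assert len(elements) == 115 and len(rings) == 148
    return {
        "version": LAYOUT_VERSION,
        "n_bits": N_BITS,
        "sections": {
            "element_counts": [0, 114],
            "rings": [115, 262],
            "atom_pairs": [263, 326],
            "patterns": [327, 880],
        },
        "element_counts": elements,
        "rings": rings,
        "atom_pairs": pairs,
        "patterns": smarts,
    }


def layout_json() -> str:
    """The layout serialized exactly as shipped in the data directory."""
    return json.dumps(build_layout(), indent=None, separators=(",", ":"))
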