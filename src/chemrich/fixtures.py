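"""Synthetic self-contained test studies and a miniature chemical ontology.

The generator emulates the statistical structure a set-enrichment method
assumes: classes of structurally homologous real metabolites
(lysophosphatidylcholines, triacylglycerols, sphingomyelins, amino
acids, sugars, oxylipins, ...) whose member p-values are Uniform(0,1)
for null classes and stochastically small (Beta(a,1), a in (0,1]) for
planted enriched classes, with direction-consistent log-normal fold
changes.  Structures are curated real metabolites plus homologs obtained
by acyl-chain length/unsaturation edits, which produces realistic
within-class Tanimoto similarities (~0.8-0.95) and between-class
similarities (~0.1-0.4).  The miniature ontology mirrors MeSH tree
number semantics, including a parent/child specificity pair and one
deliberately unannotated class (sugar alcohols) so that similarity
rescue and new-cluster discovery are exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CompoundRecord, StudyTable
from .ontology import MeshTerm, OntologyDB

__all__ = [
    "ClassSpec",
    "FixtureSpec",
    "class_library",
    "generate_fixture_study",
    "default_fixture_spec",
    "mini_ontology",
]


# --- structure templates ----------------------------------------------------


def _tail(n_c: int, n_db: int) -> str:
    """Linear acyl tail of ``n_c`` carbons with ``n_db`` double bonds."""
    if n_db == 0:
        return "C" * n_c
    head = min(7, n_c - 3 * n_db)
    rest = n_c - head - 3 * n_db
    if head < 1 or rest < 0:
        raise ValueError(f"cannot place {n_db} double bonds in {n_c} carbons")
    return "C" * head + "C=CC" * n_db + "C" * rest


def _acyl(n_c: int, n_db: int) -> str:
    """Acyl group R-C(=O)- with ``n_c`` carbons in total."""
    return _tail(n_c - 1, n_db) + "C(=O)"


def _lpc(n_c: int, n_db: int) -> str:
    return _acyl(n_c, n_db) + "OCC(O)COP(=O)([O-])OCC[N+](C)(C)C"


def _pc(c1: int, d1: int, c2: int, d2: int) -> str:
    return (
        _acyl(c1, d1)
        + "OCC(OC(=O)"
        + _tail(c2 - 1, d2)
        + ")COP(=O)([O-])OCC[N+](C)(C)C"
    )


def _pe(c1: int, d1: int, c2: int, d2: int) -> str:
    return _acyl(c1, d1) + "OCC(OC(=O)" + _tail(c2 - 1, d2) + ")COP(=O)(O)OCCN"


def _tg(c1: int, d1: int, c2: int, d2: int, c3: int, d3: int) -> str:
    return (
        _acyl(c1, d1)
        + "OCC(OC(=O)"
        + _tail(c2 - 1, d2)
        + ")COC(=O)"
        + _tail(c3 - 1, d3)
    )


def _sphingomyelin(acyl_c: int, acyl_db: int, dihydro: bool = False) -> str:
    sphingoid = "CCCCCCCCCCCCC" + ("CC" if dihydro else "C=CC")
    return (
        sphingoid
        + "C(O)C(COP(=O)([O-])OCC[N+](C)(C)C)NC(=O)"
        + _tail(acyl_c - 1, acyl_db)
    )


def _fa(n_c: int, n_db: int) -> str:
    return "OC(=O)" + _tail(n_c - 1, n_db)


def _hydroxy_fa(n_c: int, n_db: int) -> str:
    # hydroxyl on a saturated carbon six positions from the methyl end
    return "OC(=O)" + _tail(n_c - 7, n_db) + "C(O)CCCCC"


_AMINO_ACIDS = [
    ("glycine", "NCC(=O)O"),
    ("alanine", "CC(N)C(=O)O"),
    ("serine", "OCC(N)C(=O)O"),
    ("threonine", "CC(O)C(N)C(=O)O"),
    ("aspartate", "NC(CC(=O)O)C(=O)O"),
    ("glutamate", "NC(CCC(=O)O)C(=O)O"),
    ("asparagine", "NC(=O)CC(N)C(=O)O"),
    ("glutamine", "NC(=O)CCC(N)C(=O)O"),
    ("lysine", "NCCCCC(N)C(=O)O"),
    ("arginine", "NC(CCCNC(=N)N)C(=O)O"),
    ("histidine", "NC(Cc1c[nH]cn1)C(=O)O"),
    ("proline", "OC(=O)C1CCCN1"),
]

_BCAA = [
    ("valine", "CC(C)C(N)C(=O)O"),
    ("leucine", "CC(C)CC(N)C(=O)O"),
    ("isoleucine", "CCC(C)C(N)C(=O)O"),
]

_AROMATIC_AA = [
    ("phenylalanine", "NC(Cc1ccccc1)C(=O)O"),
    ("tyrosine", "NC(Cc1ccc(O)cc1)C(=O)O"),
    ("tryptophan", "NC(Cc1c[nH]c2ccccc12)C(=O)O"),
]

_SULFUR_AA = [
    ("methionine", "CSCCC(N)C(=O)O"),
    ("cysteine", "NC(CS)C(=O)O"),
    ("cystathionine", "NC(CCSCC(N)C(=O)O)C(=O)O"),
]

_HEXOSES = [
    ("glucose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"),
    ("galactose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@H]1O"),
    ("mannose", "OC[C@H]1OC(O)[C@@H](O)[C@@H](O)[C@@H]1O"),
    ("fructose", "OCC1(O)OC[C@@H](O)[C@@H](O)[C@@H]1O"),
    ("allose", "OC[C@H]1OC(O)[C@H](O)[C@H](O)[C@H]1O"),
    ("altrose", "OC[C@H]1OC(O)[C@@H](O)[C@H](O)[C@@H]1O"),
]

_PENTOSES = [
    ("ribose", "OC[C@H]1OC(O)[C@H](O)[C@H]1O"),
    ("xylose", "OC[C@H]1OC(O)[C@H](O)[C@@H]1O"),
    ("arabinose", "OC[C@H]1OC(O)[C@@H](O)[C@@H]1O"),
    ("lyxose", "OC[C@H]1OC(O)[C@@H](O)[C@H]1O"),
]

_DISACCHARIDES = [
    ("sucrose", "OC[C@H]1O[C@](CO)(O[C@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)[C@@H](O)[C@@H]1O"),
    ("maltose", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O[C@H]1O[C@H](CO)[C@@H](O)[C@H](O)[C@H]1O"),
    ("trehalose", "OC[C@H]1OC(O[C@H]2O[C@H](CO)[C@@H](O)[C@H](O)[C@H]2O)[C@H](O)[C@@H](O)[C@@H]1O"),
]

_SUGAR_ALCOHOLS = [
    ("sorbitol", "OCC(O)C(O)C(O)C(O)CO"),
    ("mannitol", "OC[C@@H](O)[C@@H](O)[C@H](O)[C@H](O)CO"),
    ("xylitol", "OCC(O)C(O)C(O)CO"),
    ("erythritol", "OCC(O)C(O)CO"),
]

_BUTYRATES = [
    ("butyrate", "CCCC(=O)O"),
    ("2-hydroxybutyrate", "CCC(O)C(=O)O"),
    ("3-hydroxybutyrate", "CC(O)CC(=O)O"),
    ("2-aminobutyrate", "CCC(N)C(=O)O"),
]

_TCA_ACIDS = [
    ("citrate", "OC(=O)CC(O)(CC(=O)O)C(=O)O"),
    ("isocitrate", "OC(=O)C(O)C(CC(=O)O)C(=O)O"),
    ("aconitate", "OC(=O)/C=C(\\CC(=O)O)C(=O)O"),
]

_PYRIDINES = [
    ("nicotinamide", "NC(=O)c1cccnc1"),
    ("nicotinic acid", "OC(=O)c1cccnc1"),
    ("pyridoxine", "Cc1ncc(CO)c(CO)c1O"),
]

_INDOLES = [
    ("indole-3-acetate", "OC(=O)Cc1c[nH]c2ccccc12"),
    ("indole-3-lactate", "OC(=O)C(O)Cc1c[nH]c2ccccc12"),
    ("indole-3-propionate", "OC(=O)CCc1c[nH]c2ccccc12"),
]

_ONIUM = [
    ("betaine", "C[N+](C)(C)CC(=O)[O-]"),
    ("carnitine", "C[N+](C)(C)CC(O)CC(=O)[O-]"),
    ("choline", "C[N+](C)(C)CCO"),
]


def class_library() -> dict[str, list[tuple[str, str]]]:
    """Curated (name, SMILES) templates per class, deterministic order."""
    lpc_sat = [(f"LPC {c}:0", _lpc(c, 0)) for c in (14, 15, 16, 17, 18, 20)]
    lpc_unsat = [
        (f"LPC {c}:{d}", _lpc(c, d))
        for c, d in [(16, 1), (18, 1), (18, 2), (18, 3), (20, 3), (20, 4),
                     (22, 4), (22, 5), (22, 6), (24, 4), (24, 5), (24, 6)]
    ]
    tg_sat = [
        (f"TG {3 * c}:0", _tg(c, 0, c, 0, c, 0)) for c in (14, 15, 16, 17, 18)
    ]
    tg_unsat = [
        (f"TG {c1}:{d1}/{c2}:{d2}/{c3}:{d3}", _tg(c1, d1, c2, d2, c3, d3))
        for c1, d1, c2, d2, c3, d3 in [
            (16, 0, 18, 1, 18, 1), (16, 0, 18, 1, 18, 2), (18, 1, 18, 1, 18, 1),
            (18, 1, 18, 2, 18, 2), (16, 1, 18, 1, 18, 2), (18, 2, 18, 2, 18, 2),
            (16, 0, 18, 2, 20, 4), (18, 1, 18, 2, 20, 4), (16, 0, 16, 1, 18, 1),
            (18, 1, 18, 1, 20, 4), (16, 1, 18, 2, 22, 6), (18, 2, 18, 2, 22, 6),
        ]
    ]
    pc = [
        (f"PC {c1 + c2}:{d1 + d2}", _pc(c1, d1, c2, d2))
        for c1, d1, c2, d2 in [
            (16, 0, 18, 1), (16, 0, 18, 2), (18, 0, 18, 1), (18, 1, 18, 1),
            (16, 0, 20, 4), (18, 0, 20, 4), (16, 0, 22, 6), (18, 1, 18, 2),
        ]
    ]
    pe = [
        (f"PE {c1 + c2}:{d1 + d2}", _pe(c1, d1, c2, d2))
        for c1, d1, c2, d2 in [
            (16, 0, 18, 1), (16, 0, 18, 2), (18, 0, 18, 1), (16, 0, 20, 4),
        ]
    ]
    sm_unsat = [
        (f"SM d18:1/{c}:{d}", _sphingomyelin(c, d))
        for c, d in [(16, 0), (18, 0), (20, 0), (22, 0), (24, 0), (24, 1),
                     (22, 1), (16, 1)]
    ]
    sm_sat = [
        (f"SM d18:0/{c}:0", _sphingomyelin(c, 0, dihydro=True))
        for c in (16, 18, 22, 24)
    ]
    fa_sat = [
        (f"FA {c}:0", _fa(c, 0)) for c in (12, 14, 15, 16, 17, 18, 20, 22)
    ]
    fa_unsat = [
        (f"FA {c}:{d}", _fa(c, d))
        for c, d in [(16, 1), (18, 1), (18, 2), (18, 3), (20, 4), (20, 5), (22, 6)]
    ]
    oxylipins = [
        (f"HFA {c}:{d}", _hydroxy_fa(c, d))
        for c, d in [(18, 0), (18, 1), (18, 2), (20, 1), (20, 2), (20, 3),
                     (20, 4), (22, 4), (16, 0), (22, 3)]
    ]
    return {
        "saturated lysophosphatidylcholines": lpc_sat,
        "unsaturated lysophosphatidylcholines": lpc_unsat,
        "saturated triacylglycerols": tg_sat,
        "unsaturated triacylglycerols": tg_unsat,
        "phosphatidylcholines": pc,
        "phosphatidylethanolamines": pe,
        "sphingomyelins": sm_unsat,
        "saturated sphingomyelins": sm_sat,
        "saturated fatty acids": fa_sat,
        "unsaturated fatty acids": fa_unsat,
        "hydroxy fatty acids": oxylipins,
        "amino acids": _AMINO_ACIDS,
        "branched-chain amino acids": _BCAA,
        "aromatic amino acids": _AROMATIC_AA,
        "sulfur amino acids": _SULFUR_AA,
        "hexoses": _HEXOSES,
        "pentoses": _PENTOSES,
        "disaccharides": _DISACCHARIDES,
        "sugar alcohols": _SUGAR_ALCOHOLS,
        "butyrates": _BUTYRATES,
        "tricarboxylic acids": _TCA_ACIDS,
        "pyridines": _PYRIDINES,
        "indoles": _INDOLES,
        "onium compounds": _ONIUM,
    }


# --- study generation -------------------------------------------------------


@dataclass(frozen=True)
class ClassSpec:
    """One planted class: label, size, and its effect model."""

    label: str
    n: int
    enriched: bool = False
    beta_a: float = 0.1  # Beta(a, 1) shape for enriched member p-values
    frac_increased: float = 0.5

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("class size must be >= 1")
        if not (0 < self.beta_a <= 1):
            raise ValueError("beta_a must lie in (0, 1]")


@dataclass
class FixtureSpec:
    classes: list[ClassSpec]
    seed: int = 0
    fold_sigma: float = 0.4  # log-scale spread of fold-change magnitudes
    fold_mu: float = 0.9  # log-scale mean magnitude (~2.5-fold)


def default_fixture_spec(seed: int = 0) -> FixtureSpec:
    """Default study: a diabetes-like mix of enriched and null classes."""
    return FixtureSpec(
        classes=[
            ClassSpec("unsaturated lysophosphatidylcholines", 9, True, 0.05, 0.0),
            ClassSpec("saturated lysophosphatidylcholines", 3, True, 0.05, 0.0),
            ClassSpec("unsaturated triacylglycerols", 9, True, 0.05, 1.0),
            ClassSpec("saturated triacylglycerols", 4, True, 0.05, 1.0),
            ClassSpec("phosphatidylcholines", 8, True, 0.1, 0.1),
            ClassSpec("sphingomyelins", 8, True, 0.15, 0.9),
            ClassSpec("saturated sphingomyelins", 4, True, 0.15, 1.0),
            ClassSpec("branched-chain amino acids", 3, True, 0.05, 1.0),
            ClassSpec("hexoses", 6, True, 0.2, 0.9),
            ClassSpec("amino acids", 12),
            ClassSpec("aromatic amino acids", 3),
            ClassSpec("sulfur amino acids", 3),
            ClassSpec("pentoses", 3),
            ClassSpec("disaccharides", 3),
            ClassSpec("sugar alcohols", 4),
            ClassSpec("saturated fatty acids", 6),
            ClassSpec("unsaturated fatty acids", 5),
            ClassSpec("hydroxy fatty acids", 8),
            ClassSpec("butyrates", 3),
            ClassSpec("tricarboxylic acids", 3),
            ClassSpec("pyridines", 3),
            ClassSpec("indoles", 3),
            ClassSpec("onium compounds", 3),
        ],
        seed=seed,
    )


def generate_fixture_study(
    spec: FixtureSpec | None = None, seed: int | None = None
) -> tuple[StudyTable, pd.DataFrame]:
    """Generate a synthetic study table plus its truth labels.

    Member p-values are Uniform(0,1) for null classes and Beta(a,1) for
    enriched classes; fold changes are log-normal in magnitude with the
    direction drawn per member from the class's ``frac_increased``.
    Fully deterministic under a fixed seed.
    """
    if spec is None:
        spec = default_fixture_spec(seed if seed is not None else 0)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    library = class_library()
    records, truth = [], []
    for cls in spec.classes:
        if cls.label not in library:
            raise ValueError(f"unknown fixture class {cls.label!r}")
        templates = library[cls.label]
        if cls.n > len(templates):
            raise ValueError(
                f"class {cls.label!r}: requested {cls.n} members but only "
                f"{len(templates)} templates available"
            )
        for name, smiles in templates[: cls.n]:
            p = (
                float(rng.beta(cls.beta_a, 1.0))
                if cls.enriched
                else float(rng.uniform())
            )
            increased = bool(rng.uniform() < cls.frac_increased)
            magnitude = float(
                np.exp(abs(rng.normal(spec.fold_mu, spec.fold_sigma)))
            )
            fc = magnitude if increased else 1.0 / magnitude
            records.append(
                CompoundRecord(
                    compound_id=name,
                    name=name,
                    smiles=smiles,
                    effect_p=p,
                    fold_change=fc,
                )
            )
            truth.append(
                {
                    "compound_id": name,
                    "true_class": cls.label,
                    "enriched": cls.enriched,
                    "increased": increased,
                }
            )
    for rec in records:
        rec.validate()
    return (
        StudyTable(records=records, source=f"<fixture seed={spec.seed}>"),
        pd.DataFrame(truth),
    )


# --- miniature ontology -----------------------------------------------------

# (term_id, name, tree number); tree numbers follow MeSH dot semantics.
# "sugar alcohols" is deliberately absent so its members exercise the
# similarity rescue / new-cluster path.
_MINI_TERMS = [
    ("68009005", "onium compounds", "D02.675"),
    ("68007211", "quaternary ammonium compounds", "D02.092.877"),
    ("68000596", "amino acids", "D12.125"),
    ("68000597", "branched-chain amino acids", "D12.125.067"),
    ("68000598", "aromatic amino acids", "D12.125.166"),
    ("68000599", "sulfur amino acids", "D12.125.740"),
    ("68002241", "carboxylic acids", "D02.241"),
    ("68002242", "tricarboxylic acids", "D02.241.755"),
    ("68002110", "butyrates", "D02.241.081.337.200"),
    ("68006601", "hydroxybutyrates", "D02.241.081.337.200.450"),
    ("68011725", "pyridines", "D03.383.725"),
    ("68007211-i", "indoles", "D03.633.100.473"),
    ("68009005-c", "carbohydrates", "D09"),
    ("68009006", "monosaccharides", "D09.100"),
    ("68006601-h", "hexoses", "D09.100.400"),
    ("68010427", "pentoses", "D09.100.700"),
    ("68004220", "disaccharides", "D09.200"),
    ("68008055", "lipids", "D10"),
    ("68008056", "glycerophospholipids", "D10.570"),
    ("68008244", "lysophosphatidylcholines", "D10.570.100"),
    ("68010714", "phosphatidylcholines", "D10.570.200"),
    ("68010715", "phosphatidylethanolamines", "D10.570.300"),
    ("68013107", "sphingolipids", "D10.673"),
    ("68013109", "sphingomyelins", "D10.673.100"),
    ("68013110", "saturated sphingomyelins", "D10.673.100.500"),
    ("68014280", "triacylglycerols", "D10.212"),
    ("68005227", "fatty acids", "D10.251"),
    ("68005228", "unsaturated fatty acids", "D10.251.400"),
]

# class label in the library -> leaf term name used for annotation
_CLASS_TO_TERM = {
    "saturated lysophosphatidylcholines": "lysophosphatidylcholines",
    "unsaturated lysophosphatidylcholines": "lysophosphatidylcholines",
    "saturated triacylglycerols": "triacylglycerols",
    "unsaturated triacylglycerols": "triacylglycerols",
    "phosphatidylcholines": "phosphatidylcholines",
    "phosphatidylethanolamines": "phosphatidylethanolamines",
    "sphingomyelins": "sphingomyelins",
    "saturated sphingomyelins": "saturated sphingomyelins",
    "saturated fatty acids": "fatty acids",
    "unsaturated fatty acids": "unsaturated fatty acids",
    "hydroxy fatty acids": None,  # covered by the lipid rules instead
    "amino acids": "amino acids",
    "branched-chain amino acids": "branched-chain amino acids",
    "aromatic amino acids": "aromatic amino acids",
    "sulfur amino acids": "sulfur amino acids",
    "hexoses": "hexoses",
    "pentoses": "pentoses",
    "disaccharides": "disaccharides",
    "sugar alcohols": None,  # deliberately unannotated
    "butyrates": "butyrates",
    "tricarboxylic acids": "tricarboxylic acids",
    "pyridines": "pyridines",
    "indoles": "indoles",
    "onium compounds": "quaternary ammonium compounds",
}


def mini_ontology() -> OntologyDB:
    """Fixture ontology covering the class library (name-keyed annotations).

    The betaine entry reproduces the parent/child specificity pattern: it
    is annotated with both 'onium compounds' (D02.675) and the deeper
    'quaternary ammonium compounds' (D02.092.877).
    """
    db = OntologyDB()
    for term_id, name, tree in _MINI_TERMS:
        db.add_term(MeshTerm(term_id, name, frozenset({tree})))
    by_name = {t.name: t.term_id for t in db.terms.values()}
    for label, entries in class_library().items():
        term_name = _CLASS_TO_TERM[label]
        if term_name is None:
            continue
        for name, _smiles in entries:
            db.annotate("name", name, by_name[term_name])
    for name, _smiles in _ONIUM:
        db.annotate("name", name, by_name["onium compounds"])
    return db
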