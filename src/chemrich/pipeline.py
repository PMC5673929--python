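"""End-to-end enrichment run: from study table to result tables and plots.

Stage order: substructure fingerprints; direct ontology annotation;
lipid rules (fatty acids / oxylipins / prostaglandins); greedy
non-overlapping class selection; similarity rescue of unannotated
compounds (> 0.90, then > 0.75, against directly annotated compounds
only); new-cluster discovery among the remainder; saturated/unsaturated
split of lipid classes; per-set KS statistics; Benjamini-Hochberg FDR
across tested sets; ordering of sets along the similarity tree.  Every
input compound ends up in exactly one of: a tested set, an untested
small set, or the singleton list.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, enrichment, lipids
from .fingerprints import SimilarityMatrix, similarity_matrix
from .io import StudyTable
from .ontology import ChemSet, ClassAssignment, OntologyDB, direct_annotations, select_nonoverlapping_classes

__all__ = ["RunConfig", "RunResult", "run_chemrich", "write_results"]


@dataclass
class RunConfig:
    """All tunable constants of an enrichment run."""

    t_high: float = 0.90  # strict Tanimoto cutoff for similarity rescue
    t_low: float = 0.75  # relaxed fallback cutoff
    min_set_size: int = 3  # minimum members for a tested class
    alpha: float = 0.05  # raw per-metabolite significance threshold
    min_cluster_size: int = 3  # dynamic tree cut minimum
    deep_split: int = 2  # tree cut sensitivity (0..3)
    saturation_mode: str = "structural"  # or "literal"
    plot_filter: str = "p"  # "p" (raw set p) or "fdr"
    plot_cutoff: float = 0.05
    display_floor: float = 1e-30  # -log10 floor, display only
    seed: int = 0  # reserved for jittered plot layouts

    def __post_init__(self):
        if not (0 < self.t_low < self.t_high <= 1):
            raise ValueError("thresholds must satisfy 0 < t_low < t_high <= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunResult:
    """Everything an enrichment run produces."""

    rows: list[enrichment.EnrichmentRow]
    assignment: ClassAssignment
    tree: clustering.Dendrogram
    sim: SimilarityMatrix
    untested: list[ChemSet]
    config: RunConfig
    m_tested: int

    def results_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "set": [r.set_label for r in self.rows],
                "size": [r.size for r in self.rows],
                "p_value": [r.ks_p for r in self.rows],
                "fdr": [r.fdr for r in self.rows],
                "altered": [r.n_altered for r in self.rows],
                "increased": [r.n_increased for r in self.rows],
                "decreased": [r.n_decreased for r in self.rows],
                "flat_fold_change": [r.n_flat_fold_change for r in self.rows],
                "tree_position": [r.tree_position for r in self.rows],
                "provenance": [r.provenance for r in self.rows],
            }
        )
        return df.sort_values("p_value", kind="stable").reset_index(drop=True)

    def membership_frame(self) -> pd.DataFrame:
        rows = [
            {"compound_id": cid, "set_label": label, "provenance": prov}
            for cid, (label, prov) in sorted(self.assignment.assignments.items())
        ]
        return pd.DataFrame(rows)


def _set_provenance(members: list[str], assignment: ClassAssignment) -> str:
    provs = {assignment.assignments[cid][1] for cid in members}
    for p in ("mesh_direct", "lipid_rule", "tree_cut_new"):
        if p in provs:
            return p
    return sorted(provs)[0]


def run_chemrich(
    study: StudyTable,
    ontology: OntologyDB,
    config: RunConfig | None = None,
    lipid_rules: lipids.LipidRuleSet | None = None,
) -> RunResult:
    """Execute the full enrichment analysis on a validated study table."""
    config = config or RunConfig()
    rules = lipid_rules or lipids.default_rules()

    # 1. fingerprints + similarity matrix + tree over all compounds
    sim = similarity_matrix(study)
    tree = clustering.build_tree(sim)

    # 2. direct ontology annotation
    annotations = {rec.compound_id: direct_annotations(rec, ontology) for rec in study}

    # 3. lipid rules: first-match-wins class, takes precedence
    assignment = ClassAssignment()
    rule_matched: set[str] = set()
    for rec in study:
        target = lipids.classify_lipid(rec.smiles, rules)
        if target is not None:
            assignment.add(rec.compound_id, target, "lipid_rule")
            rule_matched.add(rec.compound_id)

    # 4. greedy non-overlapping class selection on annotated compounds
    mesh_annotations = {
        cid: terms
        for cid, terms in annotations.items()
        if terms and cid not in rule_matched
    }
    mesh_assignment = select_nonoverlapping_classes(
        mesh_annotations, min_size=config.min_set_size
    )
    for cid, (label, prov) in mesh_assignment.assignments.items():
        assignment.add(cid, label, prov)

    # 5. similarity rescue against directly annotated compounds only
    refs = [
        (sim.fingerprints[cid], label)
        for cid, (label, prov) in assignment.assignments.items()
        if prov == "mesh_direct"
    ]
    unassigned = [
        rec for rec in study if rec.compound_id not in assignment.assignments
    ]
    still_unassigned = []
    for rec in unassigned:
        hit = (
            clustering.assign_unmapped(
                rec,
                refs,
                t_high=config.t_high,
                t_low=config.t_low,
                fingerprint=sim.fingerprints[rec.compound_id],
            )
            if refs
            else None
        )
        if hit is not None:
            assignment.add(rec.compound_id, hit[0], hit[1])
        else:
            still_unassigned.append(rec)

    # 6. new-cluster discovery among the remainder
    named_refs: dict[str, list] = {}
    for label, members in assignment.classes().items():
        named_refs[label] = [sim.fingerprints[cid] for cid in members]
    new_sets, leftovers = clustering.detect_new_clusters(
        still_unassigned,
        sim=sim,
        min_cluster_size=config.min_cluster_size,
        deep_split=config.deep_split,
        named_refs=named_refs or None,
    )
    for chemset in new_sets:
        for cid in chemset.compound_ids:
            assignment.add(cid, chemset.label, "tree_cut_new")
    for cid in leftovers:
        assignment.add(cid, cid, "singleton")

    # 7. saturated / unsaturated split of lipid classes
    for label, members in sorted(assignment.classes().items()):
        records = [study.get(cid) for cid in members]
        parts = lipids.split_saturation(
            label, records, rules, mode=config.saturation_mode
        )
        if len(parts) == 1 and parts[0].label == label:
            continue
        for part in parts:
            assignment.relabel(label, part.label, part.compound_ids)

    # 8.-10. KS per set, BH across tested sets, tree order
    classes = assignment.classes()
    tested, untested = [], []
    for label in sorted(classes):
        members = sorted(classes[label])
        chemset = ChemSet(label, members, _set_provenance(members, assignment))
        (tested if len(members) >= config.min_set_size else untested).append(chemset)

    rows = [
        enrichment.set_statistics(cs, study, alpha=config.alpha) for cs in tested
    ]
    m = len(rows)
    fdr = enrichment.bh_fdr({r.set_label: r.ks_p for r in rows}, m=m)
    order = clustering.tree_order(tree, assignment)
    position = {label: i + 1 for i, label in enumerate(order)}
    for row in rows:
        row.fdr = fdr[row.set_label]
        row.tree_position = position.get(row.set_label, 0)
    rows.sort(key=lambda r: (r.ks_p, r.set_label))

    # conservation check: every compound in exactly one bucket
    n_assigned = len(assignment.assignments)
    if n_assigned != len(study):
        missing = {r.compound_id for r in study} - set(assignment.assignments)
        raise RuntimeError(f"compounds lost in pipeline: {sorted(missing)}")

    return RunResult(
        rows=rows,
        assignment=assignment,
        tree=tree,
        sim=sim,
        untested=untested,
        config=config,
        m_tested=m,
    )


def write_results(result: RunResult, out_dir: str | Path, study: StudyTable) -> dict[str, Path]:
    """Write all result tables, the Newick tree and the parse report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["enrichment"] = out / "enrichment_results.tsv"
    result.results_frame().to_csv(paths["enrichment"], sep="\t", index=False)

    paths["membership"] = out / "cluster_membership.tsv"
    result.membership_frame().to_csv(paths["membership"], sep="\t", index=False)

    paths["untested"] = out / "untested_sets.tsv"
    pd.DataFrame(
        [
            {"set": s.label, "size": len(s), "members": ";".join(s.compound_ids)}
            for s in result.untested
        ],
        columns=["set", "size", "members"],
    ).to_csv(paths["untested"], sep="\t", index=False)

    paths["newick"] = out / "similarity_tree.nwk"
    paths["newick"].write_text(clustering.export_newick(result.tree) + "\n")

    paths["parse_report"] = out / "parse_report.txt"
    paths["parse_report"].write_text(study.parse_report())

    paths["config"] = out / "run_config.yaml"
    result.config.to_yaml(paths["config"])
    return paths
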