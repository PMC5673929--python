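# Methods

## Overview

`chemrich` performs chemical similarity enrichment analysis for
metabolomics: instead of mapping identified metabolites onto sparse
biochemical pathway databases, it groups them into **study-specific,
non-overlapping sets** defined by chemical ontology membership and
structural similarity, and then tests each set with a **self-contained**
statistic whose p-value does not depend on any background compound
database.

The unit of inference is the set of per-metabolite raw p-values.  Under
the null hypothesis that a set is unaffected by the studied contrast,
its member p-values are draws from Uniform(0,1).  Each set is therefore
scored with a two-sided one-sample Kolmogorov–Smirnov (KS) test of its
member p-values against Uniform(0,1):

    D = max_i  max( i/n − p_(i) ,  p_(i) − (i−1)/n )

with the exact small-sample distribution of D used for n < 100 and the
asymptotic Kolmogorov distribution beyond.  Set-level p-values are
adjusted across the m tested sets with the Benjamini–Hochberg step-up:
adjusted_(i) = min_{j≥i}( p_(j) · m / j ), capped at 1.

## Set construction

Sets are built in a fixed stage order; each compound is assigned exactly
once, and every stage records its provenance:

1. **Fingerprints.** Every SMILES is converted to an 881-position binary
   substructure fingerprint (below) and the pairwise Tanimoto matrix
   T(A,B) = AB/(A+B−AB) is computed, where A and B are the set-bit
   counts of the two molecules and AB the shared count.
2. **Direct ontology annotation** (`mesh_direct`). Compounds are looked
   up in a MeSH-style ontology by PubChem CID, canonical SMILES, then
   normalized name.  Terms carry dot-delimited tree numbers
   (`D02.092.877`); depth encodes specificity, and a compound *carries*
   a term when any of its tree numbers has that term's tree number as a
   dot-prefix.
3. **Lipid rules** (`lipid_rule`). Fatty acids, hydroxy-/epoxy-/oxo-
   fatty acids (oxylipins) and prostaglandins are recognized directly
   from structure by an ordered first-match-wins rule file
   (`data/lipid_rules.yaml`): carboxylic-acid terminus plus a minimum
   chain length of 8 carbons for plain fatty acids; additional
   hydroxyl/epoxide/ketone functions for the oxylipin subclasses; a
   five-membered carbocycle bearing two chains plus the acid terminus
   for prostaglandins.  Patterns are SMARTS evaluated on the sanitized
   Kekulé structure, so the outcome does not depend on how the input
   SMILES was written.
4. **Non-overlapping class selection.** Greedy, from the most specific
   ontology level upward: a term becomes a class once at least
   `min_set_size` (default 3) still-unassigned compounds carry it; its
   carriers are then removed from consideration.  Ties between equally
   specific candidates go to the larger prospective class, then to the
   lexicographically smaller term name, which makes the assignment
   independent of input row order.  Compounds never absorbed into a
   class keep their own most specific term as a singleton annotation.
5. **Similarity rescue** (`similarity_090` / `similarity_075`).
   Unannotated compounds are compared against the directly annotated
   compounds only (never against other rescued compounds, to prevent
   transitive drift).  The nearest neighbour's class is adopted at
   Tanimoto strictly > 0.90, or, failing that, strictly > 0.75; ties at
   the maximum go to the class with more reference members, then to the
   lexicographically smaller label.
6. **New-cluster discovery** (`tree_cut_new`). The compounds still
   unassigned are clustered on their own similarity subtree; every
   cluster of at least `min_cluster_size` members becomes a new set
   labelled `Cluster_k`, suffixed `near <label>` when its best Tanimoto
   similarity to a named set reaches 0.5.  Remaining compounds become
   singletons.
7. **Saturation split.** A class whose label is on the configurable
   lipid-class list is split into `Unsaturated_<label>` /
   `Saturated_<label>` when at least three members contain a
   carbon–carbon double bond and at least one does not; when all
   members are unsaturated the class is relabelled as a whole.
   Double-bond detection defaults to bond-order inspection of the
   Kekulé structure (`structural`); a `literal` mode searches the plain
   token `C=C` in the canonical Kekulé SMILES for compatibility with
   regular-expression implementations.  The two agree on acyl chains
   and differ only for ring double bonds written with ring-closure
   digits (e.g. `C1=CCCCC1`), which cannot occur in acyl chains.

Sets smaller than `min_set_size` are excluded from testing and reported
in a separate untested table, so the accounting invariant holds: every
input compound lies in exactly one of tested sets, untested sets, or
the singleton list (plus the parse-report rows dropped on input).

## The similarity tree and its decomposition

The tree is average-linkage hierarchical clustering of the
dissimilarity d = 1 − T.  Leaf ordering is canonicalized (the child
with the smaller minimum leaf label goes left at every merge) so tree
positions, the Newick export and plots are reproducible across
platforms and row orders.  Sets are placed on the x-axis of the impact
plot by the median canonical position of their member leaves.

Clusters are detected with an adaptive (dynamic) tree cut implemented
here:

* top-down, a node is split into its two branches when the mean
  between-branch distance exceeds the larger mean within-branch
  distance by more than a gap threshold set by `deep_split`
  (0 → 0.25, 1 → 0.15, 2 → 0.10 (default), 3 → 0.05, on the 0–1
  distance scale);
* branches below `min_cluster_size` are shed as stragglers while the
  large branch is descended further; stragglers are re-attached
  PAM-style to the closest cluster when their average distance to it is
  within that cluster's mean internal distance plus three gaps;
* finally, any two clusters whose between-cluster similarity reaches
  the within-cluster similarity of either are re-merged, so every
  reported cluster is more similar internally than to any other
  cluster.

The criteria this construction is validated against: clearly planted
partitions (within-T ≈ 0.85, between-T ≈ 0.25, cluster size ≥ 4) are
recovered with adjusted Rand index 1.0; a uniform matrix yields a
single cluster; all reported clusters respect the minimum size.

## The 881-bit substructure fingerprint

No installed toolkit computes the PubChem/CACTVS substructure
fingerprint, so it is implemented here following the published section
layout: element-count thresholds (positions 0–114), ring features
(115–262), bonded element pairs (263–326) and structural patterns
(327–880).  The element-count thresholds follow the public
specification; the ring section is evaluated on RDKit's smallest set of
smallest rings rather than the original extended ring ensemble, and the
pattern sections use a curated SMARTS set (functional groups, chain
lengths, unsaturation ladders, lipid and carbohydrate scaffolds,
atom-centred neighborhoods).  Positions without a reproducible original
definition are frozen to constant zero; since Tanimoto similarity only
sees set bits, constant-zero positions change no pairwise value.  The
complete definition of every position ships as
`data/fingerprint_layout.json` and is unit-tested against the in-code
source, so matrices are reproducible across releases.

One aromaticity model (RDKit default sanitization) is applied before
all pattern matching; the same molecule always yields identical bits
regardless of the SMILES spelling (property-tested over random SMILES
rewritings).  On the bundled metabolite library this fingerprint gives
within-class Tanimoto ≈ 0.8–0.99 and between-class ≈ 0.1–0.4, the
regime the 0.90/0.75 rescue cutoffs assume.  Positionwise identity
with the original CACTVS bits is not claimed and is not needed: all
downstream decisions are threshold comparisons on Tanimoto values.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `t_high` | 0.90 | strict Tanimoto cutoff for similarity rescue (strictly greater) |
| `t_low` | 0.75 | relaxed fallback cutoff |
| `min_set_size` | 3 | minimum members for a class / tested set |
| `alpha` | 0.05 | raw per-metabolite threshold for "altered" counts |
| `min_cluster_size` | 3 | dynamic tree cut minimum cluster size |
| `deep_split` | 2 | tree-cut sensitivity, 0 (coarse) – 3 (fine) |
| `saturation_mode` | structural | C=C detection: bond orders vs literal token |
| `plot_filter` | p | impact-plot node filter: raw set p or FDR |
| `plot_cutoff` | 0.05 | filter cutoff |
| `display_floor` | 1e-30 | −log10 floor for plotting only, never stored |

`m` for the BH adjustment is the number of sets actually tested (all
sets of size ≥ 3, including similarity-only and new clusters), not
only the significant ones.  "Altered" members are counted at raw
p < alpha; altered members with fold change exactly 1 count in neither
direction and are surfaced in a separate column.

## Numerical choices and degenerate inputs

* Exact KS p-values come from the Birnbaum-style exact distribution of
  D (scipy's `kstwo`); ties among member p-values keep the exact method
  with a logged warning, because rounded p-values are common and the
  asymptotic approximation is badly wrong for small sets.
* A p-value of exactly 0 is accepted and passed through unmodified.
* Tanimoto of two empty fingerprints is defined as 0.0 (never occurs
  for real organic molecules; avoids 0/0).
* A compound with zero variance in both groups of the convenience
  t-test utility gets p = 1 and a flag rather than an exception.
* Fold change exactly 1 is neither increased nor decreased.
* All tie-breaks (class selection, rescue, cluster numbering, leaf
  ordering, output sorting) are total, so a rerun with identical inputs
  and configuration is byte-identical.

## The synthetic-data generator

`chemrich.fixtures` generates fully self-contained test studies from a
curated library of ~130 real metabolite structures (saturated and
unsaturated lysophosphatidylcholines, phosphatidylcholines and
-ethanolamines, triacylglycerols, sphingomyelins and their dihydro
(saturated) counterparts, fatty acids, hydroxy fatty acids, amino acid
groups, sugars, sugar alcohols, organic acids, pyridines, indoles,
onium compounds).  Homologs are produced by acyl-chain length and
unsaturation edits, which yields the realistic within/between-class
similarity structure noted above.  Member p-values are Uniform(0,1) for
null classes and Beta(a,1) with a ∈ (0,1] (default 0.1) for planted
enriched classes; fold-change magnitudes are log-normal
(exp|N(0.9, 0.4)| ≈ 2.5-fold median) with the direction drawn per
member from the class's `frac_increased`.  The default study spec mixes
strongly enriched lipid classes with null classes, mirroring a
diabetes-like contrast.

The companion miniature ontology (~28 terms) mirrors MeSH tree-number
semantics, contains a parent/child specificity pair (betaine maps to
both `D02.675` "onium compounds" and the deeper `D02.092.877`
"quaternary ammonium compounds"), and deliberately omits the sugar
alcohols so that the rescue and new-cluster paths are exercised in
every end-to-end run.

What the generator does **not** emulate: instrument noise and missing
values, correlated member p-values within a set, identification errors,
and the long tail of singleton chemistry in real untargeted data.
Passing tests on fixtures therefore demonstrate the statistical and
structural correctness of the machinery, not performance on any
particular real study.

## Known limitations

* Ring-feature bits approximate the original extended-ring definition
  with SSSR; molecules whose similarity hinges on fused-ring subtleties
  may differ slightly from the original tool's values.
* The lipid rule file reproduces the intended categories, but
  pattern-for-pattern identity with the original implementation's
  regular expressions cannot be established from the literature.
* The dynamic tree cut is this package's own adaptive construction; it
  satisfies the published algorithm's contract (branch-shape-driven
  clusters, minimum size, PAM-like straggler assignment) but is not a
  line-for-line port, so exact cluster counts on a given study may
  require scanning `deep_split` over its 0–3 grid.
* Problem sizes used by the test suite and the acceptance script are
  chosen for fast, deterministic runs (studies of ~116 compounds,
  10^5–10^6-sample Monte-Carlo checks, 100–200 simulation seeds); all
  are configurable upward.
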