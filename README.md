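# chemrich

Chemical similarity enrichment analysis for metabolomics datasets.

Typical metabolomics studies identify 100–800 metabolites, but roughly
half of them — complex lipids and oxylipins above all — map to no
curated biochemical pathway, and pathway-based enrichment p-values
additionally depend on the size of an arbitrary background database.
`chemrich` takes a different route: it builds **study-specific,
non-overlapping sets of structurally related metabolites** from a
chemical ontology (MeSH-style terms with dot-delimited tree numbers),
substructure Tanimoto similarity and lipid classification rules, and
scores each set with a **self-contained statistic** that needs no
background database at all.

For a set of n member p-values p₍₁₎ ≤ … ≤ p₍ₙ₎ the set statistic is the
two-sided one-sample Kolmogorov–Smirnov distance to the Uniform(0,1)
null,

    D = max_i max( i/n − p₍ᵢ₎ , p₍ᵢ₎ − (i−1)/n ),

whose exact small-sample p-value is computed for n < 100.  Set p-values
are adjusted across the m tested sets with Benjamini–Hochberg,
adjusted₍ᵢ₎ = min₍ⱼ≥ᵢ₎ ( p₍ⱼ₎ · m / j ).  Each set also reports how many
members are altered (raw p < 0.05) and, of those, how many increased
(fold change > 1, ratio of group medians) or decreased.

The pipeline: 881-bit substructure fingerprints → direct ontology
annotation → lipid rules (fatty acids, oxylipins, prostaglandins) →
greedy most-specific-first class selection (minimum 3 compounds per
class) → similarity rescue of unannotated compounds (Tanimoto > 0.90,
then > 0.75) → discovery of entirely new clusters by an adaptive cut of
the average-linkage similarity tree → saturated/unsaturated split of
lipid classes → KS statistics, FDR, plots.  Details and all defaults
are in [docs/methods.md](docs/methods.md).

## Worked example

The package ships a synthetic-study generator (curated real metabolite
structures, planted enriched classes) so the whole pipeline can be run
without any external data:

```
$ chemrich fixture --seed 11 --out study.csv --ontology-out onto.tsv
wrote 116 compounds to study.csv

$ chemrich run --input study.csv --ontology onto.tsv --out results
input: study.csv (116 compounds, 0 dropped)
load stage: 0.02s
analysis stage: 0.23s (23 tested sets, 1 untested)
plots: 9 nodes pass the p filter
total: 0.68s
results written to results
```

The first rows of `results/enrichment_results.tsv` (columns abridged):

```
set                           size  p_value   fdr       altered  increased  decreased
branched-chain amino acids    3     3.1e-09   7.2e-08   3        3          0
Saturated_triacylglycerols    4     6.8e-09   7.8e-08   4        4          0
Unsaturated_triacylglycerols  9     1.3e-08   1.0e-07   8        8          0
hexoses                       6     8.9e-05   5.1e-04   3        3          0
Unsaturated_lysophosphatidylcholines  9  1.9e-04  8.6e-04  6  0  6
```

Reading it: the planted enriched classes surface at the top; the
triacylglycerols were split into saturated/unsaturated partitions by
the double-bond rule; lysophosphatidylcholines are significantly
*decreased* (all altered members have fold change < 1), so their node
renders blue in `results/impact_plot.svg`, while the increased sets
render red.  `results/cluster_membership.tsv` records how every
compound was assigned (`mesh_direct`, `lipid_rule`, `similarity_090`,
`similarity_075`, `tree_cut_new`, or `singleton` — in this run the
sugar alcohols, absent from the ontology on purpose, come back as a
discovered cluster "near hexoses").  The average-linkage similarity
tree is written as Newick (`similarity_tree.nwk`) and as a radial plot.

The same functionality is available as a library:

```python
from chemrich import fixtures, pipeline

study, truth = fixtures.generate_fixture_study(seed=11)
result = pipeline.run_chemrich(study, fixtures.mini_ontology())
print(result.results_frame().head())
```

Real studies are CSV/TSV tables with columns `compound_name`, `smiles`,
`pubchem_id`, `pvalue`, `foldchange` (names remappable); the ontology
is a TSV of `key_type, key, term_id, term_name, tree_number` rows, with
a converter expected to produce it from official MeSH + CID–MeSH dumps.

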