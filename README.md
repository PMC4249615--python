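# hifnet

Seed-anchored mutual-information network analysis for dual-cohort expression
data, built for the question: *which part of a transcription factor's
downstream network is specifically dysregulated in one disease subtype?* The
motivating case is the HIF-1 target network in acute promyelocytic leukemia
(APL, FAB subtype M3 of AML): starting from a list of validated HIF-1 target
genes and two independent AML cohorts profiled on different microarray
platforms, the pipeline reconstructs a consensus relevance network and
extracts the subnetwork concordantly dysregulated in M3.

It is intended for computational biologists who have probe-level expression
matrices with subtype labels, a seed gene list, and optionally matched miRNA
expression, and who want a tested, reproducible implementation of each stage
rather than a black box.

## Method

1. **Harmonize** the cohorts to their common probe sets; log2-transform and
   mean-center each probe per cohort; drop the lowest-entropy decile of
   probes (histogram entropy, `ceil(√n)` bins).
2. **Infer** a relevance network per cohort: adaptive-partitioning mutual
   information I(X; Y) in nats between every seed probe and every other
   probe, with edge significance calibrated against a permutation null whose
   log survival tail is fitted as ln P(MI > m) ≈ a + b·m. Asymmetric edge
   thresholds (p < 10⁻¹⁵ and p < 10⁻¹⁰ by default) account for the different
   cohort sizes. Optional data-processing-inequality pruning removes the
   weakest edge of each triangle: (i, j) falls when
   mi(i,j) < (1 − ε)·min(mi(i,k), mi(j,k)).
3. **Intersect** the two networks (an edge survives only if significant in
   both) and run per-cohort Welch t-tests, M3 vs the rest, with
   Benjamini–Hochberg FDR.
4. **Extract** the APL subnetwork: nodes with q < 0.05 in both cohorts and
   concordant direction; connected components with ≤ 10 distinct genes are
   discarded. Hub tables (degree vs worst-of-two-cohorts p), per-subtype
   colorings (M0–M5 one-vs-rest), sample clustering over the subnetwork
   (1 − Pearson r, average linkage, plus PCA), and a treatment-reversal
   score for time-course data profile the result.
5. **Integrate miRNAs**: miRNAs up-regulated in M3 (Bonferroni p < 0.05)
   ranked by the number of down-regulated subnetwork transcripts with
   Pearson r < −0.4; externally predicted target tables annotate each miRNA
   with its predicted-target fraction. A generic hypergeometric
   over-representation test covers annotation enrichment.

A fully deterministic synthetic-data generator (`hifnet.simulate`) plants
seed-anchored star modules, APL-specific up/down modules, subtype shifts,
multi-probe genes, regulator miRNAs, and a relaxation time-course, and emits
the ground truth for recovery scoring — it is how the package validates
itself end to end. See `docs/methods.md` for the full model and numerical
choices.

## Worked example

```python
import hifnet as hn

cfg = hn.GeneratorConfig(seed=0)           # ~2,200 probes, 150+145 samples
em_a, em_b, annotation, seeds, truth = hn.generate_cohorts(cfg)
res = hn.run_pipeline(em_a, em_b, annotation, seeds, rng_seed=101)

print(f"consensus: {res.consensus.number_of_edges()} edges / "
      f"{res.consensus.number_of_nodes()} nodes")
print(f"subnetwork: {res.subnetwork.graph.number_of_nodes()} probes, "
      f"{len(res.subnetwork.genes())} genes, "
      f"{len(res.subnetwork.components)} components")
rep = hn.evaluate_recovery(res.consensus, truth, annotation)
print(f"edge precision {rep.edge_precision:.3f}, recall {rep.edge_recall:.3f}")
sub = hn.evaluate_recovery(res.subnetwork, truth, annotation)
print(f"APL-module gene recovery {sub.apl_gene_recovery:.3f}, "
      f"background contamination {sub.background_gene_fraction:.3f}")
print(res.hubs.head(3).to_string(index=False))
```

Output:

```text
consensus: 1447 edges / 1235 nodes
subnetwork: 167 probes, 88 genes, 6 components
edge precision 1.000, recall 0.960
APL-module gene recovery 0.978, background contamination 0.000
      node    gene  degree  worst_p
SEED000_p1 SEED000      27 0.000029
SEED003_p1 SEED003      27 0.000009
SEED004_p1 SEED004      24 0.000006
```

Reading: the dual-cohort consensus recovered 96% of the planted anchor–member
edges with no false gene pairs; the extracted APL subnetwork contains 88 of
the 90 planted module genes and no background genes, in 6 star-shaped
components; the top hubs are the planted APL anchor genes, all strongly
differential in both cohorts (`worst_p` is the less significant of the two
cohorts' raw t-test p-values).

The same run is available from the shell:

```sh
hifnet simulate --outdir data --seed 0
hifnet run --expression-a data/expression_a.tsv --labels-a data/labels_a.tsv \
           --expression-b data/expression_b.tsv --labels-b data/labels_b.tsv \
           --annotation data/annotation.tsv --seeds data/seeds.txt --outdir out
```

which writes SIF + attribute tables for the networks, differential tables,
the subnetwork node table, and the hub table under `out/`.

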