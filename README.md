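# tcrhallmark

Repertoire-level hallmarks of an effective peptide vaccination, inferred from
TCRβ clonotype tables of tumor-draining (dLN) and non-draining (ndLN)
lymph-node CD8+ T cells. The package implements the full inference chain used
to compare vaccine groups in mouse tumor-challenge experiments:

1. **Clonotype table I/O** — VDJTools-style (`count, freq, cdr3nt, cdr3aa,
   v, d, j`) and MiXCR-style tab-separated tables, plus a `minimal` dialect
   (`count, freq, cdr3aa, v`) used for synthetic fixtures; sample sheets
   (`sample_id, mouse_id, group, ln_side, subset, cell_count, path`) and
   specificity databases (`cdr3aa, trbv, label, source`); segment calls
   reduced to gene level (`TRBV17*01` → `TRBV17`).
2. **Preprocessing** — detection-threshold filtering with rescaling
   (clones with frequency > 2.5×10⁻⁵ kept, survivors renormalized), a
   cell-count consistency rule (total reads / smallest clone's reads must
   stay below the number of sorted cells), pooling of same-group samples by
   CDR3 amino acid with a cumulative-frequency cutoff of 5×10⁻⁵, and
   cross-group exclusion of shared clonotypes.
3. **Diversity** — clonality as 1 − H/ln N, the complement of the normalized
   Shannon–Wiener index of clone frequencies, plus V-segment usage
   (frequency- or clonotype-count-weighted).
4. **Convergence detection** — an ALICE-style neighbor-enrichment scan: a
   clonotype is convergent when the pooled cloneset contains more
   single-substitution CDR3 variants than expected under a generative
   background. The expected count for a clonotype with neighbor sequences
   *s* in a cloneset of *N* clonotypes is
   `E = Σ_s [1 − (1 − π(s))^N]` with `π(s) = Pgen(s)` (times the background
   V/J usage in segment-linked mode), tested with a Poisson upper tail and
   Benjamini–Hochberg correction (hits: adjusted p < 5×10⁻⁵).
5. **Clustering** — connected components of the Hamming-1 graph over hits
   (optionally V/J-linked), with consensus sequences, position-frequency
   matrices, and Cytoscape-ready edge-list/GraphML export.
6. **Enrichment** — dLN/ndLN frequency ratios at clone, cluster and
   specificity-group level (zero sides floored at the detection threshold),
   with top-k cluster summaries (mean ± SD, SEM).
7. **Specificity matching** — fuzzy overlap with known antigen-specific TCRs
   (TRP-2, gp100, GVHD, influenza, …): exact gene-level TRBV match plus at
   most one amino-acid mismatch and/or one indel in the CDR3.
8. **Synthetic studies** — a seeded generator of complete group × mouse ×
   dLN/ndLN studies with log-normal clone sizes and planted structure
   (convergent clusters with a dominant seed, dLN-enriched bystanders,
   database-matching public clones), with ground truth for recovery scoring.

The generative background is a factorized CDR3 model (length distribution ×
position-binned amino-acid emissions with conserved anchor bins); an
externally computed Pgen table can be plugged in via `TabularPgen`.

## Worked example

Simulate a one-group study (2 mice × dLN/ndLN, 1.4×10⁴ clonotypes and 10⁶
reads per sample, 10 planted convergent clusters of size 8 with a 3-fold
dLN enrichment) and run the chain:

```python
from tcrhallmark import (StudyConfig, simulate_study, clonality, alice_scan,
    significant_hits, build_clusters, evaluate_recovery)
from tcrhallmark.preprocess import filter_and_rescale, pool_repertoires
from tcrhallmark.enrichment import cluster_ln_ratio

study = simulate_study(StudyConfig(groups=("p30",), seed=7))
filtered = [filter_and_rescale(r) for r in study.samples]
for rep in filtered:
    print(f"{rep.sample_id}: {len(rep)} clonotypes, clonality {clonality(rep).clonality:.3f}")

pool = pool_repertoires(filtered)
records = alice_scan(pool, study.model, link_vj=True)
hits = significant_hits(records)
clusters = build_clusters(hits, link_vj=True)
print(f"neighbor-enriched hits: {len(hits)}; clusters: {len(clusters.clusters)}")

top = clusters.clusters[0]
print(f"top cluster: size {top.size}, consensus {top.consensus}, "
      f"dLN/ndLN ratio {cluster_ln_ratio(top, filtered).ratio:.2f}")
report = evaluate_recovery(study.truth, clusters, "p30")
print(f"planted clusters recovered: {report.n_recovered}/{report.n_planted}, "
      f"spurious: {report.n_spurious}")
```

Output:

```
p30_m1_dLN: 6600 clonotypes, clonality 0.075
p30_m1_ndLN: 6718 clonotypes, clonality 0.075
p30_m2_dLN: 6429 clonotypes, clonality 0.078
p30_m2_ndLN: 6551 clonotypes, clonality 0.077
neighbor-enriched hits: 80; clusters: 10
top cluster: size 8, consensus CSAPVLTATSMAEF, dLN/ndLN ratio 3.09
planted clusters recovered: 10/10, spurious: 0
```

About half of each sample's 14,000 clonotypes survive the 2.5×10⁻⁵
detection filter; the scan flags exactly the 80 planted cluster members
(10 clusters × 8), every cluster is recovered with no false clusters, and
the recovered dLN/ndLN ratio matches the planted 3-fold enrichment.

The same chain is scriptable from the shell:

```bash
tcrhallmark simulate --seed 7 --out study/
tcrhallmark report --sheet study/sample_sheet.tsv --db study/specificity_db.tsv --outdir results/
```

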