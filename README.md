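# smallrna-traj

Small-RNA profiling along alternative developmental trajectories.

Annual killifish embryos can develop along two temperature-controlled
programs — continuous ("escape", 30 °C) development or arrest in diapause
(20 °C) — and small noncoding RNAs are candidates for switching between
them. This package implements the complete computational path of such a
study for researchers working with stage-resolved small RNA-seq in
non-model genomes:

* **Unique-tag quantification** — 3′ adapter trimming, collapsing to
  distinct 15–30 nt tags, CPM normalization (raw × 10⁶ / library total)
  with a ≥ 2 CPM retention filter, length distributions, exact-match
  annotation against miRBase/RFAM-like references, and top-contributor
  summaries per stage.
* **miRNA gene mapping** — perfect-match alignment of mature sequences to a
  genome on both strands, single-linkage clustering of loci into paralog
  clusters (gap ≤ 10 kb), precursor window extraction, hairpin evaluation by
  base-pair maximization (Nussinov recursion with G·U pairs, min loop 3),
  and 5′-anchored consensus sequences with IUPAC ambiguity codes.
* **Differential expression** — per-stage two-sample t-tests on
  log2(CPM + 1) between trajectories (n = 3 per group), Benjamini–Hochberg
  FDR within each stage (q < 0.05), median-centered matrices and
  average-linkage clustering under uncentered Pearson distance
  (d = 1 − Σxy/√(Σx²Σy²)) for heatmaps, and per-paralog trajectory-split
  expression profiles.
* **Target prediction** — 3′UTR inference from GFF3 by exon-minus-CDS
  interval arithmetic in transcript orientation, scanning spliced UTRs for
  reverse complements of 6-/7-mer seeds (AGUGCU / AAGUGCU for the
  miR-430-like family), per-gene site counts (max over transcripts),
  stage-wise intersections with expressed and DE gene sets, a UTR-length
  ANOVA confound check, and exact hypergeometric term enrichment with BH
  adjustment.
* **A ground-truthed simulator** — a toy genome + annotation + references +
  42 stage/trajectory-structured FASTQ libraries with negative-binomial
  counts (gamma–multinomial, dispersion 0.1), a declining escape-enriched
  5-paralog family in 2 genomic clusters, an increasing 4-paralog family
  with trajectory-shifted onset, 17-nt background tags, and seeded 3′UTR
  target sites — so the whole pipeline is testable without downloads.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Run the pipeline on the default simulated study (or point the config at
real FASTQ/FASTA/GFF3 inputs instead of the `simulate` block):

```python
from smallrna_traj.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig(outdir="out", seed=1, simulate={}))

profiles = res["paralog_profiles"]
fam = profiles.loc[[p for p in profiles.index if p.startswith("mir430")]].sum()
print(round(fam[("NK", "escape")]), round(fam[("NK", "diapause")]))
print(len(res["loci"]), "loci in", len(res["clusters"]), "clusters")
nk = res["de"][res["de"]["stage"] == "NK"]
print(int(nk["significant"].sum()), "tags DE at NK (q < 0.05)")
print(res["gene_sites"].head(3))
```

prints

```
382433 78900
9 loci in 6 clusters
10 tags DE at NK (q < 0.05)
   gene  seed6mer  seed7mer
0  g032      12.0       5.0
1  g043      12.0       4.0
2  g007      11.0       1.0
```

i.e. the declining family is ~4.8× more abundant on the escape trajectory at
the neural-keel stage and 10 miRNA tags are significantly
trajectory-specific there; the 9 simulated paralog loci map into 6 clusters
(2 for the declining family, 4 for the increasing one); and the top target
gene carries 12 seed sites in its 3′UTR, 5 of which also match the
stricter 7-mer seed.

The same stages are available from the shell:

```bash
smallrna-traj simulate --seed 1 --out study
smallrna-traj quant --reads study/reads --adapter TGGAATTCTCGGGTGCCAAGG \
    --refs study/refs --min-cpm 2 --out quant_out
smallrna-traj map-loci --mature study/refs/mirna.fa --genome study/genome.fa \
    --out loci_out
smallrna-traj targets --gff study/annotation.gff3 --genome study/genome.fa \
    --seed AAGUGCU --seed AGUGCU --out targets_out
smallrna-traj de --matrix quant_out/normalized_matrix.tsv \
    --design study/design.tsv --out de_out
```

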