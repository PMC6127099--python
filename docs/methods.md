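# Methods

This note documents the models, procedures and design choices behind
`smallrna-traj`. The package reconstructs a small-noncoding-RNA analysis of
alternative developmental trajectories in an annual killifish: embryos
incubated at 30 °C develop continuously ("escape"), embryos at 20 °C arrest
in diapause, and small-RNA libraries are sampled at seven morphological
stages (DC, NK, 6S, 10S, 16S, 20S, 24S) in both conditions with three
replicates each. Because the original sequencing depth (millions of reads
per library) is not reproducible at desk scale, the package ships a
ground-truthed synthetic study generator that emulates the design, and every
analysis stage is validated against that ground truth or against exact
brute-force oracles.

## Unique-tag quantification

Reads are 3′-adapter trimmed by removing the leftmost occurrence of an
adapter prefix of ≥ `min_overlap` (default 8) nt together with everything
downstream; tags outside 15–30 nt are rejected. Trimmed tags are collapsed
to distinct sequences, counted per library, normalized to counts per million
(CPM = raw × 10⁶ / library total) and filtered to tags reaching ≥ 2 CPM in
at least one library. The filter threshold follows the study's "≥ 2
normalized counts per library" rule; we read it as *any* library because a
stage-restricted tag would otherwise be discarded by construction.
Annotation is exact full-length matching (U/T-insensitive) against reference
mature sequences, with category priority miRNA > rRNA > tRNA > snRNA when a
sequence occurs in several references. Tags are canonicalized to the DNA
alphabet internally and emitted as RNA in miRNA-facing outputs.

## Paralog mapping and hairpin evaluation

miRNA genes are located by perfect-match search of mature sequences on both
genome strands (1-based inclusive coordinates; minus-strand hits reported on
the forward scaffold). Loci on the same scaffold and strand are grouped by
single-linkage with a 10 kb gap threshold — teleost miR-430 clusters are
tandem repeats within a few kb, so 10 kb is generous — and clusters are
lettered a, b, c… by (scaffold, start), which makes the naming deterministic
and order-invariant.

Candidate precursor windows (mature ± 60 nt, strand-aware) are folded by
base-pair maximization (Nussinov recursion) with Watson–Crick and G·U
pairs, a minimum loop of 3 nt, and no pseudoknots. The traceback prefers
closing the outer pair, then the smallest split point, so dot-bracket output
is deterministic. A fold is called a hairpin when the maximal-pair structure
has a single terminal loop, a longest stacked-stem run ≥ 16 pairs, and a
paired fraction ≥ 0.5. This deliberately replaces thermodynamic free-energy
folding: the decision being made is binary (plausible precursor or not) and
the maximization model is exactly checkable against enumeration of all
nested structures, which the test suite and acceptance script do for every
length ≤ 12.

Two caveats follow from the simple model. First, a symmetric ±60 nt flank is
a stand-in for unknown precursor boundaries; second, under maximum pairing a
random flanking sequence folds into additional small stem-loops, so windows
with generous flanks usually fail the single-terminal-loop test even when
the embedded precursor is a textbook hairpin. Hairpin statistics on windows
are reported as computed; the acceptance script evaluates classification on
the exact precursor spans, where the call is unambiguous.

Consensus sequences of paralog variants are built by 5′-anchored majority
vote (no indel alignment; shorter variants simply stop voting), with IUPAC
ambiguity codes at ties.

## Differential expression

Per stage, each tag is tested between trajectories with a classical
two-sample (pooled-variance) t-test on log2(CPM + 1), n = 3 per group, and
p values are Benjamini–Hochberg adjusted within the stage; a tag is called
at q < 0.05. The pooled test is used rather than the unequal-variance
(Welch) variant: at n = 3 the Satterthwaite degrees-of-freedom estimate is
extremely noisy (frequently near 2), which in simulation under the package's
own count model costs roughly a third of the achievable sensitivity at
matched error control, while the log transform makes group variances
comparable in practice. Zero-variance ties, which exact counts can produce,
follow fixed conventions: both groups constant and equal → p = 1; constant
but unequal → p = 0 with a `degenerate` flag.

In the full pipeline the per-stage BH family is the miRNA-annotated tags.
At desk scale the unique-tag matrix is dominated by singleton 17-nt
background tags (~10⁵ rows whose CPM at a 10⁴-read depth is far above any
filter), and adjusting across them would swamp the family-level analysis the
heatmap panels describe.

Heatmap inputs are median-centered by tag (mid-point median for even
lengths) and ordered by average-linkage clustering under uncentered Pearson
correlation distance, d = 1 − Σxy/√(Σx²·Σy²); zero rows are assigned
distance 1 to everything. Leaf order and a Newick dendrogram are emitted.
Paralog profiles sum member-tag CPM per library and average replicates per
(stage, trajectory); tag→paralog membership must partition.

## 3′UTR inference and target scanning

3′UTRs are inferred from GFF3 as the exonic positions strictly downstream of
the CDS end in transcript orientation (higher coordinates on +, lower on −),
per transcript; transcripts without CDS are skipped with a warning, and CDS
features outside exons produce per-transcript error records rather than
aborting. Spliced UTR sequences are scanned for all (including overlapping)
occurrences of the reverse complement of each seed — 7-mer AAGUGCU and 6-mer
AGUGCU for the declining family — U/T-insensitively. "Complement" is
implemented as reverse complement, since antiparallel pairing geometry is
what a seed match means; every 7-mer site therefore contains a 6-mer site at
the same position (the 6-mer motif is a prefix of the 7-mer motif).
Gene-level counts take the maximum over the gene's transcripts, keeping
"the transcript with the most binding sites" semantics, and headline counts
use the 6-mer (the more inclusive site definition). A one-way ANOVA of UTR
length across site-count bins (0, 1, 2, ≥3) checks that site counts are not
a UTR-length artifact.

## Enrichment

Term enrichment is the exact hypergeometric upper tail
p = Σ_{x≥k} C(K,x)·C(N−K,n−x)/C(N,n), BH-adjusted across terms, with the
universe defined as all genes with a nonempty inferred 3′UTR. This replaces
service-based functional annotation with a formula the repository can pin
and test against full enumeration.

## The synthetic study generator

The generator emulates the study design, not its scale. Defaults: 6
scaffolds × 50 kb; 7 stages × 2 trajectories × 3 replicates = 42 libraries
of 10,000 reads (50-nt reads, TruSeq-style 3′ adapter, constant qualities);
NB dispersion 0.1 (variance = μ + 0.1 μ²); 30% of reads are anonymous
random 17-nt tags, reproducing the study's unannotatable 17-nt size class.

Two miRNA families are simulated, each paralog sharing 5′/3′ ends around a
unique central 4-mer (mature = 10 + 4 + 8 = 22 nt):

* a **declining, escape-enriched family** (5 paralogs in 2 genomic
  clusters; per-stage weights 120, 80, 48, 20, 10, 4, 2 on the diapause
  trajectory, ×10 at the first three stages on escape) emulating
  maternal-clearing miR-430-like dynamics;
* an **increasing family** (4 paralogs in 4 clusters; near-silent weights of
  2 before onset, then 120, 240, 400, 520) with onset at stage index 3
  (10S) in escape and 4 (16S) in diapause, emulating miR-10-like dynamics.

Within a family, paralog abundances fall geometrically (×0.5) so the first
paralog dominates, and each paralog emits three isomiR tags (canonical,
3′-trimmed, templated 3′-extended at weights 1 / 0.35 / 0.2) — the
desk-scale analog of the dozens of variants per family seen in real
small-RNA data. Eighteen decoy reference tags (rRNA/tRNA/snRNA categories)
at lengths 15–30 nt excluding 17 and 22 provide the non-miRNA annotation
classes without disturbing the two length peaks.

Precursors are 5′ arm (mature + 14-nt templated extension) + 8-nt loop +
complementary 3′ arm, ≈ 80 nt in total. The 3′ arm is the reverse
complement of the 5′ arm with three G·U wobble substitutions placed
opposite the mature span (A→G opposite U, C→T opposite G). Real pre-miRNA
duplexes are imperfect, and the wobbles serve that role here with a useful
side effect: the DNA reverse complement of the mature tag does not occur in
the precursor, so perfect-match mapping returns exactly one locus per
paralog instead of a spurious second minus-strand hit, while the RNA duplex
stays fully paired and the fold remains a clean single stem-loop.

Library counts are drawn by the gamma–multinomial construction: per-tag
gamma rates with shape 1/dispersion and mean proportional to the tag's
stage/trajectory weight, then one multinomial of exactly `library_size`
reads. This is the negative binomial as a gamma-mixed Poisson conditioned on
the total — marginals match the targeted NB mean and dispersion (checked by
Monte Carlo) and per-library sums are exact, so read conservation holds by
construction.

Gene models (default 60 genes; 2–3 exons of 200–600 nt, introns 150–400 nt,
~90% with a 150–500 nt 3′UTR) are laid down outside precursor exclusion
zones. A quarter of the UTR-bearing genes receive 1–12 copies of the
declining family's 6-mer seed complement, written strand-aware into single
exon chunks of the UTR; truth site counts are then *re-measured* from the
finished genome with a naive overlapping-substring scan, so chance
background occurrences are part of the truth table rather than a discrepancy
to explain. Per-stage expressed-mRNA sets grow from 40% to 100% of genes
along a fixed random order (nested, hence monotone expressed-target counts),
and per-(stage, trajectory) DE-mRNA sets are small random subsets of the
expressed genes. The term map seeds one molecular-function term with the
true target genes so the enrichment stage has a known positive, plus three
random terms.

All randomness derives from a single seed via labelled sub-streams
(`default_rng([seed, crc32(label)])`): re-running any component with the
same configuration yields byte-identical files.

### What the generator does not emulate

Sequencing errors, quality-score structure, ligation bias, multi-mapping
ambiguity, isoform complexity beyond one transcript per gene, realistic
read depth, and genuine biological variance structure (counts are exactly
NB with a shared dispersion). Passing tests therefore demonstrate that the
pipeline's logic is correct under its stated model, not that the statistical
procedures are robust to artefacts those features introduce in real
libraries.

## Operating characteristics of the DE test

`simulate_de_counts` benchmarks the per-stage test under the study's
replication: 500 tags, n = 3 per group, dispersion 0.1, base means uniform
on 50–500 counts, half the tags truly changed 4-fold. The fold is applied
symmetrically (×√4 in one group, ÷√4 in the other, alternating direction)
so both groups carry the same expected library mass and CPM normalization
does not convert true changes into compositional false positives elsewhere.
Under these conditions the pipeline's test averages ≈ 0.85 sensitivity with
empirical FDR ≈ 0.03 at q < 0.05 over 20 replicate simulations (recomputed
by `scripts/acceptance.py`, not asserted here).

## Numerical and formatting conventions

Coordinates are 1-based inclusive internally (GFF3 convention) and converted
to 0-based half-open only on BED output. Tables are TSV with fixed `%.6g`
float formatting so the run manifest (SHA-256 per output file) is
hash-stable across identical runs. Ties are broken lexicographically
wherever a ranking is emitted. The problem sizes used throughout (10⁴-read
libraries, 50 kb scaffolds, 60 genes) are the package's desk-scale defaults;
every operation accepts genome-scale inputs unchanged.

## Known limitations

* Base-pair maximization over-pairs relative to thermodynamic folding; the
  hairpin classifier is calibrated for precursor-sized windows and is not a
  general-purpose structure predictor.
* Annotation is exact-match only; tags with sequencing errors or
  non-templated additions would fall into `unannotated`.
* The DE test is per-stage and per-tag; no shrinkage across tags or stages
  is attempted, which costs power at very low counts.
* mRNA expression and DE gene sets for the stage-target profile are external
  inputs; the simulator supplies toy sets, and real-data use requires a
  matching mRNA-seq analysis.
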