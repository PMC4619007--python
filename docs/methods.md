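# Methods

This note documents the models, conventions and design choices behind
`mcseq`, and what the simulation-based validation does and does not show.

## Coordinates, sites and contexts

All in-memory and BED coordinates are 0-based half-open; the per-cytosine
text report is 1-based (the common cytosine-report dialect). A *site* is a
cytosine on either strand, indexed by its Watson-forward coordinate (a − 
strand site sits where Watson carries a G). Context is read from the two
bases 3' of the cytosine on its own strand: CG, CHG, CHH (H = A/C/T). A
cytosine whose context bases run off the contig or include N is classed CNN
and excluded from CHG/CHH tallies — with one exception: C immediately
followed by G is CG even with no second base, since the dinucleotide alone
settles the class. The two cytosines of a CpG dyad are distinct sites
throughout; dyad-level operations (island classification, truth levels)
pair them explicitly via `cg_dyads`.

## Read processing

Reads with more than three cytosines in a non-CG read-internal context are
removed as unconverted (a trailing C counts as non-CG; for A-rich reads the
rule is applied to the reverse complement). The filter runs before
alignment; an alternative is to apply it on reference context after
alignment, which for error-light data changes almost nothing because the
read-internal and reference contexts coincide away from sequencing errors.

The built-in aligner is deliberately small: both converted references
(Watson C→T, Watson G→A — the latter is the Crick bisulfite strand in
Watson coordinates) are k-mer indexed, and each read is searched ungapped in
the two orientations its richness allows (T-rich: Watson-C2T forward or
Crick-G2A reverse; A-rich: the converse), with three non-overlapping seeds
guaranteeing every placement with ≤ 2 mismatches is found. A read with no
placement, or more than one placement at the best mismatch count, is
dropped (ambiguous). This replaces a genome-scale aligner for the package's
desk-scale use; externally aligned data can be imported from SAM.

Clonal reads — same library, contig, strand and 5' position — are collapsed
to the first read in input order. Pileup counts, per site: C (methylated)
and T (unmethylated) read bases at Watson sites from Watson-target
alignments; G and A at Crick sites from Crick-target alignments; any other
base is uninformative and excluded from n.

## Methylcytosine calling

The null for an unmethylated cytosine at depth n is B(n, p), with p = Σm/Σn
over all cytosine positions of the designated unmethylated mitochondrial
contig (both strands, all contexts); this folds non-conversion and
sequencing error into one rate. If the mito contig shows zero errors, p is
clamped to 1/(Σn+1) with a warning.

Two calling modes are kept deliberately:

* **literal** evaluates C(n,m)p^m(1−p)^(n−m) < 0.01·m/(n−m) exactly as the
  protocol prints it, resolving the m = n division by zero as RHS = +∞. The
  right-hand side has no standard tail-probability interpretation, so this
  mode exists for protocol fidelity. The satisfied region is upward-closed
  in m for every (n, p) checked (n ≤ 200); the implementation calls from the
  start of the upward-closed tail, so calls are monotone in m by
  construction even if an exotic (n, p) violated that.
* **tail_fdr** (default) uses one-sided tails P(X ≥ m | n, p) with a
  depth-specific threshold m*(n), the per-site level halved iteratively
  until the expected false positives Σ_tested P(X ≥ m*(n_site)) fall below
  1% of the calls made — the "false positives below 1% of methylcytosines
  identified" guarantee. m*(n) is non-decreasing in n at fixed level.

Technical libraries are pooled before calling; biological replicates are
combined by consensus (site-wise intersection of the replicate call sets,
levels reported from pooled counts).

## CpG islands

Criteria: GC > 55% (strict), observed/expected CpG ≥ 0.65 with
obs/exp = (#CpG·L)/(#C·#G), and length > 500 bp. Since the source catalogue
method is not reproducible from sequence alone, detection is a
Takai–Jones-style scan: every 501-bp window is marked if it satisfies the
criteria and contains no N, overlapping/book-ended marked windows are
merged, and each merged region is trimmed to its longest qualifying
sub-interval (leftmost on ties). Each reported island re-checks the
criteria (self-validation), and the scan is tested for exact equality
against an exhaustive-interval oracle on small contigs. A dyad counts as
methylated when either strand carries a call; an island is methylated at a
dyad fraction ≥ 0.70, and islands with no read-covered dyad are classed
unknown rather than unmethylated. Genomic assignment uses the island
midpoint with precedence gene body > upstream > downstream > intergenic and
a 2 kb flank (the flank width is configurable; the original analysis does
not state it).

## DMRs

Differential CG sites: both lines covered (n ≥ 1), two-sided Fisher's exact
test on [[m_a, n_a−m_a], [m_b, n_b−m_b]], BH correction across all tested CG
sites at 5% FDR, and a two-fold ratio between the larger and smaller level
m/n. A level of 0 against a positive level counts as satisfying the fold
criterion (a pseudocount alternative is available); both conditions are
required. Per-line counts are replicate-pooled before testing.

Region calling: 1 kb windows at 100 bp steps; a window with ≥ 4 significant
sites seeds a region, which grows in 100 bp increments while the trailing
1 kb window at the moving edge still holds ≥ 4 — equivalently, a candidate
is a maximal run of consecutive qualifying step-aligned windows. Candidates
with ≥ 5 significant sites spanning ≥ 1 kb survive; overlapping candidates
merge. The reported interval is the merged window span; because window
spans systematically overhang the underlying signal by several hundred bp,
each DMR also records the span of its member significant sites
(`core_start`/`core_end`), which is the boundary estimate to use when
localisation matters. The direction is the majority sign of
level_a − level_b over member sites; swapping the input lines provably
flips directions and nothing else.

DMR–gene association uses any ≥ 1 bp overlap with gene spans ± 2 kb.
Expression integration applies the stated filters: genes below 10 reads in
both lines are not-expressed; differential expression requires a strict
fold change > 2 (max/min).

## Profiles and integration

Promoters are −1.5 kb..+0.5 kb around the TSS, strand-aware, clipped at
contig ends. Metagene profiles split genes into upstream, first exon, first
intron, internal exons, internal introns, last exon and downstream; each
segment is length-normalised into a fixed number of bins (minus-strand
coordinates reversed), the chosen metric is computed per gene per bin, and
bins average across genes with per-bin contributing counts. Single-exon
genes keep only the (merged) exon segment; two-exon genes have no internal
exons. Element (repeat) profiles use length-normalised bodies with
fixed-width flanks and emit both absolute and relative levels. Matched
random regions preserve the template length multiset and are placed
uniformly outside repeats and genic spans ± 2 kb, mutually disjoint and
excluding the mito contig.

Hyper/hypo gene classification uses the relative level (mC/CG) with
inclusive thresholds ≥ 0.70 / ≤ 0.30; genes with no covered CG are excluded
and counted. Expression quintiles are rank-based with ties broken by gene
id for determinism; the promoter-methylation/expression association is
summarised by Spearman correlation on the methylation degree. Group
comparisons (e.g. gene-age classes, pseudogene/parent pairs supplied as a
grouping file) use Welch's unequal-variance t-test pairwise — a robust
reading of "Student's t-test". Per-gene divergence between lines uses a χ²
test without continuity correction on methylated/unmethylated read totals
over the gene span's CG sites (expression: gene reads vs the remaining
library total), falling back to Fisher's exact test when an expected cell
is below 1; the 2×2 construction is a reconstruction, as the original
analysis does not state its tables.

## The simulator

The generator emulates the study conditions the analysis assumes:

* **Genome** — iid background at GC 0.42 (chicken-like) with CpG
  dinucleotides retained at 1/`cpg_enrichment_factor` (default 1/4,
  observed/expected ≈ 0.25, vertebrate-like); planted islands are iid GC
  0.60 without depletion (obs/exp ≈ 1), default 4 kb — long enough that the
  window scan's ~150 bp edge uncertainty keeps reciprocal overlap with the
  truth above 90%; genes (4 exons by default), repeats and islands are
  mutually non-overlapping with a 2.5 kb margin; one 16 kb
  mitochondrion-like contig is fully unmethylated.
* **Methylome** — per-dyad bimodal CG levels (62% high in U(0.7, 1.0), the
  rest in U(0, 0.1)), matching a somatic vertebrate profile where most mCGs
  are 70–100% methylated and over half of CGs are methylated; non-CG sites
  methylated at 1.2×10⁻³; planted islands mostly (80%) unmethylated;
  promoters carry a continuous per-gene level that drives the expression
  coupling. Line B equals line A except inside `n_dmrs` disjoint planted
  DMRs where the two lines sit at 0.7 ± Δ/2 (Δ = 0.5 by default, alternating
  direction).
* **Counts fast path** — n ~ Poisson(depth), m ~ B(n, p + e(1−p)) per site.
* **Reads** — single-end directional chemistry at 14× per strand (read
  length 80 bp), C emitted at cytosines with probability p + e(1−p), uniform
  substitution errors on top, and a configurable fraction of exact clonal
  (PCR) copies at identical 5' positions; clones inherit their template's
  errors, and truth alignments are recorded for oracle tests. Depth includes
  clones, so post-dedup depth is lower by roughly the clonal fraction.
* **Expression** — a Gaussian copula on promoter-truth ranks with Pearson
  parameter 2·sin(π·ρ/6) so the realised Spearman correlation with promoter
  methylation is ≈ −ρ (default ρ = 0.6); counts are log-normal around 200
  reads, and line B's expression responds to promoter methylation
  differences at −3 log2 units per unit level difference.

Not emulated: base-quality variation, indels, GC-dependent coverage bias,
fragment-length distributions, partially methylated domains, and biological
replicate dispersion beyond binomial sampling. Consequently the validation
demonstrates the correctness of the algorithms under their own model
assumptions — FDR control, oracle agreement, recovery of planted structure
— not robustness to real-data artefacts such as mapping bias or
overdispersion.

## Validation experiment sizes

The end-to-end checks run at desk scale, chosen to give comfortable
statistical margins: FDR control on a 1 Mb genome (~580k sites, ~13.5k
calls); error-rate recovery over 100 count draws on a 16 kb mito contig;
exact-oracle sweeps for the literal inequality (n ≤ 50), Fisher p-values
(all 2×2 tables with margins ≤ 30) and the CGI scan (50 random 5 kb
contigs); DMR recovery with 10 planted DMRs in 2 Mb with two pooled 15×
replicates per line — under which planted regions hold ~25 significant
sites/kb, so recall, precision and core-boundary accuracy (mean error
≈ 50 bp) are well inside their bounds — and a 20 × 0.5 Mb null for
specificity; metagene flatness with 100 genes and 35 bins (the 3-SE band is
calibrated so ~0.1 chance exceedances are expected genome-wide); and
expression-coupling recovery with 120 genes (Spearman sampling error
≈ 0.09).

## Numerical and degenerate-input choices

Fisher p-values come from `scipy.stats.fisher_exact` with memoisation over
distinct tables; agreement with exhaustive hypergeometric enumeration is
within 10⁻¹⁰. χ² marginals of zero give p = 1 (identical composition).
Empty call sets produce all-zero summaries with a warning rather than
errors. Uncovered regions report undefined (None) CG metrics while the
absolute level is still defined. The random-region sampler and all
generators take explicit `numpy.random.Generator` seeds; identical seeds
give byte-identical outputs.
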