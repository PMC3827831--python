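# Methods

## The measurement model

The package targets genomes whose methylome is a two-state mosaic: long
intervals ("methylated domains") in which essentially every CpG is
methylated, alternating sharply with unmethylated promoters and intergenic
space, with domains coinciding with a subset of gene bodies. Two orthogonal
assays observe this structure:

* **CAP-seq** (CXXC affinity purification + sequencing). The CXXC zinc
  finger binds unmethylated CpG DNA, so coverage in the affinity-purified
  library marks unmethylated regions; the unfractionated input library
  covers the mappable genome and controls for what *could* have been
  observed. Methylated domains are therefore defined negatively: regions
  with input coverage from which affinity coverage is absent.
* **BS-seq** (whole-genome bisulfite sequencing). Bisulfite converts
  unmethylated C to T; each cytosine site yields a coverage X and a count m
  of reads that stayed C ("methylated evidence"). m at a truly unmethylated
  site is governed by a small combined error rate (failed conversion,
  sequencing error, mismapping).

All coordinates are 0-based half-open internally; GFF3 is converted at the
boundary. Interval sets are kept canonical (sorted, disjoint, adjacent
intervals merged), so every per-base membership pattern has one
representation and set algebra has no off-by-one ambiguity.

## Covered-region calling (H, L, G)

Covered regions are maximal runs of depth ≥ H, after which runs separated
by ≤ G bp are merged, and merged regions shorter than L bp (gaps included)
are discarded. Defaults H = 4 reads, L = 90 bp, G = 700 bp. The
order of operations — threshold, then gap-merge, then length filter, with
bridged gaps counting toward L — is a deliberate reading: it is the only
order in which a 700 bp tolerated gap is compatible with a 90 bp minimum
length. Both libraries are processed independently with identical
parameters on raw (unnormalized) depth, and no additional length filter is
applied after the subtraction that yields methylated domains.

The calibrator grid-searches (H, L, G) to maximize the base-pair Jaccard
index between called covered regions and reference unmethylated regions
inside a calibration window, breaking ties toward smaller H, then smaller
G, then larger L (prefer the least aggressive thresholding that achieves
the same agreement).

## Per-cytosine binomial calls

The error rate e is pooled over the control contig: e = Σm / ΣX. Pooling
(rather than averaging per-site rates) weights every read equally and is
the maximum-likelihood estimate under a shared error probability. A pooled
rate ≥ 0.5 is rejected outright — such a "control" is methylated, not a
control. Each site with X ≥ 2 is tested with the exact binomial upper tail
P(M ≥ m | X, e), computed via the regularized incomplete beta function
(scipy's survival function), never a normal or Poisson approximation:
e ≈ 9×10⁻⁴ puts low-coverage sites far outside the approximations'
comfort zone. m is interpreted as the count of reads giving *methylated*
evidence (unconverted C); a binomial test against a small error rate is
only meaningful in that orientation. Calls use a fixed per-site α = 0.01
with no multiple-testing correction — the fixed α is part of the procedure
being implemented. Strands are never merged per CpG dyad; every cytosine
is its own site. Context is read from the two downstream bases on the
site's own strand (CG → CpG; C-H-G → CHG; C-H-H → CHH, H ∈ {A,C,T}); a CpG
needs only its first downstream base, so a terminal ...CG still yields two
sites, while CHG/CHH require both bases and sites with N in the needed
window are skipped.

## Per-gene degrees and classification

Degrees live on [0, 1] over the transcription unit (strand-aware TSS to
poly(A) site, i.e. the full span):

* **domain_overlap**: covered bp / span bp against methylated domains;
  eligible only if the span is 100% contained in input-covered regions.
* **cpg_fraction**: methylated-called CpGs / assessed CpGs (X ≥ 2) in the
  span; eligible only if assessed/all > 0.6 (strictly) and the span holds
  ≥ 1 CpG. The denominator uses *assessed* sites by default: with only
  ~60% of sites assessed, an all-CpG denominator would bias a fully
  methylated gene's degree toward 0.6 and break the bimodal
  classification; `ScoreConfig(cpg_denominator="all")` restores the
  literal reading.

Classification is bimodal: degree > hi → methylated, < lo → unmethylated,
else intermediate (lo = 0.1, hi = 0.9; 0.05/0.95 and 0.2/0.8 supported as
sensitivity settings).

Metagene profiles count, per position relative to an anchor (5′ end,
3′ end, start codon, stop codon; minus-strand genes flipped), how many
domain-resident genes (> 0.8 overlap) have that position inside a domain;
the x-axis is absolute bp with a configurable flank, not length-normalized.
Convergent shared-domain pairs are adjacent (+, −) gene pairs whose
poly(A)-to-poly(A) gap exceeds 500 bp and for which a *single* domain
interval covers the entire gap plus ≥ 1 bp of each body; the gap threshold
is measured between the facing span ends.

## Concordance and enrichment statistics

Cross-tissue agreement uses the Pearson correlation of matched degree
vectors (the quantity is a correlation coefficient by construction;
Spearman is available as an option), with significance from a one-sided
permutation test that shuffles one tissue's gene labels:
p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1). The add-one rule means the
smallest reportable p is 1/(n_perm + 1) — with 100,000 permutations,
9.99×10⁻⁶ — and the test never reports below that floor. The 2×2
contingency table counts genes bimodally classified in *both* tissues.
Class enrichment tests each expression class with a two-sided Fisher exact
test (in-class vs out-of-class × methylated vs unmethylated), fold
enrichment relative to the methylated fraction among all genes carrying
both labels, and Bonferroni correction by the number of classes actually
tested (5 when all classes are populated).

## What the generator emulates — and what it does not

The generator's defaults are the emulated study conditions: 5 contigs of
1 Mb, 2,000 genes of 1.2–2.2 kb, 60% methylated, within-domain CpG levels
0.979 (sperm-like) and 0.705 (muscle-like), error rate 0.00091, 20× CAP-seq
at 36 bp reads, 10× BS-seq, a 60 kb unmethylated control contig, and 5
convergent shared-domain pairs.

Counts a test can pin down are deterministic: exactly
round(fraction × n_genes) methylated genes and exactly the configured
number of convergent pairs — only identities and positions are random.
True domains are constructed per methylated gene as the span inset by a
promoter window (default 30 bp around the TSS) plus small random offsets
(≤ 1% of span per side), guaranteeing > 90% domain coverage for methylated
genes and 0% for unmethylated genes; for designated convergent pairs one
domain runs from the + gene's 5′ inset across the gap to the − gene's 5′
inset. Intergenic gaps are ≥ 600 bp, which (a) makes every designated
pair's poly(A) gap exceed the 500 bp detection threshold and (b) places
the TSS−500 position of essentially every gene in domain-free intergenic
space, producing the promoter dip that the metagene checks quantify. The
promoter hypomethylation of real genomes is thus represented chiefly by
intergenic spacing; the explicit TSS window only adds a small inset.

Sequence is i.i.d. at GC 0.36 with additional CpG dinucleotides planted at
rate 0.02 per position (non-overlapping, greedy); context is then read from
the realized sequence, so CHG/CHH sites arise naturally. The within-domain
tissue level applies to CpG-context sites only; CHG/CHH sites carry the
error rate everywhere, matching the near-zero non-CpG methylation of the
emulated system.

CAP-seq reads are fixed-length intervals: input starts uniform per contig;
CXXC starts uniform within the complement of the true domains except for a
contamination fraction (default 0.01) placed uniformly genome-wide. The
default is deliberately small: the affinity background must stay well
below the H = 4 calling threshold (background depth ≈ contamination ×
total depth ≈ 0.2×) for domain subtraction to be meaningful, which mirrors
the strong depletion the assay itself requires. There is no quantitative
retention chemistry behind this model — it is a stand-in with the right
first-order statistics. BS-seq draws X ~ Poisson(depth) and
m ~ Binomial(X, p_site) independently per site.

Not modeled, hence not validated by passing tests: GC/mappability bias,
fragment-length extension of reads, PCR duplicates, read-level bisulfite
strand bookkeeping, M-bias, SNPs under cytosines, repeat-derived
mismapping (the main source of discordant genes in real data), and
intermediate/partially methylated domains. On real data the two degree
modes disagree more than they do here.

## Numerical and scale choices

* Interval algebra is breakpoint-based on int64 arrays; property tests
  compare it base-by-base against boolean-array oracles, and the H/L/G
  caller against an independent per-base scan.
* The coverage caller's boundary resolution is about one read length: at a
  domain edge the affinity coverage decays linearly over the read length,
  crossing H ≈ 31 bp inside the domain at default depths. Called domains
  are therefore inset by a few tens of bp relative to truth, which is why
  called degrees of methylated genes sit near 0.93–0.96 rather than at the
  truth degrees' 0.95–0.98.
* Default problem sizes were chosen so every statistical check has
  comfortable power while a full pipeline pass stays in the tens of
  seconds: ~200,000 in-domain CpGs give a 3-SE window of ±0.3 percentage
  points on the within-domain levels; ~21,000 control cytosines at 25×
  give ±1.3×10⁻⁴ on the error rate.
* Permutation tests standardize once and evaluate permutations in batched
  matrix products; seeds derive from a stage-indexed generator hierarchy
  (`default_rng([stage, seed])`), so stages are independently reproducible.
* Degenerate inputs fail loudly and specifically: empty calibration
  references, zero-coverage controls, controls with pooled rate ≥ 0.5,
  zero-length spans, all-zero contingency tables, configs whose gene
  packing cannot fit a contig.

## Known limitations

* The domain caller assumes the original order of operations
  (threshold → gap-merge → length filter); other orders are defensible and
  would differ on tracks with many sub-L runs. The calibration operation
  exists precisely to validate the choice against reference regions.
* `fisher_2x2` and the binomial tail delegate to scipy; tests cross-check
  them against full enumeration and direct pmf summation, but extreme
  tables (counts ≫ 10⁶) inherit scipy's floating-point behavior.
* The eligibility rules are strict inequalities at their boundaries
  (exactly 60% assessed CpGs is ineligible); real pipelines vary here.
* The generator cannot produce intermediate methylation states, so the
  intermediate class is exercised only by boundary effects, not by
  biology.
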