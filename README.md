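# mosaicmeth

Analysis of **mosaic gene-body methylomes** — genomes (typified by
invertebrates such as ascidians) in which DNA methylation forms sharp,
contiguous *methylated domains* over a subset of gene bodies, while
promoters and intergenic DNA stay unmethylated. The package implements the
full desk side of a two-assay comparison of such a methylome across tissues:

1. **CAP-seq domain calling.** The CXXC domain binds unmethylated CpG DNA,
   so affinity-purified read coverage marks *unmethylated* regions. Covered
   regions are called from a depth track with three parameters — minimum
   depth *H*, maximum bridged gap *G*, and minimum span *L* (defaults
   H=4, L=90, G=700; order: threshold → gap-merge → length filter) — and
   methylated domains are the input-library coverage *deprived of* the
   affinity coverage (set difference). A grid-search calibrator recovers
   H/L/G against bisulfite-validated reference regions by base-pair Jaccard
   index.
2. **BS-seq per-cytosine calls.** For each cytosine with coverage X and
   methylated-evidence count m, the null that m arises from the bisulfite
   error rate e alone is tested with the exact binomial upper tail
   P(M ≥ m | X, e); sites with p < 0.01 are methylated, sites with X < 2
   unassessed. e is pooled (Σm/ΣX) over an unmethylated mitochondrial-like
   control contig (≈ 9.1 × 10⁻⁴ in the emulated study).
3. **Per-gene degrees in two modes.** A gene's methylation degree is the
   fraction of its transcription unit (TSS to poly(A) site) that is
   methylated — by bp overlap with domains (CAP-seq mode, genes fully
   input-covered) or by the fraction of methylated CpG sites (BS-seq mode,
   genes with > 60% of CpGs assessed). Degrees are bimodal: > 0.9
   "methylated", < 0.1 "unmethylated".
4. **Cross-tissue statistics.** Pearson correlation of degrees with a
   one-sided permutation test (add-one rule), 2×2 contingency of bimodal
   calls, joint degree distributions, metagene domain profiles, convergent
   (tail-to-tail) shared-domain pair detection, and Fisher-exact /
   Bonferroni enrichment of expression classes among methylated genes.

Because the original sequencing data are not required for development or
testing, a first-class **synthetic-methylome generator** reproduces the
statistical structure the analysis assumes — ~60% of genes methylated,
within-domain CpG levels 0.979 (sperm-like) and 0.705 (muscle-like),
error rate 0.00091, CXXC reads concentrated in unmethylated regions, and a
configurable number of convergent gene pairs sharing one uninterrupted
domain — with deterministic counts and byte-identical outputs under a fixed
seed.

## Worked example

Run the whole pipeline on a small synthetic genome (2 × 500 kb, 300 genes):

```sh
cat > example.yaml <<'YAML'
outdir: example_run
n_perm: 10000
sim:
  seed: 7
  n_contigs: 2
  contig_length: 500000
  n_genes: 300
  n_convergent_shared_pairs: 3
  control_contig_length: 30000
YAML
mosaicmeth run-all --config example.yaml
```

which prints

```
run complete: r=0.9986 p=0.0001 discordant=0.0000% -> example_run/report.json
```

`report.json` then contains, among per-stage counts and output digests:

```
score.sperm_like   : eligible 300, methylated 179, unmethylated 120, intermediate 1
score.muscle_like  : eligible 300, methylated 179, unmethylated 120, intermediate 1
cpg.error_rate     : 0.000997
compare            : pearson_r 0.9986, permutation_p 1.0e-04,
                     contingency a=178 b=0 c=0 d=120, discordant_fraction 0.0
```

Reading: both tissue modes independently classify the same 179-gene
methylated set (the generator planted 180 = 60% of 300; one gene lands
intermediate at the domain boundary), no gene switches state between
tissues, and the degree vectors correlate at r ≈ 0.999 with the permutation
p at its add-one floor 1/(n_perm+1). The error rate estimated from the
control contig recovers the generating 0.00091 within sampling noise.

Every step is also available separately (`mosaicmeth simulate`,
`call-domains`, `calibrate`, `call-cpg`, `score-genes`, `metagene`,
`compare`, `enrich`) and as library functions.

## Layout

```
src/mosaicmeth/
  core.py        genome layout, interval algebra, coverage, gene models, I/O
  simulate.py    synthetic mosaic-methylome generator (truth + observations)
  domains.py     H/L/G covered-region caller, domain subtraction, calibration
  methylation.py cytosine extraction, error model, binomial calls
  scores.py      per-gene degrees, classification, metagene, convergent pairs
  stats.py       correlation/permutation, contingency, Fisher enrichment
  pipeline.py    staged, seeded, logged end-to-end runs
  cli.py         `mosaicmeth` command-line interface
docs/methods.md  model, assumptions, parameter choices, limitations
```
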