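# Methods

## Coordinate conventions

All in-memory coordinates are 0-based, half-open; conversion happens only at
the I/O boundary (GFF3 is 1-based closed on disk; BED, the 6-column
alignment dialect, and GFA A-line offsets are half-open/0-based). Strand and
read orientation are carried through but never flip coordinates: the
contamination arithmetic is purely positional. Introns are derived as the
gaps between consecutive exons of an mRNA, so exon and intron bases tile the
mRNA span exactly.

## Classification arms

**k-mer/LCA arm.** References are indexed by canonical k-mer (lexicographic
minimum of a k-mer and its reverse complement); a k-mer present in several
taxa maps to their LCA. Windows containing non-ACGT characters or lowercase
(soft-masked) bases are skipped, mirroring dust-style masking of
low-complexity reference regions. Classification tallies index hits over the
query's k-mers, scores every node with a nonzero tally by the sum of tallies
along its root-to-node path, and returns the deepest node attaining the
maximal score; when the maximum is shared by incomparable nodes the call is
their LCA. The candidate set is restricted to tallied nodes — without that
restriction every descendant of the argmax would tie it and "deepest" would
be ill-defined. Defaults: k = 21 (standard for k-mer classification and
small enough for desk-scale references), minimum one hit, no fractional
confidence threshold. A query shorter than k is unclassified with support 0,
not an error.

**bestsum arm.** Hits above the e-value cutoff (default 1e−50) are
discarded; each surviving hit contributes its bitscore to its subject
taxon's ancestor at the target rank (default phylum; a taxon with no
ancestor at that rank contributes under itself). The rank-level argmax of
the summed bitscores is the call. An exact tie of the top sums is reported
as unclassified — this is the package's realization of the "undef" class of
ambiguous matches, whose precise trigger in blob-style tooling is not
standardized. Per-taxon sums use `math.fsum` over sorted scores so the
result is exactly invariant to hit order. Summation is over the whole query;
no windowing or partitioning of long queries is attempted.

## Consensus retention

keep(a, b, t) ⇔ (a = t ∧ b = t) ∨ (a = t ∧ b = unclassified) ∨
(a = unclassified ∧ b = t). A sequence absent from one arm's output is
treated as unclassified by that arm, since "failed to classify" is a state
of the rule. Summary percentages are rounded half-up (2 decimals by
default), which is what the `percent` helper implements throughout.

## The audit

1. **Alignment filtering.** Duplicates and secondary records are removed;
   each read keeps its single highest-mapq record (ties broken by leftmost
   target coordinate); records with mapq < 20 are then dropped. The
   threshold is inclusive: mapq 20 survives.
2. **Evidence.** A = union of assembler placements of contaminant-classified
   reads; M = union of their filtered alignment positions. Evidence is A ∩ M
   per contig by default — a read must both have been placed in the contig
   by the assembler *and* map back there confidently — with A ∪ M available
   as `evidence_mode="union"`. Intersection is the stricter and default
   reading; both are implemented because the two set operations give
   different audits and the choice is a genuine design point. By
   construction, intersection evidence ⊆ union evidence per base.
3. **Per-feature metrics.** For each gene and each feature class (gene,
   transcript, exon, intron, CDS, pooling all mRNAs of the gene), the unique
   contaminated bp is the union length of feature ∩ evidence; contaminant
   depth is the mean contaminant-read pileup over those positions; total
   depth is the mean all-read pileup over the same positions, or over the
   whole feature when it is uncontaminated (the logistic model needs an x
   for y = 0 cases, and the whole-feature mean is the natural covariate).
   Depth is computed from all filtered alignments; contaminant depth from
   the contaminant subset only. Feature classes with no intervals (introns
   of a single-exon gene; absent CDS) are emitted as zero rows so the table
   always has exactly five rows per gene.
4. **Regressions.** The regression unit is the gene. OLS of contaminant
   depth on total depth is fit over contaminated genes; logistic regression
   of the contaminated indicator on total depth over all genes, by Newton's
   method (tolerance 1e−8 on coefficients, ≤ 100 iterations, via
   statsmodels). The LLR p-value is the upper χ²₁ tail at twice the
   log-likelihood gap against the intercept-only model. A response with one
   class absent, or a slope diverging past ±50 (complete separation), is a
   hard error. R² is defined as 0 for a constant response.
5. **Reporting.** Per feature class: contaminated count and mean ± SE
   (sample sd, n − 1) of contaminant depth, unique bp and total depth over
   contaminated rows; the integer percent of genes contaminated (half-up);
   and a density table counting contaminated genes on a fixed square grid
   over (total depth, contaminant depth), bin width 1, for hexbin-style
   plots.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale:

- **Reads.** Lengths Normal(15,105, 1,070) bp truncated below at 1,000 bp —
  the circular-consensus length distribution of the sequencing run the
  pipeline targets — sampled uniformly and error-free from their source
  genome, at a default host depth of 16×.
- **Genes.** Default 40 genes over 4 contigs of 90–120 kb. Exon count is
  1 + Poisson(3); exon lengths uniform 160–460 bp (mean ≈ 310) and intron
  lengths uniform 500–3,300 bp (mean ≈ 1,900), matching the annotation
  summary the audit operates on; CDS are the exons with 30 bp UTR trims at
  the mRNA ends.
- **Contamination.** Each gene is contaminated with probability
  σ(β₀ + β₁·depth), β₀ = −2.6527, β₁ = −0.0184 — the audit's fitted
  coefficients reused as the canonical generative truth (no generative model
  for the contamination process exists independently, so the fitted form is
  adopted and is fully configurable, including a fixed-rate override).
  Contaminated genes receive 1 + Poisson placements of bacterial pool reads
  overlapping the gene by ≥ 200 bp, written as GFA A-lines plus matching
  alignments whose mapq falls below 20 with configurable probability.
  Implantation is interval-level: contig sequences are not mutated, because
  the audit consumes coordinates, not bases.
- **Classifiers.** Per arm, a call is the true phylum with probability
  1 − miss − cross, unclassified with probability miss, a uniform wrong
  phylum with probability cross. Defaults: k-mer arm miss 0.008 (a
  classifier that places ~99.2% of reads), cross 0.002; alignment arm miss
  0.95 (a stringent aligner that leaves ~95% of reads unclassified), cross
  0.001. The emitted hit table is constructed so bestsum aggregation
  reproduces the intended call: dominant bitscore on the intended taxon's
  species, occasional decoys at ≤ half the score, misses as absent or
  e-value-filtered hits.
- **Regression harnesses.** Gene-table generators (no sequences) draw depth
  from Gamma(2, 8) (mean 16, matching the audit's background coverage) and
  apply either the logistic truth above or the linear truth
  contam = 1.83 + 0.25·depth + ε, ε ~ N(0, 5.49²); the noise sd is chosen so
  the generating process has R² = β²Var(x)/(β²Var(x) + σ²) ≈ 0.21.

Every stream derives from the single configured seed
(`default_rng([seed, stream])`), so one seed yields a byte-identical file
set. What the generator does **not** emulate: sequencing error and quality
strings, heterozygosity, adapter artifacts, repeat structure, or
composition-dependent classification difficulty (synthetic genomes are
uniform-random, so real k-mer classifiers would behave far better on them
than on low-complexity or conserved regions). Passing tests therefore
demonstrate correctness of the rule/interval/regression machinery, not
real-data classifier accuracy.

## Assembly statistics

N/L50 follows the BBMap stats.sh convention — N is the count of largest
contigs needed to reach half the assembly, L the length of the smallest of
them — the reverse of some communities' usage; outputs spell out both. The
">50 kb" percentage is by bases, not contig count. GC is computed over
non-N bases. Blob rows report per-contig GC fraction, mean depth (aligned
bases / contig length) and the k-mer-arm taxon.

## Problem sizes

Defaults are sized so the whole pipeline and its property suites run in
seconds: 4 × ~100 kb contigs, 40 genes, ~450 reads; regression recovery uses
20,000 gene-table rows; brute-force interval oracles fuzz > 1,000 cases on
≤ 300 bp toy coordinates. These are the package's chosen study conditions,
stated here so they can be scaled up knowingly.

## Known limitations

- The taxonomy is a generic rooted tree with string ids; NCBI taxdump
  ingestion is out of scope (a 4-column TSV is the exchange format).
- BAM/CRAM are not parsed; alignments enter via the 6-column text dialect
  (SAM/PAF exports and synthetic files share one path).
- The k-mer index is a plain Python dict of canonical k-mer strings —
  correct and adequate for desk-scale references, not a minimizer/compact
  hash design for real databases.
- bestsum windowing across very long queries, and per-read LCA maps in the
  classifier output, are not modelled.
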