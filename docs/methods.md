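# Methods

This note records the models implemented in `heteroseek`, the defaults and
why they were chosen, the numerical decisions made where the design was
genuinely open, and what the synthetic-data world does and does not show
about real sequencing data.

## Coordinate and reference conventions

All coordinates are 1-based, fully closed intervals on a circular
reference, matching the rCRS community convention for human mtDNA.
Features that wrap the replication origin (the D-loop) are stored as two
intervals sharing one name, and annotation queries de-duplicate the name.
The bundled reference is a *synthetic* random sequence of the rCRS length
(16,569 bp): it provides the coordinate system and a realistic genome size
without shipping human sequence, and none of the analyses depend on real
mtDNA base content. The bundled gene map uses the standard rCRS feature
coordinates (13 protein genes, 22 tRNAs, 2 rRNAs, D-loop, including the
ATP8/ATP6 overlap region around positions 8527–8572) but is deliberately
treated as versioned configuration: annotation enters the pipeline only as
labels attached to calls. Ambiguity codes in input FASTA are rejected
rather than randomly resolved, keeping the pipeline deterministic.

## Read simulation

The simulator emulates a single-end MiSeq-like run on exonuclease-purified
mtDNA:

* **Fragments** are uniform on the circle (reads may wrap the origin and
  are emitted as one record spanning the junction — circularity is native,
  not an artifact to patch around) with probability `purity`, otherwise
  uniform on a linear nuclear background.
* **Fragment length** is uniform in `read_length ± length_jitter`
  (default 100 ± 10 nt). The jitter emulates the spread of sonication
  fragment sizes and is load-bearing: with strictly fixed-length
  fragments, a genome of L = 16,569 offers only 2L start/strand
  combinations, so at depths of a few hundred many *distinct* fragments
  coincide to byte-identical reads; clonal collapse would then remove real
  observations preferentially from the majority allele and bias frequency
  estimates. With ±10 nt of length variation the coincidence rate drops
  to the percent level and collapse remains faithful to true duplicates.
* **Errors** are independent substitutions at `per_base_error` (default
  10⁻³, the error level of Q30 bases); indels are not simulated because
  the downstream variant analysis is substitution-only.
* **Clonal duplicates** are exact copies of a fragment's read (same
  sequence and strand), emitted Poisson(`clonal_rate`) times — clonality
  is defined by read identity, so the simulator reproduces exactly what
  the collapse step removes.
* **Qualities** are a two-level fixture: constant Q35 with an optional
  fraction of reads carrying an 11-base Q15 run, enough to exercise the
  low-quality-run filter deterministically. No claim is made about real
  MiSeq quality-score distributions.

The nuclear background carries Numt intervals (circular mtDNA segments
copied with per-base substitution at a configurable divergence, default
2%) and LINE/SINE-like repeat tracts built by tiling fixed random motifs
(1,500 and 300 nt). Tracts are placed disjointly with random gaps; the
realized repeat fraction is stored exactly. Default contamination levels
in examples (0.5–5% nuclear) match what repeat-content estimation reports
for exonuclease-purified libraries.

Variant generators are transition-biased at 4:1 odds (expected transition
fraction 0.8), reflecting the polymerase-γ replication-error spectrum that
dominates mtDNA mutation. Arbitrary per-variant population frequencies
(the 0.1–0.9 ladder) are realized with *nested* haplotypes, since disjoint
haplotypes cannot carry variants whose frequencies sum above 1.

## Mapping

The mapper is deliberately simple plumbing, not a contribution: exact
15-mer seeds at stride 15 on both strands against the doubled circular
reference, candidate loci scored by Hamming mismatches, best hit wins
under a ceiling of 5 mismatches per 100 nt (≈ 3σ above the Q30
expectation). Ties across distinct loci — e.g. inside a zero-divergence
Numt — are assigned to mtDNA and counted: the analytical premise is that
nDNA *depletion*, not mapping cleverness, removes Numts, so residual
Numt reads are expected to fold into the mtDNA signal and ambiguity is
reported rather than dropped. Reads are labeled `nuclear-repeat` when at
least half the read is an exact match to a repeat-family motif; the
half-read rule makes the labeling probability of a uniformly drawn
nuclear read equal the genomic repeat fraction, which keeps the
contamination estimator unbiased at tract boundaries. Reads failing both
are optionally aligned to the nuclear background (`nuclear-other`) or
left `unmapped`.

The contamination estimate is (repeat reads / mapped reads) /
repeat_fraction, clipped to [0, 1]; it is undefined (an error) when the
repeat fraction is zero.

## Variant calling

Non-clonal (duplicate-collapsed) alignments feed a dense pileup recording,
per position, allele and strand, (a) every base and (b) only *interior*
bases ≥ 10 nt from both read ends. A call requires:

1. interior alt support ≥ 3 non-clonal reads,
2. non-clonal depth ≥ 10,
3. strand balance: max(plus, minus)/total alt support ≤ 0.80 (strictly
   greater excludes; computed over alt-supporting reads, not total depth),
4. frequency ≥ detection floor (default 0.02).

Two clauses were genuinely open and are package decisions, not inferred
authorial intent:

* **End-distance scope.** The ≥ 10 nt rule governs *eligibility* (filters
  untrustworthy end-of-read support); the reported frequency uses *all*
  non-clonal alt observations over all non-clonal depth. Restricting the
  numerator to interior bases would deflate every frequency by the
  interior fraction of a read (~0.8 for 100 nt reads), so the split is
  required for unbiased estimates.
* **Strand rule base set.** The > 80% fraction is evaluated over
  alt-supporting reads only; 3 reads at 2+/1− (0.67) and 5 at 4+/1−
  (exactly 0.80) pass, 5+/0− fails.

The detection floor matters at depth: with e = 10⁻³ and per-allele rate
e/3, three coincident errors at one site occur with probability ≈ 4×10⁻⁴
at depth 500, i.e. ~18 sites genome-wide would pass the support filter by
chance. The 2% floor demands ≥ 10 coincident errors at that depth
(probability ~10⁻¹³), which is what delivers zero false positives on
variant-free simulations at high depth. At depth 100 the floor coincides
with the 3-read rule, and the genome-wide expectation of coincidence calls
is L·3·P(X ≥ 3) ≈ 0.3 — occasional isolated low-frequency false calls at
moderate depth are a property of the filter set, and the test suite
asserts exactly this computed bound rather than an unconditional zero.

`residual_error_bound(e, C, k)` returns the exact binomial tail
P(X ≥ k) at rate e/3 and depth C, under the documented uniform-miscall
assumption. Multi-allelic sites emit one call per passing allele.

## Segregation drift and exchange

Division is modeled as hypergeometric half-sampling (mtDNA copies are
discrete physical molecules split without replacement) followed by
deterministic doubling back to quorum N. One daughter per division is
tracked, giving the per-cell frequency distribution across independent
lineages. For this default scheme the one-generation variance recursion
closes exactly and yields

  Var_g = P(1−P)·[1 − (1 − 1/(N−1))^g],

used throughout as the analytic oracle. Because the assortment/replication
microphysics is not observable, two alternatives ship behind flags —
binomial assortment and stochastic (Pólya-urn) replication — but the
oracle applies only to the default. Mitochondria and mtDNA copies are
collapsed into a single count N; genomes-per-organelle substructure is
not modeled, nor is selection, balancing selection, fixed-composition
segregating units or spatial structure.

Exchange at rate m replaces Binomial(N, m) copies per cell per generation
with draws from the pooled population frequency: removal is
hypergeometric in the cell's composition, income is binomial at the pool
frequency. m = 0 is the identity; m = 1 re-draws every cell at the pool
mean. At N = 250, P = 0.5, g = 26, m = 0.2 the inter-cell variance
reaches a quasi-steady state roughly an order of magnitude below the pure
drift value (the paired-seed reduction measured by the acceptance script
is ~9×).

The "first generation at which half the lineages are homoplasmic" summary
(`fixation_generation`) is exposed as an exploratory estimate only; it is
strongly N-dependent and is not calibrated against any external value.

## Profile comparison and transfer

Profiles match variants by exact (pos, ref, alt) identity; no fuzzy allele
matching. The detection floor (default 0.02) partitions the key union
into shared and private sets — variants below the floor in both samples
are outside the comparison, reflecting that sub-2% variants are unstable
across single-cell bottlenecks. Concordance is summarized by max |Δf| and
Pearson r over shared variants.

Transfer detection requires all three profiles (donor, recipient
baseline, recipient after co-culture); a donor-only mode is refused
rather than guessed, because donor-private status is defined against the
recipient baseline. Per-variant transfer index = f_after/f_donor; the
pair verdict is `transfer` when ≥ half (configurable) of donor-private
variants reach the floor after co-culture, `no transfer` when none do,
`partial` otherwise, `indeterminate` with no donor-private variants. The
half rule is artifact policy for a discrete verdict; the per-variant
indices are the primary output and are never averaged away in the report.

## Problem sizes and tolerances

Statistical tests are seeded and sized so that their tolerances are
3-standard-error bounds at the stated n: caller accuracy uses the full
16,569 bp genome at depth 500 (~83k reads); drift checks use 10,000
lineages per (N, P) combination; the exchange comparison uses 1,000
paired-seed lineages; transfer uses three depth-300 runs; contamination
recovery uses ~200k reads at purity 0.95 (and ~100k at 0.99 in the
acceptance script). Floating-point invariants (frequency sums, realized
repeat fraction) are enforced at 10⁻⁹.

## Known limitations

* The mapper is a stand-in: no gapped alignment, no base-quality use, no
  mapping-quality model. Reads from highly diverged Numts (> 5 mismatches
  per 100 nt) fall out as unmapped rather than mis-assigned, which is
  optimistic relative to real repeat-rich genomes.
* Repeat labeling is motif-exact in the synthetic world; real LINE/SINE
  divergence and masking are out of scope, so passing the contamination
  tests shows estimator correctness given recognizable repeats, not
  repeat-annotation robustness.
* The read simulator omits PCR amplification bias, GC effects, quality
  decay along reads and indels; passing caller tests therefore
  demonstrates the filter logic and its statistics, not robustness to
  every real library artifact.
* SAM export soft-clips the wrapped portion of origin-spanning alignments
  (the in-memory representation keeps the full circular span); VCF export
  is a minimal v4.2 schema validated against pysam's reader.
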