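# Methods

This note documents the models behind `hairdna`, the parameters that
matter, what the synthetic data do and do not emulate, and the numerical
and design choices made where more than one defensible option existed.

## 1. Forced pseudo-haploid kinship

### Model

At coverage well below 1× almost every covered SNP is seen by a single
read, so diploid genotypes cannot be called. Each sample is therefore
represented pseudo-haploidly: at every covered site, one observed allele
chosen uniformly at random (among reads, or among the two alleles of a
diploid genotype — with one read per site the two are equivalent).

For two pseudo-haploid profiles the statistic is the **mismatch
proportion** over the sites called in both. Under Hardy–Weinberg
equilibrium with alternate-allele frequency *p* and kinship coefficient
φ — the probability that one allele drawn from each individual is
identical by descent (same individual ½, parent–child ¼, full siblings
¼, unrelated 0) — the per-site mismatch probability is

    m(p, φ) = (1 − φ) · 2p(1 − p),

since IBD alleles never mismatch and non-IBD alleles behave as two
independent population draws. A symmetric observation error *e*
(each observation flipped to the other panel allele independently) gives

    m_obs = m·((1 − e)² + e²) + (1 − m)·2e(1 − e).

The error lump-sums deamination, depurination, PCR, sequencing and
mapping error; rates of 0–2% span the regime relevant to degraded hair.
Parent–child and full siblings share φ = ¼ and hence the same expected
mismatch; with sites independent given the relationship, the per-site
mismatch indicator is Bernoulli(m) in both classes, so the two are not
distinguishable by this statistic — only by richer IBD-segment methods,
which are out of scope.

### Conditional null and classification

The observed comparison conditions on a particular overlap-site set
(both its size and its frequency spectrum), so expected distributions
are obtained by Monte-Carlo simulation **on exactly that site set**:
each replicate draws a fresh genotype pair for the class,
pseudo-haploidises both, applies the error, and records the proportion.
Defaults: error grid {0, 0.005, 0.01, 0.02}; 10,000 replicates (recorded
in the output). Replicates reuse the same underlying uniform draws
across the error grid, which makes replicate means exactly monotone in
*e* and reduces grid-to-grid Monte-Carlo noise.

A class is *compatible* at error rate *e* when the observed proportion
falls inside the central 95% empirical interval (2.5th–97.5th
percentiles) of its replicates. A named verdict requires that exactly
one class has grid points where it alone is compatible; if no class is
compatible anywhere the verdict is "inconclusive: outside simulated
classes" (no forced calls), and if several classes have exclusive
support it is "inconclusive: multiple classes compatible". Interval
membership was chosen as the decision rule because it is reproducible
and mirrors how an observed line is read against simulated distributions;
no likelihood-ratio machinery is implied.

The closed-form expectation above serves as an independent oracle for
the simulator: the test suite checks every (class, error) null mean
against it within 3 standard errors, and separately checks the closed
form against brute-force enumeration of the full single-site probability
space (founders × meioses × picks × error flips).

### Power at the study scale

With ~1,200 overlap sites and uniform(0.05, 0.95) frequencies, the
same-individual and parent–child means are separated by ~0.09 while the
replicate SD is ~0.011, so same-vs-first-degree discrimination is
essentially deterministic; the acceptance script measures ≥ 99%
same-individual recovery and 0% unrelated-as-same at 1% error.

## 2. Rx sexing

`r_i = (N_X/L_X)/(N_i/L_i)` per autosome; Rx is the mean of the 22
ratios, the CI half-width is `1.96·SD/√22` with the sample (n−1) SD —
this orientation and CI form reproduce published Rx/SD/CI tables to
three decimals, which fixes the otherwise under-determined convention.
Assignment: male iff CI upper bound < 0.60, female iff lower bound
> 0.80, else inconclusive; inequalities are strict. Y-chromosome reads
are ignored entirely. Scaling all counts by a constant leaves every
ratio unchanged. Autosomes with zero reads make the ratio undefined and
raise rather than silently degrade.

GRCh37 chromosome lengths are shipped as a packaged constant because the
read counts the statistic consumes are conventionally produced against
that assembly.

## 3. Circular mtDNA pipeline

### Chimeric reference and liftover

The chimera is genome + 14 N + genome rotated to start at position 8284
(2L + 14 = 33,152 bp at L = 16,569), giving every circular fragment a
contiguous linear placement. The liftover back to circular coordinates
is the deterministic inverse of this construction: copy-1 positions map
identically; copy-2 position *q* maps to
`((q − (L + 14) + 8284 − 2) mod L) + 1`; footprints crossing L split
into two intervals. A placement overlapping the N spacer is rejected
with an explicit reason — a real aligned read cannot span it. Re-mapping
reads to a circular reference with a second aligner pass would add
nothing at this scale, since placements on the chimera already determine
circular footprints exactly; the liftover replaces that pass.

Every non-spacer chimeric position has exactly one circular image and
every circular position exactly two preimages; this round-trip is
property-tested over random genome lengths and rotation points.

### Filtering, deduplication, accounting

Mapping-quality filter at ≥ 30 (boundary retained). Duplicates are
placements with identical circular fragment endpoints and strand —
presumed PCR copies of one template molecule in a degraded-sample
library; the representative is the highest-MQ read, ties broken by
read id, and the operation is idempotent. The pipeline accounts for
every input read: input = spacer-rejected + MQ-filtered +
duplicates-removed + retained.

### Consensus and heteroplasmy

Per-position base counts (A/C/G/T/deletion) feed a majority-call rule.
A position is a **point heteroplasmy** when the minor base reaches both
≥ 10% of depth and ≥ 2 reads; it is then reported as the IUPAC code of
the two bases with the majority fraction (57 T + 18 C → `Y`, 76% T).
The two thresholds are the package's own cut-offs, chosen so that a 24%
minor allele is called mixed while a 1.9% minor allele (a plausible
single deaminated base) is called homoplasmic; published forensic
workflows make these two decisions but state no numeric rule. Zero-depth
positions are no-calls, never reference matches. Insertions are
annotated per read (anchor, rank, base), counted, and called when
supported by ≥ 2 reads and ≥ 50% of reads covering the anchor; they
render as `anchor.rankBase` (`315.1C`). Deletions are representable in
the pileup but not simulated; complex rearrangements are out of scope.

Haplotypes are ordered difference lists against the reference;
comparisons of two profiles are restricted to positions called in both,
so missing data never counts as a difference.

### Statistics

Depth summaries are over all L positions (mean, min, max, sample SD);
fragment lengths are summarised over unique placements with a 1 bp
histogram.

## 4. Synthetic data: what it emulates, and what it does not

All generators flow from explicit integer seeds and are byte-reproducible.

* **SNP panel** — sites spread over autosomes 1–22 proportional to
  GRCh37 lengths; frequencies i.i.d. uniform(0.05, 0.95) by default, a
  stand-in for common European-ancestry panel variants that keeps
  per-site informativeness realistic without external downloads
  (E[2p(1−p)] ≈ 0.37). The law is pluggable; a floor keeps sites
  polymorphic. Real panels have LD, frequency spectra skewed toward
  common variants by ascertainment, and chromosome-level structure —
  none of which the mismatch statistic uses, since it treats sites
  exchangeably.
* **Genotype pairs** — founders under HWE; parent–child by Mendelian
  transmission plus a population draw; siblings as two children of two
  simulated parents. No inbreeding, no mutation.
* **Coverage masks** — a latent per-site lognormal "mappability" weight
  (log-scale σ = 2·correlation) shared by both samples, sampled without
  replacement via Gumbel top-k. At correlation 0 the overlap is exactly
  hypergeometric; at ≈ 0.5 the expected overlap is ~3× the independence
  expectation, matching the empirically observed excess sharing of
  covered SNPs between libraries from the same tissue. Default 0.5.
* **Observation error** — symmetric biallelic flip per observation, the
  same single-parameter model the null assumes. Real error is
  asymmetric (C→T excess from deamination); the symmetric model is the
  stated simulation condition, not a claim about chemistry.
* **Chromosome counts** — multinomial with weights length × dosage,
  X dosage 1 (female) or 0.5 (male). No Y, no per-chromosome
  mappability variation.
* **mtDNA reads** — uniform start positions on the mutated circle,
  lognormal fragment lengths (default mean 65 bp, SD 0.35·mean, floor
  20 bp — the degraded-hair regime), reads emitted until the target mean
  depth is reached, origin-spanning fragments arising naturally.
  Deamination is modelled as C→T at fragment terminal bases only, where
  damage concentrates in aged DNA; at rate 0.05 the induced minor-allele
  fractions stay an order of magnitude below the 10% heteroplasmy
  threshold, which the tests verify. Reads start on non-inserted bases
  (a read beginning inside an insertion has no anchored placement in
  this representation). No base-quality strings, no alignment errors:
  placements are emitted directly, because alignment itself is external
  to this package.

Consequently, passing tests demonstrate the correctness of the
statistics, the coordinate arithmetic, the calling logic and the
decision rules under the stated generative model — not robustness to
LD, ascertainment bias, contamination, NUMT interference or alignment
artefacts in real data.

## 5. Problem sizes and numerical choices

Test and acceptance runs use the study's characteristic sizes where they
matter statistically — 1,196 overlap sites, 10,000 null replicates, 100
classification trials per class, 200 sexing replicates per sex at 10⁵
reads, 60× mtDNA depth on a 16,569 bp circle — and smaller panels
elsewhere (e.g. the hypergeometric-overlap check runs one 1.3 M-site
frame). Percentile intervals use NumPy's default linear interpolation;
consensus ties break deterministically by base order; all coordinates
are 1-based inclusive throughout mtDNA handling, with 0-based conversion
only at SAM boundaries. Seeds derived from a master seed stay below
2³¹.

## 6. Known limitations

* Parent–child vs full siblings cannot be separated by the mismatch
  statistic (identical expectation); both are reported as compatible
  when either is.
* The classification is interval-membership, not a calibrated posterior;
  with very few overlap sites the intervals widen and verdicts
  degenerate to inconclusive rather than quantifying uncertainty.
* The mtDNA caller consumes placements, not raw alignments; CIGAR
  deletions are skipped by the SAM adapter rather than modelled, and
  insertion placement follows the input pileup without EMPOP-style
  length re-alignment of homopolymer stretches.
* The synthetic reference is a random sequence with mtDNA-like length
  and GC content, not the rCRS itself; position numbers in simulated
  profiles are therefore structural, not biological.
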