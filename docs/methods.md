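# Methods

## Coordinate and identity conventions

All internal coordinates are 0-based half-open on the reference strand.
VCF (1-based) and GFF3 (1-based closed) are converted at the I/O
boundary only; BED passes through unchanged. A SNP's identity is the
tuple (contig, position, ref, alt): requiring the same alternate allele
prevents conflating different substitutions at one site when sets are
intersected or subtracted, and membership never consults read depths.
A call without usable allele depths has *unknown* frequency — it
participates in set algebra but is excluded from frequency statistics
rather than being treated as frequency 0.

## The screening cascade

Stage order: wild-type stock SNPs are removed from every replicate
first; replicates are intersected (SNP^ori); the background union
SNP^negative (empty-vector control ∪ deaminase-only control ∪
wild-type stock) is subtracted; SNPs in configured exclusion intervals
(e.g. the hypermutable pf4 prophage span of PAO1 — shipped as an
approximate preset, since only the locus-tag range is published) are
dropped; SNPs recurring in more than `cross_tf_max_occurrences = 2`
distinct TF experiments are dropped. The recurrence count includes the
focal experiment by default ("appeared more than twice" ⇒ removal at
≥ 3 occurrences); because the published rule does not say whether the
focal experiment counts, `count_focal_tf=False` selects the other
reading. Every stage only removes records, so per-stage counts are
monotone non-increasing, and the background-subtraction and
region-exclusion stages commute (both are pure identity/locus filters)
— both properties are asserted in the test suite.

Promoter attribution is purely positional: a SNP inside any gene body
is nonpromoter; an intergenic SNP is promoter-like iff the nearer
flanking gene on its right is on '+' and/or the nearer on its left is
on '-' (its 5′ end faces the SNP), listing one or — for divergent gene
pairs — two downstream genes. There is deliberately no maximum upstream
distance: the operational promoter definition is "intergenic, upstream
of at least one gene", so the whole intergenic region qualifies.
Between convergent 3′ ends, and on gene-free contigs, the class is
nonpromoter. Flank windows (default ±100 bp, 201 bp in all) are
truncated at contig ends and flagged, never N-padded — motif tools
tolerate ragged lengths, whereas padding invents sequence.

## Background-sharing arithmetic

If stochastic mutations hit each of N positions independently with
per-experiment probability p0, the expected count shared by k
replicates is N·p0^k (`expected_shared_stochastic`). The Monte-Carlo
counterpart (`simulate_shared_count`) draws k Bernoulli(p0) masks per
seed and counts all-k positions; tests verify agreement within 3
standard errors for p0 ∈ {1e-5, 1e-4, 1e-3} and k ∈ {2, 3} at N scaled
so the expectation is resolvable (the expectation is linear in N, so
reduced-scale means rescale exactly).

## The simulator

The simulator emulates the experiment's readout, not its biochemistry:

- **Genome**: uniform-composition random sequence; non-overlapping gene
  bodies (300–900 bp) with random strands; intergenic gaps ≥ 150 bp so
  boxes fit. Deterministic per seed.
- **Boxes**: a consensus (default an AT-rich-core 16-mer with
  CTGT…ACAG ends, the reverse-symmetric shape of LuxR-family operator
  boxes) written into intergenic gaps that are 5′ of a gene, each box
  recorded with its downstream gene and an occupancy drawn from a
  configurable distribution (default Uniform(0.5, 1)). Occupancy stands
  for the binding isotherm [TF]/([TF]+Kd).
- **Directed editing**: per-generation site rate
  μ(d) = μ0 · occupancy · exp(−d/λ) for C/G sites, d clipped to 0
  inside the box and rate 0 beyond `window_max`. Defaults μ0 = 0.015,
  λ = 15 bp, `window_max` = 100 bp place the detectable directed events
  within ~40 bp of the box, the concentration observed for real
  TF-directed deamination. Population frequency after G generations is
  the deterministic recursion f ← f + (1−f)·μ, then selection
  f ← f(1−s)/(1−f·s); with s = 0 this is exactly 1−(1−μ)^G. G = 24 by
  default: two 12-h culture rounds with 5× dilution between them, long
  enough to complete conversions without eliminating slow-growing
  mutants. A 1e5-cell stochastic population (conversion + selective
  resampling per generation) serves as the oracle for this recursion in
  tests; it is not the default engine.
- **Background**: each position mutates with the compounded
  per-experiment probability 1−(1−p_bg)^G to a random different base.
  Its frequency is 2^(−g) for a generation of origin g drawn uniformly
  from {1..G} — the jackpot profile of a neutral mutation arising early
  versus late in an expansion. Only early-origin (high-frequency)
  mutations pass the caller thresholds, so the default per-generation
  p_bg = 4e-6 yields a per-experiment mutation probability of ~1e-4/bp
  with a smaller *detected* background rate, matching a deaminase-only
  control burden of a few hundred SNPs per genome at full scale.
- **Sequencing/caller emulation**: alt reads ~ Binomial(depth, f) at
  depth 100×; a record is emitted only if the alt fraction ≥ 0.1 and
  the alt count ≥ 3. These thresholds are not published for the real
  caller and are configurable.

Deliberately out of scope: read-level (FASTQ) simulation, sequencing
error, PCR duplicates, sequence-context (hotspot) preferences of the
deaminase, and transcription-coupled strand asymmetry — editing is
strand-symmetric, matching the absence of template/coding strand bias
in the real data. Consequences for interpretation: passing tests show
the *screening logic* is correct under a faithful noise model, not that
the pipeline is robust to caller artifacts or alignment error in real
data.

Because every in-window C/G site's frequency is a deterministic
function of distance and occupancy, all ~4 in-box C/G sites share one
frequency; with parameters strong enough to guarantee that every
occupancy-0.5 box stays detectable across three replicates, each box
therefore yields ~10–20 surviving SNPs rather than the single dominant
site often seen in real spectra. Reproducing "mostly one SNP per box"
would require per-site stochastic editing or context-dependent rates,
which this model intentionally omits.

## Emergent, not tuned

At the defaults above, the pairwise replicate R² of mutation
frequencies lands in the 0.3–0.6 range purely from binomial sampling at
100× depth — the moderate frequency reproducibility seen in real
replicate experiments — and zero background SNPs survive three-replicate
intersection, consistent with N·p0³ << 1.

## Statistics conventions

- **Distance to box**: outside, the gap to the nearest box base
  (adjacent base = 1); inside, −(1 + bases to the nearest edge). The
  published convention fixes only the sign (negative = in box); the
  in-box magnitude is this package's choice, so in-box distances are
  comparable only qualitatively with published plots. Nearest box wins;
  ties break toward the lower coordinate.
- **Strand class**: a reference-strand C→T means the plus strand
  carried the deaminated C — the coding strand (CS) for a '+' gene, the
  template strand (TS) for a '−' gene; G→A swaps the classes. Other
  substitutions are rejected as non-deamination signatures.
- **Replicate R²**: computed pairwise (three values for three
  replicates — the published triplet is assumed pairwise since exactly
  three values accompany three samples), OLS with intercept, replicate
  j regressed on i for i < j; a constant vector makes R² undefined and
  it is reported as such, never as 0.
- **Benchmarking**: detected promoter ids are the downstream gene ids
  of promoter-like regions (both ids for divergent regions; either
  matching counts as overlap). overlap + new = |detected| and
  overlap + missed = |reference| hold by construction and are
  property-tested.
- **Per-promoter peak frequency**: the maximum SNP frequency in the
  region, the standard summary when one promoter holds several sites.

## Problem sizes

Tests and the acceptance script run the simulator at 50–100 kb genomes
with 30–50 genes and 5–10 boxes, 200-seed Monte-Carlo loops at 1e5
positions, and a 1e5-cell population oracle — sizes chosen so the full
suite completes in seconds while every statistical comparison retains
3-standard-error resolution. Sharing expectations rescale linearly to
the 6.3-Mb genome where needed.
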