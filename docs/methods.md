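# Methods

## The genotype model

A genotype of ploidy K over n distinct elements is an unordered multiset of
size K, represented internally as a dosage vector (c₁, …, cₙ), Σcᵢ = K.
The space has C(n+K−1, K) members — 5 for a biallelic tetraploid site, but
already 3 876 for a tetraploid block with 16 candidate haplotypes — which is
why polyploid genotyping needs both careful enumeration and a bounded
search. Genotypes are kept in a canonical order (lexicographic-descending
on the dosage vector, elements in input order); the canonical order is also
the deterministic tie-break everywhere a tie can occur.

**Site-wise likelihood.** The variant-allele read count at a site with
dosage c out of K copies, sequenced to depth d, is modelled as
Binomial(d, p′) with

    p′ = (c/K)(1 − ε) + (1 − c/K) ε.

ε is a symmetric per-base error probability (default 1e-3, a typical
Illumina substitution rate after base-quality filtering). At ε = 0 the
model is the pure binomial c/K sampling model, and data that contradict a
genotype (an alt read under hom-ref) have likelihood zero. The balanced
heterozygote c = K/2 sits at the point of maximal binomial variance
p′(1−p′), which is why it dominates both false-positive calls and
prevalence-normalised false negatives in every experiment this package
runs. At K = 4, ε = 0, the maximum-likelihood boundary between simplex and
duplex lies at VAF = log(½/¾)/log(¼/¾) ≈ 0.369 — alt fractions of 0.38
(30/78) therefore call duplex even when the truth is simplex.

**Haplotype-aware likelihood.** Over a phased block, genotypes range over
candidate haplotypes rather than site alleles. Each read is modelled as a
uniform draw from the K chromosome copies:

    log P(reads | g) = Σ_r w_r · log Σ_h (c_h / K) · P(r | h, ε),

where P(r | h, ε) multiplies (1−ε) per matching covered site and ε per
mismatch. Reads that only partially overlap a block contribute the sites
they cover; this partial overlap is precisely how longer haplotypes add
power, because a read informative for one site constrains the dosage of
every allele on the same haplotype. On single-site biallelic reads the
mixture collapses to the binomial model (minus the combinatorial constant),
which the tests verify numerically.

**Posterior and GQ.** Posteriors are prior × likelihood, normalised with
log-sum-exp. The prior is uniform over candidate genotypes by default; a
dosage-binomial prior with configurable allele frequency is available for
site-wise use. GQ = −10·log₁₀(1 − P(best)), capped at 99 and rounded to
two decimals in VCF output. Per-site GQ inside a block is the marginal
posterior mass of the called per-site dosage vector, summed over all block
genotypes that project to it.

## Bounded genotype proposal

Exhaustive evaluation is used whenever C(n+K−1, K) ≤ L (limit L, default
1024). Otherwise: find the largest k₀ ≤ K with C(n+k₀−1, k₀) ≤ L, evaluate
that space exhaustively under the genuine ploidy-k₀ model (dosages
normalised by k₀, not K), keep a carry subset, extend every kept genotype
with each candidate haplotype (deduplicating as multisets), and repeat,
raising the ploidy by one per iteration until K. The carry subset is either
the top m genotypes by score (default m = 10) or the smallest set with
cumulative posterior ≥ 0.9999; ties resolve in canonical order. The
procedure is expected to work well when the number of haplotypes actually
present is not much larger than k₀; the test suite measures the recovery
rate of the exhaustive-search ML genotype across simulated blocks
(n ≤ 6, K ∈ {4, 6}, ≥ 30 reads per haplotype copy) and requires ≥ 95%.

## Synthetic polyploid construction

The generator emulates how in-silico polyploid benchmarks are built from
diploid truth sets, at the level of read observations rather than FASTQs —
no mapper in the loop, but the statistical structure the genotyper consumes
is preserved.

* **Reference**: i.i.d. bases at 41% GC (human-like) — no repeats,
  homopolymer structure, or mappability pathology.
* **Diploid truths**: SNV rate 1e-3/bp and indel rate 1e-4/bp (human-scale
  heterozygosity), Poisson counts, 67% heterozygous with uniform random
  phase, the rest hom-alt; overlapping indels are redrawn. Confident
  regions keep 2 kb windows with probability 0.9 (high-confidence-benchmark-like coverage with
  gaps); truth is asserted only inside them.
* **Merging**: the polyploid genotype at a site is the concatenation of the
  contributors' phased diploid genotypes; a sample without a record
  contributes hom-ref wherever its confident regions cover the site, and
  sites outside any contributor's confident region are dropped. Confident
  regions are intersected exactly. Conflicting ref alleles (representation
  mismatches) raise rather than merge; the simulator itself emits
  left-aligned, decomposed records, and `normalize_records` is provided for
  imported VCFs.
* **Depths**: full mixture depth = per-sample depth × K/2 (35× per diploid
  → 70× tetraploid, 105× hexaploid); lower test depths are binomial
  thinnings with fraction test/full, mirroring FASTQ subsampling.
* **Reads**: truth sites closer than 300 bp (a short-read footprint) form
  linkage groups; each read covers up to `read_span_sites` consecutive
  sites at a uniformly random window offset, clipped at group edges, with
  window starts balanced so per-site coverage is exactly Poisson(depth).
  Each read copies one of the K chromosomes uniformly — making per-site
  alt counts Binomial(c/K) marginally, the model's generative assumption —
  and each observed allele is replaced by a uniformly chosen different
  allele with probability ε. Span 1 reproduces pure site-wise data.

Because samples are simulated independently, variants shared between
contributors are rare, so high-dosage classes (triplex and above) are
sparse compared with benchmarks built from related individuals; the
balanced-heterozygote error structure is unaffected. Passing tests on this
generator demonstrate the model's behaviour under its own generative
assumptions (plus the staggered-read linkage structure); they do not
certify performance on real reads with mapping error, indel realignment
ambiguity, or non-uniform coverage.

## Calling pipeline

Candidate sites (a truth or candidate-list VCF; genotypes ignored) plus the
reads TSV drive calling. Reads sharing any site are grouped into phased
blocks by union–find; a `span` option truncates read linkage first
(span 1 = site-wise calling). Within a block, candidate haplotypes are the
full allele-combination lattice when it has ≤ 256 members, otherwise the
reference haplotype, every single-alt haplotype, and the observed read
patterns (ref-filled at uncovered sites). Genotypes are scored against a
precomputed read × haplotype log-likelihood matrix; blocks whose genotype
space exceeds the limit go through the bounded proposal. Sites whose best
genotype carries no variant allele are not emitted; emitted records carry
GT (phased with PS inside multi-site blocks), GQ, DP, and AD.

A known limitation of the uniform genotype prior: when all reads span an
entire block, a spurious haplotype matching a recurrent error pattern can
absorb those reads and slightly distort dosages, since no penalty is paid
for postulating an extra distinct haplotype. Production callers temper
this with haplotype-sparsity priors; here candidate quality is instead
maintained by the simulator's staggered reads and by the lattice candidates
for small blocks.

## Evaluation

Matching is order-independent and restricted to confident regions.
Genotype mode compares the full allele-dosage multiset at a site; a call at
a truth site with the wrong multiset is a single genotype-error record that
counts as one false positive and one false negative (as combine-mode
benchmarking annotates FP_CA/FN_CA pairs), so summaries report raw FP/FN
splits alongside. A ploidy mismatch is a flagged genotype error. Allele
mode scores each (site, alt allele) pair and ignores dosage. Precision,
recall, and F are harmonic-mean based with NaN (never 0) for empty
denominators. False-positive stratification keys biallelic calls by the
called class label ((K−c)×'A' + c×'a'); false-negative rates normalise
missed truths by truth-set prevalence within evaluated regions (not
confident-region length — the documented choice where both readings were
defensible). The copy-number spectrum histograms Δ = called − true dosage.
PR curves sweep GQ descending with ties grouped; recall is non-decreasing
as the threshold relaxes. Concordance assigns every distinct
(site, genotype) or (site, allele) key to its exact callset-membership
subset; with (caller, dataset) keys and two datasets per caller, per-caller
discordance counts keys present in exactly one of the pair.

## Numerical and design choices

* Exact integer combinatorics everywhere (`math.comb`); enumeration refuses
  spaces above 2×10⁶ members and directs callers to the proposal module.
* Log-space throughout; log-sum-exp for normalisation; −∞ likelihoods are
  legal and an all-−∞ candidate set is an error ("no viable genotype").
* Ties in dosage argmax break toward the lower dosage; ties in posterior
  break toward canonical order. No directional bias is engineered, even
  though real callers empirically show a −1-copy tendency.
* Coordinates are 0-based half-open internally, 1-based in VCF, 0-based
  half-open in BED, converted only at the I/O boundary.
* One master seed is split with `numpy.random.SeedSequence.spawn` per stage
  and per depth-grid cell (each derived seed < 2³¹), so grid cells are
  independently reproducible and an experiment re-run is byte-identical.
* Intermediate-ploidy scoring in the proposal uses the genuine
  reduced-ploidy mixture (dosages normalised by the current k), not the
  target-ploidy model.

## Problem sizes used in tests

Unit and property tests run on references of 30–400 kb with 2–3 simulated
diploids; the parameter-recovery check uses a 1 Mb tetraploid at 100× per
haplotype copy (~1 800 truth sites) and requires ≥ 99% genotype recovery;
the proposal recovery property uses 200 simulated blocks. These sizes keep
the full suite under a minute while leaving every statistical assertion
comfortably powered.

## Known limitations

* No indel realignment, pair-HMM error model, or de novo assembly: reads
  are abstract allele observations, so alignment-induced error structure is
  out of scope by design.
* The AAaa-style stratification labels apply to biallelic records only;
  multi-allelic sites are modelled (multinomial mixture) but excluded from
  class tables, as in biallelic-stratified benchmarks.
* The bounded window comparator for imported callsets normalises by
  left-alignment and decomposition; full haplotype-playout
  equivalence between alternative phased representations is not
  implemented.
* Candidate haplotypes are derived from read patterns, not assembly;
  haplotypes supported only by reads that never co-cover informative sites
  can be missed in very long blocks.
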