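# polygt — polyploid small-variant genotyping and benchmarking

Genotyping polyploids (tetraploid potato, hexaploid wheat, triploid banana,
polyploid tumor genomes) from short-read sequencing is much harder than
genotyping diploids: the number of possible genotypes at a locus is
combinatorial in the ploidy K and the number of distinct alleles, and a read
cannot distinguish identical chromosome copies without physical linkage to a
nearby heterozygous allele. `polygt` is a desk-scale toolkit for studying
exactly this problem. It provides:

* **the genotype model** — a genotype of ploidy K over n elements (alleles
  or haplotypes) is a multiset of size K, counted by C(n+K−1, K). Site-wise,
  the variant-allele count at depth d under dosage c is
  Binomial(d, p′) with p′ = (c/K)(1−ε) + (1−c/K)ε for per-base error ε.
  Haplotype-aware, each read is a mixture draw over chromosome copies:
  log P(reads | g) = Σ_r w_r · log Σ_h (c_h/K) · P(r | h, ε).
  Posteriors come with phred-scaled genotype qualities (GQ).
* **a bounded genotype-proposal algorithm** for high ploidy: exhaustively
  evaluate the largest ploidy k₀ ≤ K whose genotype space fits a limit L,
  carry the m best-scoring genotypes forward, extend each by one haplotype
  copy, and iterate until ploidy K.
* **a synthetic-polyploid constructor** that emulates in-silico diploid
  mixtures: simulated phased diploid truths are merged by genotype
  concatenation, confident regions intersected, and reads drawn from the K
  chromosome copies at mixture depth d·K/2 (35× per diploid → 70× tetraploid,
  105× hexaploid), with binomial downsampling by test/full depth.
* **an evaluation engine** — genotype-match and allele-match ("squash
  ploidy") benchmarking inside confident regions, genotype-error
  classification (one false positive plus one false negative per wrong
  dosage), stratification by genotype class (AAaa-style labels), allele
  copy-number error spectra, GQ-ranked precision–recall curves, and
  multi-callset concordance tables.

Everything runs on plain-text formats: FASTA, VCF 4.2 (arbitrary-ploidy GT,
GQ/DP/AD/PS), BED, and a small reads TSV that stands in for BAM at desk
scale.

## Worked example

Run a tetraploid experiment (two simulated 35× diploids merged into one 70×
tetraploid mixture on a 100 kb reference, then called and evaluated at 10×,
30×, and 70×):

```sh
cat > demo.yaml <<EOF
master_seed: 1
reference_length: 100000
n_samples: 2
depth_grid: [10.0, 30.0, 70.0]
EOF
polygt -v experiment --config demo.yaml --out demo_out
```

which logs

```
INFO polygt: experiment: ploidy=4 full_depth=70.0 seeds={'reference': 1641411168, ...}
INFO polygt: merged truth: 164 sites in 10 regions
INFO polygt: depth 10x: F=0.7250 (genotype), F=0.9750 (allele)
INFO polygt: depth 30x: F=0.9390 (genotype), F=1.0000 (allele)
INFO polygt: depth 70x: F=0.9878 (genotype), F=1.0000 (allele)
```

Genotype-level F-measure climbs with depth (0.73 → 0.94 → 0.99) while
allele-level F saturates almost immediately: nearly all residual errors are
wrong allele dosages at real variant sites, not wrong alleles. The emitted
calls (`demo_out/calls_30x.vcf`) carry arbitrary-ploidy genotypes:

```
chr1  1321  .  C  T  .  PASS  .  GT:GQ:DP:AD  0/0/0/1:13:37:26,11
chr1  2203  .  G  A  .  PASS  .  GT:GQ:DP:AD  0/0/1/1:13:27:13,14
```

`demo_out/experiment.json` additionally contains the per-depth
stratifications; at every depth the modal false-positive genotype class is a
balanced heterozygote (`AAaa`) — the point of maximal binomial variance.

The library surface mirrors the CLI. The classic three-linked-SNV rescue:

```python
>>> import polygt as pg
>>> [pg.ml_site_genotype(a, 50, 4, 0.01) for a in (19, 30, 16)]   # site-wise
[2, 2, 1]
>>> haps = [pg.Haplotype("b", 0, 3, ((0, 0), (1, 1), (2, 0))),
...         pg.Haplotype("b", 0, 3, ((0, 1), (1, 0), (2, 1)))]
>>> reads = [pg.ReadObservation((p,), (1,), w) for p, w in [(0, 19), (1, 30), (2, 16)]] + \
...         [pg.ReadObservation((p,), (0,), w) for p, w in [(0, 31), (1, 20), (2, 34)]]
>>> res = pg.call_block(reads, haps, pg.ModelParams(ploidy=4, error_rate=0.01))
>>> [sum(res.site_dosages[p][1:]) for p in (0, 1, 2)]             # phased
[1, 3, 1]
```

Site-wise likelihoods miscall the first two sites as duplex; phasing the
three sites through two haplotypes recovers the true simplex/triplex/simplex
dosages, because reads supporting any site of a haplotype count toward every
allele on it.

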