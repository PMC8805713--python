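"""Synthetic polyploid construction: diploid truths, merges, read simulation.

Polyploid benchmark samples are built the way in-silico mixture benchmarks
build them: simulate K/2 diploid samples against one reference, merge their
phased truth genotypes by concatenation into a ploidy-K truth, intersect
their confident regions, and mix reads drawn from all K chromosome copies.
Sequencing each contributing diploid to depth d yields a mixture of full
depth d * K / 2 (35x per sample -> 70x tetraploid, 105x hexaploid), and
lower test depths are produced by binomial downsampling with fraction
test_depth / full_depth.

Reads are simulated at the observation level: each read picks one of the K
haplotype copies uniformly at random and reports that copy's alleles at up
to ``read_span_sites`` consecutive truth sites, with symmetric per-base
error.  Marginally the variant-allele count at a site with dosage c is then
binomial with success probability c/K — exactly the genotype model's
generative assumption.  Span 1 gives pure site-wise data; larger spans give
the linkage that haplotype-aware calling exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "DiploidVariant",
    "DiploidTruth",
    "TruthSite",
    "PolyploidTruth",
    "ReadRow",
    "simulate_reference",
    "simulate_diploid_truth",
    "merge_polyploid_truth",
    "intersect_regions",
    "full_mixture_depth",
    "downsample_fraction",
    "simulate_reads",
    "downsample_reads",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiploidVariant:
    """One phased diploid truth record (0-based position, single alt)."""

    position: int
    ref: str
    alt: str
    genotype: tuple[int, int]  # phased pair of allele indices, 0 = ref


@dataclass
class DiploidTruth:
    """A simulated diploid sample: phased variants plus confident regions."""

    sample: str
    contig: str
    variants: list[DiploidVariant]
    regions: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping
    reference_length: int


@dataclass(frozen=True)
class TruthSite:
    position: int
    ref: str
    alts: tuple[str, ...]
    phased_alleles: tuple[int, ...]  # one allele index per chromosome copy

    @property
    def dosages(self) -> tuple[int, ...]:
        counts = [0] * (1 + len(self.alts))
        for a in self.phased_alleles:
            counts[a] += 1
        return tuple(counts)


@dataclass
class PolyploidTruth:
    """Merged ploidy-K truth: K = 2 x number of contributing diploids."""

    ploidy: int
    contig: str
    sites: list[TruthSite]
    regions: list[tuple[int, int]]
    samples: list[str]
    reference_length: int


@dataclass(frozen=True)
class ReadRow:
    """Aggregated read observations: identical reads share a row."""

    contig: str
    positions: tuple[int, ...]  # 0-based, ascending
    alleles: tuple[int, ...]
    count: int = 1

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.alleles):
            raise ValueError("positions and alleles differ in length")
        if list(self.positions) != sorted(self.positions):
            raise ValueError("positions must be sorted ascending")
        if self.count < 1:
            raise ValueError("count must be >= 1")


# ---------------------------------------------------------------------------
# Reference and diploid truth simulation
# ---------------------------------------------------------------------------

def simulate_reference(length: int, seed: int, gc_content: float = 0.41) -> str:
    """Random uppercase ACGT sequence; GC split evenly between G and C."""
    if length < 1:
        raise ValueError("reference length must be >= 1")
    if not (0 < gc_content < 1):
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2
    gc = gc_content / 2
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(_BASES[idx])


def _draw_confident_regions(
    length: int, fraction: float, rng: np.random.Generator, window: int = 2000
) -> list[tuple[int, int]]:
    """Windows kept with probability ``fraction``, merged where adjacent."""
    if fraction >= 1.0:
        return [(0, length)]
    kept: list[tuple[int, int]] = []
    for start in range(0, length, window):
        if rng.random() < fraction:
            kept.append((start, min(start + window, length)))
    merged: list[tuple[int, int]] = []
    for s, e in kept:
        if merged and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [tuple(iv) for iv in merged]


def _in_regions(pos: int, regions: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in regions)


def simulate_diploid_truth(
    reference: str,
    snv_rate: float = 1e-3,
    indel_rate: float = 1e-4,
    het_fraction: float = 0.67,
    seed: int = 0,
    sample: str = "S1",
    contig: str = "chr1",
    confident_fraction: float = 0.9,
    max_indel_len: int = 4,
) -> DiploidTruth:
    """Emulate one diploid truth sample against ``reference``.

    Variant counts are Poisson with mean rate x length; a ``het_fraction``
    of variants are heterozygous with the alt phased onto one of the two
    haplotypes uniformly, the rest hom-alt.  Overlapping indels are redrawn.
    Only variants inside the confident regions are asserted.
    """
    if not (0 <= snv_rate <= 0.1 and 0 <= indel_rate <= 0.1):
        raise ValueError("variant rates must be in [0, 0.1]")
    if not (0 <= het_fraction <= 1):
        raise ValueError("het_fraction must be in [0, 1]")
    length = len(reference)
    rng = np.random.default_rng(seed)
    regions = _draw_confident_regions(length, confident_fraction, rng)

    occupied: set[int] = set()
    variants: list[DiploidVariant] = []

    def place(position: int, ref: str, alt: str, footprint: range) -> bool:
        if any(p in occupied for p in footprint):
            return False
        occupied.update(footprint)
        if rng.random() < het_fraction:
            gt = (0, 1) if rng.random() < 0.5 else (1, 0)
        else:
            gt = (1, 1)
        variants.append(DiploidVariant(position, ref, alt, gt))
        return True

    n_snv = rng.poisson(snv_rate * length)
    for pos in rng.integers(0, length, size=n_snv):
        pos = int(pos)
        ref = reference[pos]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        place(pos, ref, alt, range(pos, pos + 1))

    n_indel = rng.poisson(indel_rate * length)
    attempts = 0
    placed = 0
    while placed < n_indel and attempts < 10 * n_indel + 100:
        attempts += 1
        pos = int(rng.integers(0, max(1, length - max_indel_len - 1)))
        ilen = int(rng.integers(1, max_indel_len + 1))
        if rng.random() < 0.5:  # deletion: anchor base + deleted span
            ref = reference[pos : pos + 1 + ilen]
            alt = reference[pos]
            footprint = range(pos, pos + 1 + ilen)
        else:  # insertion after the anchor base
            ref = reference[pos]
            alt = ref + "".join(rng.choice(list("ACGT"), size=ilen))
            footprint = range(pos, pos + 1)
        if len(ref) != len(alt) and ref != alt and place(pos, ref, alt, footprint):
            placed += 1

    variants = [v for v in variants if _in_regions(v.position, regions)]
    variants.sort(key=lambda v: v.position)
    return DiploidTruth(sample, contig, variants, regions, length)


# ---------------------------------------------------------------------------
# Region algebra and merging
# ---------------------------------------------------------------------------

def intersect_regions(
    bed_sets: Sequence[Sequence[tuple[int, int]]]
) -> list[tuple[int, int]]:
    """Exact intersection of interval sets (0-based half-open, sorted output)."""
    if not bed_sets:
        raise ValueError("need at least one interval set")

    def normalize(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
        for s, e in ivs:
            if s >= e:
                raise ValueError(f"malformed interval [{s}, {e})")
        merged: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    result = normalize(bed_sets[0])
    for ivs in bed_sets[1:]:
        other = normalize(ivs)
        out: list[tuple[int, int]] = []
        i = j = 0
        while i < len(result) and j < len(other):
            s = max(result[i][0], other[j][0])
            e = min(result[i][1], other[j][1])
            if s < e:
                out.append((s, e))
            if result[i][1] < other[j][1]:
                i += 1
            else:
                j += 1
        result = out
    return result


def as_polyploid(truth: DiploidTruth) -> PolyploidTruth:
    """View a single diploid truth as a ploidy-2 truth (diploid baseline)."""
    sites = [
        TruthSite(v.position, v.ref, (v.alt,), v.genotype) for v in truth.variants
    ]
    return PolyploidTruth(
        ploidy=2,
        contig=truth.contig,
        sites=sites,
        regions=list(truth.regions),
        samples=[truth.sample],
        reference_length=truth.reference_length,
    )


def merge_polyploid_truth(truths: Sequence[DiploidTruth]) -> PolyploidTruth:
    """Concatenate diploid genotypes into a ploidy-2n truth.

    A site recorded in some samples but not others contributes hom-ref from
    each absent sample whose confident regions cover it; a site outside any
    contributor's confident region is excluded.  Alt alleles are unioned
    across samples with dosage-preserving index remapping.  Conflicting ref
    alleles at a position are a representation mismatch and raise.
    """
    if len(truths) < 2:
        raise ValueError("need at least two diploid truths to merge")
    contig = truths[0].contig
    length = truths[0].reference_length
    if any(t.contig != contig or t.reference_length != length for t in truths):
        raise ValueError("all truths must share the same reference")

    regions = intersect_regions([t.regions for t in truths])
    by_sample = [{v.position: v for v in t.variants} for t in truths]
    positions = sorted({p for d in by_sample for p in d})

    sites: list[TruthSite] = []
    for pos in positions:
        if not all(_in_regions(pos, t.regions) for t in truths):
            continue  # outside some contributor's confident region
        refs = {by_sample[i][pos].ref for i in range(len(truths)) if pos in by_sample[i]}
        if len(refs) > 1:
            raise ValueError(
                f"conflicting ref alleles at {contig}:{pos + 1}: {sorted(refs)} "
                "(variant representation mismatch; left-align and decompose first)"
            )
        ref = refs.pop()
        alts: list[str] = []
        phased: list[int] = []
        for d in by_sample:
            var = d.get(pos)
            if var is None:
                phased.extend([0, 0])  # confident hom-ref
                continue
            if var.alt not in alts:
                alts.append(var.alt)
            idx = 1 + alts.index(var.alt)
            phased.extend(idx if a else 0 for a in var.genotype)
        sites.append(TruthSite(pos, ref, tuple(alts), tuple(phased)))

    return PolyploidTruth(
        ploidy=2 * len(truths),
        contig=contig,
        sites=sites,
        regions=regions,
        samples=[t.sample for t in truths],
        reference_length=length,
    )


# ---------------------------------------------------------------------------
# Depth arithmetic
# ---------------------------------------------------------------------------

def full_mixture_depth(per_sample_depth: float, ploidy: int) -> float:
    """Full mixture depth = per-sample depth x ploidy / 2 (diploid mixtures)."""
    if per_sample_depth <= 0:
        raise ValueError("per-sample depth must be positive")
    if ploidy < 2 or ploidy % 2 != 0:
        raise ValueError("ploidy must be an even integer >= 2 (mixtures of diploids)")
    return per_sample_depth * ploidy / 2


def downsample_fraction(test_depth: float, full_depth: float) -> Fraction | float:
    """Sampling fraction test_depth / full_depth, in (0, 1]."""
    if not (0 < test_depth <= full_depth):
        raise ValueError("need 0 < test_depth <= full_depth")
    if float(test_depth).is_integer() and float(full_depth).is_integer():
        return Fraction(int(test_depth), int(full_depth))
    return test_depth / full_depth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    truth: PolyploidTruth,
    depth: float,
    read_span_sites: int = 1,
    error_rate: float = 1e-3,
    seed: int = 0,
    max_span_bp: int = 300,
) -> list[ReadRow]:
    """Draw staggered reads from the K phased copies of ``truth``.

    Sites closer than ``max_span_bp`` form linkage groups (a short-read
    footprint).  Within a group of m sites, each read covers a window of up
    to ``read_span_sites`` consecutive sites at a uniformly random offset
    (windows are clipped at the group edges), so neighbouring windows
    partially overlap — the configuration in which reads covering one site
    still discriminate the haplotype dosage at linked sites.  Window starts
    are drawn so that every site's coverage is exactly Poisson(depth).

    Each read copies one of the K chromosomes uniformly at random; a
    sequencing error replaces the observed allele with a uniformly chosen
    different allele with probability ``error_rate``.  Span 1 reproduces
    pure site-wise data.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if read_span_sites < 1:
        raise ValueError("read span must be >= 1")
    rng = np.random.default_rng(seed)
    k = truth.ploidy
    rows: dict[tuple[tuple[int, ...], tuple[int, ...]], int] = {}

    groups: list[list[TruthSite]] = []
    for site in truth.sites:
        if groups and site.position - groups[-1][-1].position <= max_span_bp:
            groups[-1].append(site)
        else:
            groups.append([site])

    for group in groups:
        m = len(group)
        s = min(read_span_sites, m)
        # a site is covered by s of the m+s-1 possible window starts
        n_reads = rng.poisson(depth * (m + s - 1) / s)
        if n_reads == 0:
            continue
        starts = rng.integers(-(s - 1), m, size=n_reads)
        copies = rng.integers(0, k, size=n_reads)
        for start, copy in zip(starts, copies):
            lo, hi = max(int(start), 0), min(int(start) + s, m)
            window = group[lo:hi]
            positions = tuple(site.position for site in window)
            alleles = []
            for site in window:
                a = site.phased_alleles[copy]
                if error_rate > 0 and rng.random() < error_rate:
                    n_all = 1 + len(site.alts)
                    if n_all > 1:
                        others = [x for x in range(n_all) if x != a]
                        a = int(others[rng.integers(0, len(others))])
                alleles.append(int(a))
            key = (positions, tuple(alleles))
            rows[key] = rows.get(key, 0) + 1
    return [
        ReadRow(truth.contig, pos, alle, count)
        for (pos, alle), count in sorted(rows.items())
    ]


def downsample_reads(
    rows: Sequence[ReadRow], fraction: Fraction | float, seed: int = 0
) -> list[ReadRow]:
    """Binomial thinning: each read survives independently with ``fraction``."""
    f = float(fraction)
    if not (0 < f <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if f == 1.0:
        return list(rows)
    rng = np.random.default_rng(seed)
    out: list[ReadRow] = []
    for row in rows:
        kept = int(rng.binomial(row.count, f))
        if kept:
            out.append(ReadRow(row.contig, row.positions, row.alleles, kept))
    return out
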