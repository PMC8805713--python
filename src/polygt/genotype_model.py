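"""Polyploid genotype space and likelihood model.

A genotype of ploidy K over n distinct elements (alleles at one site, or
haplotypes across a phased block) is a multiset of size K, represented by a
dosage vector ``(c_1, ..., c_n)`` with ``sum(c_i) == K``.  The number of such
genotypes is C(n + K - 1, K), combinatorial in both ploidy and allele count —
which is what makes polyploid genotyping hard in the first place.

Two likelihood routes are provided:

* **site-wise**: allele observations at one site are binomial with success
  probability ``p' = (c/K)(1 - eps) + (1 - c/K) eps``, where ``c`` is the
  variant-allele dosage and ``eps`` a symmetric per-base error rate.  With
  ``eps = 0`` this is the pure binomial c/K model.
* **haplotype-aware**: each read is a draw from one of the K chromosome
  copies, so the read likelihood under a genotype is a mixture over
  haplotypes weighted by dosage/K.  Reads covering several phased sites
  discriminate between haplotypes and sharpen the dosage posterior — the
  mechanism by which longer haplotypes improve genotyping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

GQ_CAP = 99.0  # phred cap on genotype quality, common VCF practice
GENOTYPE_SPACE_SAFETY_CAP = 2_000_000  # refuse exhaustive enumeration above this

__all__ = [
    "Site",
    "Haplotype",
    "Genotype",
    "ReadObservation",
    "GenotypePosterior",
    "ModelParams",
    "BlockCall",
    "genotype_space_size",
    "enumerate_genotypes",
    "site_dosage_log_likelihood",
    "ml_site_genotype",
    "read_haplotype_log_likelihood",
    "genotype_log_likelihood",
    "genotype_posteriors",
    "call_block",
    "genotype_class_label",
    "parse_genotype_class_label",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Site:
    """A variant site. ``position`` is 0-based internally (VCF adds 1)."""

    contig: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")
        if not self.ref_allele:
            raise ValueError("empty ref allele")
        alts = tuple(self.alt_alleles)
        object.__setattr__(self, "alt_alleles", alts)
        if len(set(alts)) != len(alts) or self.ref_allele in alts:
            raise ValueError(f"alt alleles must be distinct from each other and ref: {alts}")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)


@dataclass(frozen=True)
class Haplotype:
    """One chromosome copy's alleles over a half-open genomic window.

    ``alleles`` maps site position -> allele index (0 = ref).
    """

    contig: str
    start: int
    end: int
    alleles: tuple[tuple[int, int], ...]  # sorted (position, allele_index)

    def __post_init__(self) -> None:
        pairs = tuple(sorted(dict(self.alleles).items()))
        object.__setattr__(self, "alleles", pairs)
        for pos, _ in pairs:
            if not (self.start <= pos < self.end):
                raise ValueError(f"site {pos} outside window [{self.start}, {self.end})")

    def allele_at(self, position: int) -> int:
        mapping = self.__dict__.get("_map")
        if mapping is None:
            mapping = dict(self.alleles)
            object.__setattr__(self, "_map", mapping)
        try:
            return mapping[position]
        except KeyError:
            raise KeyError(f"haplotype does not map site {position}") from None

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(pos for pos, _ in self.alleles)


@dataclass(frozen=True)
class Genotype:
    """A multiset of ploidy K over an (external) ordered element list.

    ``dosages[i]`` is the copy count of element i.  Canonical ordering of
    genotypes is lexicographic-descending on the dosage vector, so for two
    alleles and K=2 the order is (2,0), (1,1), (0,2).
    """

    dosages: tuple[int, ...]

    def __post_init__(self) -> None:
        ds = tuple(int(d) for d in self.dosages)
        object.__setattr__(self, "dosages", ds)
        if any(d < 0 for d in ds):
            raise ValueError(f"negative dosage in {ds}")
        if sum(ds) < 1:
            raise ValueError("ploidy must be >= 1")

    @property
    def ploidy(self) -> int:
        return sum(self.dosages)

    @property
    def support(self) -> tuple[int, ...]:
        """Indices of elements with nonzero dosage."""
        return tuple(i for i, d in enumerate(self.dosages) if d > 0)

    def expand(self) -> tuple[int, ...]:
        """Element index repeated by dosage, e.g. (1, 3) -> (0, 1, 1, 1)."""
        out: list[int] = []
        for i, d in enumerate(self.dosages):
            out.extend([i] * d)
        return tuple(out)

    def sort_key(self) -> tuple[int, ...]:
        # canonical (descending-lex) order == ascending order of negated vector
        return tuple(-d for d in self.dosages)


@dataclass(frozen=True)
class ReadObservation:
    """Alleles one read (or a group of identical reads) observed.

    ``covered_sites`` are 0-based positions in ascending order; ``weight`` is
    the read multiplicity (aggregated identical observations).
    """

    covered_sites: tuple[int, ...]
    observed_allele_indices: tuple[int, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        sites = tuple(self.covered_sites)
        obs = tuple(self.observed_allele_indices)
        object.__setattr__(self, "covered_sites", sites)
        object.__setattr__(self, "observed_allele_indices", obs)
        if len(sites) != len(obs):
            raise ValueError("covered_sites and observed_allele_indices differ in length")
        if list(sites) != sorted(sites):
            raise ValueError("covered sites must be sorted ascending")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class GenotypePosterior:
    candidates: list[Genotype]
    log_likelihoods: np.ndarray
    log_priors: np.ndarray
    posteriors: np.ndarray
    best_index: int
    gq: float

    @property
    def best(self) -> Genotype:
        return self.candidates[self.best_index]


@dataclass
class ModelParams:
    """Model configuration: ploidy K, error rate, proposal bounds, prior."""

    ploidy: int
    error_rate: float = 1e-3
    genotype_limit: int = 1024
    carry: int = 10
    prior: str = "uniform"  # "uniform" or "dosage-binomial"
    prior_allele_freq: float = 0.5

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error rate must be in [0, 0.5)")
        if self.genotype_limit < 1 or self.carry < 1:
            raise ValueError("genotype limit and carry size must be >= 1")
        if self.prior not in ("uniform", "dosage-binomial"):
            raise ValueError(f"unknown prior {self.prior!r}")


# ---------------------------------------------------------------------------
# Genotype space
# ---------------------------------------------------------------------------

def genotype_space_size(n_elements: int, ploidy: int) -> int:
    """Number of multisets of size ``ploidy`` from ``n_elements``: C(n+K-1, K)."""
    if n_elements < 1 or ploidy < 1:
        raise ValueError("n_elements and ploidy must be >= 1")
    return math.comb(n_elements + ploidy - 1, ploidy)


def enumerate_genotypes(n_elements: int, ploidy: int) -> list[Genotype]:
    """All dosage vectors summing to ``ploidy``, in canonical order."""
    size = genotype_space_size(n_elements, ploidy)
    if size > GENOTYPE_SPACE_SAFETY_CAP:
        raise ValueError(
            f"genotype space of size {size} exceeds the safety cap "
            f"({GENOTYPE_SPACE_SAFETY_CAP}); use the proposal module"
        )

    out: list[Genotype] = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            out.append(Genotype(tuple(prefix + [remaining])))
            return
        for d in range(remaining, -1, -1):  # descending => canonical order
            rec(prefix + [d], remaining - d, slots - 1)

    rec([], ploidy, n_elements)
    assert len(out) == size
    return out


# ---------------------------------------------------------------------------
# Site-wise (binomial) likelihood
# ---------------------------------------------------------------------------

def _dosage_error_prob(dosage: int, ploidy: int, error_rate: float) -> float:
    """P(read shows alt | dosage c of K, symmetric per-base error eps)."""
    vaf = dosage / ploidy
    return vaf * (1.0 - error_rate) + (1.0 - vaf) * error_rate


def site_dosage_log_likelihood(
    alt_count: int, depth: int, dosage: int, ploidy: int, error_rate: float = 0.0
) -> float:
    """log Binomial(alt_count; depth, p') with p' = (c/K)(1-eps) + (1-c/K)eps.

    With ``error_rate == 0`` and a dosage the data contradict (e.g. alt reads
    under hom-ref), returns -inf.
    """
    if not (0 <= alt_count <= depth):
        raise ValueError(f"need 0 <= alt_count <= depth, got {alt_count}/{depth}")
    if not (0 <= dosage <= ploidy):
        raise ValueError(f"need 0 <= dosage <= ploidy, got {dosage}/{ploidy}")
    if not (0 <= error_rate < 0.5):
        raise ValueError("error rate must be in [0, 0.5)")
    p = _dosage_error_prob(dosage, ploidy, error_rate)
    log_comb = gammaln(depth + 1) - gammaln(alt_count + 1) - gammaln(depth - alt_count + 1)
    if p == 0.0:
        return float(log_comb) if alt_count == 0 else -math.inf
    if p == 1.0:
        return float(log_comb) if alt_count == depth else -math.inf
    return float(log_comb + alt_count * math.log(p) + (depth - alt_count) * math.log1p(-p))


def ml_site_genotype(alt_count: int, depth: int, ploidy: int, error_rate: float = 0.0) -> int:
    """Maximum-likelihood variant-allele dosage; ties broken toward lower c."""
    best_c, best_ll = 0, -math.inf
    for c in range(ploidy + 1):
        ll = site_dosage_log_likelihood(alt_count, depth, c, ploidy, error_rate)
        if ll > best_ll:  # strict > keeps the lowest dosage on ties
            best_c, best_ll = c, ll
    return best_c


# ---------------------------------------------------------------------------
# Haplotype-aware (mixture) likelihood
# ---------------------------------------------------------------------------

def read_haplotype_log_likelihood(
    read: ReadObservation, hap: Haplotype, error_rate: float
) -> float:
    """Sum over covered sites of log(1-eps) on match, log(eps) on mismatch."""
    total = 0.0
    for pos, obs in zip(read.covered_sites, read.observed_allele_indices):
        expected = hap.allele_at(pos)  # KeyError if hap does not map the site
        if obs == expected:
            total += math.log1p(-error_rate) if error_rate > 0 else 0.0
        else:
            if error_rate == 0.0:
                return -math.inf
            total += math.log(error_rate)
    return total


def genotype_log_likelihood(
    reads: Sequence[ReadObservation],
    genotype: Genotype,
    haplotypes: Sequence[Haplotype],
    error_rate: float,
) -> float:
    """Mixture likelihood: each read drawn from one copy, weights dosage/K.

    ``sum_r w_r * log( sum_h (c_h / K) * P(read_r | h) )``.  On single-site
    biallelic reads this equals the binomial form minus its combinatorial
    constant.  An empty read list returns 0 with a warning.
    """
    if len(genotype.dosages) != len(haplotypes):
        raise ValueError("genotype dosage vector length must match haplotype list")
    if not reads:
        warnings.warn("genotype_log_likelihood called with no reads", stacklevel=2)
        return 0.0
    ploidy = genotype.ploidy
    support = genotype.support
    log_weights = np.log([genotype.dosages[i] / ploidy for i in support])
    total = 0.0
    for read in reads:
        terms = log_weights + np.array(
            [read_haplotype_log_likelihood(read, haplotypes[i], error_rate) for i in support]
        )
        total += read.weight * float(logsumexp(terms))
    return total


def _likelihood_matrix(
    reads: Sequence[ReadObservation],
    haplotypes: Sequence[Haplotype],
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(read, haplotype) log-likelihoods and read weights, computed once
    so candidate genotypes can be scored as mixtures over the same matrix."""
    mat = np.empty((len(reads), len(haplotypes)))
    for i, read in enumerate(reads):
        for j, hap in enumerate(haplotypes):
            mat[i, j] = read_haplotype_log_likelihood(read, hap, error_rate)
    weights = np.array([r.weight for r in reads])
    return mat, weights


def _batch_genotype_ll(
    mat: np.ndarray, weights: np.ndarray, dosage_matrix: np.ndarray, ploidy: int
) -> np.ndarray:
    """Mixture log-likelihood for many genotypes at once.

    ``dosage_matrix`` is (candidates x haplotypes); returns one value per
    candidate: sum_r w_r logsumexp_h( log(d_h/K) + mat[r, h] ).
    """
    with np.errstate(divide="ignore"):
        log_mix = np.log(dosage_matrix / ploidy)  # -inf where dosage 0
    terms = mat[None, :, :] + log_mix[:, None, :]
    per_read = logsumexp(terms, axis=2)
    return per_read @ weights


# ---------------------------------------------------------------------------
# Posterior and calling
# ---------------------------------------------------------------------------

def _log_prior(genotype: Genotype, params: ModelParams) -> float:
    if params.prior == "uniform":
        return 0.0
    # dosage-binomial: multiset-permutation prior with per-element frequency;
    # for two elements this is Binomial(c; K, f).
    n = len(genotype.dosages)
    k = genotype.ploidy
    if n == 2:
        f = params.prior_allele_freq
        c = genotype.dosages[1]
        return (
            float(gammaln(k + 1) - gammaln(c + 1) - gammaln(k - c + 1))
            + c * math.log(f)
            + (k - c) * math.log1p(-f)
        )
    log_multi = float(gammaln(k + 1) - sum(gammaln(d + 1) for d in genotype.dosages))
    return log_multi - k * math.log(n)


def genotype_posteriors(
    candidates: Sequence[Genotype],
    log_likelihoods: Sequence[float],
    log_priors: Sequence[float] | None = None,
) -> GenotypePosterior:
    """Normalize prior x likelihood with log-sum-exp; GQ = -10 log10(1 - P(best)).

    Deterministic tie-break by canonical genotype order.
    """
    if not candidates:
        raise ValueError("no candidate genotypes")
    ll = np.asarray(log_likelihoods, dtype=float)
    lp = np.zeros_like(ll) if log_priors is None else np.asarray(log_priors, dtype=float)
    unnorm = ll + lp
    if not np.any(np.isfinite(unnorm)):
        raise ValueError("no viable genotype: all candidate likelihoods are -inf")
    log_z = logsumexp(unnorm)
    post = np.exp(unnorm - log_z)
    post /= post.sum()
    best_post = post.max()
    tied = [i for i in range(len(candidates)) if post[i] >= best_post - 1e-12]
    best_index = min(tied, key=lambda i: candidates[i].sort_key())
    one_minus = max(0.0, 1.0 - float(post[best_index]))
    gq = GQ_CAP if one_minus <= 10 ** (-GQ_CAP / 10) else -10.0 * math.log10(one_minus)
    return GenotypePosterior(
        candidates=list(candidates),
        log_likelihoods=ll,
        log_priors=lp,
        posteriors=post,
        best_index=best_index,
        gq=min(gq, GQ_CAP),
    )


@dataclass
class BlockCall:
    """Joint genotype call for one phased block."""

    haplotypes: list[Haplotype]
    posterior: GenotypePosterior
    site_dosages: dict[int, tuple[int, ...]]  # position -> dosage per allele index
    site_gq: dict[int, float]
    phased_alleles: dict[int, tuple[int, ...]]  # position -> allele per copy (phase-ordered)
    block_start: int
    block_end: int

    @property
    def block_length(self) -> int:
        return self.block_end - self.block_start

    @property
    def gq(self) -> float:
        return self.posterior.gq


def _project_genotype(
    genotype: Genotype, haplotypes: Sequence[Haplotype], positions: Sequence[int]
) -> dict[int, tuple[int, ...]]:
    """Per-site allele-dosage vectors implied by a haplotype genotype."""
    out: dict[int, tuple[int, ...]] = {}
    for pos in positions:
        n_alleles = max(h.allele_at(pos) for h in haplotypes) + 1
        dosage = [0] * n_alleles
        for i, d in enumerate(genotype.dosages):
            if d:
                dosage[haplotypes[i].allele_at(pos)] += d
        out[pos] = tuple(dosage)
    return out


def call_block(
    reads: Sequence[ReadObservation],
    candidate_haplotypes: Sequence[Haplotype],
    params: ModelParams,
) -> BlockCall:
    """Call the joint genotype of a phased block and project per-site dosages.

    Candidate genotypes come from exhaustive enumeration when the space fits
    within ``params.genotype_limit``, otherwise from the bounded proposal
    algorithm.  Per-site GQ is the marginal posterior mass of the called
    per-site dosage vector.
    """
    if not candidate_haplotypes:
        raise ValueError("no candidate haplotypes")
    if not reads:
        raise ValueError("call_block requires at least one read")
    n = len(candidate_haplotypes)
    k = params.ploidy
    eps = params.error_rate

    mat, weights = _likelihood_matrix(reads, candidate_haplotypes, eps)

    if genotype_space_size(n, k) <= params.genotype_limit:
        candidates = enumerate_genotypes(n, k)
    else:
        from .proposal import ProposalConfig, propose_genotypes

        def scorer(g: Genotype) -> float:
            ll = float(
                _batch_genotype_ll(mat, weights, np.array([g.dosages]), g.ploidy)[0]
            )
            return ll + _log_prior(
                g, ModelParams(ploidy=g.ploidy, error_rate=eps, prior=params.prior,
                               prior_allele_freq=params.prior_allele_freq)
            )

        config = ProposalConfig(
            ploidy=k, limit=params.genotype_limit, carry=params.carry, scorer=scorer
        )
        candidates = propose_genotypes(n, config)

    dosage_matrix = np.array([g.dosages for g in candidates])
    lls = _batch_genotype_ll(mat, weights, dosage_matrix, k)
    if params.prior == "uniform":
        lps = np.zeros(len(candidates))
    else:
        lps = np.array([_log_prior(g, params) for g in candidates])
    posterior = genotype_posteriors(candidates, lls, lps)

    positions = sorted({p for h in candidate_haplotypes for p in h.positions})
    best_proj = _project_genotype(posterior.best, candidate_haplotypes, positions)

    # marginal per-site GQ: posterior mass of genotypes sharing the call's
    # per-site dosage vector
    hap_alleles = np.array(
        [[h.allele_at(p) for p in positions] for h in candidate_haplotypes]
    )  # H x S
    site_gq: dict[int, float] = {}
    for s_idx, pos in enumerate(positions):
        alleles = hap_alleles[:, s_idx]
        onehot = np.eye(int(alleles.max()) + 1)[alleles]  # H x n_alleles
        proj = dosage_matrix @ onehot  # C x n_alleles
        same = (proj == proj[posterior.best_index]).all(axis=1)
        mass = float(posterior.posteriors[same].sum())
        one_minus = max(0.0, 1.0 - mass)
        gq = GQ_CAP if one_minus <= 10 ** (-GQ_CAP / 10) else -10.0 * math.log10(one_minus)
        site_gq[pos] = min(gq, GQ_CAP)

    # phase-ordered per-copy alleles: expand dosages in canonical element order
    copies = posterior.best.expand()
    phased = {pos: tuple(candidate_haplotypes[i].allele_at(pos) for i in copies) for pos in positions}

    start = min(h.start for h in candidate_haplotypes)
    end = max(h.end for h in candidate_haplotypes)
    return BlockCall(
        haplotypes=list(candidate_haplotypes),
        posterior=posterior,
        site_dosages=best_proj,
        site_gq=site_gq,
        phased_alleles=phased,
        block_start=start,
        block_end=end,
    )


# ---------------------------------------------------------------------------
# Genotype-class labels
# ---------------------------------------------------------------------------

def genotype_class_label(dosage: int, ploidy: int) -> str:
    """Biallelic dosage class string: (K-c) x 'A' then c x 'a', e.g. 'AAaa'."""
    if not (0 <= dosage <= ploidy):
        raise ValueError(f"need 0 <= dosage <= ploidy, got {dosage}/{ploidy}")
    return "A" * (ploidy - dosage) + "a" * dosage


def parse_genotype_class_label(label: str) -> tuple[int, int]:
    """Inverse of :func:`genotype_class_label`: returns (dosage, ploidy)."""
    ploidy = len(label)
    dosage = label.count("a")
    if label != "A" * (ploidy - dosage) + "a" * dosage:
        raise ValueError(f"malformed genotype class label {label!r}")
    return dosage, ploidy
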