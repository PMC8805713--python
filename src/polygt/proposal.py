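"""Bounded iterative genotype proposal for high ploidy.

Exhaustive genotype evaluation is C(n + K - 1, K) in the number of candidate
haplotypes n and ploidy K, which is intractable for large n and K.  The
bounded proposal keeps evaluation under a user limit L by:

1. finding the largest ploidy k0 <= K whose full genotype space fits within L,
2. enumerating and scoring that space exhaustively,
3. keeping the top-scoring subset (carry size m, or a cumulative-posterior
   mass cutoff) and extending each kept genotype with every candidate
   haplotype, raising the ploidy by one,
4. re-scoring and repeating until the target ploidy is reached.

This works well when the number of distinct haplotypes actually present is
not much greater than k0, since the true genotype's lower-ploidy projections
then score near the top at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .genotype_model import Genotype, enumerate_genotypes, genotype_space_size

__all__ = [
    "ProposalConfig",
    "max_evaluable_ploidy",
    "extend_genotypes",
    "propose_genotypes",
]


@dataclass
class ProposalConfig:
    """Bounds and scorer for the iterative proposal.

    ``scorer`` maps a :class:`Genotype` (of any intermediate ploidy) to a log
    posterior score under the genuine model at that genotype's own ploidy.
    ``carry_mode`` selects between keeping the top ``carry`` genotypes and
    keeping the smallest set with cumulative posterior >= ``carry_mass``.
    """

    ploidy: int
    limit: int
    carry: int = 10
    scorer: Callable[[Genotype], float] | None = None
    carry_mode: str = "count"  # "count" | "mass"
    carry_mass: float = 0.9999

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.limit < 1 or self.carry < 1:
            raise ValueError("limit and carry must be >= 1")
        if self.carry_mode not in ("count", "mass"):
            raise ValueError(f"unknown carry mode {self.carry_mode!r}")


def max_evaluable_ploidy(n_haplotypes: int, target_ploidy: int, limit: int) -> int:
    """Largest k <= K with genotype_space_size(n, k) <= limit."""
    if n_haplotypes < 1 or target_ploidy < 1:
        raise ValueError("n_haplotypes and target ploidy must be >= 1")
    if limit < n_haplotypes:
        raise ValueError(
            f"genotype limit {limit} below haplotype count {n_haplotypes}: "
            "even the ploidy-1 space exceeds the limit"
        )
    k0 = 1
    for k in range(2, target_ploidy + 1):
        if genotype_space_size(n_haplotypes, k) > limit:
            break
        k0 = k
    return k0


def extend_genotypes(
    genotypes: Iterable[Genotype], n_haplotypes: int
) -> set[Genotype]:
    """All ploidy-(k+1) genotypes reachable by adding one haplotype copy."""
    out: set[Genotype] = set()
    ploidies = set()
    for g in genotypes:
        ploidies.add(g.ploidy)
        if len(g.dosages) != n_haplotypes:
            raise ValueError("genotype dosage length must equal n_haplotypes")
        for i in range(n_haplotypes):
            ds = list(g.dosages)
            ds[i] += 1
            out.add(Genotype(tuple(ds)))
    if len(ploidies) > 1:
        raise ValueError(f"mixed input ploidies {sorted(ploidies)}")
    return out


def _carry_subset(
    genotypes: Sequence[Genotype], scores: Sequence[float], config: ProposalConfig
) -> list[Genotype]:
    """Top-scoring subset; ties resolved by canonical genotype order."""
    order = sorted(range(len(genotypes)), key=lambda i: (-scores[i], genotypes[i].sort_key()))
    if config.carry_mode == "count":
        keep = order[: config.carry]
    else:
        arr = np.asarray(scores, dtype=float)[order]
        post = np.exp(arr - logsumexp(arr))
        total, keep = 0.0, []
        for idx, p in zip(order, post):
            keep.append(idx)
            total += float(p)
            if total >= config.carry_mass:
                break
    return [genotypes[i] for i in keep]


def propose_genotypes(n_haplotypes: int, config: ProposalConfig) -> list[Genotype]:
    """Candidate genotypes at the target ploidy, at most ~max(L, m*n) of them.

    Falls back to the exhaustive space whenever it fits within the limit.
    Returned in canonical order.
    """
    k_target = config.ploidy
    if genotype_space_size(n_haplotypes, k_target) <= config.limit:
        return enumerate_genotypes(n_haplotypes, k_target)
    if config.scorer is None:
        raise ValueError("bounded proposal requires a scorer")

    k0 = max_evaluable_ploidy(n_haplotypes, k_target, config.limit)
    current: list[Genotype] = enumerate_genotypes(n_haplotypes, k0)
    for _ in range(k0, k_target):
        scores = [config.scorer(g) for g in current]
        kept = _carry_subset(current, scores, config)
        current = sorted(extend_genotypes(kept, n_haplotypes), key=Genotype.sort_key)
    return current
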