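"""Shared fixtures: small simulated cohorts and the linked-SNV block."""

import pytest

import polygt as pg


@pytest.fixture(scope="session")
def tetraploid_truth():
    """Two merged diploids on a 100 kb reference (ploidy 4)."""
    seeds = pg.stage_seeds(11, ["ref", "s0", "s1"])
    ref = pg.simulate_reference(100_000, seeds["ref"])
    truths = [
        pg.simulate_diploid_truth(ref, seed=seeds[f"s{i}"], sample=f"S{i + 1}")
        for i in range(2)
    ]
    return ref, truths, pg.merge_polyploid_truth(truths)


@pytest.fixture()
def linked_block():
    """The three linked SNVs with alt counts 19/50, 30/50, 16/50.

    Haplotype A carries (ref, alt, ref), haplotype B (alt, ref, alt); the
    true haplotype dosage is (A, B) = (3, 1), i.e. per-site alt dosages
    (1, 3, 1), while site-wise maximum likelihood gives (2, 2, 1).
    """
    hap_a = pg.Haplotype("blk", 0, 3, ((0, 0), (1, 1), (2, 0)))
    hap_b = pg.Haplotype("blk", 0, 3, ((0, 1), (1, 0), (2, 1)))
    reads = []
    for pos, (alt, depth) in enumerate([(19, 50), (30, 50), (16, 50)]):
        reads.append(pg.ReadObservation((pos,), (1,), weight=alt))
        reads.append(pg.ReadObservation((pos,), (0,), weight=depth - alt))
    return [hap_a, hap_b], reads
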