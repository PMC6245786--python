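"""Shared fixtures: small simulated studies and record builders."""

from __future__ import annotations

import pytest

from homozymap.cross import GenomeSpec, PoolSpec
from homozymap.bundle import simulate_study
from homozymap.variants import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    MUTANT,
    SIBLING,
    GenotypeCall,
    VariantRecord,
)


def make_call(gt: str, gq: int = 50, depth: int = 10) -> GenotypeCall:
    if gt == MISSING:
        return GenotypeCall(gt=MISSING, gq=0, depth=0, allele_counts=(0, 0))
    alt_n = {HOM_REF: 0, HET: depth // 2, HOM_ALT: depth}[gt]
    return GenotypeCall(gt=gt, gq=gq, depth=depth,
                        allele_counts=(depth - alt_n, alt_n))


def make_record(
    chrom: str = "chr1",
    pos: int = 100,
    ref: str = "A",
    alts: tuple[str, ...] = ("T",),
    mut: str = HET,
    sib: str = HET,
    mut_gq: int = 50,
    sib_gq: int = 50,
    filter: str = "PASS",
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=alts,
        calls={MUTANT: make_call(mut, mut_gq), SIBLING: make_call(sib, sib_gq)},
        filter=filter,
    )


def small_genome(seed: int = 0, causal: bool = True) -> GenomeSpec:
    """3 chromosomes x 10 Mb; causal site mid-chr2."""
    return GenomeSpec(
        chromosomes=(("chr1", 10_000_000), ("chr2", 10_000_000),
                     ("chr3", 10_000_000)),
        marker_density=2.0,
        causal_site=("chr2", 5_000_000, "A", "T") if causal else None,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study reused across read-only tests."""
    return simulate_study(
        genome=small_genome(seed=42),
        pools=PoolSpec(n_mutants=20, n_siblings=20),
    )


@pytest.fixture(scope="session")
def default_study():
    """One default-scale simulated study (25 x 50 Mb), read-only."""
    return simulate_study(seed=1)
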