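"""Simulation of an F2 incross of heterozygous carriers with pooled genotyping.

The model emulates a classic mapping-by-sequencing study design for a fully
penetrant recessive allele: two F1 parents heterozygous at every marker
(mutagenized-strain haplotype carrying the causal allele, mapping-strain
haplotype carrying the reference allele), F2 offspring produced by two
independent meioses under the Haldane map function (no interference),
phenotype-based sorting of offspring into a homozygous-mutant pool and a
phenotypically wild-type sibling pool, and shallow pooled short-read
genotyping.  Each pool is genotyped as one pseudo-diploid sample: read
depths are Poisson, per-read alt probability is the pool alt-allele
frequency perturbed by a base-call error rate, and a single diploid
genotype with a phred-scaled quality is called per pool per marker from a
binomial read model.

Mendelian expectations: an incross of two carriers segregates 1:2:1, so 25%
of offspring are homozygous mutant -- the fraction the phenotype sort
selects on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .variants import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    MUTANT,
    ROLES,
    SIBLING,
    GenotypeCall,
    VariantRecord,
)

GT_STRINGS = (HOM_REF, HET, HOM_ALT)


# ---------------------------------------------------------------------------
# Mendelian arithmetic
# ---------------------------------------------------------------------------

_ALLELE_PROBS = {HOM_REF: (1.0, 0.0), HET: (0.5, 0.5), HOM_ALT: (0.0, 1.0)}


def expected_offspring_fractions(
    parent1: str = HET, parent2: str = HET
) -> tuple[float, float, float]:
    """Expected (hom_ref, het, hom_alt) offspring fractions at one locus.

    For the default het x het incross this is the 1:2:1 ratio, i.e. an
    expected 25% of offspring homozygous for the recessive allele -- the
    phenotypically mutant fraction under full penetrance.
    """
    p1 = _ALLELE_PROBS[parent1]
    p2 = _ALLELE_PROBS[parent2]
    hom_ref = p1[0] * p2[0]
    hom_alt = p1[1] * p2[1]
    het = p1[0] * p2[1] + p1[1] * p2[0]
    return (hom_ref, het, hom_alt)


def haldane_r(d: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for map distance ``d`` (Morgans), Haldane.

    r = (1 - exp(-2d)) / 2; no crossover interference.  0 <= r <= 0.5.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticMap:
    """Map distances (Morgans) between adjacent markers of one chromosome."""

    distances: tuple[float, ...]  # len = n_markers - 1

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.distances):
            raise ValueError("map distances must be >= 0")

    @property
    def rec_fractions(self) -> np.ndarray:
        return haldane_r(np.asarray(self.distances, dtype=float))

    @classmethod
    def from_positions(cls, positions: Sequence[int], cm_per_mb: float = 2.0) -> "GeneticMap":
        """Uniform-rate map: ``cm_per_mb`` centimorgans per megabase."""
        pos = np.asarray(positions, dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing")
        d = np.diff(pos) * cm_per_mb / 100.0 / 1e6
        return cls(distances=tuple(d.tolist()))


@dataclass(frozen=True)
class GenomeSpec:
    """Study-design genome: chromosomes, marker density and the causal site.

    ``causal_site`` is (chrom, pos, ref, alt); ``None`` simulates a neutral
    cross with no phenotype to select on (used to exercise the
    no-linkage-detected path downstream).
    """

    chromosomes: tuple[tuple[str, int], ...]
    marker_density: float = 2.0  # markers per Mb
    causal_site: tuple[str, int, str, str] | None = ("chr13", 29_288_858, "A", "T")
    seed: int = 0
    cm_per_mb: float = 2.0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("chromosome lengths must be > 0")
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be > 0")
        if self.causal_site is not None:
            chrom, pos, ref, alt = self.causal_site
            if chrom not in lengths:
                raise ValueError(f"causal chromosome {chrom} not in genome")
            if not (1 <= pos <= lengths[chrom]):
                raise ValueError("causal position outside its chromosome")
            if ref == alt or len(ref) != 1 or len(alt) != 1:
                raise ValueError("causal ref/alt must be distinct single bases")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


def default_genome(seed: int = 0) -> GenomeSpec:
    """25 chromosomes of 50 Mb at 2 markers/Mb; causal A>T on chr13:29,288,858."""
    return GenomeSpec(
        chromosomes=tuple((f"chr{i}", 50_000_000) for i in range(1, 26)),
        marker_density=2.0,
        causal_site=("chr13", 29_288_858, "A", "T"),
        seed=seed,
    )


@dataclass(frozen=True)
class PoolSpec:
    """Pooled-sequencing design: embryos per pool, coverage and error rate.

    Mean depths default to 9x for the mutant pool and 8x for the sibling
    pool, matching shallow whole-genome pool sequencing; ``base_error`` is
    the per-read allele miscall probability.
    """

    n_mutants: int = 40
    n_siblings: int = 40
    mean_depth_mutant: float = 9.0
    mean_depth_sibling: float = 8.0
    base_error: float = 0.01

    def __post_init__(self) -> None:
        if self.n_mutants < 1 or self.n_siblings < 1:
            raise ValueError("pool sizes must be >= 1")
        if not (0 <= self.base_error < 0.5):
            raise ValueError("base_error must be in [0, 0.5)")
        if self.mean_depth_mutant <= 0 or self.mean_depth_sibling <= 0:
            raise ValueError("mean depths must be > 0")


@dataclass
class TruthRecord:
    """Ground truth of one simulated cross, for parameter-recovery checks.

    Genotypes (0/1/2 alt-allele dosage) of every pooled individual at every
    marker, keyed by chromosome; mutant-pool rows first, then siblings.
    """

    causal_chrom: str | None
    causal_pos: int | None
    marker_positions: dict[str, np.ndarray]
    mutant_genotypes: dict[str, np.ndarray]  # (n_mutants, n_markers)
    sibling_genotypes: dict[str, np.ndarray]

    def pool_alt_freq(self, chrom: str, pool: str = MUTANT) -> np.ndarray:
        g = self.mutant_genotypes[chrom] if pool == MUTANT else self.sibling_genotypes[chrom]
        return g.sum(axis=0) / (2.0 * g.shape[0])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tpool\tindividual\tgt\n")
            for chrom, positions in self.marker_positions.items():
                for pool, mat in ((MUTANT, self.mutant_genotypes[chrom]),
                                  (SIBLING, self.sibling_genotypes[chrom])):
                    for ind in range(mat.shape[0]):
                        row = mat[ind]
                        for j, pos in enumerate(positions):
                            fh.write(f"{chrom}\t{pos}\t{pool}\t{ind}\t{row[j]}\n")


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def simulate_meiosis(
    parent: tuple[np.ndarray, np.ndarray],
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a parent's two marker haplotypes.

    Phase switches between adjacent markers occur independently with the
    interval's recombination fraction; the starting haplotype is chosen
    uniformly, so each parental allele is marginally transmitted with
    probability 1/2.
    """
    hap1, hap2 = (np.asarray(h) for h in parent)
    if hap1.shape != hap2.shape:
        raise ValueError("parental haplotypes differ in length")
    m = hap1.shape[0]
    if len(gmap.distances) != m - 1:
        raise ValueError(
            f"map has {len(gmap.distances)} intervals for {m} markers (need {m - 1})"
        )
    which = _phase_indicator(1, m, gmap.rec_fractions, rng)[0]
    return np.where(which == 0, hap1, hap2)


def _phase_indicator(
    n: int, m: int, rec: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(n, m) matrix of which parental haplotype each gamete carries per marker."""
    start = rng.integers(0, 2, size=(n, 1))
    if m == 1:
        return start
    switches = rng.random(size=(n, m - 1)) < rec[None, :]
    crossings = np.concatenate(
        [np.zeros((n, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
    )
    return (start + crossings) % 2


def _f2_genotypes(
    n: int, m: int, rec: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Alt-allele dosage (0/1/2) for n F2 individuals at m linked markers.

    Both F1 parents carry one all-alt and one all-ref haplotype, so a
    gamete's allele equals the indicator of carrying haplotype 0.
    """
    g1 = 1 - _phase_indicator(n, m, rec, rng)
    g2 = 1 - _phase_indicator(n, m, rec, rng)
    return (g1 + g2).astype(np.int8)


# ---------------------------------------------------------------------------
# pseudo-diploid genotype calling
# ---------------------------------------------------------------------------


def simulate_f2_cohort(
    n: int, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Alt-allele dosages (0/1/2) of ``n`` F2 offspring of carrier F1 parents.

    Shape (n, n_markers); markers are linked per ``gmap``.  The marginal
    genotype distribution at every marker is the Mendelian 1:2:1.
    """
    return _f2_genotypes(n, len(gmap.distances) + 1, gmap.rec_fractions, rng)


def call_genotype(allele_counts: tuple[int, int], base_error: float) -> GenotypeCall:
    """Call one diploid genotype from (ref, alt) read counts.

    Binomial read model with per-read alt probabilities ``base_error``,
    0.5 and ``1 - base_error`` for 0/0, 0/1 and 1/1; the call is the
    maximum-likelihood genotype and GQ the phred-scaled likelihood ratio of
    the best to the second-best genotype, capped at 99.  Zero depth yields
    a missing call with GQ 0.
    """
    ref_n, alt_n = allele_counts
    if ref_n < 0 or alt_n < 0:
        raise ValueError("read counts must be >= 0")
    depth = ref_n + alt_n
    if depth == 0:
        return GenotypeCall(gt=MISSING, gq=0, depth=0, allele_counts=(0, 0))
    gts, gqs = _call_genotypes_vec(
        np.array([ref_n]), np.array([alt_n]), base_error
    )
    return GenotypeCall(
        gt=GT_STRINGS[gts[0]], gq=int(gqs[0]), depth=depth, allele_counts=(ref_n, alt_n)
    )


def _call_genotypes_vec(
    ref_n: np.ndarray, alt_n: np.ndarray, base_error: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized genotype calls; returns (gt codes 0/1/2, gq ints)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.array([base_error, 0.5, 1.0 - base_error])
        # log10 likelihoods, binomial coefficient omitted (common factor)
        ll = alt_n[:, None] * np.log10(p)[None, :] + ref_n[:, None] * np.log10(1 - p)[None, :]
    ll = np.where(np.isnan(ll), -np.inf, ll)
    order = np.argsort(ll, axis=1)
    best = order[:, -1]
    second = order[:, -2]
    rows = np.arange(ll.shape[0])
    diff = 10.0 * (ll[rows, best] - ll[rows, second])
    gq = np.minimum(99, np.round(np.where(np.isfinite(diff), diff, 99.0))).astype(int)
    return best.astype(int), np.maximum(gq, 0)


# ---------------------------------------------------------------------------
# full cross simulation
# ---------------------------------------------------------------------------


def draw_marker_positions(
    genome: GenomeSpec,
    rng: np.random.Generator,
    exclude: dict[str, list[tuple[int, int]]] | None = None,
) -> dict[str, np.ndarray]:
    """Uniform random marker positions per chromosome at the spec's density.

    The causal site is always included as a marker.  ``exclude`` maps a
    chromosome to closed intervals no other marker may fall into (used to
    keep designed gene bodies free of stray markers).
    """
    exclude = exclude or {}
    markers: dict[str, np.ndarray] = {}
    for name, length in genome.chromosomes:
        n = max(1, int(round(genome.marker_density * length / 1e6)))
        zones = list(exclude.get(name, []))
        if genome.causal_site is not None and genome.causal_site[0] == name:
            zones.append((genome.causal_site[1], genome.causal_site[1]))
        pos: set[int] = set()
        while len(pos) < n:
            cand = rng.integers(1, length + 1, size=n - len(pos))
            for p in cand.tolist():
                if any(lo <= p <= hi for lo, hi in zones):
                    continue
                pos.add(p)
        arr = np.array(sorted(pos), dtype=np.int64)
        if genome.causal_site is not None and genome.causal_site[0] == name:
            arr = np.unique(np.append(arr, genome.causal_site[1]))
        markers[name] = arr
    return markers


def _pool_calls(
    geno: np.ndarray,
    mean_depth: float,
    base_error: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pseudo-diploid calls for one pool on one chromosome.

    Returns (gt codes with -1 = missing, gq, ref reads, alt reads).
    """
    n_ind, m = geno.shape
    freq = geno.sum(axis=0) / (2.0 * n_ind)
    depth = rng.poisson(mean_depth, size=m)
    p_alt = base_error + freq * (1.0 - 2.0 * base_error)
    alt_n = rng.binomial(depth, p_alt)
    ref_n = depth - alt_n
    gts, gqs = _call_genotypes_vec(ref_n, alt_n, base_error)
    gts = np.where(depth == 0, -1, gts)
    gqs = np.where(depth == 0, 0, gqs)
    return gts, gqs, ref_n, alt_n


class PoolFillError(RuntimeError):
    """Raised when the requested pool sizes cannot be reached."""


def simulate_f2_pools(
    genome: GenomeSpec,
    pools: PoolSpec,
    markers: dict[str, np.ndarray] | None = None,
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    max_batches: int = 40,
) -> tuple[list[VariantRecord], TruthRecord]:
    """Simulate the full pooled mapping cross.

    F2 individuals are drawn by two meioses from F1 carrier parents;
    individuals homozygous alt at the causal marker fill the mutant pool,
    any others fill the sibling pool, until the requested pool sizes are
    reached (``PoolFillError`` after ``max_batches`` cohorts).  Per marker,
    one pseudo-diploid genotype per pool is called from simulated pooled
    reads.

    ``alleles`` optionally fixes (ref bases, alt bases) per chromosome;
    otherwise distinct random bases are drawn.  Returns the two-sample
    variant table (sorted by chromosome then position) and the truth record.
    """
    rng = np.random.default_rng(genome.seed)
    if markers is None:
        markers = draw_marker_positions(genome, rng)
    lengths = genome.lengths
    chroms = [name for name, _ in genome.chromosomes]
    recs = {c: GeneticMap.from_positions(markers[c], genome.cm_per_mb).rec_fractions
            if len(markers[c]) > 1 else np.empty(0)
            for c in chroms}

    causal = genome.causal_site
    if causal is not None:
        c_chrom, c_pos = causal[0], causal[1]
        c_idx = int(np.searchsorted(markers[c_chrom], c_pos))
        if c_idx >= len(markers[c_chrom]) or markers[c_chrom][c_idx] != c_pos:
            raise ValueError("causal site must be one of the markers")
    else:
        c_chrom, c_pos, c_idx = None, None, None

    n_mut, n_sib = pools.n_mutants, pools.n_siblings
    batch = 4 * (n_mut + n_sib)
    mut_rows: list[np.ndarray] = []
    sib_rows: list[np.ndarray] = []
    # draw the causal chromosome (or chroms[0] for a neutral cross) first;
    # pool membership is decided there, remaining chromosomes are simulated
    # afterwards for the selected individuals only (chromosomes assort
    # independently, so this is distributionally exact).
    first_chrom = c_chrom if c_chrom is not None else chroms[0]
    for _ in range(max_batches):
        g = _f2_genotypes(batch, len(markers[first_chrom]), recs[first_chrom], rng)
        if causal is not None:
            is_mut = g[:, c_idx] == 2
        else:
            is_mut = np.zeros(batch, dtype=bool)
            is_mut[:n_mut] = True
        mut_rows.append(g[is_mut])
        sib_rows.append(g[~is_mut])
        if (sum(x.shape[0] for x in mut_rows) >= n_mut
                and sum(x.shape[0] for x in sib_rows) >= n_sib):
            break
    else:
        raise PoolFillError(
            f"could not fill pools ({n_mut} mutants, {n_sib} siblings) "
            f"within {max_batches} cohorts of {batch}"
        )

    G_first_mut = np.concatenate(mut_rows)[:n_mut]
    G_first_sib = np.concatenate(sib_rows)[:n_sib]

    mut_geno: dict[str, np.ndarray] = {first_chrom: G_first_mut}
    sib_geno: dict[str, np.ndarray] = {first_chrom: G_first_sib}
    for chrom in chroms:
        if chrom == first_chrom:
            continue
        m = len(markers[chrom])
        mut_geno[chrom] = _f2_genotypes(n_mut, m, recs[chrom], rng)
        sib_geno[chrom] = _f2_genotypes(n_sib, m, recs[chrom], rng)

    bases = np.array(list("ACGT"))
    records: list[VariantRecord] = []
    for chrom in chroms:
        pos = markers[chrom]
        m = len(pos)
        if alleles is not None and chrom in alleles:
            ref_b, alt_b = alleles[chrom]
            ref_b, alt_b = np.asarray(ref_b), np.asarray(alt_b)
        else:
            ref_i = rng.integers(0, 4, size=m)
            alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
            ref_b, alt_b = bases[ref_i], bases[alt_i]
        if causal is not None and chrom == c_chrom:
            ref_b = ref_b.copy()
            alt_b = alt_b.copy()
            ref_b[c_idx] = causal[2]
            alt_b[c_idx] = causal[3]
        mg, mq, mr, ma = _pool_calls(mut_geno[chrom], pools.mean_depth_mutant,
                                     pools.base_error, rng)
        sg, sq, sr, sa = _pool_calls(sib_geno[chrom], pools.mean_depth_sibling,
                                     pools.base_error, rng)
        for j in range(m):
            calls = {
                MUTANT: _mk_call(mg[j], mq[j], mr[j], ma[j]),
                SIBLING: _mk_call(sg[j], sq[j], sr[j], sa[j]),
            }
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(pos[j]),
                    ref=str(ref_b[j]),
                    alts=(str(alt_b[j]),),
                    calls=calls,
                )
            )

    truth = TruthRecord(
        causal_chrom=c_chrom,
        causal_pos=c_pos,
        marker_positions=markers,
        mutant_genotypes=mut_geno,
        sibling_genotypes=sib_geno,
    )
    return records, truth


def _mk_call(gt_code: int, gq: int, ref_n: int, alt_n: int) -> GenotypeCall:
    if gt_code < 0:
        return GenotypeCall(gt=MISSING, gq=0, depth=0, allele_counts=(0, 0))
    return GenotypeCall(
        gt=GT_STRINGS[gt_code],
        gq=int(gq),
        depth=int(ref_n + alt_n),
        allele_counts=(int(ref_n), int(alt_n)),
    )
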