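"""Self-contained simulated mapping study: cross, genome, genes, known sites.

Everything a full pipeline run needs is generated from one seed: the
pooled F2 variant tables (:mod:`homozymap.cross`), a random reference
sequence for the causal chromosome, toy transcript models placed on it,
and a catalogue of "known" (previously catalogued) marker sites.

The causal gene (*motA*, synthetic) is a three-exon minus-strand model
whose codon 102 is the serine codon AGT with its third base at the causal
genomic position, so the injected forward-strand A>T allele reads T>A on
the transcript and annotates as the missense change S102R.  A second
isoform lacking the in-frame middle exon is included, so the gene-level
consequence aggregates over multiple transcripts.  A synonymous decoy
gene (*nulB*, synthetic) is placed over a nearby non-causal marker: its
marker codon is CTN (leucine for every third base), so any alternate
allele there is synonymous and must be removed by the impact filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import TranscriptModel, revcomp
from .candidates import KnownSites
from .cross import (
    GenomeSpec,
    PoolSpec,
    TruthRecord,
    default_genome,
    draw_marker_positions,
    simulate_f2_pools,
)
from .variants import VariantRecord, write_vcf

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOPS
)

CAUSAL_GENE = "motA"
DECOY_GENE = "nulB"

# transcript-order CDS lengths of the three coding exons (sum = 309 = 103
# codons: start + 100 internal + Ser102 + stop); middle exon in frame so the
# exon-skipped isoform stays translatable
_EXON_CDS_LENS = (105, 120, 84)
_CAUSAL_CDS_POS = 306  # third base of codon 102
_UTR_LEN = 20
_INTRON_LEN = 500


@dataclass
class GeneDesign:
    """A designed toy gene: transcript models plus the CDS it encodes."""

    gene: str
    transcripts: list[TranscriptModel]
    cds_seq: str  # transcript-strand CDS of the full-length isoform
    # genomic (start, end, transcript-strand piece) for sequence imprinting
    imprint: list[tuple[int, int, str]]

    @property
    def span(self) -> tuple[int, int]:
        return self.transcripts[0].span


def _random_cds(rng: np.random.Generator, n_internal: int) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_internal)
    return [_SENSE_CODONS[i] for i in idx]


def design_causal_gene(causal_pos: int, chrom: str, rng: np.random.Generator) -> GeneDesign:
    """Minus-strand three-exon gene with AGT (Ser) codon 102 at the causal site."""
    la, lb, lc = _EXON_CDS_LENS
    codons = ["ATG"] + _random_cds(rng, 100) + ["AGT", "TAA"]
    cds = "".join(codons)
    assert len(cds) == la + lb + lc
    assert cds[_CAUSAL_CDS_POS - 1] == "T"

    # genomic layout, ascending: exon C (3'), exon B, exon A (5');
    # minus strand: cds position (la+lb+1) sits at genomic c_end, so the
    # causal cds position maps to c_end - (_CAUSAL_CDS_POS - (la+lb) - 1)
    c_end = causal_pos + (_CAUSAL_CDS_POS - (la + lb) - 1)  # = causal_pos + 80
    c_start = c_end - lc + 1
    b_start = c_end + _INTRON_LEN + 1
    b_end = b_start + lb - 1
    a_start = b_end + _INTRON_LEN + 1
    a_end = a_start + la - 1

    exons_full = (
        (c_start - _UTR_LEN, c_end),
        (b_start, b_end),
        (a_start, a_end + _UTR_LEN),
    )
    tx1 = TranscriptModel(
        transcript_id=f"{CAUSAL_GENE}.1", gene=CAUSAL_GENE, chrom=chrom,
        strand="-", exons=exons_full, cds_start=c_start, cds_end=a_end,
    )
    # exon-skipped isoform: drops the in-frame middle exon
    tx2 = TranscriptModel(
        transcript_id=f"{CAUSAL_GENE}.2", gene=CAUSAL_GENE, chrom=chrom,
        strand="-", exons=(exons_full[0], exons_full[2]),
        cds_start=c_start, cds_end=a_end,
    )
    # transcript-order pieces: exon A = cds[0:la], B = cds[la:la+lb], C = rest
    imprint = [
        (a_start, a_end, cds[:la]),
        (b_start, b_end, cds[la : la + lb]),
        (c_start, c_end, cds[la + lb :]),
    ]
    return GeneDesign(gene=CAUSAL_GENE, transcripts=[tx1, tx2], cds_seq=cds,
                      imprint=imprint)


def design_decoy_gene(marker_pos: int, chrom: str, rng: np.random.Generator) -> GeneDesign:
    """Plus-strand single-exon gene whose marker codon is CTN (always leucine)."""
    third = "ACGT"[rng.integers(0, 4)]
    codons = ["ATG"] + _random_cds(rng, 4) + ["CT" + third] + _random_cds(rng, 5) + ["TAA"]
    cds = "".join(codons)
    start = marker_pos - 17  # marker at CDS position 18 (codon 6, base 3)
    end = start + len(cds) - 1
    tx = TranscriptModel(
        transcript_id=f"{DECOY_GENE}.1", gene=DECOY_GENE, chrom=chrom,
        strand="+", exons=((start, end),), cds_start=start, cds_end=end,
    )
    return GeneDesign(gene=DECOY_GENE, transcripts=[tx], cds_seq=cds,
                      imprint=[(start, end, cds)])


def _build_sequence(length: int, designs: Sequence[GeneDesign],
                    rng: np.random.Generator) -> np.ndarray:
    seq = _BASES[rng.integers(0, 4, size=length)].copy()
    for d in designs:
        for s, e, piece in d.imprint:
            forward = piece if d.transcripts[0].strand == "+" else revcomp(piece)
            seq[s - 1 : e] = np.frombuffer(forward.encode(), dtype="S1")
    return seq


@dataclass
class StudyBundle:
    """All inputs and ground truth of one simulated mapping study."""

    genome: GenomeSpec
    pools: PoolSpec
    records: list[VariantRecord]
    truth: TruthRecord
    transcripts: list[TranscriptModel]
    sequences: dict[str, str]  # chromosomes carrying transcript models
    known: KnownSites
    designs: list[GeneDesign]

    @property
    def causal_key(self) -> tuple[str, int, str]:
        chrom, pos, _, alt = self.genome.causal_site
        return (chrom, pos, alt)


def simulate_study(
    genome: GenomeSpec | None = None,
    pools: PoolSpec | None = None,
    seed: int | None = None,
    known_fraction: float = 0.25,
) -> StudyBundle:
    """Simulate the complete study for one seed.

    ``seed`` overrides ``genome.seed`` when given.  ``known_fraction`` of
    the non-causal markers are declared previously-known sites.
    """
    genome = genome or default_genome(seed if seed is not None else 0)
    if seed is not None and genome.seed != seed:
        genome = GenomeSpec(
            chromosomes=genome.chromosomes,
            marker_density=genome.marker_density,
            causal_site=genome.causal_site,
            seed=seed,
            cm_per_mb=genome.cm_per_mb,
        )
    pools = pools or PoolSpec()
    if genome.causal_site is None:
        # neutral cross: no genes to design, no sequence needed
        records, truth = simulate_f2_pools(genome, pools)
        return StudyBundle(
            genome=genome, pools=pools, records=records, truth=truth,
            transcripts=[], sequences={}, known=KnownSites.empty(), designs=[],
        )

    c_chrom, c_pos, _, _ = genome.causal_site
    rng = np.random.default_rng([genome.seed, 1])

    causal_design = design_causal_gene(c_pos, c_chrom, rng)
    lo, hi = causal_design.span
    markers = draw_marker_positions(
        genome, rng, exclude={c_chrom: [(lo - 50, hi + 50)]}
    )

    # decoy marker: the nearest non-causal marker more than 2 kb from the
    # causal site (so it lies inside the linked region) with no neighbour
    # within the decoy gene body
    mpos = markers[c_chrom]
    decoy_pos = None
    for p in sorted(mpos, key=lambda p: abs(int(p) - c_pos)):
        p = int(p)
        if p == c_pos or abs(p - c_pos) < 2000:
            continue
        if np.sum(np.abs(mpos - p) < 60) == 1 and p > 60:
            decoy_pos = p
            break
    designs = [causal_design]
    if decoy_pos is not None:
        designs.append(design_decoy_gene(decoy_pos, c_chrom, rng))

    length = genome.lengths[c_chrom]
    seq = _build_sequence(length, designs, rng)

    ref_b = seq[mpos - 1].astype("U1")
    shift = rng.integers(1, 4, size=len(mpos))
    base_idx = np.searchsorted(_BASES, ref_b.astype("S1"))
    alt_b = _BASES[(base_idx + shift) % 4].astype("U1")
    alleles = {c_chrom: (ref_b, alt_b)}

    records, truth = simulate_f2_pools(genome, pools, markers=markers, alleles=alleles)

    non_causal = [r for r in records if not (r.chrom == c_chrom and r.pos == c_pos)]
    n_known = int(round(known_fraction * len(non_causal)))
    known_idx = rng.choice(len(non_causal), size=n_known, replace=False)
    known = KnownSites(
        keys=frozenset(
            (non_causal[i].chrom, non_causal[i].pos, non_causal[i].alt)
            for i in known_idx
        )
    )

    transcripts = [t for d in designs for t in d.transcripts]
    return StudyBundle(
        genome=genome, pools=pools, records=records, truth=truth,
        transcripts=transcripts, sequences={c_chrom: seq.tobytes().decode()},
        known=known, designs=designs,
    )


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_gff3(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Minimal GFF3 with gene/mRNA/exon/CDS features."""
    lines = ["##gff-version 3"]
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene, []).append(t)
    for gene, txs in by_gene.items():
        g_start = min(t.span[0] for t in txs)
        g_end = max(t.span[1] for t in txs)
        chrom, strand = txs[0].chrom, txs[0].strand
        lines.append(
            f"{chrom}\tsim\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\t"
            f"ID=gene:{gene};Name={gene}"
        )
        for t in txs:
            s, e = t.span
            lines.append(
                f"{chrom}\tsim\tmRNA\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={t.transcript_id};Parent=gene:{gene}"
            )
            for es, ee in t.exons:
                lines.append(
                    f"{chrom}\tsim\texon\t{es}\t{ee}\t.\t{strand}\t.\t"
                    f"Parent={t.transcript_id}"
                )
            ivs = t.cds_intervals if strand == "+" else tuple(reversed(t.cds_intervals))
            done = 0
            phased = []
            for cs, ce in ivs:
                phase = (3 - done % 3) % 3
                phased.append((cs, ce, phase))
                done += ce - cs + 1
            for cs, ce, phase in sorted(phased):
                lines.append(
                    f"{chrom}\tsim\tCDS\t{cs}\t{ce}\t.\t{strand}\t{phase}\t"
                    f"Parent={t.transcript_id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_known_sites(known: KnownSites, path: str | Path) -> None:
    lines = ["chrom\tpos\tref\talt"]
    for chrom, pos, alt in sorted(known.keys):
        lines.append(f"{chrom}\t{pos}\t.\t{alt}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bundle(bundle: StudyBundle, outdir: str | Path,
                 split_pools: bool = False) -> dict[str, Path]:
    """Write every bundle artifact; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    contigs = list(bundle.genome.chromosomes)
    if split_pools:
        from .variants import MUTANT, SIBLING

        for role in (MUTANT, SIBLING):
            p = outdir / f"pool_{role}.vcf"
            write_vcf(bundle.records, p, contigs=contigs, roles=[role])
            paths[f"vcf_{role}"] = p
    else:
        p = outdir / "pools.vcf"
        write_vcf(bundle.records, p, contigs=contigs)
        paths["vcf"] = p
    paths["truth"] = outdir / "truth.tsv"
    bundle.truth.write_tsv(paths["truth"])
    if bundle.sequences:
        paths["fasta"] = outdir / "genome.fa"
        write_fasta(bundle.sequences, paths["fasta"])
    if bundle.transcripts:
        paths["gff3"] = outdir / "genes.gff3"
        write_gff3(bundle.transcripts, paths["gff3"])
    paths["known"] = outdir / "known_sites.tsv"
    write_known_sites(bundle.known, paths["known"])
    return paths
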