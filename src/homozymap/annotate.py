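"""Variant consequence annotation against transcript models.

A genomic SNV is mapped into a transcript's spliced CDS (with full strand
handling: on minus-strand transcripts CDS position 1 is the 3'-most
genomic CDS base and alleles are complemented), the affected codon is
rebuilt with the alternate base and translated with the standard genetic
code, and the consequence type is rated on the four-level impact scheme
used by variant effect predictors: stop_gained / stop_lost / splice_site
are HIGH, missense MODERATE, synonymous LOW, and intron / UTR / intergenic
MODIFIER.  Positions within 2 bp of an exon/intron boundary on the intron
side (the canonical donor/acceptor dinucleotides) are splice_site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
from Bio import AlignIO
from Bio.Seq import Seq

from .variants import VariantRecord

log = logging.getLogger(__name__)

SPLICE_WINDOW = 2  # bp into the intron

IMPACT_OF_TYPE = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "splice_site": "HIGH",
    "missense": "MODERATE",
    "synonymous": "LOW",
    "intron": "MODIFIER",
    "UTR": "MODIFIER",
    "intergenic": "MODIFIER",
}

IMPACT_SEVERITY = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def impact_of(ctype: str) -> str:
    """Impact rating for a consequence type (fixed VEP-style table)."""
    try:
        return IMPACT_OF_TYPE[ctype]
    except KeyError:
        raise ValueError(f"unknown consequence type {ctype!r}") from None


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one mRNA.

    Exons are 1-based inclusive genomic intervals, non-overlapping and
    sorted by genomic position; ``cds_start``/``cds_end`` bound the coding
    region in genomic coordinates.  A CDS whose spliced length is not a
    multiple of 3 is flagged incomplete and annotated with a warning.
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            if e < s:
                raise ValueError("exon end before start")
            prev_end = e
        if not self.cds_intervals:
            raise ValueError("CDS does not overlap any exon")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exon pieces inside [cds_start, cds_end], genomic order."""
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                out.append((s2, e2))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def is_incomplete(self) -> bool:
        return self.cds_length % 3 != 0


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Genome slice, 1-based inclusive; accepts pyfaidx.Fasta or a dict."""
    if isinstance(genome, Mapping):
        return genome[chrom][start - 1 : end]
    return str(genome[chrom][start - 1 : end]).upper()


def cds_sequence(t: TranscriptModel, genome) -> str:
    """Transcript-strand CDS sequence (minus strand reverse-complemented)."""
    seq = "".join(_fetch(genome, t.chrom, s, e) for s, e in t.cds_intervals)
    return revcomp(seq) if t.strand == "-" else seq


def genomic_to_cds(t: TranscriptModel, gpos: int) -> int | str:
    """CDS position (1-based) of a genomic position, or a region label.

    Returns ``"intergenic"`` outside the transcript span, ``"intron"``
    between exons, ``"UTR"`` in an exon outside the coding region.  On the
    minus strand CDS position 1 is the 3'-most genomic CDS base.
    """
    if gpos < 1:
        raise ValueError("gpos must be >= 1")
    lo, hi = t.span
    if gpos < lo or gpos > hi:
        return "intergenic"
    in_exon = any(s <= gpos <= e for s, e in t.exons)
    if not in_exon:
        return "intron"
    ivs = t.cds_intervals
    if not any(s <= gpos <= e for s, e in ivs):
        return "UTR"
    if t.strand == "+":
        off = 0
        for s, e in ivs:
            if gpos > e:
                off += e - s + 1
            else:
                return off + (gpos - s) + 1
    else:
        off = 0
        for s, e in reversed(ivs):
            if gpos < s:
                off += e - s + 1
            else:
                return off + (e - gpos) + 1
    raise AssertionError("unreachable")


def cds_to_genomic(t: TranscriptModel, cpos: int) -> int:
    """Inverse of :func:`genomic_to_cds` on coding positions."""
    if not (1 <= cpos <= t.cds_length):
        raise ValueError(f"cds position {cpos} outside CDS of length {t.cds_length}")
    ivs = t.cds_intervals if t.strand == "+" else tuple(reversed(t.cds_intervals))
    rem = cpos - 1
    for s, e in ivs:
        n = e - s + 1
        if rem < n:
            return s + rem if t.strand == "+" else e - rem
        rem -= n
    raise AssertionError("unreachable")


def _is_splice_site(t: TranscriptModel, gpos: int) -> bool:
    """Within SPLICE_WINDOW bp into an intron of an internal exon boundary."""
    for i, (s, e) in enumerate(t.exons):
        if i > 0 and s - SPLICE_WINDOW <= gpos <= s - 1:
            return True
        if i < len(t.exons) - 1 and e + 1 <= gpos <= e + SPLICE_WINDOW:
            return True
    return False


@dataclass(frozen=True)
class Consequence:
    """Annotated effect of one variant on one transcript."""

    chrom: str
    pos: int
    ref: str
    alt: str
    transcript_id: str
    gene: str
    type: str
    impact: str
    codon_change: str | None = None
    protein_change: str | None = None
    cds_pos: int | None = None
    protein_pos: int | None = None
    incomplete_cds: bool = False

    @property
    def severity(self) -> int:
        return IMPACT_SEVERITY[self.impact]


def annotate_variant(v: VariantRecord, t: TranscriptModel, genome) -> Consequence:
    """Consequence of a biallelic SNV on one transcript model."""
    if not v.is_snv:
        raise ValueError("only biallelic SNVs are annotated")
    base = dict(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                transcript_id=t.transcript_id, gene=t.gene,
                incomplete_cds=t.is_incomplete)
    if v.chrom != t.chrom:
        return Consequence(type="intergenic", impact="MODIFIER", **base)
    if _is_splice_site(t, v.pos):
        return Consequence(type="splice_site", impact="HIGH", **base)
    where = genomic_to_cds(t, v.pos)
    if isinstance(where, str):
        return Consequence(type=where, impact=impact_of(where), **base)
    if t.is_incomplete:
        log.warning(
            "transcript %s has incomplete CDS (length %d); codon annotation "
            "may be frame-shifted", t.transcript_id, t.cds_length,
        )
    cds = cds_sequence(t, genome)
    codon_i = (where - 1) // 3  # 0-based codon index
    in_codon = (where - 1) % 3
    ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
    if len(ref_codon) < 3:
        # trailing partial codon of an incomplete CDS
        return Consequence(type="UTR", impact="MODIFIER", **base)
    ref_base = v.ref if t.strand == "+" else revcomp(v.ref)
    alt_base = v.alt if t.strand == "+" else revcomp(v.alt)
    if ref_codon[in_codon] != ref_base.upper():
        log.warning(
            "reference mismatch at %s:%d: VCF ref %s vs genome codon base %s",
            v.chrom, v.pos, ref_base, ref_codon[in_codon],
        )
    alt_codon = ref_codon[:in_codon] + alt_base.upper() + ref_codon[in_codon + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        ctype = "synonymous"
    elif alt_aa == "*":
        ctype = "stop_gained"
    elif ref_aa == "*":
        ctype = "stop_lost"
    else:
        ctype = "missense"
    protein_pos = (where - 1) // 3 + 1
    return Consequence(
        type=ctype,
        impact=impact_of(ctype),
        codon_change=f"{ref_codon}>{alt_codon}",
        protein_change=f"{ref_aa}{protein_pos}{alt_aa}",
        cds_pos=where,
        protein_pos=protein_pos,
        **base,
    )


@dataclass
class AnnotatedVariant:
    """A variant with its per-transcript consequences; worst one first."""

    record: VariantRecord
    consequences: list[Consequence]

    @property
    def worst(self) -> Consequence:
        return max(
            self.consequences,
            key=lambda c: (c.severity, c.gene != "", c.transcript_id),
        )


def annotate_all(
    variants: Sequence[VariantRecord],
    transcripts: Sequence[TranscriptModel],
    genome,
) -> list[AnnotatedVariant]:
    """Annotate every variant against every same-chromosome transcript.

    Variants on chromosomes without transcript models get a single
    intergenic consequence.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    out = []
    for v in variants:
        cons = [
            annotate_variant(v, t, genome) for t in by_chrom.get(v.chrom, [])
        ]
        if not cons:
            cons = [
                Consequence(
                    chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                    transcript_id="", gene="", type="intergenic",
                    impact="MODIFIER",
                )
            ]
        out.append(AnnotatedVariant(record=v, consequences=cons))
    return out


# ---------------------------------------------------------------------------
# transcript loading
# ---------------------------------------------------------------------------


def load_transcripts(gff3_path: str | Path, fasta=None) -> list[TranscriptModel]:
    """Build transcript models from a GFF3 file (gene/mRNA/exon/CDS).

    If ``fasta`` (a pyfaidx.Fasta or chrom->sequence mapping) is given,
    transcripts exceeding chromosome bounds are rejected.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    seen: set[str] = set()
    for mrna in db.features_of_type("mRNA"):
        tid = mrna.id
        if tid in seen:
            raise ValueError(f"duplicate transcript id {tid}")
        seen.add(tid)
        gene_name = mrna.attributes.get("gene_name", [None])[0]
        if gene_name is None:
            parents = list(db.parents(mrna, featuretype="gene"))
            if parents:
                g = parents[0]
                gene_name = g.attributes.get("Name", [g.id])[0]
            else:
                gene_name = tid
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_parts = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons and cds_parts:
            exons = sorted(cds_parts)
        if not cds_parts:
            continue
        t = TranscriptModel(
            transcript_id=tid,
            gene=gene_name,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=tuple(exons),
            cds_start=min(s for s, _ in cds_parts),
            cds_end=max(e for _, e in cds_parts),
        )
        if fasta is not None:
            chrom_len = len(fasta[t.chrom])
            if t.span[1] > chrom_len:
                raise ValueError(
                    f"transcript {tid} exceeds {t.chrom} length {chrom_len}"
                )
        if t.is_incomplete:
            log.warning(
                "transcript %s: CDS length %d not divisible by 3 (incomplete)",
                tid, t.cds_length,
            )
        models.append(t)
    return models


# ---------------------------------------------------------------------------
# alignment-column conservation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MsaColumn:
    """One column of a protein multiple alignment."""

    index: int  # 0-based
    residues: tuple[str, ...]
    majority: str | None
    conservation: float | None  # None when the column is all gaps


def load_msa(path: str | Path):
    return AlignIO.read(str(path), "fasta")


def conservation_score(msa, column: int) -> MsaColumn:
    """Fraction of non-gap residues matching the majority residue.

    Ties report the lexicographically smallest majority residue (the score
    is unaffected); an all-gap column has undefined conservation.
    """
    residues = tuple(str(rec.seq[column]).upper() for rec in msa)
    non_gap = [r for r in residues if r not in "-."]
    if not non_gap:
        return MsaColumn(index=column, residues=residues, majority=None,
                         conservation=None)
    counts: dict[str, int] = {}
    for r in non_gap:
        counts[r] = counts.get(r, 0) + 1
    top = max(counts.values())
    majority = min(r for r, c in counts.items() if c == top)
    return MsaColumn(
        index=column,
        residues=residues,
        majority=majority,
        conservation=top / len(non_gap),
    )
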