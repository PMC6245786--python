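"""Core variant containers and the minimal two-sample VCF dialect.

A :class:`VariantRecord` is one biallelic (or, pre-QC, multi-allelic) site
with per-sample genotype calls keyed by sample *role* -- ``"mutant"`` for the
pooled homozygous-mutant sample and ``"sibling"`` for the pooled
phenotypically wild-type sample.  Files are read through :mod:`cyvcf2`, so
any standards-conforming VCF 4.2 with extra INFO/FORMAT keys is accepted
(the extras are ignored); output is the minimal dialect
``GT:GQ:DP:AD`` with ``FILTER`` set to ``PASS``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF

MUTANT = "mutant"
SIBLING = "sibling"
ROLES = (MUTANT, SIBLING)

HOM_REF = "0/0"
HET = "0/1"
HOM_ALT = "1/1"
MISSING = "./."


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype call for one sample at one site.

    ``gt`` is one of ``0/0``, ``0/1``, ``1/1`` or ``./.`` (missing);
    ``gq`` is the phred-scaled genotype quality, ``depth`` the read count
    and ``allele_counts`` the (ref, alt) read counts, which must sum to
    ``depth``.
    """

    gt: str
    gq: int
    depth: int
    allele_counts: tuple[int, int]

    def __post_init__(self) -> None:
        if self.gt not in (HOM_REF, HET, HOM_ALT, MISSING):
            raise ValueError(f"invalid genotype {self.gt!r}")
        if self.gq < 0:
            raise ValueError("gq must be >= 0")
        if sum(self.allele_counts) != self.depth:
            raise ValueError(
                f"allele counts {self.allele_counts} do not sum to depth {self.depth}"
            )
        if self.depth == 0 and self.gt != MISSING:
            raise ValueError("zero-depth call must be missing")

    @property
    def is_missing(self) -> bool:
        return self.gt == MISSING

    @property
    def is_hom_alt(self) -> bool:
        return self.gt == HOM_ALT

    @property
    def is_het(self) -> bool:
        return self.gt == HET

    @property
    def is_hom_ref(self) -> bool:
        return self.gt == HOM_REF


@dataclass
class VariantRecord:
    """One variant site with calls for the mutant and sibling pools."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    calls: dict[str, GenotypeCall]
    filter: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        if not self.ref or not self.alts:
            raise ValueError("ref and alts must be non-empty")
        if set(self.calls) != set(ROLES):
            raise ValueError(f"sample roles must be exactly {set(ROLES)}")

    @property
    def alt(self) -> str:
        """The single alternate allele of a biallelic record."""
        if len(self.alts) != 1:
            raise ValueError("record is not biallelic")
        return self.alts[0]

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_snv(self) -> bool:
        return self.is_biallelic and len(self.ref) == 1 and len(self.alts[0]) == 1


def check_sorted(records: Sequence[VariantRecord]) -> None:
    """Require records grouped by chromosome with strictly increasing positions.

    Raises ``ValueError`` naming the offending position otherwise.
    """
    seen: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = 0
    for rec in records:
        if rec.chrom != prev_chrom:
            if rec.chrom in seen:
                raise ValueError(
                    f"unsorted input: chromosome {rec.chrom} reappears at position {rec.pos}"
                )
            seen.add(rec.chrom)
            prev_chrom = rec.chrom
            prev_pos = 0
        if rec.pos <= prev_pos:
            raise ValueError(
                f"unsorted input: {rec.chrom}:{rec.pos} follows {rec.chrom}:{prev_pos}"
            )
        prev_pos = rec.pos


_NAT_SPLIT = re.compile(r"(\d+)")


def natural_key(name: str) -> tuple:
    """Sort key ordering chr2 before chr13 (numeric runs compared as integers)."""
    return tuple(int(p) if p.isdigit() else p for p in _NAT_SPLIT.split(name))


# ---------------------------------------------------------------------------
# minimal VCF 4.2 dialect
# ---------------------------------------------------------------------------

_FORMAT_META = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (phred)">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths (ref,alt)">',
]


def _format_call(call: GenotypeCall) -> str:
    ref_n, alt_n = call.allele_counts
    return f"{call.gt}:{call.gq}:{call.depth}:{ref_n},{alt_n}"


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    contigs: Sequence[tuple[str, int]] | None = None,
    roles: Sequence[str] = ROLES,
) -> None:
    """Write records as a minimal VCF 4.2 file with one column per role.

    ``contigs`` (name, length) pairs become ``##contig`` header lines; they
    are required by strict readers and carry the chromosome lengths.
    """
    roles = list(roles)
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs or []:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.extend(_FORMAT_META)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(roles))
    for rec in records:
        calls = "\t".join(_format_call(rec.calls[r]) for r in roles)
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{','.join(rec.alts)}\t.\t"
            f"{rec.filter}\t.\tGT:GQ:DP:AD\t{calls}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _gt_string(alleles: list[int]) -> str:
    pair = [a for a in alleles if isinstance(a, int)]
    if len(pair) < 2 or -1 in pair[:2]:
        return MISSING
    a, b = sorted(pair[:2])
    if a == 0 and b == 0:
        return HOM_REF
    if a == 0 and b >= 1:
        return HET
    if a >= 1 and b >= 1:
        return HOM_ALT
    return MISSING


def read_vcf(
    path: str | Path,
    mutant_sample: str | None = None,
    sibling_sample: str | None = None,
) -> list[VariantRecord]:
    """Read a two-sample VCF into :class:`VariantRecord` objects.

    Sample-to-role assignment: explicit names win; otherwise samples named
    ``mutant``/``sibling`` are matched by name; otherwise the first sample is
    taken as the mutant pool and the second as the sibling pool.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != 2:
        raise ValueError(f"expected a two-sample VCF, found samples {samples}")
    if mutant_sample is None and sibling_sample is None:
        if set(samples) == set(ROLES):
            mutant_sample, sibling_sample = MUTANT, SIBLING
        else:
            mutant_sample, sibling_sample = samples
    elif mutant_sample is None:
        mutant_sample = next(s for s in samples if s != sibling_sample)
    elif sibling_sample is None:
        sibling_sample = next(s for s in samples if s != mutant_sample)
    idx = {MUTANT: samples.index(mutant_sample), SIBLING: samples.index(sibling_sample)}

    records: list[VariantRecord] = []
    for v in vcf:
        gqs = v.gt_quals
        try:
            dps = v.format("DP")
        except KeyError:
            dps = None
        try:
            ads = v.format("AD")
        except KeyError:
            ads = None
        calls: dict[str, GenotypeCall] = {}
        for role, i in idx.items():
            gt = _gt_string(v.genotypes[i])
            depth = int(dps[i][0]) if dps is not None and dps[i][0] >= 0 else 0
            if ads is not None and ads[i][0] >= 0:
                ref_n = int(ads[i][0])
                alt_n = int(ads[i][1]) if ads.shape[1] > 1 and ads[i][1] >= 0 else 0
            else:
                ref_n, alt_n = depth, 0
            if ref_n + alt_n != depth:
                depth = ref_n + alt_n
            gq = int(gqs[i]) if gqs is not None and gqs[i] >= 0 else 0
            if depth == 0:
                gt, gq = MISSING, 0
            calls[role] = GenotypeCall(gt=gt, gq=gq, depth=depth, allele_counts=(ref_n, alt_n))
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                calls=calls,
                filter=v.FILTER or "PASS",
            )
        )
    vcf.close()
    return records
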