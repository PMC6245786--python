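"""Candidate-reduction cascade and the final ranked report.

Linked, annotated variants pass through two per-record filters -- removal
of sites already present in a known-variants catalogue (exact match on
chromosome, position and alternate allele) and removal of variants whose
most severe impact is LOW or MODIFIER -- and the survivors are ranked by
impact severity, alignment-column conservation and position into a
tabular report with a cascade tally (count entering, after each filter,
genes represented).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .annotate import AnnotatedVariant, IMPACT_SEVERITY
from .variants import MUTANT, SIBLING

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KnownSites:
    """Catalogue of already-known variants, keyed by (chrom, pos, alt)."""

    keys: frozenset[tuple[str, int, str]]

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def empty(cls) -> "KnownSites":
        return cls(keys=frozenset())

    @classmethod
    def from_file(cls, path: str | Path) -> "KnownSites":
        """Load from VCF (by extension) or a TSV with chrom/pos/ref/alt columns."""
        path = Path(path)
        if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
            from cyvcf2 import VCF

            keys = set()
            vcf = VCF(str(path))
            for v in vcf:
                for alt in v.ALT:
                    keys.add((v.CHROM, v.POS, alt))
            vcf.close()
            return cls(keys=frozenset(keys))
        keys = set()
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("chrom"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{ln}: expected at least chrom, pos, alt columns"
                    )
                chrom, pos = fields[0], fields[1]
                alt = fields[3] if len(fields) >= 4 else fields[2]
                try:
                    keys.add((chrom, int(pos), alt))
                except ValueError:
                    raise ValueError(f"{path}:{ln}: malformed position {pos!r}")
        return cls(keys=frozenset(keys))


def filter_known_variants(
    variants: Sequence[AnnotatedVariant], known: KnownSites
) -> tuple[list[AnnotatedVariant], int]:
    """Drop variants whose (chrom, pos, alt) is in the known catalogue.

    A known site with a *different* alternate allele does not match.
    Returns (retained, removed count).
    """
    kept = [
        v for v in variants
        if (v.record.chrom, v.record.pos, v.record.alt) not in known
    ]
    return kept, len(variants) - len(kept)


def filter_by_impact(
    variants: Sequence[AnnotatedVariant],
) -> tuple[list[AnnotatedVariant], int]:
    """Retain only variants whose most severe impact is HIGH or MODERATE."""
    for v in variants:
        if not v.consequences:
            raise ValueError(
                f"unannotated variant {v.record.chrom}:{v.record.pos}"
            )
    kept = [v for v in variants if v.worst.impact in ("HIGH", "MODERATE")]
    return kept, len(variants) - len(kept)


@dataclass
class CandidateRow:
    """One report row, mirroring the candidate-table column layout."""

    location: str
    variation: str
    gene: str
    transcripts: str
    consequence: str
    amino_acid: str
    impact: str
    mutant_gt: str
    sibling_gt: str
    conservation: float | None

    @classmethod
    def from_variant(
        cls, v: AnnotatedVariant, conservation: float | None = None
    ) -> "CandidateRow":
        worst = v.worst
        tids = sorted(
            {c.transcript_id for c in v.consequences
             if c.transcript_id and c.severity == worst.severity}
        )
        aa = worst.protein_change or ""
        if worst.protein_change:
            aa = f"{worst.protein_change[0]} to {worst.protein_change[-1]}"
        return cls(
            location=f"{v.record.chrom}:{v.record.pos}",
            variation=f"{v.record.ref} to {v.record.alt}",
            gene=worst.gene,
            transcripts=" ".join(tids),
            consequence=worst.type,
            amino_acid=aa,
            impact=worst.impact,
            mutant_gt=v.record.calls[MUTANT].gt,
            sibling_gt=v.record.calls[SIBLING].gt,
            conservation=conservation,
        )


@dataclass
class CandidateReport:
    """Ranked surviving candidates plus the cascade tally."""

    rows: list[CandidateRow]
    n_entering: int
    n_after_known: int
    n_after_impact: int

    def __post_init__(self) -> None:
        if not (self.n_entering >= self.n_after_known >= self.n_after_impact):
            raise ValueError("cascade tallies must be monotone non-increasing")

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.gene and r.gene not in seen:
                seen.append(r.gene)
        return seen

    @property
    def tally(self) -> dict:
        return {
            "entering": self.n_entering,
            "after_known_filter": self.n_after_known,
            "after_impact_filter": self.n_after_impact,
            "genes": self.genes,
        }

    HEADER = (
        "Location\tVariation\tGene\tTranscripts\tConsequence\tAmino acid\t"
        "Impact\tMutant GT\tSibling GT\tConservation"
    )

    def to_tsv(self, path: str | Path) -> None:
        lines = [self.HEADER]
        for r in self.rows:
            cons = "" if r.conservation is None else f"{r.conservation:.3f}"
            lines.append(
                f"{r.location}\t{r.variation}\t{r.gene}\t{r.transcripts}\t"
                f"{r.consequence}\t{r.amino_acid}\t{r.impact}\t{r.mutant_gt}\t"
                f"{r.sibling_gt}\t{cons}"
            )
        lines.append(f"# variants entering cascade: {self.n_entering}")
        lines.append(f"# after known-site filter: {self.n_after_known}")
        lines.append(f"# after impact filter: {self.n_after_impact}")
        lines.append(f"# genes represented: {', '.join(self.genes) or '(none)'}")
        Path(path).write_text("\n".join(lines) + "\n")

    def summary(self) -> str:
        return (
            f"{self.n_entering} variants entered the cascade; "
            f"{self.n_after_known} survived the known-site filter; "
            f"{self.n_after_impact} with HIGH/MODERATE impact on "
            f"{len(self.genes)} gene(s): {', '.join(self.genes) or '(none)'}"
        )


def build_candidate_report(
    variants: Sequence[AnnotatedVariant],
    known: KnownSites | None = None,
    conservation: dict[tuple[str, int], float] | None = None,
) -> CandidateReport:
    """Run the cascade and rank survivors.

    ``conservation`` optionally maps (chrom, pos) to an alignment-column
    conservation score.  Rows are sorted by impact severity (descending),
    conservation (descending, unknown last) and position.
    """
    known = known or KnownSites.empty()
    conservation = conservation or {}
    after_known, _ = filter_known_variants(variants, known)
    after_impact, _ = filter_by_impact(after_known)
    rows = [
        CandidateRow.from_variant(
            v, conservation.get((v.record.chrom, v.record.pos))
        )
        for v in after_impact
    ]
    # position sort must be numeric, not lexicographic
    rows.sort(
        key=lambda r: (
            -IMPACT_SEVERITY[r.impact],
            -(r.conservation if r.conservation is not None else -1.0),
            r.location.split(":")[0],
            int(r.location.split(":")[1]),
        )
    )
    return CandidateReport(
        rows=rows,
        n_entering=len(variants),
        n_after_known=len(after_known),
        n_after_impact=len(after_impact),
    )
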