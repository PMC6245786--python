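"""Homozygosity-based linkage mapping on the QC-passed two-sample table.

The mapping statistic works in three steps: (1) a per-chromosome
homozygosity score -- the fraction of markers called homozygous
non-reference (1/1) in each pool -- identifies the chromosome carrying the
recessive allele as the one with the highest mutant-pool score; (2) on
that chromosome, sliding windows count homozygous and heterozygous
mutant-pool calls and the pseudocounted ratio (n_hom + c) / (n_het + c) is
smoothed by LOESS; (3) the critical region is the contiguous run of
windows around the smoothed maximum whose fitted value stays above a
fraction of the peak.  Variants inside the region that are 1/1 in the
mutant pool and 0/0 or 0/1 in the sibling pool are the linked candidates
passed on to annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .loess import LoessConfig, loess_fit
from .variants import MUTANT, ROLES, SIBLING, VariantRecord, natural_key

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChromScore:
    """Genotype-class counts of one sample on one chromosome."""

    chrom: str
    role: str
    n_hom_alt: int
    n_het: int
    n_hom_ref: int
    n_total: int

    @property
    def homozygosity_score(self) -> float | None:
        """Fraction of markers called 1/1, or None for an empty chromosome."""
        if self.n_total == 0:
            return None
        return self.n_hom_alt / self.n_total


def chromosome_homozygosity_scores(
    records: Sequence[VariantRecord], informative_only: bool = False
) -> list[ChromScore]:
    """One score per (chromosome, sample role), in input chromosome order.

    Missing calls are excluded from the counts.  With ``informative_only``
    the score is computed over markers heterozygous in the sibling pool
    only (the markers that are informative about segregation).
    """
    order: list[str] = []
    counts: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        if rec.chrom not in order:
            order.append(rec.chrom)
        if informative_only and not rec.calls[SIBLING].is_het:
            continue
        for role in ROLES:
            call = rec.calls[role]
            key = (rec.chrom, role)
            c = counts.setdefault(key, [0, 0, 0, 0])
            if call.is_missing:
                continue
            c[3] += 1
            if call.is_hom_alt:
                c[0] += 1
            elif call.is_het:
                c[1] += 1
            else:
                c[2] += 1
    scores = []
    for chrom in order:
        for role in ROLES:
            c = counts.get((chrom, role), [0, 0, 0, 0])
            scores.append(
                ChromScore(
                    chrom=chrom, role=role,
                    n_hom_alt=c[0], n_het=c[1], n_hom_ref=c[2], n_total=c[3],
                )
            )
    return scores


def select_candidate_chromosome(scores: Sequence[ChromScore]) -> str:
    """Chromosome with the highest mutant-pool homozygosity score.

    Undefined (empty-chromosome) scores are excluded.  Exact ties are
    broken by natural chromosome-name order with a logged warning.
    """
    defined = [
        s for s in scores
        if s.role == MUTANT and s.homozygosity_score is not None
    ]
    if not defined:
        raise ValueError("no chromosome has a defined homozygosity score")
    best = max(s.homozygosity_score for s in defined)
    tied = sorted(
        (s.chrom for s in defined if s.homozygosity_score == best), key=natural_key
    )
    if len(tied) > 1:
        log.warning(
            "homozygosity-score tie between %s; selecting %s", tied, tied[0]
        )
    return tied[0]


@dataclass(frozen=True)
class WindowStats:
    """Mutant-pool genotype counts in one window (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n: int
    n_hom: int
    n_het: int
    ratio: float

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def frac_hom(self) -> float:
        return self.n_hom / self.n

    @property
    def frac_het(self) -> float:
        return self.n_het / self.n


def window_hom_het_ratio(
    records: Sequence[VariantRecord],
    chrom: str,
    window_size: int = 1_000_000,
    step: int = 500_000,
    pseudocount: float = 1.0,
) -> list[WindowStats]:
    """Sliding-window homozygosity/heterozygosity ratio along one chromosome.

    Windows of ``window_size`` bp tile the chromosome every ``step`` bp
    starting at 0; windows containing no genotyped marker are omitted.  The
    ratio is (n_hom + pseudocount) / (n_het + pseudocount); the pseudocount
    keeps the quotient finite in fully homozygous windows.
    """
    if not (window_size >= step > 0):
        raise ValueError("require window_size >= step > 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    on_chrom = [r for r in records if r.chrom == chrom]
    if not on_chrom:
        raise ValueError(f"chromosome {chrom} absent from table")
    pos = np.array([r.pos - 1 for r in on_chrom])  # 0-based
    is_hom = np.array([r.calls[MUTANT].is_hom_alt for r in on_chrom])
    is_het = np.array([r.calls[MUTANT].is_het for r in on_chrom])
    genotyped = np.array([not r.calls[MUTANT].is_missing for r in on_chrom])

    out: list[WindowStats] = []
    last = int(pos.max())
    start = 0
    while start <= last:
        end = start + window_size
        in_win = (pos >= start) & (pos < end) & genotyped
        n = int(in_win.sum())
        if n > 0:
            n_hom = int((in_win & is_hom).sum())
            n_het = int((in_win & is_het).sum())
            out.append(
                WindowStats(
                    chrom=chrom, start=start, end=end, n=n,
                    n_hom=n_hom, n_het=n_het,
                    ratio=(n_hom + pseudocount) / (n_het + pseudocount),
                )
            )
        start += step
    return out


@dataclass(frozen=True)
class CriticalRegion:
    """The mapped interval (1-based inclusive bp bounds)."""

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_value: float
    threshold_frac: float

    def __post_init__(self) -> None:
        if not (self.start <= self.peak_pos <= self.end):
            raise ValueError("peak must lie inside the region")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def critical_region_from_fit(
    windows: Sequence[WindowStats],
    fitted: np.ndarray,
    threshold_frac: float = 0.95,
    min_fit_floor: float = 1.5,
) -> CriticalRegion | None:
    """Critical region around the maximum of the LOESS-smoothed ratio.

    The peak is the (first) argmax of the fitted values; the region is the
    maximal contiguous run of windows containing the peak whose fitted
    value is >= ``threshold_frac`` times the peak value.  A peak below
    ``min_fit_floor`` means no credible linkage anywhere -- returns None.
    """
    if len(windows) == 0:
        raise ValueError("no windows")
    if not (0 < threshold_frac <= 1):
        raise ValueError("threshold_frac must be in (0, 1]")
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape[0] != len(windows):
        raise ValueError("fit length does not match windows")
    peak_i = int(np.argmax(fitted))
    peak_val = float(fitted[peak_i])
    n_ties = int(np.sum(fitted == peak_val))
    if n_ties > 1:
        log.warning("%d equal-height maxima; using the leftmost", n_ties)
    if peak_val < min_fit_floor:
        return None
    cut = threshold_frac * peak_val
    lo = peak_i
    while lo > 0 and fitted[lo - 1] >= cut:
        lo -= 1
    hi = peak_i
    while hi < len(windows) - 1 and fitted[hi + 1] >= cut:
        hi += 1
    return CriticalRegion(
        chrom=windows[0].chrom,
        start=windows[lo].start + 1,
        end=windows[hi].end,
        peak_pos=int(windows[peak_i].center) + 1,
        peak_value=peak_val,
        threshold_frac=threshold_frac,
    )


def extract_linked_variants(
    records: Sequence[VariantRecord], region: CriticalRegion
) -> list[VariantRecord]:
    """Variants in the region that segregate like the causal mutation.

    Keeps records 1/1 in the mutant pool and 0/1 or 0/0 in the sibling
    pool; input order is preserved.
    """
    out = []
    for r in records:
        if not region.contains(r.chrom, r.pos):
            continue
        if r.calls[MUTANT].is_hom_alt and (
            r.calls[SIBLING].is_het or r.calls[SIBLING].is_hom_ref
        ):
            out.append(r)
    return out


def map_linkage(
    records: Sequence[VariantRecord],
    window_size: int = 1_000_000,
    step: int = 500_000,
    pseudocount: float = 1.0,
    loess_cfg: LoessConfig | None = None,
    threshold_frac: float = 0.95,
    min_fit_floor: float = 1.5,
    informative_only: bool = False,
) -> tuple[list[ChromScore], str, list[WindowStats], np.ndarray, CriticalRegion | None]:
    """Run the full mapping stage; returns all intermediate statistics."""
    scores = chromosome_homozygosity_scores(records, informative_only=informative_only)
    chrom = select_candidate_chromosome(scores)
    windows = window_hom_het_ratio(records, chrom, window_size, step, pseudocount)
    x = np.array([w.center for w in windows])
    y = np.array([w.ratio for w in windows])
    cfg = loess_cfg or LoessConfig()
    if len(windows) >= cfg.degree + 2:
        fitted = loess_fit(x, y, cfg)
    else:
        fitted = y.copy()
    region = critical_region_from_fit(windows, fitted, threshold_frac, min_fit_floor)
    return scores, chrom, windows, fitted, region
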