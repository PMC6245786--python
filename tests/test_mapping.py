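"""Linkage-mapper contracts: homozygosity scores, chromosome selection,
window ratios, critical-region extraction and the genotype-pattern filter."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from homozymap.mapping import (
    ChromScore,
    CriticalRegion,
    WindowStats,
    chromosome_homozygosity_scores,
    critical_region_from_fit,
    extract_linked_variants,
    select_candidate_chromosome,
    window_hom_het_ratio,
)
from homozymap.variants import HET, HOM_ALT, HOM_REF, MUTANT, SIBLING

from conftest import make_record


def _score(chrom, value, role=MUTANT, n=100):
    n_hom = int(round(value * n))
    return ChromScore(chrom=chrom, role=role, n_hom_alt=n_hom,
                      n_het=n - n_hom, n_hom_ref=0, n_total=n)


class TestChromScores:
    def test_all_homozygous_scores_one(self):
        recs = [make_record(pos=100 * (i + 1), mut=HOM_ALT) for i in range(10)]
        scores = chromosome_homozygosity_scores(recs)
        mut = next(s for s in scores if s.role == MUTANT)
        assert mut.homozygosity_score == 1.0

    def test_hand_counted_fraction(self):
        gts = [HOM_ALT] * 2 + [HET] * 4 + [HOM_REF] * 2
        recs = [make_record(pos=100 * (i + 1), mut=g) for i, g in enumerate(gts)]
        mut = next(s for s in chromosome_homozygosity_scores(recs)
                   if s.role == MUTANT)
        assert mut.homozygosity_score == 0.25
        assert (mut.n_hom_alt, mut.n_het, mut.n_hom_ref, mut.n_total) == (2, 4, 2, 8)

    def test_sibling_without_hom_calls_scores_zero(self):
        recs = [make_record(pos=100 * (i + 1), sib=HET) for i in range(5)]
        sib = next(s for s in chromosome_homozygosity_scores(recs)
                   if s.role == SIBLING)
        assert sib.homozygosity_score == 0.0

    def test_informative_only_restricts_to_sibling_hets(self):
        recs = [
            make_record(pos=100, mut=HOM_ALT, sib=HET),
            make_record(pos=200, mut=HOM_ALT, sib=HOM_ALT),
        ]
        mut = next(s for s in chromosome_homozygosity_scores(
            recs, informative_only=True) if s.role == MUTANT)
        assert mut.n_total == 1


class TestSelectChromosome:
    def test_argmax(self):
        scores = [_score("chr1", 0.26), _score("chr13", 0.61), _score("chr20", 0.24)]
        assert select_candidate_chromosome(scores) == "chr13"

    def test_single_chromosome(self):
        assert select_candidate_chromosome([_score("chr7", 0.4)]) == "chr7"

    def test_tie_broken_by_natural_name_order_with_warning(self, caplog):
        scores = [_score("chr5", 0.5), _score("chr2", 0.5)]
        with caplog.at_level(logging.WARNING):
            assert select_candidate_chromosome(scores) == "chr2"
        assert "tie" in caplog.text

    def test_natural_order_prefers_chr2_over_chr13(self):
        scores = [_score("chr13", 0.5), _score("chr2", 0.5)]
        assert select_candidate_chromosome(scores) == "chr2"

    def test_undefined_scores_excluded(self):
        empty = ChromScore("chrU", MUTANT, 0, 0, 0, 0)
        assert select_candidate_chromosome([empty, _score("chr1", 0.1)]) == "chr1"
        with pytest.raises(ValueError):
            select_candidate_chromosome([empty])


class TestWindows:
    def _records(self, gts, spacing=10_000):
        return [make_record(pos=spacing * (i + 1), mut=g) for i, g in enumerate(gts)]

    def test_hand_arithmetic(self):
        recs = self._records([HOM_ALT] * 6 + [HET] * 4)
        (w,) = window_hom_het_ratio(recs, "chr1", window_size=1_000_000,
                                    step=1_000_000, pseudocount=1)
        assert (w.n_hom, w.n_het) == (6, 4)
        assert w.frac_hom == pytest.approx(0.6)
        assert w.frac_het == pytest.approx(0.4)
        assert w.ratio == pytest.approx(1.4)

    def test_balanced_window_ratio_one(self):
        recs = self._records([HOM_ALT] * 5 + [HET] * 5)
        for pc in (0.5, 1, 2):
            (w,) = window_hom_het_ratio(recs, "chr1", 1_000_000, 1_000_000, pc)
            assert w.ratio == 1.0

    def test_pure_hom_window_finite_ratio(self):
        recs = self._records([HOM_ALT] * 10)
        (w,) = window_hom_het_ratio(recs, "chr1", 1_000_000, 1_000_000, 1)
        assert w.ratio == 11.0

    def test_empty_windows_omitted(self):
        recs = [make_record(pos=100), make_record(pos=5_000_100)]
        wins = window_hom_het_ratio(recs, "chr1", 1_000_000, 1_000_000, 1)
        assert [w.start for w in wins] == [0, 5_000_000]

    def test_absent_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chrX"):
            window_hom_het_ratio([make_record()], "chrX", 1_000_000, 500_000, 1)

    def test_nonoverlapping_windows_partition_hom_count(self, small_study):
        from homozymap.qc import apply_hard_filters

        kept, _ = apply_hard_filters(small_study.records)
        wins = window_hom_het_ratio(kept, "chr2", 1_000_000, 1_000_000, 1)
        total = sum(w.n_hom for w in wins)
        mut = next(
            s for s in chromosome_homozygosity_scores(kept)
            if s.chrom == "chr2" and s.role == MUTANT
        )
        assert total == mut.n_hom_alt


def _windows(n, chrom="chr13", size=1_000_000, step=500_000):
    return [
        WindowStats(chrom=chrom, start=i * step, end=i * step + size,
                    n=2, n_hom=1, n_het=1, ratio=1.0)
        for i in range(n)
    ]


class TestCriticalRegion:
    def test_unimodal_peak_bounds_at_threshold_crossings(self):
        wins = _windows(60)
        centers = np.array([w.center for w in wins])
        fitted = 3 * np.exp(-0.5 * ((centers - 29e6) / 3e6) ** 2) + 0.3
        region = critical_region_from_fit(wins, fitted, 0.95, 1.5)
        assert region.contains("chr13", 29_000_000)
        # direct scan oracle
        cut = 0.95 * fitted.max()
        inside = fitted >= cut
        peak = int(np.argmax(fitted))
        lo = peak
        while lo > 0 and inside[lo - 1]:
            lo -= 1
        hi = peak
        while hi < len(wins) - 1 and inside[hi + 1]:
            hi += 1
        assert (region.start, region.end) == (wins[lo].start + 1, wins[hi].end)

    def test_constant_fit_spans_everything(self, caplog):
        wins = _windows(10)
        with caplog.at_level(logging.WARNING):
            region = critical_region_from_fit(wins, np.full(10, 2.0), 0.95, 1.5)
        assert (region.start, region.end) == (1, wins[-1].end)
        assert "maxima" in caplog.text

    def test_two_equal_peaks_leftmost_wins(self, caplog):
        wins = _windows(30)
        fitted = np.full(30, 1.6)
        fitted[8] = fitted[22] = 3.0
        with caplog.at_level(logging.WARNING):
            region = critical_region_from_fit(wins, fitted, 0.95, 1.5)
        assert region.start == wins[8].start + 1
        assert "maxima" in caplog.text

    def test_peak_below_floor_reports_no_linkage(self):
        wins = _windows(10)
        assert critical_region_from_fit(wins, np.full(10, 1.2), 0.95, 1.5) is None

    def test_lower_threshold_never_shrinks_region(self):
        rng = np.random.default_rng(5)
        wins = _windows(50)
        centers = np.array([w.center for w in wins])
        fitted = 2.5 * np.exp(-0.5 * ((centers - 12e6) / 4e6) ** 2) + \
            0.2 * np.sin(centers / 2e6) + 0.5 + 0.05 * rng.normal(size=50)
        prev = None
        for frac in (0.99, 0.95, 0.9, 0.8, 0.5):
            region = critical_region_from_fit(wins, fitted, frac, 0.5)
            if prev is not None:
                assert region.start <= prev.start and region.end >= prev.end
            prev = region


class TestExtractLinked:
    REGION = CriticalRegion(chrom="chr13", start=1_000_000, end=2_000_000,
                            peak_pos=1_500_000, peak_value=3.0,
                            threshold_frac=0.95)

    @pytest.mark.parametrize(
        "mut,sib,kept",
        [
            (HOM_ALT, HET, True),
            (HOM_ALT, HOM_REF, True),
            (HOM_ALT, HOM_ALT, False),
            (HET, HOM_REF, False),
            (HOM_REF, HET, False),
        ],
    )
    def test_genotype_pattern(self, mut, sib, kept):
        rec = make_record(chrom="chr13", pos=1_500_000, mut=mut, sib=sib)
        assert (extract_linked_variants([rec], self.REGION) == [rec]) == kept

    def test_position_bounds_inclusive(self):
        inside = [
            make_record(chrom="chr13", pos=p, mut=HOM_ALT, sib=HET)
            for p in (1_000_000, 2_000_000)
        ]
        outside = [
            make_record(chrom="chr13", pos=p, mut=HOM_ALT, sib=HET)
            for p in (999_999, 2_000_001)
        ]
        assert extract_linked_variants(inside + outside, self.REGION) == inside

    def test_other_chromosome_excluded(self):
        rec = make_record(chrom="chr1", pos=1_500_000, mut=HOM_ALT, sib=HET)
        assert extract_linked_variants([rec], self.REGION) == []
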