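"""Consequence-annotator contracts: strand-aware CDS mapping, codon
translation, splice-site calling, impact rating and alignment conservation."""

from __future__ import annotations

import numpy as np
import pytest

from homozymap.annotate import (
    IMPACT_OF_TYPE,
    Consequence,
    TranscriptModel,
    annotate_all,
    annotate_variant,
    cds_sequence,
    cds_to_genomic,
    conservation_score,
    genomic_to_cds,
    impact_of,
    load_transcripts,
    revcomp,
)
from homozymap.variants import HOM_ALT, HET

from conftest import make_record

# independent standard-genetic-code oracle (hand-entered, not Biopython)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _plus_tx(cds: str, chrom="c", offset=100):
    """Single-exon plus-strand transcript with CDS at [offset+1, ...]."""
    start, end = offset + 1, offset + len(cds)
    genome = {chrom: "N" * offset + cds + "N" * 50}
    t = TranscriptModel(transcript_id="t+", gene="g", chrom=chrom, strand="+",
                        exons=((start, end),), cds_start=start, cds_end=end)
    return t, genome


class TestCdsMapping:
    def test_plus_strand_first_base(self):
        t, _ = _plus_tx("ATGAAATAA")
        assert genomic_to_cds(t, 101) == 1
        assert genomic_to_cds(t, 109) == 9

    def test_minus_strand_counts_from_top(self):
        t = TranscriptModel(transcript_id="t-", gene="g", chrom="c", strand="-",
                            exons=((101, 109),), cds_start=101, cds_end=109)
        assert genomic_to_cds(t, 109) == 1
        assert genomic_to_cds(t, 101) == 9

    def test_intron_utr_intergenic_labels(self):
        t = TranscriptModel(transcript_id="t", gene="g", chrom="c", strand="+",
                            exons=((91, 120), (201, 240)),
                            cds_start=101, cds_end=220)
        assert genomic_to_cds(t, 150) == "intron"
        assert genomic_to_cds(t, 95) == "UTR"
        assert genomic_to_cds(t, 230) == "UTR"
        assert genomic_to_cds(t, 50) == "intergenic"
        assert genomic_to_cds(t, 500) == "intergenic"

    @pytest.mark.parametrize("strand", "+-")
    @pytest.mark.parametrize("seed", range(4))
    def test_round_trip_exhaustive_on_random_transcripts(self, strand, seed):
        rng = np.random.default_rng(seed)
        pos = 1000
        exons = []
        for _ in range(int(rng.integers(1, 5))):
            length = int(rng.integers(20, 100))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(50, 200))
        t = TranscriptModel(
            transcript_id="t", gene="g", chrom="c", strand=strand,
            exons=tuple(exons), cds_start=exons[0][0], cds_end=exons[-1][1],
        )
        for cpos in range(1, t.cds_length + 1):
            g = cds_to_genomic(t, cpos)
            assert genomic_to_cds(t, g) == cpos


class TestLoadTranscripts:
    GFF = """##gff-version 3
c\tx\tgene\t101\t400\t.\t+\t.\tID=gene:gp;Name=gp
c\tx\tmRNA\t101\t400\t.\t+\t.\tID=gp.1;Parent=gene:gp
c\tx\texon\t101\t160\t.\t+\t.\tParent=gp.1
c\tx\texon\t201\t260\t.\t+\t.\tParent=gp.1
c\tx\texon\t301\t400\t.\t+\t.\tParent=gp.1
c\tx\tCDS\t101\t160\t.\t+\t0\tParent=gp.1
c\tx\tCDS\t201\t260\t.\t+\t0\tParent=gp.1
c\tx\tCDS\t301\t400\t.\t+\t2\tParent=gp.1
c\tx\tmRNA\t101\t400\t.\t+\t.\tID=gp.2;Parent=gene:gp
c\tx\texon\t101\t160\t.\t+\t.\tParent=gp.2
c\tx\texon\t301\t400\t.\t+\t.\tParent=gp.2
c\tx\tCDS\t101\t160\t.\t+\t0\tParent=gp.2
c\tx\tCDS\t301\t400\t.\t+\t0\tParent=gp.2
c\tx\tgene\t501\t560\t.\t-\t.\tID=gene:gm;Name=gm
c\tx\tmRNA\t501\t560\t.\t-\t.\tID=gm.1;Parent=gene:gm
c\tx\texon\t501\t560\t.\t-\t.\tParent=gm.1
c\tx\tCDS\t501\t560\t.\t-\t0\tParent=gm.1
"""

    @pytest.fixture()
    def gff_path(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(self.GFF)
        return p

    def test_models_built_per_mrna(self, gff_path):
        models = {t.transcript_id: t for t in load_transcripts(gff_path)}
        assert set(models) == {"gp.1", "gp.2", "gm.1"}
        assert models["gp.1"].gene == "gp"
        assert models["gp.1"].cds_length == 220
        # exon-skipped isoform has the shorter CDS
        assert models["gp.2"].cds_length == 160

    def test_minus_strand_cds_is_reverse_complement(self, gff_path):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        genome = {"c": seq}
        models = {t.transcript_id: t for t in load_transcripts(gff_path)}
        assert cds_sequence(models["gm.1"], genome) == revcomp(seq[500:560])
        assert cds_sequence(models["gp.2"], genome) == seq[100:160] + seq[300:400]


class TestAnnotateVariant:
    def test_serine_to_arginine_on_minus_strand(self):
        # transcript-strand codon AGT (Ser) with its third base at the
        # genomic position; forward-strand ref A, alt T reads T>A on the
        # transcript and turns AGT into AGA (Arg)
        cds = "ATG" + "AGT" + "TAA"
        genomic = revcomp(cds)
        genome = {"c": "N" * 100 + genomic + "N" * 20}
        t = TranscriptModel(transcript_id="t-", gene="g", chrom="c", strand="-",
                            exons=((101, 109),), cds_start=101, cds_end=109)
        # cds position 6 (codon 2 base 3) on minus strand = genomic 109-5
        gpos = 104
        assert genome["c"][gpos - 1] == "A"
        v = make_record(chrom="c", pos=gpos, ref="A", alts=("T",),
                        mut=HOM_ALT, sib=HET)
        c = annotate_variant(v, t, genome)
        assert c.type == "missense" and c.impact == "MODERATE"
        assert c.codon_change == "AGT>AGA"
        assert c.protein_change == "S2R"

    def test_synonymous_third_base(self):
        t, genome = _plus_tx("ATG" + "AGT" + "TAA")
        v = make_record(chrom="c", pos=106, ref="T", alts=("C",))
        c = annotate_variant(v, t, genome)
        assert c.type == "synonymous" and c.impact == "LOW"
        assert c.codon_change == "AGT>AGC"

    def test_stop_gained(self):
        t, genome = _plus_tx("ATG" + "TGC" + "TAA")
        v = make_record(chrom="c", pos=106, ref="C", alts=("A",))
        c = annotate_variant(v, t, genome)
        assert c.type == "stop_gained" and c.impact == "HIGH"

    def test_splice_site_window(self):
        t = TranscriptModel(transcript_id="t", gene="g", chrom="c", strand="+",
                            exons=((101, 160), (301, 400)),
                            cds_start=101, cds_end=400)
        genome = {"c": "A" * 500}
        for gpos, expected in [(161, "splice_site"), (162, "splice_site"),
                               (163, "intron"), (299, "splice_site"),
                               (300, "splice_site"), (298, "intron")]:
            v = make_record(chrom="c", pos=gpos, ref="A", alts=("G",))
            assert annotate_variant(v, t, genome).type == expected, gpos

    def test_other_chromosome_is_intergenic(self):
        t, genome = _plus_tx("ATGTAA")
        v = make_record(chrom="other", pos=104, ref="A", alts=("T",))
        c = annotate_variant(v, t, genome)
        assert c.type == "intergenic" and c.impact == "MODIFIER"

    def test_protein_position_is_ceiling_of_cds_thirds(self):
        t, genome = _plus_tx("ATG" + "AAA" * 40 + "TAA")
        v = make_record(chrom="c", pos=100 + 35, ref="A", alts=("C",))
        c = annotate_variant(v, t, genome)
        assert c.cds_pos == 35 and c.protein_pos == 12  # ceil(35/3)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        L = 400
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        exons = ((51, 110), (171, 290))
        t_minus = TranscriptModel(transcript_id="m", gene="g", chrom="c",
                                  strand="-", exons=exons,
                                  cds_start=51, cds_end=290)
        # mirror construct: reverse-complemented genome, mirrored exons
        mirror = tuple(sorted((L + 1 - e, L + 1 - s) for s, e in exons))
        t_plus = TranscriptModel(transcript_id="p", gene="g", chrom="c",
                                 strand="+", exons=mirror,
                                 cds_start=mirror[0][0], cds_end=mirror[-1][1])
        g_minus = {"c": seq}
        g_plus = {"c": revcomp(seq)}
        for gpos in (60, 75, 200, 250):
            ref = seq[gpos - 1]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            vm = make_record(chrom="c", pos=gpos, ref=ref, alts=(alt,))
            comp = str.maketrans("ACGT", "TGCA")
            vp = make_record(chrom="c", pos=L + 1 - gpos,
                             ref=ref.translate(comp), alts=(alt.translate(comp),))
            cm = annotate_variant(vm, t_minus, g_minus)
            cp = annotate_variant(vp, t_plus, g_plus)
            assert (cm.type, cm.codon_change, cm.protein_change) == (
                cp.type, cp.codon_change, cp.protein_change)


class TestExhaustiveCodonOracle:
    def test_all_single_base_changes_of_all_codons(self):
        """All 64 x 9 single-base substitutions in a middle codon classify
        exactly as the independent hand-entered codon table dictates."""
        for codon, ref_aa in CODON_TABLE.items():
            t, genome = _plus_tx("ATG" + codon + "TAATAA")
            for i in range(3):
                for alt in "ACGT":
                    if alt == codon[i]:
                        continue
                    mutated = codon[:i] + alt + codon[i + 1 :]
                    alt_aa = CODON_TABLE[mutated]
                    if ref_aa == alt_aa:
                        expected = "synonymous"
                    elif alt_aa == "*":
                        expected = "stop_gained"
                    elif ref_aa == "*":
                        expected = "stop_lost"
                    else:
                        expected = "missense"
                    v = make_record(chrom="c", pos=104 + i,
                                    ref=codon[i], alts=(alt,))
                    c = annotate_variant(v, t, genome)
                    assert c.type == expected, (codon, i, alt)
                    if expected == "missense":
                        assert c.protein_change[0] != c.protein_change[-1]
                    if expected == "synonymous":
                        assert c.protein_change[0] == c.protein_change[-1]


class TestImpactTable:
    @pytest.mark.parametrize("ctype,impact", sorted(IMPACT_OF_TYPE.items()))
    def test_fixed_table(self, ctype, impact):
        assert impact_of(ctype) == impact

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            impact_of("frameshift")


class _Msa:
    """Minimal stand-in for a Biopython alignment (iterable of .seq)."""

    def __init__(self, rows):
        class Rec:
            def __init__(self, s):
                self.seq = s

        self.rows = [Rec(r) for r in rows]

    def __iter__(self):
        return iter(self.rows)


class TestConservation:
    def test_full_identity(self):
        col = conservation_score(_Msa(["S", "S", "S", "S", "S"]), 0)
        assert col.conservation == 1.0 and col.majority == "S"

    def test_four_of_five(self):
        assert conservation_score(_Msa(list("SSSST")), 0).conservation == 0.8

    def test_gaps_excluded(self):
        col = conservation_score(_Msa(["S", "-", "S", "S", "S"]), 0)
        assert col.conservation == 1.0

    def test_all_gap_column_undefined(self):
        col = conservation_score(_Msa(["-", "-", "-"]), 0)
        assert col.conservation is None and col.majority is None

    def test_tie_reports_lexicographically_smallest(self):
        col = conservation_score(_Msa(list("TTSS")), 0)
        assert col.majority == "S" and col.conservation == 0.5


class TestAnnotateAll:
    def test_variant_without_transcript_gets_intergenic(self):
        out = annotate_all([make_record(chrom="nowhere", pos=5)], [], {})
        assert out[0].worst.type == "intergenic"

    def test_gene_level_most_severe_wins(self):
        t1, genome = _plus_tx("ATG" + "TGC" + "TAA")
        t2 = TranscriptModel(transcript_id="t2", gene="g", chrom="c",
                             strand="+", exons=((90, 130),),
                             cds_start=101, cds_end=109)
        v = make_record(chrom="c", pos=106, ref="C", alts=("A",))
        out = annotate_all([v], [t1, t2], genome)
        assert out[0].worst.type == "stop_gained"
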