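"""Shared fixtures: hand-built transcripts with exactly known geometry."""

import pytest

from dntb.gene_model import TranscriptModel, revcomp

FLANK = "TTTTTGGGGG"  # 10 nt
INTRON = "GT" + "A" * 46 + "AG"  # 50 nt, canonical splice dinucleotides

# two-exon gene: exon1 100 nt, exon2 80 nt; 6 nt 5'UTR, 120 nt CDS, 54 nt 3'UTR
UTR5 = "GATTAC"
CDS_TWO_EXON = "ATG" + "CAA" * 38 + "TGA"
UTR3 = "ACT" * 18
MRNA_TWO_EXON = UTR5 + CDS_TWO_EXON + UTR3
assert len(MRNA_TWO_EXON) == 180


def build_two_exon(strand: str = "+") -> TranscriptModel:
    """Two-exon transcript with junction at mRNA offset 99, CDS in [6, 126)."""
    exon1, exon2 = MRNA_TWO_EXON[:100], MRNA_TWO_EXON[100:]
    chrom_seq = FLANK + exon1 + INTRON + exon2 + FLANK
    exons = [(10, 110), (160, 240)]
    cds_start, cds_end = 16, 186
    if strand == "-":
        L = len(chrom_seq)
        chrom_seq = revcomp(chrom_seq)
        exons = sorted((L - b, L - a) for a, b in exons)
        cds_start, cds_end = L - cds_end, L - cds_start
    tm = TranscriptModel(
        id="TWOEX",
        chrom="chrT",
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        seq=chrom_seq,
        span_start=0,
    )
    tm.validate(strict=True)
    return tm


def build_single_exon(cds: str, utr5: str = "AACCTT", utr3: str = "AGGAGG",
                      flank: str = "ACGTACGT") -> TranscriptModel:
    """Single-exon transcript around an explicit CDS string."""
    mrna = utr5 + cds + utr3
    chrom_seq = flank + mrna + flank
    tm = TranscriptModel(
        id="MONO",
        chrom="chrM1",
        strand="+",
        exons=[(len(flank), len(flank) + len(mrna))],
        cds_start=len(flank) + len(utr5),
        cds_end=len(flank) + len(utr5) + len(cds),
        seq=chrom_seq,
        span_start=0,
    )
    tm.validate(strict=True)
    return tm


@pytest.fixture
def two_exon_tm() -> TranscriptModel:
    return build_two_exon("+")


@pytest.fixture
def micro_tm() -> TranscriptModel:
    # ATG CAA CCC TGG TGA -> protein MQPW*
    return build_single_exon("ATGCAACCCTGGTGA")
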