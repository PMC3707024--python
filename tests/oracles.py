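"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the package's annotation code paths:
mutations are applied to the raw genomic sequence, transcripts are
respliced from scratch, and translation goes through Biopython's codon
tables.  Rate arithmetic is re-derived inline.
"""

import dataclasses

from Bio.Seq import Seq

from dntb.consequence import VariantCall
from dntb.gene_model import TranscriptModel

_TS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def bio_translate(seq: str) -> str:
    n = len(seq) - len(seq) % 3
    return str(Seq(seq[:n]).translate())


def splice(chrom_seq: str, exons, strand: str) -> str:
    s = "".join(chrom_seq[a:b] for a, b in exons)
    return s if strand == "+" else str(Seq(s).reverse_complement())


def mutate_snv_tm(tm: TranscriptModel, v: VariantCall) -> TranscriptModel:
    """New transcript whose genomic sequence carries the SNV."""
    i = v.pos - 1 - tm.span_start
    seq = tm.seq[:i] + v.alt + tm.seq[i + 1 :]
    new = dataclasses.replace(tm, seq=seq)
    return new


def snv_effect_oracle(tm: TranscriptModel, v: VariantCall) -> str:
    """Classify an SNV by full re-translation of the mutated CDS."""
    c0, c1 = tm.cds_mrna_interval
    mut = mutate_snv_tm(tm, v)
    ref_p = bio_translate(tm.mrna[c0:c1])
    alt_p = bio_translate(mut.mrna[c0:c1])
    if ref_p == alt_p:
        try:
            tm.genomic_to_cds(v.pos)
        except Exception:
            return "noncoding"
        return "synonymous"
    diff = [i for i, (a, b) in enumerate(zip(ref_p, alt_p)) if a != b]
    i = diff[0]
    if ref_p[i] == "*":
        return "synonymous" if alt_p[i] == "*" else "stop_loss"
    if alt_p[i] == "*":
        return "stop_gain"
    if i == 0 and alt_p[0] != "M":
        return "start_loss"
    return "missense"


def apply_indel_genomic(tm: TranscriptModel, v: VariantCall) -> TranscriptModel:
    """Edit the chromosome sequence and shift exon/CDS coordinates to match.

    Only supports anchored indels confined to a single exon, with the
    transcript span starting at genomic 0 (as the test fixtures do).
    """
    assert tm.span_start == 0
    pos0 = v.pos - 1
    net = len(v.alt) - len(v.ref)
    if net < 0:
        cut0, cut1 = pos0 + 1, pos0 + len(v.ref)
        seq = tm.seq[:cut0] + tm.seq[cut1:]
    else:
        seq = tm.seq[: pos0 + 1] + v.alt[1:] + tm.seq[pos0 + 1 :]
        cut0 = cut1 = pos0 + 1
    def shift(x: int) -> int:
        if x <= cut0:
            return x
        if net < 0:
            return max(cut0, x + net) if x <= cut1 else x + net
        return x + net
    exons = [(shift(a), shift(b)) for a, b in tm.exons]
    return TranscriptModel(
        id=tm.id, chrom=tm.chrom, strand=tm.strand, exons=exons,
        cds_start=shift(tm.cds_start), cds_end=shift(tm.cds_end),
        seq=seq, span_start=0,
    )


def fs_extension_oracle(tm: TranscriptModel, v: VariantCall):
    """(first_codon_1based, extension, found) by naive re-translation.

    Translates the whole mutated mRNA from the CDS start and counts
    shifted-frame codons before the first stop.
    """
    c0, _ = tm.cds_mrna_interval
    mut = apply_indel_genomic(tm, v)
    mut_tail = mut.mrna[c0:]
    ref_p = bio_translate(tm.cds_seq)
    mut_p = bio_translate(mut_tail)
    first = next(
        (i for i, (a, b) in enumerate(zip(ref_p, mut_p)) if a != b),
        min(len(ref_p), len(mut_p)),
    )
    stop = mut_p.find("*", first)
    if stop == -1:
        return first + 1, len(mut_p) - first, False
    return first + 1, stop - first, True


def nonsense_rate_oracle(tm: TranscriptModel, params) -> tuple[float, int]:
    """Enumerate all 3L substitutions, re-translate each, sum rates inline."""
    import math

    c0, c1 = tm.cds_mrna_interval
    cds = tm.mrna[c0:c1]
    ref_p = bio_translate(cds)
    rates, n_sites = [], 0
    for i in range(len(cds)):
        ref = cds[i]
        for alt in "ACGT":
            if alt == ref:
                continue
            mut_p = bio_translate(cds[:i] + alt + cds[i + 1 :])
            if "*" in mut_p[:-1] and "*" not in ref_p[:-1]:
                # genomic trinucleotide context, coding-strand oriented
                g0 = tm.cds_to_genomic(i) - 1
                tri = tm.base_at(g0 - 1) + tm.base_at(g0) + tm.base_at(g0 + 1)
                if tm.strand == "-":
                    tri = str(Seq(tri).reverse_complement())
                is_ts = (ref, alt) in _TS
                w = (params.kappa if is_ts else 1.0) / (params.kappa + 2.0)
                r = params.mu_sub * w
                if is_ts and (
                    (tri[1] == "C" and tri[2] == "G" and alt == "T")
                    or (tri[1] == "G" and tri[0] == "C" and alt == "A")
                ):
                    r *= params.cpg_multiplier
                rates.append(r)
                n_sites += 1
    return math.fsum(rates), n_sites


def binom_tail_oracle(n: int, p: float, k: int) -> float:
    """P(X >= k) by direct pmf summation with exact binomial coefficients."""
    import math

    return math.fsum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )
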