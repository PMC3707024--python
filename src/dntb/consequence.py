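"""Protein-level consequence annotation and NMD-escape classification.

Given a :class:`~dntb.gene_model.TranscriptModel` and a variant call, this
module determines the protein effect (stop-gain, frameshift with
stop-extension length, missense, synonymous, in-frame indel, start/stop
loss) and, whenever a premature termination codon (PTC) is created,
locates it relative to the last exon-exon junction and applies the
50-nucleotide rule for predicted nonsense-mediated decay (NMD):

* a PTC more than ``rule_threshold`` (default 50) nucleotides upstream of
  the last junction is predicted to trigger NMD (``nmd_predicted``);
* a PTC in the last exon, or within the threshold of the last junction,
  is predicted to escape (``nmd_escape``); single-exon transcripts always
  escape.

Frameshift extensions are reported in the style ``p.T659fsX41``: the
first changed residue, then the count of amino acids translated in the
shifted frame before the new stop codon (``X0`` means the very first
shifted codon is a stop).

Variant alleles are interpreted on the genomic plus strand (VCF
convention) and indels are left-aligned before annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .gene_model import (
    CODON_TABLE,
    STOP_CODONS,
    OutOfCdsError,
    TranscriptModel,
    revcomp,
    translate,
)

logger = logging.getLogger(__name__)

NMD_RULE_THRESHOLD = 50  # nucleotides upstream of the last junction


class ReferenceMismatchError(Exception):
    """The variant's REF allele disagrees with the transcript sequence."""


class UnsupportedVariantError(Exception):
    """Variant geometry the annotator refuses (e.g. spans a splice junction)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSupport:
    total_reads: int
    alt_reads: int
    quality_flag: bool = True
    ref_reads: Optional[int] = None


@dataclass(frozen=True)
class VariantCall:
    """One alternate allele at a genomic position, plus-strand alleles."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_support: dict[str, SampleSupport] = field(default_factory=dict)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if not self.ref or not self.alt:
            raise ValueError("empty allele; use anchored VCF-style alleles")

    @property
    def var_type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snv"
        if len(self.ref) < len(self.alt):
            return "ins"
        if len(self.ref) > len(self.alt):
            return "del"
        return "mnv"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PtcLocation:
    """Where a premature termination codon lands in the (mutated) mRNA."""

    mrna_offset: int  # first base of the termination codon
    exon_index: int  # 1-based, transcript order
    distance_to_last_junction: float  # positive = upstream of last junction


@dataclass
class Consequence:
    effect: str  # stop_gain | frameshift | missense | synonymous |
    #              inframe_indel | stop_loss | start_loss | noncoding
    protein_pos: Optional[int] = None  # 1-based codon of first affected residue
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    fs_extension_aa: Optional[int] = None
    new_stop_codon: Optional[str] = None
    hgvs_p: Optional[str] = None
    nmd_class: str = "not_applicable"
    ptc: Optional[PtcLocation] = None
    no_stop_found: bool = False
    region: Optional[str] = None  # for noncoding: 5'UTR/intron/3'UTR/intergenic


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_variant(tm: TranscriptModel, v: VariantCall) -> VariantCall:
    """Left-align and minimalize a variant against the transcript sequence.

    Uses the standard trim-right / extend-left / trim-left scheme, so
    equivalent indel representations collapse to one canonical form.
    """
    pos0, ref, alt = v.pos - 1, v.ref.upper(), v.alt.upper()
    while True:
        if len(ref) > 0 and len(alt) > 0 and ref[-1] == alt[-1] and (
            len(ref) > 1 or len(alt) > 1
        ):
            ref, alt = ref[:-1], alt[:-1]
            if ref and alt:
                continue
        if not ref or not alt:
            if pos0 <= tm.span_start:
                raise UnsupportedVariantError(
                    f"cannot left-align {v.chrom}:{v.pos} past the sequence span"
                )
            b = tm.base_at(pos0 - 1)
            ref, alt, pos0 = b + ref, b + alt, pos0 - 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos0 = ref[1:], alt[1:], pos0 + 1
    return VariantCall(v.chrom, pos0 + 1, ref, alt, v.sample_support)


def _check_ref(tm: TranscriptModel, v: VariantCall) -> None:
    g0 = v.pos - 1
    observed = "".join(tm.base_at(g0 + i) for i in range(len(v.ref)))
    if "N" not in observed and observed != v.ref.upper():
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos} REF {v.ref} does not match transcript "
            f"sequence {observed}"
        )


# ---------------------------------------------------------------------------
# NMD classification
# ---------------------------------------------------------------------------


def _classify_distance(distance: float, rule_threshold: float) -> str:
    return "nmd_escape" if distance <= rule_threshold else "nmd_predicted"


def classify_nmd(
    tm: TranscriptModel,
    ptc: PtcLocation,
    rule_threshold: int = NMD_RULE_THRESHOLD,
) -> str:
    """Apply the 50-nt boundary rule to a PTC on the reference exon layout."""
    junctions = tm.junction_positions()
    if not junctions:
        return "nmd_escape"
    return _classify_distance(junctions[-1] - ptc.mrna_offset, rule_threshold)


def _ptc_location(
    junctions: list[int], ptc_offset: int
) -> PtcLocation:
    exon_index = 1 + sum(1 for j in junctions if j < ptc_offset)
    distance = junctions[-1] - ptc_offset if junctions else float("-inf")
    return PtcLocation(ptc_offset, exon_index, distance)


# ---------------------------------------------------------------------------
# SNV annotation
# ---------------------------------------------------------------------------


def annotate_snv(
    tm: TranscriptModel,
    v: VariantCall,
    rule_threshold: int = NMD_RULE_THRESHOLD,
) -> Consequence:
    """Classify a single-nucleotide variant by translating the mutated codon."""
    if v.var_type != "snv":
        raise ValueError(f"annotate_snv got a {v.var_type}")
    _check_ref(tm, v)
    try:
        cp = tm.genomic_to_cds(v.pos)
    except OutOfCdsError as e:
        return Consequence(effect="noncoding", region=e.region)

    cds = tm.cds_seq
    ci = cp.codon_index - 1
    codon = cds[ci * 3 : ci * 3 + 3]
    alt_t = v.alt.upper() if tm.strand == "+" else revcomp(v.alt.upper())
    mut_codon = codon[: cp.codon_phase] + alt_t + codon[cp.codon_phase + 1 :]
    ref_aa = CODON_TABLE[codon]
    alt_aa = CODON_TABLE[mut_codon]

    cons = Consequence(
        effect="missense",
        protein_pos=cp.codon_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )
    if ref_aa == "*":
        # change inside the natural stop codon
        cons.effect = "synonymous" if alt_aa == "*" else "stop_loss"
    elif alt_aa == "*":
        cons.effect = "stop_gain"
        cons.new_stop_codon = mut_codon
        c0, _ = tm.cds_mrna_interval
        cons.ptc = _ptc_location(tm.junction_positions(), c0 + ci * 3)
        cons.nmd_class = _classify_distance(
            cons.ptc.distance_to_last_junction, rule_threshold
        )
    elif ci == 0 and alt_aa != "M":
        cons.effect = "start_loss"
    elif alt_aa == ref_aa:
        cons.effect = "synonymous"

    if cons.effect == "stop_gain":
        cons.hgvs_p = f"p.{ref_aa}{cp.codon_index}X"
    elif cons.effect == "synonymous":
        cons.hgvs_p = f"p.{ref_aa}{cp.codon_index}="
    else:
        cons.hgvs_p = f"p.{ref_aa}{cp.codon_index}{alt_aa}"
    return cons


# ---------------------------------------------------------------------------
# Indel annotation
# ---------------------------------------------------------------------------


def _edit_spliced(tm: TranscriptModel, v: VariantCall):
    """Locate an anchored pure indel in spliced coordinates.

    Returns ``(first_affected_mrna_offset, net, mutated_mrna)`` where
    ``net`` is the signed length change and offsets are in transcript
    orientation on the mutated mRNA.  Raises for junction-spanning indels.
    """
    pos0 = v.pos - 1
    s_plus = tm.pre_mrna_plus
    L = tm.mrna_length
    net = len(v.alt) - len(v.ref)

    def exon_of(g0: int) -> int | None:
        for i, (a, b) in enumerate(tm.exons):
            if a <= g0 < b:
                return i
        return None

    if net < 0:  # deletion of bases pos0+1 .. pos0+len(ref)-1
        dele = list(range(pos0 + 1, pos0 + len(v.ref)))
        ex = {exon_of(g) for g in dele}
        if ex == {None}:
            return None, net, None  # fully intronic/intergenic
        if None in ex or len(ex) > 1:
            raise UnsupportedVariantError(
                f"deletion at {v.chrom}:{v.pos} spans an exon-intron boundary"
            )
        d0 = tm._spliced_plus_offset(dele[0])
        dlen = len(dele)
        new_plus = s_plus[:d0] + s_plus[d0 + dlen :]
        e = d0 if tm.strand == "+" else L - (d0 + dlen)
    else:  # insertion of alt[1:] between pos0 and pos0+1
        ins = v.alt[1:].upper()
        left, right = exon_of(pos0), exon_of(pos0 + 1)
        if left is None and right is None:
            return None, net, None
        if left is None or right is None or left != right:
            raise UnsupportedVariantError(
                f"insertion at {v.chrom}:{v.pos} sits on an exon-intron boundary"
            )
        i0 = tm._spliced_plus_offset(pos0)
        new_plus = s_plus[: i0 + 1] + ins + s_plus[i0 + 1 :]
        e = i0 + 1 if tm.strand == "+" else L - 1 - i0
    mut_mrna = new_plus if tm.strand == "+" else revcomp(new_plus)
    return e, net, mut_mrna


def _shift_junctions(junctions: list[int], e: int, net: int) -> list[int]:
    """Junction offsets on the mutated mRNA after an edit at offset ``e``."""
    out = []
    for j in junctions:
        if net < 0 and e <= j < e - net:
            out.append(e - 1)  # junction fell inside the deleted run
        elif j >= e:
            out.append(j + net)
        else:
            out.append(j)
    return out


def annotate_indel(
    tm: TranscriptModel,
    v: VariantCall,
    rule_threshold: int = NMD_RULE_THRESHOLD,
) -> Consequence:
    """Classify an insertion or deletion, re-translating the shifted frame.

    Frameshifts scan the mutated mRNA from the first affected codon,
    through the 3' UTR if necessary, until a stop codon; if none exists
    before the transcript end the result is flagged ``no_stop_found``.
    """
    v = normalize_variant(tm, v)
    if v.var_type == "mnv":
        raise UnsupportedVariantError(
            f"{v.chrom}:{v.pos} {v.ref}>{v.alt} is a multi-nucleotide "
            "substitution; not supported"
        )
    if v.var_type == "snv":
        return annotate_snv(tm, v, rule_threshold)
    _check_ref(tm, v)

    e, net, mut_mrna = _edit_spliced(tm, v)
    if e is None:
        return Consequence(effect="noncoding", region="intron")

    c0, c1 = tm.cds_mrna_interval
    edit_end = e + (-net if net < 0 else 0)  # half-open affected ref interval
    if edit_end <= c0:
        return Consequence(effect="noncoding", region="5'UTR")
    if e >= c1:
        return Consequence(effect="noncoding", region="3'UTR")
    if net < 0 and e < c0:
        # deletion straddling the CDS start removes (part of) the start codon
        return Consequence(
            effect="start_loss", protein_pos=1, ref_aa="M", hgvs_p="p.M1?"
        )
    if net < 0 and net % 3 == 0 and edit_end > c1 - 3:
        # in-frame deletion eating into the natural stop codon
        ref_protein = translate(tm.cds_seq)
        return Consequence(
            effect="stop_loss", protein_pos=len(ref_protein),
            ref_aa="*", hgvs_p=f"p.*{len(ref_protein)}?",
        )

    ref_protein = translate(tm.cds_seq)
    first_cds = e - c0
    f = first_cds // 3
    if f >= len(ref_protein) - 1 and net % 3 != 0:
        # frame disruption beginning in the natural stop codon
        return Consequence(
            effect="stop_loss", protein_pos=len(ref_protein),
            ref_aa="*", hgvs_p=f"p.*{len(ref_protein)}?",
        )
    ref_aa = ref_protein[f] if f < len(ref_protein) else "*"
    junctions = _shift_junctions(tm.junction_positions(), e, net)

    if net % 3 != 0:
        # first *changed* residue: a shifted codon may coincidentally
        # reproduce the reference amino acid, so compare at protein level
        tail = mut_mrna[c0:]
        mt = translate(tail)
        first = next(
            (
                j
                for j in range(f, len(ref_protein))
                if j >= len(mt) or mt[j] != ref_protein[j]
            ),
            len(ref_protein) - 1,
        )
        ref_aa = ref_protein[first]
        cons = Consequence(
            effect="frameshift", protein_pos=first + 1, ref_aa=ref_aa
        )
        stop_at = mt.find("*", first)
        if stop_at == -1:
            cons.no_stop_found = True
            cons.fs_extension_aa = len(mt) - first
            cons.hgvs_p = f"p.{ref_aa}{first + 1}fs?"
            return cons
        cons.fs_extension_aa = stop_at - first
        cons.new_stop_codon = tail[3 * stop_at : 3 * stop_at + 3]
        cons.hgvs_p = f"p.{ref_aa}{first + 1}fsX{cons.fs_extension_aa}"
        cons.ptc = _ptc_location(junctions, c0 + 3 * stop_at)
        cons.nmd_class = _classify_distance(
            cons.ptc.distance_to_last_junction, rule_threshold
        )
        return cons

    # in-frame indel: frame preserved, but an inserted/juxtaposed stop is
    # still possible, in which case the PTC is classified for NMD
    cons = Consequence(
        effect="inframe_indel",
        protein_pos=f + 1,
        ref_aa=ref_aa,
        hgvs_p=f"p.{ref_aa}{f + 1}{'del' if net < 0 else 'ins'}",
    )
    mut_cds = mut_mrna[c0 : c1 + net]
    mut_protein = translate(mut_cds)
    if "*" in mut_protein[:-1]:
        j = mut_protein.index("*")
        cons.new_stop_codon = mut_cds[3 * j : 3 * j + 3]
        cons.ptc = _ptc_location(junctions, c0 + 3 * j)
        cons.nmd_class = _classify_distance(
            cons.ptc.distance_to_last_junction, rule_threshold
        )
    return cons


def annotate_variant(
    tm: TranscriptModel,
    v: VariantCall,
    rule_threshold: int = NMD_RULE_THRESHOLD,
) -> Consequence:
    """Dispatch to the SNV or indel annotator by variant geometry."""
    if v.var_type == "snv":
        # SNVs outside the span are noncoding by contract, so tolerate them
        if not (tm.span_start < v.pos <= tm.span_end):
            return Consequence(effect="noncoding", region="intergenic")
        return annotate_snv(tm, v, rule_threshold)
    return annotate_indel(tm, v, rule_threshold)


# ---------------------------------------------------------------------------
# Tabular / VCF output
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "effect", "hgvs_p",
    "fs_extension_aa", "new_stop_codon", "nmd_class",
]


def consequence_row(v: VariantCall, c: Consequence) -> dict:
    return {
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "effect": c.effect,
        "hgvs_p": c.hgvs_p or ".",
        "fs_extension_aa": "." if c.fs_extension_aa is None else c.fs_extension_aa,
        "new_stop_codon": c.new_stop_codon or ".",
        "nmd_class": c.nmd_class,
    }


def annotate_vcf(
    tm: TranscriptModel,
    vcf_path,
    out_tsv=None,
    out_vcf=None,
    rule_threshold: int = NMD_RULE_THRESHOLD,
):
    """Annotate every record of a VCF against one transcript.

    Writes a TSV of consequences and, optionally, a VCF with
    EFFECT/HGVSP/NMD INFO fields.  Returns the list of
    ``(VariantCall, Consequence)`` pairs in input order.
    """
    import pysam

    results = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        header = vf.header.copy()
        for tag, desc in [
            ("EFFECT", "Protein-level consequence"),
            ("HGVSP", "Protein change, p. notation"),
            ("NMD", "Predicted nonsense-mediated-decay class"),
        ]:
            header.info.add(tag, 1, "String", desc)
        out = pysam.VariantFile(str(out_vcf), "w", header=header) if out_vcf else None
        for rec in vf:
            for alt in rec.alts or ():
                v = VariantCall(rec.chrom, rec.pos, rec.ref, alt)
                try:
                    c = annotate_variant(tm, v, rule_threshold)
                except (ReferenceMismatchError, UnsupportedVariantError) as err:
                    logger.warning("skipping %s:%s: %s", rec.chrom, rec.pos, err)
                    continue
                results.append((v, c))
                if out is not None:
                    new = out.new_record(
                        contig=rec.chrom, start=rec.start, stop=rec.stop,
                        alleles=(rec.ref, alt), id=rec.id,
                    )
                    new.info["EFFECT"] = c.effect
                    new.info["HGVSP"] = c.hgvs_p or "."
                    new.info["NMD"] = c.nmd_class
                    out.write(new)
        if out is not None:
            out.close()
    if out_tsv is not None:
        import pandas as pd

        pd.DataFrame(
            [consequence_row(v, c) for v, c in results], columns=TSV_COLUMNS
        ).to_csv(out_tsv, sep="\t", index=False)
    return results
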