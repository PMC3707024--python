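"""Transcript models and strand-aware coordinate arithmetic.

A :class:`TranscriptModel` is the coordinate backbone of the whole
pipeline: it holds the exon structure, CDS bounds and genomic sequence of
a single protein-coding transcript and maps positions between four
coordinate systems:

* genomic (1-based for user-facing I/O, 0-based half-open internally),
* spliced mRNA (0-based offsets in transcript orientation),
* CDS (0-based offsets from the A of the start codon), and
* protein (1-based codon index plus codon phase).

Exactly one named transcript is modelled per run; there is no
canonical-transcript election logic.  GFF3 (with ID/Parent attributes) is
the canonical input format and BED12 is accepted as a fallback.
"""

from __future__ import annotations

import itertools
import logging
from functools import cached_property
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pyfaidx

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

# Standard genetic code, codons in TCAG-major lexicographic order.
_AA_BY_TCAG = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"  # CTT..CGG
    "IIIMTTTTNNKKSSRR"  # ATT..AGG
    "VVVVAAAADDEEGGGG"  # GTT..GGG
)
CODON_TABLE: dict[str, str] = {
    a + b + c: _AA_BY_TCAG[i]
    for i, (a, b, c) in enumerate(itertools.product("TCAG", repeat=3))
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate ``seq`` codon by codon; stops render as ``*``.

    Trailing bases that do not fill a codon are ignored.  Codons with
    ambiguous characters translate to ``X``.
    """
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aas.append(CODON_TABLE.get(seq[i : i + 3].upper(), "X"))
    return "".join(aas)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def cpg_density(seq: str) -> float:
    """Fraction of dinucleotide starts that are CpG (CG on the given strand)."""
    if len(seq) < 2:
        return 0.0
    return seq.upper().count("CG") / (len(seq) - 1)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class TranscriptError(Exception):
    """Base class for transcript-model errors."""


class TranscriptNotFoundError(TranscriptError):
    pass


class ValidationError(TranscriptError):
    pass


class FormatError(TranscriptError):
    pass


class OutOfCdsError(TranscriptError):
    """A genomic position mapped outside the CDS.

    ``region`` is one of ``5'UTR``, ``intron``, ``3'UTR`` or ``intergenic``.
    """

    def __init__(self, message: str, region: str):
        super().__init__(message)
        self.region = region


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CdsPosition:
    """A coding position expressed in all transcript-internal systems."""

    mrna_offset: int  # 0-based offset in the spliced mRNA
    cds_offset: int  # 0-based offset in the CDS
    codon_index: int  # 1-based codon number
    codon_phase: int  # 0, 1 or 2 within the codon

    def __post_init__(self):
        if self.codon_index != self.cds_offset // 3 + 1:
            raise ValueError("codon_index inconsistent with cds_offset")
        if self.codon_phase != self.cds_offset % 3:
            raise ValueError("codon_phase inconsistent with cds_offset")


@dataclass
class TranscriptModel:
    """One protein-coding transcript with its genomic sequence.

    ``exons`` are 0-based half-open genomic intervals sorted by genomic
    start; ``cds_start``/``cds_end`` bound the coding region in genomic
    coordinates (half-open, strand-independent).  ``seq`` is the plus-strand
    genomic sequence of ``[span_start, span_end)`` where ``span_start`` is
    the start of the first exon (optionally padded with extra flank).
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    seq: str
    span_start: int

    _cum: list[int] = field(init=False, repr=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValidationError(f"empty exon ({a},{b}) in {self.id}")
        for (_, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValidationError(f"overlapping exons in {self.id}")
        self.seq = self.seq.upper()
        if self.exons[-1][1] - self.span_start > len(self.seq):
            raise FormatError(
                f"sequence for {self.id} shorter than its exon span"
            )
        # cumulative spliced length before each exon, genomic order
        self._cum = [0]
        for a, b in self.exons:
            self._cum.append(self._cum[-1] + (b - a))

    # -- basic structure ---------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @cached_property
    def mrna_length(self) -> int:
        return self._cum[-1]

    @property
    def span_end(self) -> int:
        return self.span_start + len(self.seq)

    def base_at(self, g0: int) -> str:
        """Plus-strand base at 0-based genomic position ``g0``; 'N' outside span."""
        i = g0 - self.span_start
        if 0 <= i < len(self.seq):
            return self.seq[i]
        return "N"

    # -- spliced sequence --------------------------------------------------

    @cached_property
    def pre_mrna_plus(self) -> str:
        """Exonic sequence spliced in genomic (plus-strand) order."""
        return "".join(
            self.seq[a - self.span_start : b - self.span_start]
            for a, b in self.exons
        )

    @cached_property
    def mrna(self) -> str:
        """Spliced mRNA in transcript orientation."""
        s = self.pre_mrna_plus
        return s if self.strand == "+" else revcomp(s)

    @cached_property
    def cds_mrna_interval(self) -> tuple[int, int]:
        """Half-open mRNA-offset interval covered by the CDS."""
        a = b = None
        for (ea, eb), cum in zip(self.exons, self._cum):
            lo, hi = max(ea, self.cds_start), min(eb, self.cds_end)
            if lo < hi:
                if a is None:
                    a = cum + (lo - ea)
                b = cum + (hi - ea)
        if a is None:
            raise ValidationError(f"CDS of {self.id} overlaps no exon")
        if self.strand == "+":
            return a, b
        L = self.mrna_length
        return L - b, L - a

    @cached_property
    def cds_seq(self) -> str:
        c0, c1 = self.cds_mrna_interval
        return self.mrna[c0:c1]

    @property
    def cds_length(self) -> int:
        c0, c1 = self.cds_mrna_interval
        return c1 - c0

    # -- coordinate mapping ------------------------------------------------

    def _spliced_plus_offset(self, g0: int) -> int:
        """Offset of genomic position ``g0`` in the plus-strand spliced seq."""
        for (a, b), cum in zip(self.exons, self._cum):
            if a <= g0 < b:
                return cum + (g0 - a)
        if self.exons[0][0] <= g0 < self.exons[-1][1]:
            raise OutOfCdsError(f"position {g0 + 1} is intronic", "intron")
        raise OutOfCdsError(f"position {g0 + 1} is outside {self.id}", "intergenic")

    def mrna_offset(self, gpos: int) -> int:
        """Transcript-orientation mRNA offset of 1-based genomic ``gpos``."""
        s = self._spliced_plus_offset(gpos - 1)
        return s if self.strand == "+" else self.mrna_length - 1 - s

    def genomic_to_cds(self, gpos: int) -> CdsPosition:
        """Map a 1-based genomic position to CDS coordinates.

        Raises :class:`OutOfCdsError` carrying the region label (5'UTR,
        intron, 3'UTR, intergenic) for non-coding positions.
        """
        m = self.mrna_offset(gpos)  # raises for intron/intergenic
        c0, c1 = self.cds_mrna_interval
        if m < c0:
            raise OutOfCdsError(f"position {gpos} is 5' of the CDS", "5'UTR")
        if m >= c1:
            raise OutOfCdsError(f"position {gpos} is 3' of the CDS", "3'UTR")
        cds = m - c0
        return CdsPosition(m, cds, cds // 3 + 1, cds % 3)

    def cds_to_genomic(self, cds_offset: int) -> int:
        """1-based genomic position of a 0-based CDS offset."""
        c0, c1 = self.cds_mrna_interval
        if not 0 <= cds_offset < c1 - c0:
            raise ValueError(f"CDS offset {cds_offset} out of range")
        m = c0 + cds_offset
        s = m if self.strand == "+" else self.mrna_length - 1 - m
        for (a, b), cum in zip(self.exons, self._cum):
            if cum <= s < cum + (b - a):
                return a + (s - cum) + 1
        raise AssertionError("unreachable: spliced offset outside exons")

    def exon_index_of_mrna_offset(self, m: int) -> int:
        """1-based exon number (transcript order) containing mRNA offset ``m``."""
        if not 0 <= m < self.mrna_length:
            raise ValueError(f"mRNA offset {m} out of range")
        return 1 + sum(1 for j in self.junction_positions() if j < m)

    def junction_positions(self) -> list[int]:
        """0-based mRNA offsets of the last base of each non-terminal exon."""
        lengths = [b - a for a, b in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        out, cum = [], 0
        for ln in lengths[:-1]:
            cum += ln
            out.append(cum - 1)
        return out

    # -- validation --------------------------------------------------------

    def validate(self, strict: bool = True) -> list[str]:
        """Check CDS invariants; raise in strict mode, warn otherwise.

        Returns the list of problems found (empty when clean).
        """
        problems = []
        cds = self.cds_seq
        if len(cds) % 3 != 0:
            problems.append(f"CDS length {len(cds)} is not a multiple of 3")
        if len(cds) < 6:
            problems.append(f"CDS length {len(cds)} is implausibly short")
        else:
            if cds[:3] != START_CODON:
                problems.append(f"CDS does not begin with ATG (saw {cds[:3]})")
            if len(cds) % 3 == 0 and cds[-3:] not in STOP_CODONS:
                problems.append(f"CDS does not end with a stop (saw {cds[-3:]})")
        if len(cds) % 3 == 0:
            internal = translate(cds)[:-1]
            if "*" in internal:
                problems.append(
                    f"internal stop codon at codon {internal.index('*') + 1}"
                )
        if problems:
            msg = f"transcript {self.id}: " + "; ".join(problems)
            if strict:
                raise ValidationError(msg)
            logger.warning(msg)
        return problems


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def _fetch_span(fasta_path, chrom: str, start0: int, end0: int) -> str:
    fa = pyfaidx.Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    try:
        if chrom not in fa:
            raise FormatError(f"chromosome {chrom!r} missing from FASTA")
        if end0 > len(fa[chrom]):
            raise FormatError(
                f"FASTA sequence for {chrom} ends at {len(fa[chrom])}, "
                f"transcript span needs {end0}"
            )
        return str(fa[chrom][start0:end0])
    finally:
        fa.close()


def load_transcript(
    gff_path,
    fasta_path,
    transcript_id: str,
    strict: bool = True,
    flank: int = 0,
) -> TranscriptModel:
    """Load one transcript from GFF3 + FASTA and validate it.

    The GFF3 must carry ``exon`` and ``CDS`` features whose ``Parent``
    attribute is ``transcript_id``.  ``flank`` extra plus-strand bases are
    kept on either side of the exon span when available (used for
    trinucleotide mutation contexts at transcript edges).
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    exons, cds_iv = [], []
    chrom = strand = None
    for feat in db.all_features():
        if transcript_id not in feat.attributes.get("Parent", []):
            continue
        if feat.featuretype == "exon":
            exons.append((feat.start - 1, feat.end))
        elif feat.featuretype == "CDS":
            cds_iv.append((feat.start - 1, feat.end))
        else:
            continue
        chrom, strand = feat.seqid, feat.strand
    if not exons:
        raise TranscriptNotFoundError(
            f"transcript {transcript_id!r} not found in {gff_path}"
        )
    if not cds_iv:
        raise FormatError(f"transcript {transcript_id!r} has no CDS features")
    cds_start = min(a for a, _ in cds_iv)
    cds_end = max(b for _, b in cds_iv)
    span_start = max(0, min(a for a, _ in exons) - flank)
    span_end = max(b for _, b in exons) + flank
    seq = _fetch_span(fasta_path, chrom, span_start, span_end)
    tm = TranscriptModel(
        id=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        seq=seq,
        span_start=span_start,
    )
    tm.validate(strict=strict)
    return tm


def load_transcript_bed(
    bed_path, fasta_path, name: str, strict: bool = True, flank: int = 0
) -> TranscriptModel:
    """BED12 fallback loader: blocks are exons, thickStart/End bound the CDS."""
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise FormatError(f"{bed_path}: BED12 requires 12 columns, got {len(f)}")
        if f[3] != name:
            continue
        chrom, start = f[0], int(f[1])
        strand = f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
            raise FormatError(f"{bed_path}: blockCount mismatch for {name}")
        exons = [(start + s, start + s + ln) for s, ln in zip(starts, sizes)]
        span_start = max(0, exons[0][0] - flank)
        seq = _fetch_span(fasta_path, chrom, span_start, exons[-1][1] + flank)
        tm = TranscriptModel(
            id=name,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start=thick_start,
            cds_end=thick_end,
            seq=seq,
            span_start=span_start,
        )
        tm.validate(strict=strict)
        return tm
    raise TranscriptNotFoundError(f"record {name!r} not found in {bed_path}")
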