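"""Per-gene, per-generation probabilities of de novo truncating events.

The model treats each generation as spraying point mutations and small
indels over the genome at low, context-dependent rates, and asks how much
of that rate lands on substitutions that create a stop codon in a given
CDS (nonsense) or on frameshifting coding indels (truncating indels).

Substitution rates are per-site trinucleotide-context rates: a
genome-average per-base rate ``mu_sub`` is split across the three
alternate bases with transitions up-weighted by the transition/
transversion ratio ``kappa``, and transitions at CpG dinucleotides —
the one sequence context with a well-established elevated de novo rate —
are multiplied by ``cpg_multiplier``.  Gene size and base composition
therefore enter through the explicit enumeration of every
(position, alternate) pair in the CDS rather than through a single
gene-wide GC scalar; an optional gene-level GC adjustment hook is
provided but off by default.

The truncating-indel probability is a simple length model:
``cds_length x mu_indel_coding x P(frameshift | indel) x
P(truncating | frameshift)``.

All rate parameters ship as an editable TSV
(:func:`default_rate_params` / ``data/default_rates.tsv``) and every
number can be overridden; the calibration is treated as data, not code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from importlib import resources

from .gene_model import STOP_CODONS, TranscriptModel, gc_fraction, revcomp

logger = logging.getLogger(__name__)

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

#: Haploid human genome / coding-exome sizes used for scale sanity checks.
HAPLOID_GENOME_BASES = 3.1e9
HAPLOID_CODING_BASES = 3.2e7


class AmbiguousContextError(Exception):
    """A mutation-rate context contained a non-ACGT center base."""


@dataclass(frozen=True)
class RateParams:
    """Mutation-rate parameterization (per generation).

    mu_sub: genome-average per-base substitution probability.
    kappa: transition/transversion *rate* ratio (per-site weights).
    cpg_multiplier: extra factor on transitions at CpG dinucleotides.
    mu_indel_coding: per-coding-base small-indel probability.
    p_frameshift_given_indel: fraction of coding indels whose length is
        not a multiple of 3 (2/3 under a length-agnostic prior).
    p_truncating_given_frameshift: fraction of frameshifts assumed to
        truncate the protein.
    gc_scaling: optional gene-wide GC adjustment; the nonsense rate is
        multiplied by ``1 + gc_scaling * (gene_GC - 0.41)``.  Default 0
        (off); CpG context handling is the primary composition term.
    """

    mu_sub: float = 1.2e-8
    kappa: float = 2.0
    cpg_multiplier: float = 10.0
    mu_indel_coding: float = 1.0e-9
    p_frameshift_given_indel: float = 2.0 / 3.0
    p_truncating_given_frameshift: float = 1.0
    gc_scaling: float = 0.0

    def __post_init__(self):
        if self.mu_sub < 0 or self.mu_indel_coding < 0:
            raise ValueError("rates must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")
        for name in ("p_frameshift_given_indel", "p_truncating_given_frameshift"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def default_rate_params() -> RateParams:
    """Shipped default human parameters (see ``data/default_rates.tsv``)."""
    path = resources.files("dntb").joinpath("data/default_rates.tsv")
    with resources.as_file(path) as p:
        return load_rate_params(p)


def load_rate_params(tsv_path) -> RateParams:
    """Read a ``term<TAB>value[<TAB>note]`` table into :class:`RateParams`."""
    fields = {f for f in RateParams.__dataclass_fields__}
    values = {}
    with open(tsv_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "term":
                continue
            if len(parts) < 2:
                raise ValueError(f"{tsv_path}:{ln}: expected term<TAB>value")
            term, value = parts[0].strip(), parts[1].strip()
            if term not in fields:
                logger.warning("%s:%d: unknown rate term %r ignored", tsv_path, ln, term)
                continue
            values[term] = float(value)
    return RateParams(**values)


def save_rate_params(params: RateParams, tsv_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("term\tvalue\n")
        for name in RateParams.__dataclass_fields__:
            fh.write(f"{name}\t{getattr(params, name)!r}\n")


# ---------------------------------------------------------------------------
# Site rates
# ---------------------------------------------------------------------------


def is_cpg_transition(context: str, alt: str) -> bool:
    """True for C>T with a 3' G, or G>A with a 5' C (the reverse-strand read)."""
    prev, center, nxt = context[0], context[1], context[2]
    return (center == "C" and nxt == "G" and alt == "T") or (
        center == "G" and prev == "C" and alt == "A"
    )


def site_rate(context: str, alt: str, params: RateParams) -> float:
    """Per-generation probability of the specific change ``center>alt``.

    ``context`` is the trinucleotide centered on the mutated base, read on
    the coding strand.  The three alternates at a site share ``mu_sub``
    with weights kappa (transition) : 1 : 1 (transversions), i.e. a
    transition gets ``mu_sub * kappa / (kappa + 2)``; a CpG transition is
    further multiplied by ``cpg_multiplier``.  Unknown flanking bases
    ('N') are treated as non-CpG.
    """
    if len(context) != 3:
        raise ValueError("context must be a trinucleotide")
    center = context[1].upper()
    alt = alt.upper()
    if center not in "ACGT":
        raise AmbiguousContextError(f"ambiguous center base in context {context!r}")
    if alt not in "ACGT" or alt == center:
        raise ValueError(f"invalid alternate {alt!r} for center {center!r}")
    is_ts = (center, alt) in TRANSITIONS
    rate = params.mu_sub * (params.kappa if is_ts else 1.0) / (params.kappa + 2.0)
    if is_ts and is_cpg_transition(context.upper(), alt):
        rate *= params.cpg_multiplier
    return rate


# ---------------------------------------------------------------------------
# Gene-level enumeration
# ---------------------------------------------------------------------------


def cds_context(tm: TranscriptModel, cds_offset: int) -> str:
    """Genomic trinucleotide context of a CDS base, coding-strand oriented.

    The flanks come from the genomic sequence (CpG methylation acts on
    DNA, so the genomic neighbour — possibly intronic — is the relevant
    one, not the spliced neighbour).
    """
    g0 = tm.cds_to_genomic(cds_offset) - 1
    tri = tm.base_at(g0 - 1) + tm.base_at(g0) + tm.base_at(g0 + 1)
    return tri if tm.strand == "+" else revcomp(tri)


def nonsense_sites(tm: TranscriptModel):
    """All (cds_offset, alt, context) triples whose substitution creates a PTC.

    Alternate bases are in coding-strand orientation.  The natural stop
    codon and codons that are already stops are excluded.
    """
    cds = tm.cds_seq
    sites = []
    for ci in range(len(cds) // 3):
        codon = cds[3 * ci : 3 * ci + 3]
        if codon in STOP_CODONS:
            continue  # natural stop (validated CDS has no internal stops)
        for phase in range(3):
            ref = codon[phase]
            for alt in "ACGT":
                if alt == ref:
                    continue
                mut = codon[:phase] + alt + codon[phase + 1 :]
                if mut in STOP_CODONS:
                    off = 3 * ci + phase
                    sites.append((off, alt, cds_context(tm, off)))
    return sites


@dataclass(frozen=True)
class TruncationProbability:
    """Per-generation de novo truncation probabilities for one gene."""

    gene: str
    p_nonsense: float
    p_indel_trunc: float
    n_nonsense_sites: int
    cds_length: int

    @property
    def p_trunc(self) -> float:
        return self.p_nonsense + self.p_indel_trunc


def p_nonsense(tm: TranscriptModel, params: RateParams) -> TruncationProbability:
    """Sum site rates over every stop-creating substitution in the CDS."""
    sites = nonsense_sites(tm)
    total = math.fsum(site_rate(ctx, alt, params) for _, alt, ctx in sites)
    if params.gc_scaling:
        total *= 1.0 + params.gc_scaling * (gc_fraction(tm.cds_seq) - 0.41)
    return TruncationProbability(
        gene=tm.id,
        p_nonsense=total,
        p_indel_trunc=0.0,
        n_nonsense_sites=len(sites),
        cds_length=tm.cds_length,
    )


def p_indel_trunc(tm: TranscriptModel, params: RateParams) -> TruncationProbability:
    """Length model for de novo truncating coding indels."""
    p = (
        tm.cds_length
        * params.mu_indel_coding
        * params.p_frameshift_given_indel
        * params.p_truncating_given_frameshift
    )
    return TruncationProbability(
        gene=tm.id,
        p_nonsense=0.0,
        p_indel_trunc=p,
        n_nonsense_sites=0,
        cds_length=tm.cds_length,
    )


def gene_truncation_probability(
    tm: TranscriptModel, params: RateParams | None = None
) -> TruncationProbability:
    """Combined nonsense + truncating-indel probability for one gene."""
    params = params or default_rate_params()
    a = p_nonsense(tm, params)
    b = p_indel_trunc(tm, params)
    return replace(a, p_indel_trunc=b.p_indel_trunc)


# ---------------------------------------------------------------------------
# Genome-scale sanity quantities
# ---------------------------------------------------------------------------


def expected_genomewide_denovo_snvs(params: RateParams) -> float:
    """Expected de novo point mutations per diploid genome per generation."""
    return params.mu_sub * 2 * HAPLOID_GENOME_BASES


def expected_coding_denovo_snvs(params: RateParams) -> float:
    """Expected de novo coding point mutations per diploid exome per generation."""
    return params.mu_sub * 2 * HAPLOID_CODING_BASES
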