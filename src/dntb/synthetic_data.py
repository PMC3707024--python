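"""Seeded generators for every input the pipeline consumes.

Three generators, all pure functions of (spec, seed):

* :func:`make_gene` — a protein-coding transcript with a chosen exon
  structure and controlled GC / CpG composition, written as GFF3+FASTA;
* :func:`make_family` — a trio/quartet call set with planted inherited
  and de novo variants and simulated read support, written as a
  multi-sample VCF + PED, always accompanied by a truth table;
* :func:`make_truncating_set` — nonsense SNVs placed along the gene with
  a controllable density multiplier inside the NMD-escape region.

Read support uses a deliberately simple scheme — depth drawn from a
negative binomial, alternate reads binomial in the depth — which is
enough to exercise the allele-balance filters without claiming
read-level realism.  Genotyping error in parents is modelled as allele
dropout: with probability ``error_rate`` the carrier parent's genotype
is missed, which is exactly the event that manufactures a false de novo
candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .burden_stats import escape_region_fraction
from .consequence import NMD_RULE_THRESHOLD, SampleSupport, VariantCall
from .gene_model import (
    CODON_TABLE,
    STOP_CODONS,
    TranscriptModel,
    cpg_density,
    gc_fraction,
    revcomp,
)
from .trio_denovo import FamilyCallSet

logger = logging.getLogger(__name__)

SENSE_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
_GC_COUNT = {c: c.count("G") + c.count("C") for c in CODON_TABLE}


class SpecError(Exception):
    """A generator spec that cannot be realized."""


# ---------------------------------------------------------------------------
# Gene generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpec:
    """Blueprint for one synthetic protein-coding gene.

    ``exon_lengths`` is either an explicit per-exon list or a
    ``(min, max)`` range sampled per exon.  GC is controlled on the CDS
    (realized within +/-0.03 of ``gc_target`` or the spec fails); UTRs,
    introns and flanks draw bases i.i.d. at ``gc_target``.
    """

    n_exons: int = 12
    exon_lengths: tuple = (120, 700)
    gc_target: float = 0.45
    cpg_density_target: Optional[float] = None
    seed: int = 0
    strand: str = "+"
    utr5: int = 60
    utr3: int = 120
    intron_lengths: tuple[int, int] = (80, 400)
    flank: int = 30

    def __post_init__(self):
        if self.n_exons < 1:
            raise SpecError("need at least one exon")
        if not 0.0 < self.gc_target < 1.0:
            raise SpecError("gc_target must be in (0, 1)")
        if self.strand not in "+-":
            raise SpecError("strand must be + or -")


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)])


def _solve_codon_weights(gc_target: float) -> np.ndarray:
    """Boltzmann weights over sense codons whose mean GC hits the target."""
    gcs = np.array([_GC_COUNT[c] for c in SENSE_CODONS], dtype=float)
    lo, hi = -8.0, 8.0
    for _ in range(60):
        beta = (lo + hi) / 2
        w = np.exp(beta * gcs)
        mean = (w * gcs).sum() / w.sum() / 3.0
        if mean < gc_target:
            lo = beta
        else:
            hi = beta
    w = np.exp(((lo + hi) / 2) * gcs)
    return w / w.sum()


def _compose_cds(rng, n_codons: int, gc_target: float,
                 cpg_target: Optional[float]) -> str:
    """Sample sense codons, then locally refine toward GC/CpG targets."""
    if n_codons < 3:
        raise SpecError("CDS must have at least 3 codons (start, body, stop)")
    weights = _solve_codon_weights(gc_target)
    interior = list(
        np.array(SENSE_CODONS)[rng.choice(len(SENSE_CODONS), size=n_codons - 2,
                                          p=weights)]
    )
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    codons = ["ATG"] + interior + [stop]

    def cds_of(cs):
        return "".join(cs)

    def cost(cs):
        s = cds_of(cs)
        c = abs(gc_fraction(s) - gc_target)
        if cpg_target is not None:
            c += abs(cpg_density(s) - cpg_target)
        return c

    current = cost(codons)
    max_iter = 40 * n_codons
    for _ in range(max_iter):
        if current < 1e-4:
            break
        i = int(rng.integers(1, n_codons - 1))
        old = codons[i]
        codons[i] = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        new = cost(codons)
        if new < current:
            current = new
        else:
            codons[i] = old
    return cds_of(codons)


def make_gene(
    spec: GeneSpec,
    out_dir=None,
    chrom: str = "chrS",
    transcript_id: Optional[str] = None,
) -> TranscriptModel:
    """Generate a valid transcript; optionally write GFF3+FASTA files.

    The result loads cleanly through :func:`dntb.gene_model.load_transcript`
    and is bit-reproducible for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    tid = transcript_id or f"TX{spec.seed}"

    if isinstance(spec.exon_lengths, (list,)) or (
        isinstance(spec.exon_lengths, tuple) and len(spec.exon_lengths) != 2
    ):
        exon_lengths = [int(x) for x in spec.exon_lengths]
        if len(exon_lengths) != spec.n_exons:
            raise SpecError("exon_lengths list must match n_exons")
    elif isinstance(spec.exon_lengths, tuple):
        lo, hi = spec.exon_lengths
        exon_lengths = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_exons)]
    else:
        raise SpecError("exon_lengths must be a list or a (min, max) range")

    total = sum(exon_lengths)
    utr5, utr3 = spec.utr5, spec.utr3
    cds_len = total - utr5 - utr3
    utr3 += cds_len % 3
    cds_len -= cds_len % 3
    if cds_len < 9:
        raise SpecError(
            f"exon lengths leave only {cds_len} CDS bases after UTRs"
        )
    cds = _compose_cds(rng, cds_len // 3, spec.gc_target,
                       spec.cpg_density_target)
    realized_gc = gc_fraction(cds)
    realized_cpg = cpg_density(cds)
    if abs(realized_gc - spec.gc_target) > 0.03:
        raise SpecError(
            f"could not reach GC target {spec.gc_target:.3f} "
            f"(realized {realized_gc:.3f})"
        )
    if (
        spec.cpg_density_target is not None
        and abs(realized_cpg - spec.cpg_density_target) > 0.01
    ):
        raise SpecError(
            f"could not reach CpG density target {spec.cpg_density_target:.4f} "
            f"(realized {realized_cpg:.4f})"
        )
    logger.info(
        "gene %s: CDS %d nt, realized GC %.3f, CpG density %.4f",
        tid, cds_len, realized_gc, realized_cpg,
    )

    mrna = _random_seq(rng, utr5, spec.gc_target) + cds + _random_seq(
        rng, utr3, spec.gc_target
    )
    introns = [
        _random_seq(rng, int(rng.integers(*spec.intron_lengths)), spec.gc_target)
        for _ in range(spec.n_exons - 1)
    ]
    flank5 = _random_seq(rng, spec.flank, spec.gc_target)
    flank3 = _random_seq(rng, spec.flank, spec.gc_target)

    # assemble on the plus strand in transcript orientation first
    chrom_seq = flank5
    exons: list[tuple[int, int]] = []
    mrna_to_genomic: list[int] = []  # genomic start of each exon's mRNA slice
    cursor = 0
    for i, ln in enumerate(exon_lengths):
        start = len(chrom_seq)
        chrom_seq += mrna[cursor : cursor + ln]
        exons.append((start, start + ln))
        mrna_to_genomic.append(start - cursor)
        cursor += ln
        if i < spec.n_exons - 1:
            chrom_seq += introns[i]
    chrom_seq += flank3

    def genomic_of(m: int) -> int:
        run = 0
        for (a, b), off in zip(exons, mrna_to_genomic):
            ln = b - a
            if m < run + ln:
                return off + m
            run += ln
        raise AssertionError("mRNA offset outside exons")

    cds_start = genomic_of(utr5)
    cds_end = genomic_of(utr5 + cds_len - 1) + 1

    if spec.strand == "-":
        L = len(chrom_seq)
        chrom_seq = revcomp(chrom_seq)
        exons = sorted((L - b, L - a) for a, b in exons)
        cds_start, cds_end = L - cds_end, L - cds_start

    tm = TranscriptModel(
        id=tid,
        chrom=chrom,
        strand=spec.strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
        seq=chrom_seq,
        span_start=0,
    )
    tm.validate(strict=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta({chrom: chrom_seq}, out_dir / f"{tid}.fa")
        write_gff3(tm, out_dir / f"{tid}.gff3")
    return tm


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_gff3(tm: TranscriptModel, path) -> None:
    """Emit gene/mRNA/exon/CDS features with ID/Parent attributes."""
    gene_id = f"{tm.id}.gene"
    start = tm.exons[0][0] + 1
    end = tm.exons[-1][1]
    lines = [
        "##gff-version 3",
        f"{tm.chrom}\tdntb\tgene\t{start}\t{end}\t.\t{tm.strand}\t.\tID={gene_id}",
        f"{tm.chrom}\tdntb\tmRNA\t{start}\t{end}\t.\t{tm.strand}\t.\t"
        f"ID={tm.id};Parent={gene_id}",
    ]
    for a, b in tm.exons:
        lines.append(
            f"{tm.chrom}\tdntb\texon\t{a + 1}\t{b}\t.\t{tm.strand}\t.\tParent={tm.id}"
        )
    # CDS chunks with correct phase, emitted in genomic order
    chunks = []
    for a, b in tm.exons:
        lo, hi = max(a, tm.cds_start), min(b, tm.cds_end)
        if lo < hi:
            chunks.append((lo, hi))
    order = chunks if tm.strand == "+" else chunks[::-1]
    cum = 0
    phases = {}
    for lo, hi in order:
        phases[(lo, hi)] = (3 - cum % 3) % 3
        cum += hi - lo
    for lo, hi in chunks:
        lines.append(
            f"{tm.chrom}\tdntb\tCDS\t{lo + 1}\t{hi}\t.\t{tm.strand}\t"
            f"{phases[(lo, hi)]}\tParent={tm.id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Family call sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrioSpec:
    """Blueprint for one simulated family call set.

    ``af_mean`` is the true heterozygous allele fraction used for
    alternate-read draws (binomial in the sampled depth).  ``error_rate``
    is per planted inherited site: the probability that the carrier
    parent's genotype is dropped, converting the site into a false de
    novo candidate.
    """

    n_inherited_het: int = 40
    n_denovo: int = 2
    af_mean: float = 0.5
    depth_mean: float = 40.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.0
    include_sibling: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.error_rate <= 1:
            raise SpecError("error_rate must be in [0, 1]")
        if not 0 < self.af_mean < 1:
            raise SpecError("af_mean must be in (0, 1)")


SAMPLES = {"proband": "PROBAND", "father": "FATHER", "mother": "MOTHER",
           "sibling": "SIBLING"}


def _draw_depth(rng, spec: TrioSpec) -> int:
    r = spec.depth_dispersion
    p = r / (r + spec.depth_mean)
    return int(rng.negative_binomial(r, p))


def make_family(
    spec: TrioSpec, tm: TranscriptModel, out_dir=None
):
    """Plant inherited and de novo variants over a transcript's span.

    Returns ``(FamilyCallSet, truth)`` where ``truth`` is a DataFrame
    listing every planted variant with its class, carrier parent,
    dropout flag and the proband's realized read support.  With
    ``out_dir`` set, also writes ``family.vcf``, ``family.ped`` and
    ``truth.tsv``.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    roles = {k: v for k, v in SAMPLES.items()
             if k != "sibling" or spec.include_sibling}
    samples = list(roles.values())

    n_total = spec.n_inherited_het + spec.n_denovo
    lo = tm.span_start + 2
    hi = tm.span_end - 2
    if hi - lo < 4 * n_total:
        raise SpecError("transcript span too small for the requested variant count")
    positions: list[int] = []
    taken: set[int] = set()
    while len(positions) < n_total:
        g = int(rng.integers(lo, hi))
        if g in taken or tm.base_at(g) not in "ACGT":
            continue  # collision or ambiguous base: resample
        taken.add(g)
        positions.append(g)

    records = []  # (VariantCall, carriers, truth row)
    truth_rows = []
    bases = "ACGT"
    for i, g0 in enumerate(positions):
        ref = tm.base_at(g0)
        alt = bases[rng.integers(4)]
        while alt == ref:
            alt = bases[rng.integers(4)]
        is_denovo = i >= spec.n_inherited_het
        carriers = [roles["proband"]]
        carrier_parent, dropout = ".", False
        if not is_denovo:
            carrier_parent = roles["father" if rng.random() < 0.5 else "mother"]
            dropout = rng.random() < spec.error_rate
            if not dropout:
                carriers.append(carrier_parent)
            if spec.include_sibling and rng.random() < 0.5:
                carriers.append(roles["sibling"])
        support = {}
        for s in samples:
            depth = _draw_depth(rng, spec)
            alt_reads = (
                int(rng.binomial(depth, spec.af_mean)) if s in carriers else 0
            )
            support[s] = SampleSupport(
                total_reads=depth, alt_reads=alt_reads, quality_flag=True,
                ref_reads=depth - alt_reads,
            )
        v = VariantCall(tm.chrom, g0 + 1, ref, alt, support)
        records.append((v, carriers))
        truth_rows.append(
            {
                "chrom": tm.chrom, "pos": g0 + 1, "ref": ref, "alt": alt,
                "class": "denovo" if is_denovo else "inherited",
                "carrier_parent": carrier_parent,
                "parent_dropout": dropout,
                "proband_alt_reads": support[roles["proband"]].alt_reads,
                "proband_depth": support[roles["proband"]].total_reads,
            }
        )

    records.sort(key=lambda rc: rc[0].pos)
    order = sorted(range(len(truth_rows)), key=lambda i: truth_rows[i]["pos"])
    truth = pd.DataFrame([truth_rows[i] for i in order])

    calls: dict[str, list[VariantCall]] = {s: [] for s in samples}
    for v, carriers in records:
        for s in carriers:
            calls[s].append(v)
    fcs = FamilyCallSet(pedigree=roles, calls=calls)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_family_vcf(out_dir / "family.vcf", tm, records, samples)
        _write_ped(out_dir / "family.ped", roles)
        truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return fcs, truth


def _write_ped(path, roles: dict[str, str]) -> None:
    rows = [
        f"FAM\t{roles['father']}\t0\t0\t1\t1",
        f"FAM\t{roles['mother']}\t0\t0\t2\t1",
        f"FAM\t{roles['proband']}\t{roles['father']}\t{roles['mother']}\t1\t2",
    ]
    if "sibling" in roles:
        rows.append(
            f"FAM\t{roles['sibling']}\t{roles['father']}\t{roles['mother']}\t2\t1"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def _write_family_vcf(path, tm: TranscriptModel, records, samples) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=dntb-synthetic")
    header.contigs.add(tm.chrom, length=tm.span_end + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v, carriers in records:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.filter.add("PASS")
            for s in samples:
                sup = v.sample_support[s]
                rec.samples[s]["GT"] = (0, 1) if s in carriers else (0, 0)
                rec.samples[s]["DP"] = sup.total_reads
                rec.samples[s]["AD"] = (
                    sup.total_reads - sup.alt_reads, sup.alt_reads
                )
            out.write(rec)


# ---------------------------------------------------------------------------
# Truncating-variant sets with positional bias
# ---------------------------------------------------------------------------


def make_truncating_set(
    tm: TranscriptModel,
    n: int,
    escape_bias: float,
    seed: int,
    rule_threshold: int = NMD_RULE_THRESHOLD,
    sites: Optional[Sequence] = None,
):
    """Place ``n`` nonsense SNVs with escape-region density scaled by ``escape_bias``.

    Each variant falls in the NMD-escape region with probability
    ``escape_region_fraction * escape_bias`` (the length-proportional
    null times the bias) and is then drawn uniformly from the
    stop-creating sites of that region, so the expected enrichment
    recovered by the polarity statistic is ``100 * (escape_bias - 1)``
    percent.  ``sites`` may carry a precomputed
    :func:`dntb.mutation_model.nonsense_sites` list to amortize the
    enumeration across replicates.

    Returns ``(variants, truth)``; ``truth`` records the realized region
    counts and the sampling fractions.
    """
    from .mutation_model import nonsense_sites

    if escape_bias <= 0:
        raise SpecError("escape_bias must be positive")
    rng = np.random.default_rng(seed)
    frac = escape_region_fraction(tm, rule_threshold)
    p_escape = frac * escape_bias
    if p_escape > 1:
        raise SpecError(
            f"escape_bias {escape_bias} with escape fraction {frac:.3f} "
            "implies a probability above 1"
        )
    c0, _ = tm.cds_mrna_interval
    junctions = tm.junction_positions()
    boundary = (junctions[-1] - rule_threshold) if junctions else -1

    all_sites = list(sites) if sites is not None else nonsense_sites(tm)
    escape_sites, trigger_sites = [], []
    for off, alt, ctx in all_sites:
        ptc_offset = c0 + 3 * (off // 3)
        (escape_sites if ptc_offset >= boundary else trigger_sites).append(
            (off, alt)
        )
    if n > 0:
        if not escape_sites or (p_escape < 1 and not trigger_sites):
            raise SpecError(
                f"gene {tm.id} has no stop-creating site in a required region"
            )

    variants = []
    n_escape_planted = 0
    for _ in range(n):
        in_escape = rng.random() < p_escape
        pool = escape_sites if in_escape else trigger_sites
        off, alt = pool[rng.integers(len(pool))]
        n_escape_planted += in_escape
        g = tm.cds_to_genomic(off)
        ref_plus = tm.base_at(g - 1)
        alt_plus = alt if tm.strand == "+" else revcomp(alt)
        variants.append(VariantCall(tm.chrom, g, ref_plus, alt_plus))
    truth = {
        "n": n,
        "n_escape_planted": int(n_escape_planted),
        "escape_region_fraction": frac,
        "escape_bias": escape_bias,
        "p_escape": p_escape,
        "rule_threshold": rule_threshold,
    }
    return variants, truth
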