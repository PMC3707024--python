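"""Trio/quartet de novo variant calling by in-silico subtraction.

A candidate de novo variant is a proband variant absent from *every*
other sequenced family member (both parents and any sibling), which then
has to survive the read-support filters: at least ``min_reads``
alternate reads, an allele fraction within ``[af_low, af_high]``
(inclusive; heterozygous germline events expect ~0.5), and a
high-quality flag from the upstream caller.  Known population variants
(e.g. dbSNP/Thousand Genomes entries) are *flagged*, never removed —
their interpretation is a downstream decision.

Each rejected variant carries the first failing criterion in the fixed
order inherited -> support -> allele_fraction -> quality, so filter
outcomes are stable and auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .consequence import SampleSupport, VariantCall

logger = logging.getLogger(__name__)

MIN_ALT_READS = 5
AF_LOW = 0.4
AF_HIGH = 0.6
PARENT_DEPTH_WARN = 10


class PedigreeError(Exception):
    pass


@dataclass
class FamilyCallSet:
    """Per-sample variant calls plus the pedigree role mapping."""

    pedigree: dict[str, str]  # role -> sample id (proband, father, mother, sibling*)
    calls: dict[str, list[VariantCall]]  # sample id -> calls

    def __post_init__(self):
        for role in ("proband", "father", "mother"):
            if role not in self.pedigree:
                raise PedigreeError(f"pedigree is missing a {role}")
        ids = list(self.pedigree.values())
        if len(set(ids)) != len(ids):
            raise PedigreeError("sample ids must be unique")

    @property
    def proband(self) -> str:
        return self.pedigree["proband"]

    @property
    def non_proband_samples(self) -> list[str]:
        return [s for r, s in self.pedigree.items() if r != "proband"]


@dataclass
class DeNovoCall:
    variant: VariantCall
    status: str  # pass | fail_inherited | fail_support | fail_allele_fraction | fail_quality
    known_id: Optional[str] = None
    known_flag: bool = False


# ---------------------------------------------------------------------------
# Subtraction and filtering
# ---------------------------------------------------------------------------


def subtract_parental(fcs: FamilyCallSet) -> list[VariantCall]:
    """Proband variants present in no other family member (exact allele match)."""
    if fcs.proband not in fcs.calls:
        raise PedigreeError(f"no calls loaded for proband {fcs.proband!r}")
    others = set()
    for sample in fcs.non_proband_samples:
        if sample not in fcs.calls:
            raise PedigreeError(f"no calls loaded for family member {sample!r}")
        others.update(v.key for v in fcs.calls[sample])
    return [v for v in fcs.calls[fcs.proband] if v.key not in others]


def _support_of(v: VariantCall, sample: str) -> SampleSupport:
    return v.sample_support.get(sample, SampleSupport(0, 0, False))


def allele_fraction(
    support: SampleSupport, denominator: str = "total"
) -> float:
    """Alt-read fraction; ``denominator`` is 'total' (depth) or 'ref_alt'."""
    if denominator == "ref_alt" and support.ref_reads is not None:
        denom = support.ref_reads + support.alt_reads
    else:
        denom = support.total_reads
    return support.alt_reads / denom if denom > 0 else 0.0


def quality_filter(
    candidates: Sequence[VariantCall],
    proband_sample: str,
    min_reads: int = MIN_ALT_READS,
    af_low: float = AF_LOW,
    af_high: float = AF_HIGH,
    af_denominator: str = "total",
) -> list[DeNovoCall]:
    """Apply the read-support filters to subtraction survivors.

    Pass requires alt reads >= ``min_reads``, allele fraction within the
    inclusive ``[af_low, af_high]`` band, and the caller's high-quality
    flag.  A site with zero depth fails on support, never on arithmetic.
    """
    out = []
    for v in candidates:
        s = _support_of(v, proband_sample)
        if s.alt_reads < min_reads:
            status = "fail_support"
        elif not af_low <= allele_fraction(s, af_denominator) <= af_high:
            status = "fail_allele_fraction"
        elif not s.quality_flag:
            status = "fail_quality"
        else:
            status = "pass"
        out.append(DeNovoCall(variant=v, status=status))
    return out


def call_denovo(
    fcs: FamilyCallSet,
    min_reads: int = MIN_ALT_READS,
    af_low: float = AF_LOW,
    af_high: float = AF_HIGH,
    af_denominator: str = "total",
    known: Optional[dict] = None,
) -> list[DeNovoCall]:
    """Full per-family pipeline: subtraction, quality filters, known flags.

    Returns one :class:`DeNovoCall` per proband variant, including the
    inherited ones (status ``fail_inherited``), in input order.
    """
    candidates = {v.key for v in subtract_parental(fcs)}
    calls = []
    shallow_parents = 0
    parent_samples = [
        fcs.pedigree[r] for r in ("father", "mother") if r in fcs.pedigree
    ]
    for v in fcs.calls[fcs.proband]:
        if v.key not in candidates:
            calls.append(DeNovoCall(variant=v, status="fail_inherited"))
            continue
        dn = quality_filter(
            [v], fcs.proband, min_reads, af_low, af_high, af_denominator
        )[0]
        if dn.status == "pass":
            for parent in parent_samples:
                if _support_of(v, parent).total_reads < PARENT_DEPTH_WARN:
                    shallow_parents += 1
        calls.append(dn)
    if shallow_parents:
        logger.warning(
            "%d candidate site(s) have a parent below %dx depth; "
            "de novo status there rests on thin parental evidence",
            shallow_parents,
            PARENT_DEPTH_WARN,
        )
    if known is not None:
        calls = flag_known(calls, known)
    return calls


# ---------------------------------------------------------------------------
# Known-variant flagging
# ---------------------------------------------------------------------------


def load_known_table(path) -> dict[tuple[str, int, str, str], str]:
    """Read a known-variant table (4/5-column TSV or VCF) into a lookup.

    TSV columns: chrom, pos (1-based), ref, alt[, id].  Malformed rows
    are skipped with a warning count, not fatal.
    """
    path = Path(path)
    known: dict[tuple[str, int, str, str], str] = {}
    skipped = 0
    text = path.read_text().splitlines()
    is_vcf = path.suffix == ".vcf" or any(
        ln.startswith("##fileformat=VCF") for ln in text[:5]
    )
    for line in text:
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        try:
            if is_vcf:
                chrom, pos, vid, ref, alts = f[0], int(f[1]), f[2], f[3], f[4]
                for alt in alts.split(","):
                    known[(chrom, pos, ref.upper(), alt.upper())] = (
                        vid if vid != "." else ""
                    )
            else:
                chrom, pos, ref, alt = f[0], int(f[1]), f[2].upper(), f[3].upper()
                known[(chrom, pos, ref, alt)] = f[4] if len(f) > 4 else ""
        except (IndexError, ValueError):
            skipped += 1
    if skipped:
        logger.warning("known-variant table %s: skipped %d malformed row(s)", path, skipped)
    return known


def flag_known(
    calls: Sequence[DeNovoCall], known: dict[tuple[str, int, str, str], str]
) -> list[DeNovoCall]:
    """Mark calls found in the known table; nothing is removed."""
    out = []
    for dn in calls:
        key = dn.variant.key
        if key in known:
            dn = DeNovoCall(
                variant=dn.variant,
                status=dn.status,
                known_id=known[key] or None,
                known_flag=True,
            )
        out.append(dn)
    return out


# ---------------------------------------------------------------------------
# I/O: multi-sample VCF + PED
# ---------------------------------------------------------------------------


def read_ped(ped_path) -> dict[str, str]:
    """Map pedigree roles from a 6-column PED file.

    The proband is the first affected individual (phenotype 2) with both
    parents named; other children of the same parents become
    ``sibling``/``sibling2``...  Parents map to father/mother.
    """
    rows = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split()
        if len(f) < 6:
            raise PedigreeError(f"{ped_path}: PED rows need 6 columns, got {len(f)}")
        rows.append(
            dict(fid=f[0], iid=f[1], father=f[2], mother=f[3], sex=f[4], pheno=f[5])
        )
    proband = next(
        (r for r in rows if r["pheno"] == "2" and r["father"] != "0" and r["mother"] != "0"),
        None,
    )
    if proband is None:
        raise PedigreeError(f"{ped_path}: no affected individual with both parents")
    roles = {
        "proband": proband["iid"],
        "father": proband["father"],
        "mother": proband["mother"],
    }
    n_sib = 0
    for r in rows:
        if r["iid"] in roles.values():
            continue
        if r["father"] == proband["father"] and r["mother"] == proband["mother"]:
            n_sib += 1
            roles["sibling" if n_sib == 1 else f"sibling{n_sib}"] = r["iid"]
    return roles


def load_family(
    vcf_path, ped_path, quality_mode: str = "filter"
) -> FamilyCallSet:
    """Build a :class:`FamilyCallSet` from a multi-sample VCF and a PED file.

    A sample carries a variant when its genotype includes the alternate
    allele.  Read support comes from FORMAT DP/AD; the high-quality flag
    is FILTER == PASS (``quality_mode='filter'``, the VCF reduction of a
    caller-specific flag).
    """
    import pysam

    roles = read_ped(ped_path)
    calls: dict[str, list[VariantCall]] = {s: [] for s in roles.values()}
    with pysam.VariantFile(str(vcf_path)) as vf:
        vcf_samples = set(vf.header.samples)
        for sample in roles.values():
            if sample not in vcf_samples:
                raise PedigreeError(f"sample {sample!r} not present in {vcf_path}")
        for rec in vf:
            qual_ok = (not rec.filter.keys()) or ("PASS" in rec.filter.keys())
            for ai, alt in enumerate(rec.alts or (), start=1):
                support = {}
                carriers = []
                for sample in roles.values():
                    fmt = rec.samples[sample]
                    gt = fmt.get("GT") or ()
                    dp = fmt.get("DP")
                    ad = fmt.get("AD")
                    alt_reads = ad[ai] if ad is not None and len(ad) > ai else 0
                    ref_reads = ad[0] if ad is not None else None
                    support[sample] = SampleSupport(
                        total_reads=dp or 0,
                        alt_reads=alt_reads or 0,
                        quality_flag=qual_ok,
                        ref_reads=ref_reads,
                    )
                    if ai in [a for a in gt if a is not None]:
                        carriers.append(sample)
                if not carriers:
                    continue
                v = VariantCall(rec.chrom, rec.pos, rec.ref, alt, support)
                for sample in carriers:
                    calls[sample].append(v)
    return FamilyCallSet(pedigree=roles, calls=calls)


def denovo_table(calls: Sequence[DeNovoCall], proband_sample: str):
    """Calls as a tidy DataFrame (one row per proband variant)."""
    import pandas as pd

    rows = []
    for dn in calls:
        s = _support_of(dn.variant, proband_sample)
        rows.append(
            {
                "chrom": dn.variant.chrom,
                "pos": dn.variant.pos,
                "ref": dn.variant.ref,
                "alt": dn.variant.alt,
                "status": dn.status,
                "alt_reads": s.alt_reads,
                "total_reads": s.total_reads,
                "allele_fraction": round(allele_fraction(s), 4),
                "known_flag": dn.known_flag,
                "known_id": dn.known_id or ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "status", "alt_reads",
            "total_reads", "allele_fraction", "known_flag", "known_id",
        ],
    )
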