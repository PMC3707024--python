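# Methods

This note documents the models, parameter choices and numerical
conventions behind `dntb`, and what the synthetic-data experiments do
and do not demonstrate.

## Coordinate model

A transcript is a list of non-overlapping exons on one strand of one
chromosome, with the CDS a contiguous genomic sub-interval intersected
with the exons.  Internally all coordinates are 0-based half-open;
every user-facing position (VCF, GFF3, HGVS-like `g.`/`p.` strings) is
1-based inclusive.  Minus-strand transcripts are handled by mapping
through plus-strand spliced offsets and mirroring, so a gene and its
reverse-complement image are indistinguishable in CDS coordinates (this
is property-tested).  Validation requires an in-frame CDS starting with
ATG, ending in a stop, and free of internal stops; a warn-only mode
exists for messier real annotations, but synthetic inputs are always
strict.

## Consequence annotation

SNVs are classified by translating the single affected codon.  Indels
are first minimalized and left-aligned against the transcript sequence
(the standard trim/extend/roll scheme), refused explicitly if they span
an exon–intron boundary, and then applied to the spliced mRNA.
Frame-preserving indels are `inframe_indel` (with a check for an
introduced stop); frame-shifting indels are re-translated from the CDS
start through the 3′ UTR until a stop codon appears in the shifted
frame.  Two conventions matter here:

* **First changed residue.** The reported protein position is the first
  residue whose amino acid actually differs, not the first codon
  touched by the indel — a shifted codon can coincidentally re-encode
  the reference residue.
* **Extension count.** `fsX{n}` counts the residues translated in the
  shifted frame before the new stop, stop excluded; `fsX0` means the
  first shifted codon is itself a stop ("a premature termination codon
  immediately").

A frameshift with no stop before the transcript end is flagged
`no_stop_found` rather than guessed at.

## NMD classification

The classifier implements the canonical 50-nucleotide boundary rule: a
premature termination codon more than `rule_threshold` (default 50) nt
upstream of the *last* exon–exon junction is `nmd_predicted`; in the
last exon, or within the threshold of the last junction, it is
`nmd_escape`; single-exon transcripts always escape.  The threshold is
an explicit parameter because the rule is a heuristic — a substantial
fraction of transcripts predicted to undergo NMD escape degradation in
practice — and the classifier should be read as a positional label, not
a molecular fate.  For frameshifts the junction offsets are re-computed
on the mutated mRNA (junctions 3′ of the edit shift by the indel
length), since that is the transcript the surveillance machinery sees.

## Per-generation truncation probability

The model asks: for a given gene, what is the probability that one
generation produces a de novo event truncating the protein?

**Nonsense SNVs.** Every CDS position × alternate base whose mutated
codon is a stop (and whose reference codon is not) is enumerated.  Each
site contributes a trinucleotide-context rate: a genome-average
per-base substitution probability `mu_sub` split over the three
alternates with transitions weighted `kappa : 1 : 1`, i.e. a transition
gets `mu_sub·kappa/(kappa+2)`, and transitions at CpG dinucleotides
(read on either strand, using the *genomic* neighbours so that
exon-boundary sites see their true methylation context) are multiplied
by `cpg_multiplier`.  Base composition ("GC content") therefore enters
through the explicit sequence enumeration and the CpG term rather than
a gene-wide scalar; a gene-level GC multiplier hook (`gc_scaling`)
exists but defaults to off.

**Truncating indels.** A length model:
`cds_length · mu_indel_coding · P(frameshift | indel) ·
P(truncating | frameshift)`, with frameshifts assumed truncating by
default and in-frame indels contributing nothing.  Splice-site and
stop-loss mechanisms are deliberately excluded from `p_trunc`.

Defaults (editable TSV, `src/dntb/data/default_rates.tsv`):

| parameter | default | units / meaning |
|---|---|---|
| `mu_sub` | 1.2e-8 | substitutions per base per generation |
| `kappa` | 2.0 | transition/transversion rate ratio |
| `cpg_multiplier` | 10.0 | extra factor on CpG transitions |
| `mu_indel_coding` | 1.0e-9 | indels per coding base per generation |
| `p_frameshift_given_indel` | 2/3 | lengths not divisible by 3 |
| `p_truncating_given_frameshift` | 1.0 | conservative upper reading |

These values place the implied genome-wide expectation (~74 de novo
point mutations per diploid genome, <1 coding) inside the literature
band of 70–175 per generation with 0–3 coding, which the suite asserts.
The calibration is treated as data: published per-gene numbers can only
be reproduced to order of magnitude without the original rate tables,
and the suite checks exactly that (a synthetic gene of ASXL3 dimensions
lands within 10× of the published 3.35 × 10⁻⁶ nonsense and
3.91 × 10⁻⁶ indel probabilities).

## Recurrence statistic

`conditional_joint` multiplies the per-event probabilities of the *k*
additional probands, conditioning on the first observation — the
classical back-of-envelope that ignores cohort size.  Because the
statistically defensible quantity accounts for how many trios were
screened, the exact binomial tail `P(X ≥ k)` over the cohort is always
available alongside (`poisson_recurrence`, with a Poisson option whose
tail error is O(k²/n + p)).  The pipeline report prints the nonsense
reading first and the indel-only / any-truncating readings as labelled
sensitivity lines, because which per-event probability enters the
product is an interpretive choice.

## Polarity (3′-bias) statistic

For a set of PTC-bearing variants on one transcript, the escape-region
fraction *f* is the share of CDS bases whose PTC would classify as
NMD-escape.  Under the length-proportional null the escape count is
Binomial(n, f); the statistic reports
`enrichment_pct = 100·(observed/f − 1)` and a one-sided exact binomial
tail (two-sided available).

One numerical subtlety: the exact binomial test is discrete, so its
achievable size oscillates below the nominal α as n varies and is
conservative at most n.  Calibration experiments therefore choose the
per-set variant count with `calibrated_set_size`, which picks — purely
from the null parameters — the n whose achievable size is closest to
nominal, so that type-I-error simulations measure the statistic rather
than the discreteness of its null.

## Synthetic data

`make_gene` samples sense codons from a Boltzmann distribution over GC
content (solved by bisection to hit the target mean) and then refines
by local codon swaps until the CDS GC is within ±0.03 of target (and,
when requested, the CpG dinucleotide density within ±0.01); UTRs,
introns and flanks are i.i.d. bases at the same GC.  `make_family`
plants inherited heterozygous variants (proband + one carrier parent,
optionally a sibling) and de novo variants (proband only), with depth ~
negative binomial and alternate reads ~ Binomial(depth, af); parental
genotyping error is modelled as allele dropout at rate `error_rate`,
the exact event that manufactures false de novo candidates, so the
expected false-candidate count is analytically Binomial(n_inherited,
e).  `make_truncating_set` places nonsense SNVs with escape-region
probability `f · escape_bias`, making the recovered enrichment converge
to `100·(bias − 1)` percent.  All generators are pure functions of
(spec, seed) and write byte-reproducible GFF3/FASTA/VCF/PED/TSV.

What this does *not* show: the read-support model has no mapping or
base-calling structure, genes have no repeat or homopolymer content, no
mosaicism or post-zygotic events are simulated, and variant density is
uniform over the span.  Passing the recovery and calibration suites
demonstrates the correctness of the filtering, annotation and counting
logic under the stated model, not robustness to real sequencing
artefacts.

## Problem sizes in the shipped suites

The test and acceptance suites run at desk scale by design: oracle
equivalence uses 100 random genes of ≤ 300 codons plus ≥ 300 random
SNVs, de novo recovery uses 200 simulated trios (600 planted de novo
events), and polarity calibration uses 1000 null sets plus one 10⁴-
variant biased set.  The whole suite completes in well under a minute
per module on a single CPU.

## Known limitations

* One named transcript per run; no canonical-transcript election.
* Multi-nucleotide substitutions and junction-spanning indels are
  refused explicitly rather than annotated.
* Subtraction matches exact normalized alleles; an inherited MNV
  overlapping a de novo SNV would not mask it (documented trade-off).
* "Allele percentage" uses total read depth as denominator; a
  ref+alt-reads denominator is available as a switch.
* The NMD rule is positional only; no UTR-intron (EJC-independent)
  or start-proximal escape effects are modelled.
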