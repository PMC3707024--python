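# dntb — de novo truncating-mutation burden

`dntb` is a small, fully tested pipeline for the computational core of a
trio-sequencing gene-discovery study: given sequenced families, it
identifies candidate *de novo* variants in the proband, annotates their
protein-level consequence and predicted nonsense-mediated-decay (NMD)
fate, and asks how surprising recurrent *de novo* truncating mutations
in a single gene are under a per-generation mutation model.  It is
aimed at statistical geneticists and method developers who want each of
those steps as an auditable, scriptable library rather than a black
box, and it ships seeded generators for every input so the whole
analysis can be exercised end to end on synthetic data.

## What it computes

**Trio de novo calling** (`dntb.trio_denovo`). A candidate de novo
variant is a proband call absent from *all* other family members
(in-silico subtraction), supported by ≥ 5 alternate reads with an
allele fraction in [0.4, 0.6] (heterozygous germline expectation), and
flagged high-quality by the upstream caller.  Known population variants
are flagged, never removed.

**Consequence and NMD annotation** (`dntb.consequence`). SNVs are
classified by translating the mutated codon; indels by re-translating
the shifted reading frame through the 3′ UTR until the new stop codon,
reporting extensions in `p.T659fsX41` style (first changed residue, 41
further residues before the premature termination codon, PTC).  A PTC
more than 50 nt upstream of the last exon–exon junction is predicted to
trigger NMD; in the last exon or within 50 nt of the junction it is
predicted to escape.

**Per-generation truncation probability** (`dntb.mutation_model`).
For a gene with CDS sequence *S*, every (position, alternate) pair
creating a stop codon is enumerated and weighted by a
trinucleotide-context substitution rate

```
rate(site, alt) = mu_sub · w(ts/tv; kappa) · cpg_multiplier[if CpG transition]
```

with defaults `mu_sub = 1.2e-8` per base per generation, `kappa = 2`,
`cpg_multiplier = 10` (all editable TSV data, not code).  The sum is
P(de novo nonsense) per generation; truncating indels use
`cds_length · mu_indel · P(frameshift|indel) · P(truncating|frameshift)`.

**Recurrence and polarity** (`dntb.burden_stats`). Having observed one
de novo truncating event, the probability of *k* further unrelated
probands is the product of the per-event probabilities (with an exact
cohort-aware binomial tail available alongside), and the 3′ positional
bias of a truncating-variant set is measured as the percentage
enrichment of NMD-escape variants over the length-proportional null,
with an exact binomial p-value.

## Worked example

Simulate a 5-exon gene and a trio with 2 planted de novo variants, then
run the full pipeline:

```bash
python - <<'EOF'
from dntb import GeneSpec, TrioSpec, make_gene, make_family
tm = make_gene(GeneSpec(seed=42, n_exons=5), out_dir=".")
make_family(TrioSpec(seed=43, n_inherited_het=20, n_denovo=2,
                     depth_mean=200.0), tm, out_dir=".")
EOF
cat > run.yaml <<'EOF'
gff: TX42.gff3
fasta: TX42.fa
vcf: family.vcf
ped: family.ped
transcript_id: TX42
out_dir: out
cohort_size: 192
EOF
dntb run --config run.yaml
```

prints

```
# dntb run summary

Proband variants examined: 22
De novo calls passing all filters: 2 (0 flagged as known variants)

Pass de novo consequences:
  chrS:483 C>G  noncoding  .  NMD: not_applicable
  chrS:3120 A>T  noncoding  .  NMD: not_applicable

Per-generation P(de novo nonsense) in TX42: 1.401e-06
Per-generation P(de novo truncating indel): 1.202e-06

P(3 additional probands | first observation), nonsense reading: 2.750e-18
  sensitivity (indel-only reading): 1.737e-18
  sensitivity (any-truncating reading): 1.764e-17
  cohort-aware tail (n=192): 3.193e-12

NMD-escape polarity: no PTC-bearing pass variants
```

Both planted de novo variants are recovered (they happen to fall
outside the CDS, hence `noncoding`); the gene-level block says that a
de novo nonsense mutation in this 2.4 kb-CDS gene is a ~1.4-in-a-million
event per generation, and the recurrence block multiplies three such
events, conditioning on the first observation.  The cohort-aware tail
shows what the same recurrence looks like when the number of screened
trios is taken into account.  Per-stage TSVs and a reproducibility
manifest land in `out/`.

The recurrence arithmetic is also available directly:

```bash
$ dntb recurrence --probs 3.35e-6,3.35e-6,3.35e-6
k_additional    3
naive_joint     3.759538e-17
```

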