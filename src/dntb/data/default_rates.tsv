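term	value	note
mu_sub	1.2e-8	genome-average per-base per-generation substitution probability
kappa	2.0	transition/transversion rate ratio
cpg_multiplier	10.0	rate multiplier for transitions at CpG dinucleotides
mu_indel_coding	1.0e-9	per-coding-base per-generation small-indel probability
p_frameshift_given_indel	0.6666666666666666	fraction of coding indels with length not divisible by 3
p_truncating_given_frameshift	1.0	fraction of frameshifts assumed truncating
gc_scaling	0.0	optional gene-wide GC adjustment, off by default
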