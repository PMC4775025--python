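"""Turn synonymous codon encodings into the four feature blocks.

Builds a tiny synthetic panel of synonymous variants and assembles the
full feature matrix: one MFE column, 64 codon-bias columns, 64 codon-count
columns, and one codon-ID column per codon position.
"""

from codonexpress import (
    FeatureBlockSpec,
    GeneratorConfig,
    assemble_feature_matrix,
    codon_identification,
    generate_expression,
    generate_synonymous_variants,
)

cfg = GeneratorConfig(aa_length=30, n_variants=8, seed=0, noise_sd=0.2)
seqs = generate_synonymous_variants(cfg)
records = generate_expression(seqs, cfg)

print(f"protein: {seqs[0].translate()}")
print(f"first variant, first 5 codons: {seqs[0].codons()[:5]}")
print(f"their identification numbers:  {[codon_identification(c) for c in seqs[0].codons()[:5]]}")

spec = FeatureBlockSpec(use_mfe="window", use_bias="all", use_count=True, use_id=True)
X = assemble_feature_matrix(records, seqs, spec)
print(f"\nfeature matrix: {X.n_patterns} patterns x {X.n_features} features")
print("blocks:", dict(X.blocks))
# 1 MFE + 64 bias + 64 count + 31 positions (30 aa + stop) = 160 columns;
# bias entries are within-amino-acid codon frequencies in [0, 1].
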