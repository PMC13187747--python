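"""Per-gene codon-usage metrics on a tiny hand-built mitochondrial CDS.

Builds one short CDS under the invertebrate mitochondrial code (table 5),
then prints RSCU, ENC, positional GC, skews and a self-referenced CAI.
"""

from mitocodon import (
    CodingSequence,
    compute_cai,
    compute_enc,
    compute_rscu,
    compute_skews,
    count_codons,
    load_genetic_code,
    positional_gc,
    reference_weights,
)

code5 = load_genetic_code(5)

# A deliberately T-biased toy gene: Phe (TTT), Leu (TTA), Ile (ATT) heavy,
# the composition regime typical of invertebrate mitogenomes.
seq = ("TTTTTATTTATTAATAAATTAGTTTATTTTTGATTTTTATTAATT" * 8)[: 40 * 9]
seq = seq[: len(seq) - len(seq) % 3]
cds = CodingSequence("Toyus wormus", "mito", "COX1", seq, code5)

counts = count_codons(cds)
rscu = compute_rscu(counts)
pos = positional_gc(cds)
skews = compute_skews(cds)
weights = reference_weights(counts)  # self-referenced, as with pooled PCGs

print(f"codons counted: {counts.total_codons}")
print(f"ENC            : {compute_enc(counts):.2f}   "
      "(20 = one codon per amino acid; 62 = uniform use under table 5)")
print(f"GC1/GC2/GC3    : {pos.gc1:.3f} / {pos.gc2:.3f} / {pos.gc3:.3f}")
print(f"GC12, GC3s     : {pos.gc12:.3f}, {pos.gc3s:.3f}")
print(f"AT skew        : {skews.at_skew:+.3f}  (negative = T-enriched strand)")
print(f"GC skew        : {skews.gc_skew:+.3f}  (positive = G-enriched strand)")
print(f"CAI (self-ref) : {compute_cai(counts, weights):.3f}  "
      "(1 would mean only the most frequent synonym of each family)")
print("strongly preferred codons (RSCU >= 1.5):", rscu.strongly_preferred())
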