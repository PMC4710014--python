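"""Variant effect classification against a toy transcript.

Constructs a two-exon gene (5'-UTR, intron-split CDS, 3'-UTR) on a 100 bp
chromosome and classifies SNPs at characteristic positions: a start-codon
missense, a third-position synonymous change, a stop gain, a UTR variant
and a splice-region variant.
"""

from sweepscan.effects import build_gene_model, classify_variant

CDS = "ATGGAAGGATGGGCTGCTGCTGCTGCTTAA"  # 10 codons
chrom = list("T" * 100)
chrom[20:40] = CDS[:20]   # exon 1 CDS part (positions 21-40)
chrom[60:70] = CDS[20:]   # exon 2 CDS part (positions 61-70)
model = build_gene_model(
    "demo_gene", "demo_gene.t1", "chr1", "+",
    exons=[(11, 40), (61, 90)], cds=[(21, 40), (61, 70)],
    chrom_seq="".join(chrom),
)

variants = [
    (21, "A", "G", "first CDS base"),
    (29, "A", "G", "third codon position"),
    (32, "G", "A", "TGG codon, third position"),
    (15, "T", "C", "upstream exonic"),
    (45, "T", "C", "5 bp into the intron"),
    (80, "T", "C", "downstream exonic"),
]
for pos, ref, alt, where in variants:
    effects = classify_variant(("chr1", pos, ref, alt), [model])
    labels = ", ".join(
        e.consequence + (f" ({e.aa_change})" if e.aa_change else "")
        for e in effects
    )
    print(f"pos {pos:3d} {ref}>{alt}  [{where:24s}] -> {labels}")

print(
    "\nCoding changes are read in transcript orientation through the\n"
    "standard genetic code; UTR and splice-region calls come from the\n"
    "transcript's interval structure."
)
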