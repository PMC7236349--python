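"""From coding sequences to a concatenated protein supermatrix.

Translates two mitochondrial gene fragments with the invertebrate
mitochondrial code (NCBI table 5: AGA -> Ser, ATA -> Met, TGA -> Trp),
then concatenates the per-gene alignments over the union of taxa,
gap-filling a taxon missing from one gene and emitting partition
records.
"""

from aamodel import ProteinAlignment, concatenate, translate_cds

cds = {
    "sp1": "ATACGAAGATGATTT",   # ATA CGA AGA TGA TTT
    "sp2": "ATGCGAAGCTGATTC",
}
print("invertebrate mitochondrial translation (table 5):")
proteins = {}
for taxon, seq in cds.items():
    proteins[taxon] = translate_cds(seq, code=5)
    print(f"  {taxon}: {seq} -> {proteins[taxon]}")
print("  (standard-code translation of sp1 would start I-R-R and hit a stop at TGA)")

cox1 = ProteinAlignment.from_sequences(proteins.items())
cox2 = ProteinAlignment.from_sequences([("sp1", "MKV"), ("sp3", "MRV")])

merged = concatenate([("cox1", cox1), ("cox2", cox2)])
print("\nconcatenated supermatrix:")
for taxon in merged.alignment.taxa:
    print(f"  {taxon}: {merged.alignment.sequence(taxon)}")
print("\npartition records (NEXUS charsets, 1-based inclusive):")
print(merged.charset_block())
print("taxa missing from a gene get all-gap blocks there.")
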