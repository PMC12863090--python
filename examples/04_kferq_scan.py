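"""Scan sequences for KFERQ-like chaperone-mediated autophagy motifs.

Three motif classes are reported per 5-residue window: canonical (Q anchor),
phosphorylation-activated (S/T fills the acidic slot) and acetylation-
activated (K mimics the Q anchor).  Densities are motifs per residue.
"""

from degdet.kferq import dataset_kferq_rates, find_kferq_motifs
from degdet.sequences import from_sequences

seq = "MKFERQAAAAQKILDAAAKFSRQAAAKFERK" + "A" * 40
for hit in find_kferq_motifs(seq):
    print(f"  position {hit.start:>3}  {hit.pentapeptide}  {hit.motif_class}")

ds = from_sequences([("demo", seq), ("inert", "A" * 80)])
pooled, table = dataset_kferq_rates(ds)
print()
print(table.to_string(index=False))
print()
print(f"pooled density {pooled['total']:.4f} motifs per residue "
      "(counts normalized by summed dataset length, the scale on which "
      "protein groups are compared)")
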