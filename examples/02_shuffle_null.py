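"""Original-vs-shuffled null comparison.

Composition-preserving shuffling destroys anchored terminal motifs but
keeps every composition-level property.  On a dataset with planted C-end
degrons, McNemar's test on the paired presence calls shows a large excess
of original-present / shuffled-absent pairs; CTTH deltas are tested with
the signed-rank test.
"""

from degdet.degrons import degron_set_from_pairs
from degdet.pipeline import null_compare
from degdet.synthetic_data import SyntheticSpec, generate_dataset

spec = SyntheticSpec(n_sequences=300, seed=7, p_c_degron=0.4,
                     c_degron_motifs=("GG",))
ds, _, _ = generate_dataset(spec, with_companions=False)

report = null_compare(ds, seed=1,
                      c_degrons=degron_set_from_pairs([("GG", -0.5)], "C"))
cols = ["determinant", "test", "n1", "n2", "p_raw", "p_bh",
        "effect_name", "effect_value"]
print(report[cols].to_string(index=False))
print()
row = report.set_index("determinant").loc["c_degron_present"]
print(f"degrons present in original but lost after shuffling: {row['n1']} sequences")
print(f"gained by shuffling: {row['n2']}  ->  McNemar p = {row['p_raw']:.2e}")
print("The planted anchored motifs are positional information; shuffling "
      "erases them, so the paired test flags strong asymmetry.")
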