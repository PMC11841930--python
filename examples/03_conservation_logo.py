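"""Per-column conservation profile (sequence-logo data) of a lifted region.

Groups the NES windows of a simulated family by taxon and computes, per
column, residue frequencies and information content in bits (log2 20 -
Shannon entropy, no composition adjustment). Anchored columns should
tower over the freely evolving spacers, as in a real logo.
"""

from motifshift import column_profile, count_distinct
from motifshift import synthetic_data as sd

config = sd.default_vertebrate_config(seed=8)
records, truth = sd.simulate_family(config)

nes = [truth.leaf_windows[r.species]["NES"]["subsequence"] for r in records]
srr = [truth.leaf_windows[r.species]["SRR"]["subsequence"] for r in records]

profile = column_profile(nes, group="all")
print("NES window, all 30 orthologs (anchors at columns 1, 4, 7, 9):")
for i, col in enumerate(profile.columns[:9], start=1):
    top = max(col.frequencies, key=col.frequencies.get)
    mark = "*" if i in (1, 4, 7, 9) else " "
    print(f"  col {i:>2}{mark} ic={col.ic_bits:5.2f} bits  "
          f"top {top} ({col.frequencies[top]:.2f})")
print(f"distinct SRR sequences across the family: {count_distinct(srr)}")
# ic near 4.32 bits = a fully conserved column; the pinned serine-rich
# region collapses to a single distinct sequence, so one logo suffices.
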