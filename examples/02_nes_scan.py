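"""Scan sequences for the leucine-rich NES consensus.

The consensus is Phi1-X(2,3)-Phi2-X(2,3)-Phi3-X-Phi4 with Phi in
{L,I,V,F,M}: four hydrophobic anchors, 9-11 residues end to end. The
scan reports every start/spacer decomposition, so overlapping hits and
alternative spacings of the same span all appear.
"""

from motifshift import scan_nes, window_check
from motifshift.align_anchor import LiftedRegion

seq = "MEGLDLSSLAQVVFVPLLADQPKRS"
matches = scan_nes(seq)
print(f"sequence: {seq}")
print(f"{len(matches)} consensus matches:")
for m in matches:
    print(f"  {m.start:>3}-{m.end:<3} spacers ({m.spacer1},{m.spacer2})"
          f"  anchors {m.anchor_positions}  {m.matched}")

# validate an annotated 12-residue window: it conforms if it contains at
# least one full match (the window may be longer than the 11-residue
# pattern maximum)
window = LiftedRegion("demo", "NES", 8, 19, "complete", seq[7:19])
report = window_check(matches, window)
print(f"window 8-19 conforms: {report.conforms} "
      f"({len(report.contained)} contained, {len(report.overlapping)} overlapping)")
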