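# Methods

This note records the models, conventions, and numerical choices behind
`motifshift`, and what the synthetic fixtures do and do not establish.

## Reference-anchored region lifting

Functional regions are annotated once, on a single reference ortholog,
as 1-based inclusive windows on the ungapped sequence (matching the
"amino acids 150–161" convention of the literature). Each query is
aligned to the reference with an optimal global pairwise alignment:

* scoring: BLOSUM62; affine gaps, open 10 / extend 1 (the opening
  residue of a gap costs 10, each further residue 1); terminal gaps
  penalized;
* `X` (unknown residue) scores 0 against every letter — an undetermined
  position should neither support nor contradict homology;
* tie-breaks in the traceback are deterministic (the aligner's first
  enumerated optimum), so reruns are byte-identical.

Pairwise-to-reference alignment was chosen over a multiple alignment
because the lift needs only reference–query homology, is testable
against an exhaustive-recursion dynamic-programming oracle, and imposes
no choice of MSA program or parameters. An externally built MSA can be
consumed through the same column-map contract.

The lift takes every alignment column whose reference position falls in
the window: `q_start`/`q_end` are the first and last query residues
among them. Status is `complete` (no window position aligned to a query
gap), `partial` (some were; the surviving span is reported rather than
silently trimmed — the conservative reading of an ambiguous edge), or
`missing` (all were). Insertions in the query inside the window are
included in the lifted subsequence.

## NES consensus scanning

The leucine-rich nuclear export signal consensus is
Φ₁-X₂,₃-Φ₂-X₂,₃-Φ₃-X-Φ₄, Φ ∈ {L, I, V, F, M}, X any residue. The
spacer ranges force a 9–11 residue span and
`end = start + spacer₁ + spacer₂ + 4`. The scanner enumerates all
(start, spacer₁, spacer₂) combinations and reports each one — the scan
is lossless; downstream consumers deduplicate by span when they want
unique regions. `X` never counts as hydrophobic. An annotated window
*conforms* when at least one match lies entirely inside it: annotated
windows (e.g. the 12-residue reference NES) may exceed the 11-residue
pattern maximum, so containment, not span equality, is the only
consistent criterion. Matches merely overlapping the window are counted
separately, so both readings are available.

## Conservation profiles

Per column of a set of equal-length (gapped) region sequences:
frequencies over non-gap residues, gap fraction, and information
content in bits, IC = log₂ 20 − H with H = −Σ p log₂ p. No
background-composition adjustment and no small-sample correction are
applied, matching logo tools run with composition adjustment
suppressed. Gaps are excluded from the distribution and reported as a
fraction; occupancy scaling of stack heights is left to a renderer. An
all-gap column has undefined IC and is flagged (`ic_bits = None`)
rather than given a number. The numeric matrix (TSV) is the artifact;
drawing the graphic is out of scope.

## Signature-motif mapping and parsimony

The 3-residue DBD signature motif is located *positionally* — by
lifting the reference motif coordinates — never by searching for the
literal string, so a derived variant (FDG where the ancestor had YDG)
is still found at the homologous position. Variants outside the
configured class set {YDG, FDG, LDG, VDG} are labelled `other`.

Substitution histories are reconstructed by exact minimum-change
parsimony on the rooted species taxonomy, polytomies included. The
implementation is a Sankoff-style dynamic program with unit costs over
the observed state set; it returns the exact minimum, the exact number
of optimal labelings (so `is_unique` is computed, not inferred), and
one deterministic optimal labeling. Tie-breaks for the reported
labeling: among child states of equal total cost, prefer the strictly
cheaper subtree (this places changes as close to the root as possible,
reporting a stepwise derived history Y→F→L→V rather than an equally
parsimonious set of late parallel jumps), then the parent's state, then
alphabetical order; at the root, prefer the majority leaf state, then
the state of the earliest leaf in tree order. Clade tallies count each
species once per gene; nested clades are totals, not a partition.

## Structure operations

pLDDT is read from the B-factor column of each residue's CA atom (the
convention of prediction servers); residues below the threshold
(default 50) are removed before any comparison, and a model losing all
residues is flagged excluded-entirely. Superposition is least-squares
rigid-body over paired CA atoms with the reflection branch excluded by
determinant correction; pairing comes from the global alignment of the
two sequences when sequences are supplied, else from shared residue
numbering. RMSD is recomputed from the residuals of the fitted
transform rather than taken from the solver's reported residual, which
loses ~1e-8 of precision to cancellation near zero. Two models are
called similar below 1 Å (configurable). Interface conservation lifts
each contact residue as a width-1 region; a position lost to a deletion
counts against conservation by default (it stays in the denominator),
and an `X` matches nothing. An optional curation step replaces `X` by
the consensus of companion sequences at the aligned position — off by
default, logged when applied.

## Synthetic ortholog families

The generator evolves a root sequence down a known tree and emits
FASTA + metadata + newick + ground truth. Its purpose is to realize,
with known truth, exactly the statistical structure the analysis
assumes; its defaults are frozen study-shaped conditions:

* **30-species vertebrate family** (5 clades × 6 species; root length
  500) carrying an NES window at 150–161 (anchors at window offsets
  1/4/7/9 constrained to {L,I,V,F,M}, spacers free, slow tail), a
  serine-rich region at 447–468 pinned identically family-wide, and a
  YDG signature at 64–66.
* **58-species bird family** (root length 130) with the signature
  transitions planted on named stem branches — YDG→FDG into Neoaves,
  FDG→LDG into Passeriformes, LDG→VDG into Passeridae — giving
  13/30/10/5 species with YDG/FDG/LDG/VDG; homoplasy-free by default
  (an optional flag plants an independent FDG→LDG on one Neoaves tip,
  mimicking a convergent cuckoo state). The IRF6-like family plants no
  transitions: YDG is universal.
* **Substitution process**: per-site Poisson(rate × branch length)
  events; a hit site resamples uniformly within its allowed set.
  Deliberately simple — the pipeline under test makes no model
  assumptions beyond conservation structure; no WAG/LG
  exchangeabilities, no gamma rates.
* **Rate categories** (per site): background 1× the family rate
  (0.5/site for the vertebrate family — moderate divergence, as a
  confidently alignable ortholog set has); NES anchors 0.3× within the
  hydrophobic set; NES spacers 6× (visibly variable columns, as real
  spacers are); pinned and signature sites 0×. These were chosen so
  that the two properties real data exhibit hold together: windows stay
  recognizably homologous (lifting must recover every planted window)
  while anchor columns carry far more information than spacer columns.
  With a hypervariable window interior those goals conflict — a
  saturated window lets the aligner slide gaps into it — which is why
  the spacer rate is elevated but bounded and the window tail is slow.
* **Indels** occur only outside anchored windows and keep a 6-residue
  buffer from every window edge, so a gap can never sit flush against a
  boundary and slide into a diverged spacer; window coordinates shift
  but window content is never touched. Lengths are geometric (p = 0.7),
  insertion/deletion equiprobable.
* **Determinism**: one numpy Generator stream seeded from the config;
  the tree is traversed in preorder; identical seeds give byte-identical
  FASTA.

A separate generator builds a synthetic STAT2/IRF9 sequence panel (a
labelled stand-in for the real accession-anchored records) that carries
the five documented contact residues — STAT2 F174 and IRF9
L274/A276/F283/Q285 — at their reference positions, increasing
divergence and off-interface indels toward the fish-like pairs, and one
`X` at the residue homologous to IRF9 position 258 in the shark-like
record to exercise the consensus-curation path.

**What passing on these fixtures shows — and does not.** The fixtures
establish algorithmic correctness: the scanner equals brute-force
enumeration, lifting inverts the generator's coordinate bookkeeping,
parsimony equals exhaustive search and recovers planted histories, IC
matches closed forms. They do not establish robustness to what the
generator omits: alignment ambiguity in genuinely hard regions,
annotation errors, isoform confusion, compositional bias, or rate
heterogeneity beyond the coarse categories above. Per-group logo
comparisons on very small, shallow clades can tie (both anchor and
spacer columns fully conserved among six close species); the
anchors-dominate-spacers ordering is guaranteed family-wide, not within
every six-species subgroup.

## Degenerate inputs and tie-breaks (summary)

Empty FASTA, duplicate ids, out-of-alphabet characters, metadata
mismatches, regions beyond the reference, missing windows passed to the
conformity check, unlabeled leaves, < 3 atom pairs, and models fully
removed by the confidence filter are all hard errors with specific
messages. All randomness is seeded; all report files are written with
sorted keys and fixed float formatting, so pipeline reruns are
byte-identical.

## Problem sizes

The test suite and acceptance script run the scanner-vs-oracle
comparison on corpora of 10⁴ (suite) and 2×10³ (script) random
length-60 sequences, the aligner oracle on 200 pairs of length ≤ 8,
parsimony enumeration on 50 random 6-leaf trees plus 100 seeded
58-species replicates, and full-family analyses at 30 and 58 species —
sizes at which every oracle is exact and the whole suite completes in
well under a minute.
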