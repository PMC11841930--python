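"""Reference-anchored pairwise alignment and region lifting.

Functional regions (an NES, a serine-rich region, a DBD signature motif)
are annotated once on a reference sequence — e.g. human IRF5 NES at
positions 150-161 — and mapped onto each ortholog through an optimal
global pairwise alignment. Lifting through pairwise alignments rather
than an MSA keeps the coordinate contract simple: each query needs only
its own homology to the reference. An externally built MSA can be
consumed through the same column-map contract.

Coordinates are 1-based inclusive throughout, matching the way regions
are quoted in the literature ("amino acids 150-161").
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import ProteinRecord


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class RegionAnnotation:
    """A named window on the ungapped reference sequence, 1-based inclusive."""

    name: str
    ref_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise AlignmentError(
                f"region {self.name!r}: need 1 <= start <= end, got "
                f"{self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PairwiseAlignment:
    ref_id: str
    query_id: str
    aligned_ref: str
    aligned_query: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise AlignmentError("aligned rows differ in length")

    @property
    def column_map(self) -> list[tuple[int | None, int | None]]:
        """Per-column (ref position | None, query position | None), 1-based."""
        out = []
        r = q = 0
        for cr, cq in zip(self.aligned_ref, self.aligned_query):
            if cr == "-" and cq == "-":
                raise AlignmentError("column gapped in both rows")
            if cr != "-":
                r += 1
            if cq != "-":
                q += 1
            out.append((r if cr != "-" else None, q if cq != "-" else None))
        return out


@dataclass
class LiftedRegion:
    query_id: str
    name: str
    q_start: int | None
    q_end: int | None
    status: str  # complete | partial | missing
    subsequence: str


@lru_cache(maxsize=1)
def _default_aligner() -> Align.PairwiseAligner:
    """Global aligner: BLOSUM62, gap open 10 / extend 1, end gaps penalized.

    The matrix is patched so X (unknown residue) scores 0 against every
    letter: an X should neither reward nor punish homology.
    """
    matrix = substitution_matrices.load("BLOSUM62")
    arr = matrix.copy()
    xi = matrix.alphabet.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = arr
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def global_align(
    ref: ProteinRecord,
    query: ProteinRecord,
    aligner: Align.PairwiseAligner | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of query to reference.

    Ties between equally optimal tracebacks are broken deterministically
    (the aligner's first enumerated alignment).
    """
    if not ref.sequence or not query.sequence:
        raise AlignmentError("cannot align empty sequence")
    aligner = aligner or _default_aligner()
    alignments = aligner.align(ref.sequence, query.sequence)
    best = alignments[0]
    return PairwiseAlignment(
        ref_id=ref.id,
        query_id=query.id,
        aligned_ref=str(best[0]),
        aligned_query=str(best[1]),
        score=float(best.score),
    )


def lift_region(aln: PairwiseAlignment, region: RegionAnnotation) -> LiftedRegion:
    """Map a reference-annotated window onto the query through the alignment.

    ``complete``: every reference position in the window aligns to a query
    residue. ``partial``: some window positions align to query gaps (the
    surviving span is still reported rather than silently trimmed).
    ``missing``: the whole window is deleted in the query.

    Insertions in the query inside the window are included in the lifted
    subsequence: the span runs from the first to the last query residue
    aligned to the window.
    """
    if region.ref_id != aln.ref_id:
        raise AlignmentError(
            f"region {region.name!r} annotated on {region.ref_id!r}, "
            f"alignment reference is {aln.ref_id!r}"
        )
    ref_len = sum(1 for c in aln.aligned_ref if c != "-")
    if region.end > ref_len:
        raise AlignmentError(
            f"region {region.name!r} ({region.start}..{region.end}) outside "
            f"reference length {ref_len}"
        )
    window_q: list[int | None] = []
    for rpos, qpos in aln.column_map:
        if rpos is not None and region.start <= rpos <= region.end:
            window_q.append(qpos)
    present = [q for q in window_q if q is not None]
    if not present:
        return LiftedRegion(aln.query_id, region.name, None, None, "missing", "")
    q_start, q_end = present[0], present[-1]
    status = "complete" if len(present) == len(window_q) else "partial"
    query_seq = aln.aligned_query.replace("-", "")
    return LiftedRegion(
        query_id=aln.query_id,
        name=region.name,
        q_start=q_start,
        q_end=q_end,
        status=status,
        subsequence=query_seq[q_start - 1 : q_end],
    )


def lift_regions(
    ref: ProteinRecord,
    queries: list[ProteinRecord],
    regions: list[RegionAnnotation],
    aligner: Align.PairwiseAligner | None = None,
) -> list[LiftedRegion]:
    """Align every query to the reference and lift every region onto it."""
    out = []
    for query in queries:
        aln = global_align(ref, query, aligner=aligner)
        for region in regions:
            out.append(lift_region(aln, region))
    return out
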