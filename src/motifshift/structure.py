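"""Confidence filtering, rigid superposition, and interface conservation.

Predicted models carry a per-residue confidence (pLDDT, 0-100) in the
B-factor field; residues below 50 are low-confidence and are dropped
before any comparison. Superposition is least-squares optimal rigid-body
(Kabsch) over paired CA atoms, with the reflection branch excluded, and
two models are called structurally similar when the post-superposition
RMSD falls below 1 Å. Interface conservation maps a handful of known
contact residues — by default the STAT2 F174 phenylalanine against the
four-residue IRF9 groove L274/A276/F283/Q285 from the solved mouse
complex — onto query orthologs through the same alignment-lift machinery
used for sequence regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .align_anchor import RegionAnnotation, global_align, lift_region
from .seq_io import ProteinRecord, StructureModel

PLDDT_DEFAULT = 50.0
RMSD_SIMILAR_DEFAULT = 1.0  # Å


@dataclass(frozen=True)
class InterfaceEntry:
    role: str  # e.g. "STAT2" | "IRF9"
    ref_protein_id: str
    ref_position: int  # 1-based
    expected_residue: str  # 1-letter


@dataclass
class InterfaceMap:
    entries: list[InterfaceEntry] = field(default_factory=list)


def default_interface_map(stat2_ref_id: str, irf9_ref_id: str) -> InterfaceMap:
    """The five contact residues of the mouse STAT2-IRF9 complex."""
    return InterfaceMap(
        entries=[
            InterfaceEntry("STAT2", stat2_ref_id, 174, "F"),
            InterfaceEntry("IRF9", irf9_ref_id, 274, "L"),
            InterfaceEntry("IRF9", irf9_ref_id, 276, "A"),
            InterfaceEntry("IRF9", irf9_ref_id, 283, "F"),
            InterfaceEntry("IRF9", irf9_ref_id, 285, "Q"),
        ]
    )


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float
    n_atoms: int
    similar: bool


@dataclass
class InterfaceResidueReport:
    role: str
    ref_position: int
    expected: str
    query_id: str
    query_position: int | None
    observed: str
    conserved: bool
    liftable: bool


@dataclass
class InterfaceReport:
    entries: list[InterfaceResidueReport]
    conserved_count: int
    total: int


# ---------------------------------------------------------------------------
# pLDDT filtering


def filter_plddt(model: StructureModel, threshold: float = PLDDT_DEFAULT) -> StructureModel:
    """Drop residues whose pLDDT is below the threshold.

    If nothing survives, the returned model is flagged excluded-entirely so
    callers can skip the comparison instead of superposing nothing.
    Idempotent by construction.
    """
    kept = [r for r in model.residues if r.plddt >= threshold]
    return StructureModel(
        residues=kept,
        source=model.source,
        excluded_entirely=(len(kept) == 0),
    )


# ---------------------------------------------------------------------------
# Kabsch superposition


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray,
           similar_threshold: float = RMSD_SIMILAR_DEFAULT) -> SuperpositionResult:
    """Least-squares rigid superposition of paired coordinates.

    Finds the proper rotation R and translation t minimizing
    ||R·(B - centroid_B) + centroid_A - A||; reflections are excluded by
    the determinant-sign correction, so a mirrored structure keeps a
    positive RMSD. RMSD is over the paired atoms after superposition.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinates must be (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 atom pairs, got {n}")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a - cen_a, b - cen_b)
    matrix = rot.as_matrix()
    translation = cen_a - matrix @ cen_b
    # rmsd from the residuals directly: the solver's reported rssd loses
    # precision to cancellation near zero
    d = (b @ matrix.T + translation) - a
    rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    return SuperpositionResult(
        rotation=matrix,
        translation=translation,
        rmsd=rmsd,
        n_atoms=n,
        similar=bool(rmsd < similar_threshold),
    )


def superpose_models(
    model_a: StructureModel,
    model_b: StructureModel,
    seq_a: ProteinRecord | None = None,
    seq_b: ProteinRecord | None = None,
    plddt_threshold: float = PLDDT_DEFAULT,
    similar_threshold: float = RMSD_SIMILAR_DEFAULT,
) -> SuperpositionResult:
    """pLDDT-filter two CA models, pair their residues, and superpose.

    With sequences given, pairing comes from the global alignment of the
    two (one-to-one aligned residue positions, gaps excluded); without,
    residues are paired by shared residue_index — appropriate when both
    models were predicted from the same numbering.
    """
    fa = filter_plddt(model_a, plddt_threshold)
    fb = filter_plddt(model_b, plddt_threshold)
    if fa.excluded_entirely or fb.excluded_entirely:
        raise ValueError("model excluded entirely by pLDDT filter; nothing to superpose")
    if seq_a is not None and seq_b is not None:
        aln = global_align(seq_a, seq_b)
        pairs = [
            (r, q) for r, q in aln.column_map if r is not None and q is not None
        ]
        by_index_a = {r.residue_index: r for r in fa.residues}
        by_index_b = {r.residue_index: r for r in fb.residues}
        coords_a = [by_index_a[r].ca_xyz for r, q in pairs
                    if r in by_index_a and q in by_index_b]
        coords_b = [by_index_b[q].ca_xyz for r, q in pairs
                    if r in by_index_a and q in by_index_b]
    else:
        shared = sorted(
            {r.residue_index for r in fa.residues}
            & {r.residue_index for r in fb.residues}
        )
        idx_a = {r.residue_index: r.ca_xyz for r in fa.residues}
        idx_b = {r.residue_index: r.ca_xyz for r in fb.residues}
        coords_a = [idx_a[i] for i in shared]
        coords_b = [idx_b[i] for i in shared]
    return kabsch(np.array(coords_a), np.array(coords_b), similar_threshold)


# ---------------------------------------------------------------------------
# Interface-residue conservation


def sanitize_unknown(record: ProteinRecord, companions: list[ProteinRecord],
                     logger=None) -> ProteinRecord:
    """Replace X residues by the consensus of companion sequences.

    Mirrors the curation step used for records whose coding sequence
    carries an undetermined base (a single-'n' insertion yields an X
    codon): the position is filled from the column consensus of close
    homologs. Off by default in the pipeline; every replacement is logged.
    """
    if "X" not in record.sequence:
        return record
    seq = list(record.sequence)
    for pos0, aa in enumerate(record.sequence):
        if aa != "X":
            continue
        votes: dict[str, int] = {}
        for comp in companions:
            aln = global_align(comp, record)
            for rpos, qpos in aln.column_map:
                if qpos == pos0 + 1 and rpos is not None:
                    c = comp.sequence[rpos - 1]
                    if c != "X":
                        votes[c] = votes.get(c, 0) + 1
        if votes:
            best = max(sorted(votes), key=lambda c: votes[c])
            seq[pos0] = best
            if logger:
                logger.info(
                    "sanitized %s position %d: X -> %s (consensus of %d companions)",
                    record.id, pos0 + 1, best, len(companions),
                )
    return ProteinRecord(
        id=record.id, sequence="".join(seq), species=record.species,
        taxon_group=record.taxon_group, subfamily=record.subfamily,
        accession=record.accession, description=record.description,
    )


def check_interface(
    ref_records: dict[str, ProteinRecord],
    query_records: dict[str, ProteinRecord],
    interface: InterfaceMap,
    count_unliftable_as_conserved: bool = False,
) -> InterfaceReport:
    """Check conservation of mapped contact residues in query orthologs.

    ``ref_records`` / ``query_records`` are keyed by role (e.g. "STAT2",
    "IRF9"). Each entry is lifted onto the query as a width-1 region via
    the global alignment; a position lost to a deletion is reported
    not-liftable and, by default, counts against conservation (it is in
    the denominator). An X in the query matches nothing.
    """
    entries: list[InterfaceResidueReport] = []
    alignments: dict[str, object] = {}
    for entry in interface.entries:
        if entry.role not in ref_records or entry.role not in query_records:
            raise ValueError(f"no sequences supplied for role {entry.role!r}")
        ref = ref_records[entry.role]
        query = query_records[entry.role]
        if entry.role not in alignments:
            alignments[entry.role] = global_align(ref, query)
        aln = alignments[entry.role]
        region = RegionAnnotation(
            name=f"{entry.role}:{entry.expected_residue}{entry.ref_position}",
            ref_id=ref.id, start=entry.ref_position, end=entry.ref_position,
        )
        lifted = lift_region(aln, region)
        if lifted.status != "complete":
            entries.append(
                InterfaceResidueReport(
                    role=entry.role, ref_position=entry.ref_position,
                    expected=entry.expected_residue, query_id=query.id,
                    query_position=None, observed="-", conserved=False,
                    liftable=False,
                )
            )
            continue
        observed = lifted.subsequence
        conserved = observed == entry.expected_residue and observed != "X"
        entries.append(
            InterfaceResidueReport(
                role=entry.role, ref_position=entry.ref_position,
                expected=entry.expected_residue, query_id=query.id,
                query_position=lifted.q_start, observed=observed,
                conserved=conserved, liftable=True,
            )
        )
    conserved_count = sum(
        1 for e in entries
        if e.conserved or (not e.liftable and count_unliftable_as_conserved)
    )
    return InterfaceReport(
        entries=entries, conserved_count=conserved_count, total=len(entries)
    )
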