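"""Readers and writers for the formats the pipeline consumes and emits.

Sequences travel as :class:`ProteinRecord`; structures as
:class:`StructureModel` (one entry per residue, confidence taken from the
CA atom's B-factor, the convention predicted-structure servers use for
pLDDT); taxonomies as dendropy trees. Everything else the pipeline writes
is plain TSV or JSON.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues allowed in a ProteinRecord: the 20 standard amino acids plus X
#: (unknown; present in real records, e.g. from single-'n' CDS insertions)
ALPHABET = frozenset(AMINO_ACIDS + "X")

METADATA_COLUMNS = ["seq_id", "species", "taxon_group", "subfamily", "accession"]


class SeqIOError(ValueError):
    """Raised for malformed sequence, metadata, or structure input."""


@dataclass
class ProteinRecord:
    """One ortholog protein sequence with its clade metadata."""

    id: str
    sequence: str
    species: str = ""
    taxon_group: str = ""
    subfamily: str = ""
    accession: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        bad = sorted(set(self.sequence) - ALPHABET)
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: characters outside amino-acid alphabet: "
                + ", ".join(repr(c) for c in bad)
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Residue:
    chain: str
    residue_index: int
    residue_name: str
    plddt: float
    ca_xyz: tuple[float, float, float]


@dataclass
class StructureModel:
    """CA-level view of a predicted or solved structure.

    ``plddt`` is read from the B-factor column of each residue's CA atom;
    for solved structures that column holds crystallographic B-factors and
    the pLDDT filter should not be applied.
    """

    residues: list[Residue] = field(default_factory=list)
    source: str = ""
    excluded_entirely: bool = False

    @property
    def plddt(self) -> list[float]:
        return [r.plddt for r in self.residues]

    @property
    def coords(self) -> list[tuple[float, float, float]]:
        return [r.ca_xyz for r in self.residues]

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path | io.TextIOBase) -> list[ProteinRecord]:
    """Read protein FASTA into records (id + sequence only).

    The record id is the first whitespace-delimited token of the header
    (NCBI convention); the remainder is kept as ``description``. Sequences
    are uppercased and a single terminal ``*`` stop is stripped.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise SeqIOError(f"duplicate FASTA id: {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if seq.endswith("*"):
                seq = seq[:-1]
            desc = rec.description[len(rec.id):].strip()
            records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if not records:
        raise SeqIOError(f"no FASTA records found in {path!r}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# Metadata TSV


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sequence metadata table (tab-delimited, header row).

    Required columns: seq_id, species, taxon_group, subfamily, accession.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SeqIOError(f"metadata missing columns: {missing}")
    dup = df.loc[df["seq_id"].duplicated(), "seq_id"].tolist()
    if dup:
        raise SeqIOError(f"duplicate seq_id in metadata: {dup}")
    return df[METADATA_COLUMNS]


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def join_metadata(records: Sequence[ProteinRecord], metadata: pd.DataFrame) -> list[ProteinRecord]:
    """Attach metadata rows to records by seq_id; unmatched either way is an error.

    Failing fast here catches mislabeled orthologs before any analysis runs.
    """
    by_id = {row.seq_id: row for row in metadata.itertuples(index=False)}
    unmatched_meta = set(by_id) - {r.id for r in records}
    if unmatched_meta:
        raise SeqIOError(
            f"metadata rows with no FASTA record: {sorted(unmatched_meta)}"
        )
    out = []
    for rec in records:
        row = by_id.get(rec.id)
        if row is None:
            raise SeqIOError(f"FASTA record {rec.id!r} has no metadata row")
        out.append(
            ProteinRecord(
                id=rec.id,
                sequence=rec.sequence,
                species=row.species,
                taxon_group=row.taxon_group,
                subfamily=row.subfamily,
                accession=row.accession,
                description=rec.description,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Newick taxonomy


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted, possibly multifurcating taxonomy from newick.

    Leaf labels are species names and must be unique; internal labels
    (clade names) are optional.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise SeqIOError(
            f"failed to parse newick {path!r} (duplicate or malformed "
            f"labels?): {exc}"
        ) from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    dups = sorted({l for l in labels if labels.count(l) > 1})
    if dups:
        raise SeqIOError(f"duplicate leaf labels in tree: {dups}")
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
    )


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# PDB structures
#
# Parsed directly from fixed-column ATOM records rather than through a
# structure library: the error contract requires the offending line number
# for malformed records, which the library parsers do not surface.


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB coordinate file into a CA-level StructureModel.

    Per-residue confidence (pLDDT) is taken from the B-factor column of the
    CA atom, the convention AlphaFold-family servers use.
    """
    residues: list[Residue] = []
    seen: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                atom_name = line[12:16].strip()
                res_name = line[17:20].strip()
                chain = line[21].strip() or "A"
                res_index = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                bfac = float(line[60:66])
            except (ValueError, IndexError) as exc:
                raise SeqIOError(
                    f"{path}: malformed ATOM record at line {lineno}: {exc}"
                ) from exc
            if atom_name != "CA":
                continue
            if not 0.0 <= bfac <= 100.0:
                raise SeqIOError(
                    f"{path}: pLDDT (B-factor) {bfac} outside [0,100] at line {lineno}"
                )
            prev = seen.get(chain)
            if prev is not None and res_index <= prev:
                raise SeqIOError(
                    f"{path}: CA residue index not strictly increasing in chain "
                    f"{chain!r} at line {lineno}"
                )
            seen[chain] = res_index
            residues.append(Residue(chain, res_index, res_name, bfac, (x, y, z)))
    if not residues:
        raise SeqIOError(f"{path}: no CA atoms found")
    return StructureModel(residues=residues, source=str(path))


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a CA-only PDB file (round-trip partner of read_structure)."""
    with open(path, "w") as fh:
        for i, res in enumerate(model.residues, start=1):
            x, y, z = res.ca_xyz
            fh.write(
                f"ATOM  {i:5d}  CA  {res.residue_name:>3s} {res.chain:1s}"
                f"{res.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{res.plddt:6.2f}           C\n"
            )
        fh.write("END\n")
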