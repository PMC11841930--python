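"""Per-column conservation profiles and sequence-logo data.

Information content per column is log2(20) - H where H is the Shannon
entropy of the residue distribution over non-gap characters, with no
background-composition adjustment and no small-sample correction —
matching the convention of logo tools run with composition adjustment
suppressed. Stack height in a rendered logo is the IC; letter heights
within a stack are the relative frequencies.

Gaps are excluded from the frequency distribution; the gap fraction is
carried alongside so a renderer may scale stacks by occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seq_io import AMINO_ACIDS

MAX_IC_BITS = math.log2(20)


@dataclass
class ColumnStats:
    frequencies: dict[str, float]
    gap_fraction: float
    ic_bits: float | None  # None when the column is all gaps

    @property
    def occupancy(self) -> float:
        return 1.0 - self.gap_fraction


@dataclass
class FrequencyProfile:
    group: str
    n_sequences: int
    columns: list[ColumnStats] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.columns)


def column_profile(region_sequences: list[str], group: str = "") -> FrequencyProfile:
    """Column-wise residue frequencies, gap fractions, and IC in bits.

    All sequences must be equal-length (gapped with '-' where needed).
    An all-gap column gets ic_bits=None rather than a number.
    """
    if not region_sequences:
        return FrequencyProfile(group=group, n_sequences=0)
    length = len(region_sequences[0])
    bad = [s for s in region_sequences if len(s) != length]
    if bad:
        raise ValueError(
            f"sequences of unequal length: expected {length}, got {len(bad[0])}"
        )
    seqs = [s.upper() for s in region_sequences]
    columns = []
    for j in range(length):
        col = [s[j] for s in seqs]
        residues = [c for c in col if c != "-"]
        gap_fraction = 1.0 - len(residues) / len(col)
        if not residues:
            columns.append(ColumnStats({}, 1.0, None))
            continue
        freqs: dict[str, float] = {}
        for c in residues:
            freqs[c] = freqs.get(c, 0) + 1
        total = len(residues)
        freqs = {c: k / total for c, k in sorted(freqs.items())}
        entropy = -sum(p * math.log2(p) for p in freqs.values())
        columns.append(ColumnStats(freqs, gap_fraction, MAX_IC_BITS - entropy))
    return FrequencyProfile(group=group, n_sequences=len(seqs), columns=columns)


def count_distinct(region_sequences: list[str]) -> int:
    """Number of distinct sequences, case-insensitive (e.g. one logo when
    every mammal carries an identical serine-rich region)."""
    return len({s.upper() for s in region_sequences})


def profiles_by_group(
    sequences_by_group: dict[str, list[str]],
) -> dict[str, FrequencyProfile]:
    """One profile per taxon group (groups are data, not code)."""
    return {g: column_profile(seqs, group=g) for g, seqs in sequences_by_group.items()}


# ---------------------------------------------------------------------------
# Logo-matrix TSV export / import


def profile_to_frame(profile: FrequencyProfile) -> pd.DataFrame:
    rows = []
    for pos, col in enumerate(profile.columns, start=1):
        row: dict[str, object] = {"position": pos}
        for aa in AMINO_ACIDS + "X":
            row[aa] = col.frequencies.get(aa, 0.0)
        row["gap_fraction"] = col.gap_fraction
        row["ic_bits"] = "" if col.ic_bits is None else col.ic_bits
        rows.append(row)
    cols = ["position", *list(AMINO_ACIDS + "X"), "gap_fraction", "ic_bits"]
    return pd.DataFrame(rows, columns=cols)


def export_logo_data(profile: FrequencyProfile, path: str | Path) -> None:
    """Write the logo matrix (position x residue frequency + IC + gaps) as TSV."""
    profile_to_frame(profile).to_csv(path, sep="\t", index=False, float_format="%.10g")


def import_logo_data(path: str | Path, group: str = "", n_sequences: int = 0) -> FrequencyProfile:
    """Read a logo-matrix TSV back into a FrequencyProfile (lossless to 1e-9)."""
    df = pd.read_csv(path, sep="\t")
    columns = []
    letters = list(AMINO_ACIDS + "X")
    for _, row in df.iterrows():
        freqs = {aa: float(row[aa]) for aa in letters if float(row[aa]) > 0.0}
        ic = row["ic_bits"]
        ic_val = None if pd.isna(ic) else float(ic)
        columns.append(ColumnStats(freqs, float(row["gap_fraction"]), ic_val))
    return FrequencyProfile(group=group, n_sequences=n_sequences, columns=columns)
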