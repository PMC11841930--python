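"""Nuclear export signal (NES) consensus scanning.

A classical leucine-rich NES is four hydrophobic anchors with short
spacers: Phi1-X(2,3)-Phi2-X(2,3)-Phi3-X-Phi4, Phi in {L,I,V,F,M}, X any
residue. The spacer ranges force the whole match to span 9-11 residues.
Every (start, spacer1, spacer2) combination that satisfies the pattern
is reported, including overlapping matches and alternative spacer
decompositions of the same span — the scan is lossless and consumers
deduplicate by span if they need unique regions.

'X' (unknown residue) never counts as a hydrophobic anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align_anchor import LiftedRegion

HYDROPHOBIC = frozenset("LIVFM")
SPACERS = (2, 3)


@dataclass(frozen=True)
class NESMatch:
    """One consensus hit; all positions 1-based on the scanned sequence."""

    start: int
    spacer1: int
    spacer2: int
    anchor_positions: tuple[int, int, int, int]
    end: int
    matched: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class WindowReport:
    query_id: str
    region_name: str
    conforms: bool
    contained: list[NESMatch]
    overlapping: list[NESMatch]


def scan_nes(sequence: str) -> list[NESMatch]:
    """Enumerate all NES consensus matches in a protein sequence.

    Returns matches sorted by (start, spacer1, spacer2). Empty input gives
    an empty list.
    """
    seq = sequence.upper()
    n = len(seq)
    out: list[NESMatch] = []
    for start0 in range(n):  # 0-based index of Phi1
        if seq[start0] not in HYDROPHOBIC:
            continue
        for s1 in SPACERS:
            p2 = start0 + s1 + 1
            if p2 >= n or seq[p2] not in HYDROPHOBIC:
                continue
            for s2 in SPACERS:
                p3 = p2 + s2 + 1
                p4 = p3 + 2
                if p4 >= n:
                    continue
                if seq[p3] in HYDROPHOBIC and seq[p4] in HYDROPHOBIC:
                    out.append(
                        NESMatch(
                            start=start0 + 1,
                            spacer1=s1,
                            spacer2=s2,
                            anchor_positions=(start0 + 1, p2 + 1, p3 + 1, p4 + 1),
                            end=p4 + 1,
                            matched=seq[start0 : p4 + 1],
                        )
                    )
    out.sort(key=lambda m: (m.start, m.spacer1, m.spacer2))
    return out


def window_check(matches: list[NESMatch], lifted: LiftedRegion) -> WindowReport:
    """Classify consensus matches against an annotated (lifted) window.

    The window conforms when at least one match lies entirely inside it.
    Containment, not span equality, is the criterion: the reference human
    NES annotation spans 12 residues while the pattern spans at most 11.
    Matches that merely overlap the window are reported separately.
    """
    if lifted.status == "missing" or lifted.q_start is None or lifted.q_end is None:
        raise ValueError(
            f"window {lifted.name!r} is missing in {lifted.query_id!r}; "
            "nothing to check"
        )
    contained = [
        m for m in matches if lifted.q_start <= m.start and m.end <= lifted.q_end
    ]
    overlapping = [
        m
        for m in matches
        if m not in contained
        and m.start <= lifted.q_end
        and m.end >= lifted.q_start
    ]
    return WindowReport(
        query_id=lifted.query_id,
        region_name=lifted.name,
        conforms=bool(contained),
        contained=contained,
        overlapping=overlapping,
    )


def deduplicate_spans(matches: list[NESMatch]) -> list[tuple[int, int]]:
    """Unique (start, end) spans of a match list, sorted."""
    return sorted({(m.start, m.end) for m in matches})
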