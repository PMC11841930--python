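"""Synthetic ortholog families with planted, recoverable structure.

The generator evolves a root protein down a known species tree under a
deliberately simple substitution process and emits exactly the inputs
the analysis consumes (FASTA, metadata TSV, newick, plus a ground-truth
JSON). It emulates the statistical features the pipeline's claims rest
on, and nothing more:

* anchored windows — an NES whose hydrophobic anchors stay within
  {L,I,V,F,M} while spacers drift; a serine-rich region pinned
  identically across the family; a 3-residue DBD signature motif;
* indels that never touch an anchored window, so true window
  coordinates shift but window content is intact;
* motif-state transitions planted deterministically on named branches
  (the nested bird YDG -> FDG -> LDG -> VDG narrative), homoplasy-free
  by default so a parsimony reconstruction must recover them exactly.

It does not emulate realistic amino-acid exchangeabilities (WAG/LG),
rate heterogeneity beyond per-site categories, alignment error, or
annotation noise — conclusions from these fixtures are about pipeline
correctness, not about real ortholog data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .seq_io import (
    AMINO_ACIDS,
    ProteinRecord,
    tree_from_string,
    write_fasta,
    write_metadata,
)

TRUTH_SCHEMA_VERSION = 1
HYDROPHOBIC = "LIVFM"

# site-constraint kinds inside an anchored window
FIXED = "fixed"      # pinned residue, never substituted
INHERIT = "inherit"  # from root motif; changes only by planted transition
SET = "set"          # resampled within an allowed set (e.g. NES anchors)
FREE = "free"        # evolves freely (but indel-protected)


@dataclass(frozen=True)
class SiteConstraint:
    kind: str
    residues: str = ""  # for FIXED (one letter) or SET


@dataclass
class WindowSpec:
    name: str
    start: int  # 1-based inclusive on the root sequence
    end: int
    sites: list[SiteConstraint]
    root_motif: str = ""  # initial content for INHERIT sites ("" = random)

    def __post_init__(self) -> None:
        if len(self.sites) != self.end - self.start + 1:
            raise ValueError(
                f"window {self.name!r}: {len(self.sites)} site constraints "
                f"for width {self.end - self.start + 1}"
            )


@dataclass(frozen=True)
class PlantedTransition:
    child_label: str  # branch = edge into this node
    window: str
    from_motif: str
    to_motif: str


@dataclass
class SimulationConfig:
    newick: str  # rooted, branch lengths in substitutions/site
    root_length: int
    windows: list[WindowSpec] = field(default_factory=list)
    site_rate: float = 1.0
    # rate multipliers per site category: anchors (SET) substitute rarely
    # and only within their allowed set; window spacers (FREE inside a
    # window) vary faster than the background but stay far from
    # saturation — the window as a whole must remain recognizably
    # homologous, as the real regions are
    anchor_rate_mult: float = 0.3
    spacer_rate_mult: float = 6.0
    indel_rate: float = 0.0  # events per site per unit branch length
    indel_extend_p: float = 0.7  # geometric length parameter
    # indels keep this many residues clear of every window, so a gap can
    # never sit flush against a boundary and slide into a diverged spacer
    indel_buffer: int = 6
    transitions: list[PlantedTransition] = field(default_factory=list)
    subfamily: str = "FAM"
    taxon_groups: dict[str, str] = field(default_factory=dict)  # species -> group
    seed: int = 0

    def __post_init__(self) -> None:
        spans = sorted((w.start, w.end) for w in self.windows)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("anchored windows overlap")
        names = {w.name for w in self.windows}
        for t in self.transitions:
            if t.window not in names:
                raise ValueError(f"transition references unknown window {t.window!r}")
            width = next(w for w in self.windows if w.name == t.window)
            if len(t.to_motif) != width.end - width.start + 1:
                raise ValueError(
                    f"transition motif {t.to_motif!r} incompatible with window "
                    f"width {width.end - width.start + 1}"
                )


@dataclass
class SyntheticTruth:
    seed: int
    root_sequence: str
    subfamily: str
    # species -> window name -> {"start","end","subsequence"} (1-based)
    leaf_windows: dict[str, dict[str, dict]]
    applied_transitions: list[PlantedTransition]

    def to_dict(self) -> dict:
        return {
            "schema_version": TRUTH_SCHEMA_VERSION,
            "seed": self.seed,
            "subfamily": self.subfamily,
            "root_sequence": self.root_sequence,
            "leaf_windows": self.leaf_windows,
            "applied_transitions": [
                {
                    "child": t.child_label,
                    "window": t.window,
                    "from": t.from_motif,
                    "to": t.to_motif,
                }
                for t in self.applied_transitions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            seed=d["seed"],
            root_sequence=d["root_sequence"],
            subfamily=d["subfamily"],
            leaf_windows=d["leaf_windows"],
            applied_transitions=[
                PlantedTransition(t["child"], t["window"], t["from"], t["to"])
                for t in d["applied_transitions"]
            ],
        )


@dataclass
class _NodeState:
    seq: list[str]
    windows: dict[str, tuple[int, int]]  # name -> 0-based inclusive span


def _root_state(config: SimulationConfig, rng: np.random.Generator) -> _NodeState:
    seq = list(rng.choice(list(AMINO_ACIDS), size=config.root_length))
    windows: dict[str, tuple[int, int]] = {}
    for w in config.windows:
        if w.end > config.root_length:
            raise ValueError(f"window {w.name!r} outside root length")
        for offset, site in enumerate(w.sites):
            pos = w.start - 1 + offset
            if site.kind == FIXED:
                seq[pos] = site.residues
            elif site.kind == SET:
                seq[pos] = str(rng.choice(list(site.residues)))
            elif site.kind == INHERIT and w.root_motif:
                seq[pos] = w.root_motif[offset]
        windows[w.name] = (w.start - 1, w.end - 1)
    return _NodeState(seq=seq, windows=windows)


def _site_kind(config: SimulationConfig, state: _NodeState, pos: int) -> SiteConstraint:
    for w in config.windows:
        s, e = state.windows[w.name]
        if s <= pos <= e:
            return w.sites[pos - s]
    return SiteConstraint(FREE)


def _evolve_branch(
    config: SimulationConfig,
    parent: _NodeState,
    branch_length: float,
    child_label: str | None,
    rng: np.random.Generator,
    applied: list[PlantedTransition],
) -> _NodeState:
    state = _NodeState(seq=list(parent.seq), windows=dict(parent.windows))

    # 1. planted transitions on this branch, deterministic
    for t in config.transitions:
        if t.child_label != child_label:
            continue
        s, e = state.windows[t.window]
        current = "".join(state.seq[s : e + 1])
        if current != t.from_motif:
            raise ValueError(
                f"planted transition on branch into {child_label!r}: window "
                f"{t.window!r} holds {current!r}, expected {t.from_motif!r}"
            )
        state.seq[s : e + 1] = list(t.to_motif)
        applied.append(t)

    # 2. substitutions: Poisson number of events per site with per-category
    #    rates; constrained sites resample within their allowed set
    n_sites = len(state.seq)
    in_window = np.zeros(n_sites, dtype=bool)
    rates = np.full(n_sites, config.site_rate)
    for w in config.windows:
        s, e = state.windows[w.name]
        in_window[s : e + 1] = True
        for offset, site in enumerate(w.sites):
            if site.kind in (FIXED, INHERIT):
                rates[s + offset] = 0.0
            elif site.kind == SET:
                rates[s + offset] *= config.anchor_rate_mult
            else:
                rates[s + offset] *= config.spacer_rate_mult
    hits = rng.poisson(rates * branch_length)
    for pos in np.nonzero(hits)[0]:
        site = _site_kind(config, state, int(pos))
        if site.kind in (FIXED, INHERIT):
            continue
        pool = site.residues if site.kind == SET else AMINO_ACIDS
        state.seq[int(pos)] = str(rng.choice(list(pool)))

    # 3. indels, strictly outside anchored windows
    if config.indel_rate > 0 and branch_length > 0:
        n_events = rng.poisson(config.indel_rate * branch_length * n_sites)
        for _ in range(n_events):
            length = int(rng.geometric(config.indel_extend_p))
            is_insertion = bool(rng.random() < 0.5)
            L = len(state.seq)
            buf = config.indel_buffer
            spans = sorted(
                (s - buf, e + buf) for s, e in state.windows.values()
            )
            if is_insertion:
                # insertion point p: new residues go before index p;
                # p must not fall strictly inside a (buffered) window
                eligible = [
                    p for p in range(L + 1)
                    if not any(s < p <= e for s, e in spans)
                ]
                if not eligible:
                    continue
                p = int(rng.choice(eligible))
                insert = [str(c) for c in rng.choice(list(AMINO_ACIDS), size=length)]
                state.seq[p:p] = insert
                state.windows = {
                    n: (s + length, e + length) if s >= p else (s, e)
                    for n, (s, e) in state.windows.items()
                }
            else:
                eligible = [
                    p for p in range(L - length + 1)
                    if not any(s <= p + length - 1 and p <= e for s, e in spans)
                ]
                if not eligible:
                    continue
                p = int(rng.choice(eligible))
                del state.seq[p : p + length]
                state.windows = {
                    n: (s - length, e - length) if s >= p + length else (s, e)
                    for n, (s, e) in state.windows.items()
                }
    return state


def simulate_family(
    config: SimulationConfig,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Evolve one ortholog family along the configured tree.

    Deterministic for a fixed seed: the tree is traversed in preorder and
    all randomness comes from one numpy Generator stream.
    """
    rng = np.random.default_rng(config.seed)
    tree = tree_from_string(config.newick)
    root_state = _root_state(config, rng)
    root_seq = "".join(root_state.seq)

    applied: list[PlantedTransition] = []
    states: dict[int, _NodeState] = {id(tree.seed_node): root_state}
    records: list[ProteinRecord] = []
    leaf_windows: dict[str, dict[str, dict]] = {}

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = root_state
        else:
            parent_state = states[id(node.parent_node)]
            label = None
            if node.taxon is not None and node.taxon.label:
                label = node.taxon.label
            elif node.label:
                label = node.label
            bl = node.edge.length or 0.0
            state = _evolve_branch(config, parent_state, bl, label, rng, applied)
            states[id(node)] = state
        states[id(node)] = state
        if node.is_leaf():
            species = node.taxon.label
            seq = "".join(state.seq)
            seq_id = f"{species}_{config.subfamily}"
            records.append(
                ProteinRecord(
                    id=seq_id,
                    sequence=seq,
                    species=species,
                    taxon_group=config.taxon_groups.get(species, ""),
                    subfamily=config.subfamily,
                    accession=f"SYN_{seq_id}",
                )
            )
            leaf_windows[species] = {
                name: {
                    "start": s + 1,
                    "end": e + 1,
                    "subsequence": seq[s : e + 1],
                }
                for name, (s, e) in state.windows.items()
            }

    truth = SyntheticTruth(
        seed=config.seed,
        root_sequence=root_seq,
        subfamily=config.subfamily,
        leaf_windows=leaf_windows,
        applied_transitions=applied,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Default study-shaped configurations


def _clade_newick(
    clades: list[tuple[str, str, int]],
    nest: str,
    within: float = 0.05,
    stem: float = 0.1,
) -> tuple[str, dict[str, str]]:
    """Build a newick with labeled clades and a species->group map.

    ``clades``: (clade_label, group_label, n_species); ``nest`` is a newick
    template with {label} placeholders for each clade subtree.
    """
    groups: dict[str, str] = {}
    subtrees: dict[str, str] = {}
    for clade_label, group, n in clades:
        tips = []
        for i in range(1, n + 1):
            sp = f"{clade_label}_sp{i:02d}"
            groups[sp] = group
            tips.append(f"{sp}:{within}")
        # ladderized caterpillar inside the clade keeps polytomies out
        sub = tips[0]
        for tip in tips[1:]:
            sub = f"({sub},{tip}):{within}"
        subtrees[clade_label] = f"({sub}){clade_label}:{stem}"
    return nest.format(**subtrees), groups


def default_vertebrate_config(seed: int = 0, indel_rate: float = 0.02) -> SimulationConfig:
    """Jawed-vertebrate-shaped IRF5-like family: 30 species, 5 groups.

    Carries an NES window (anchors hydrophobic-constrained at spacing
    2/2, spacers free) at reference positions 150-161, a pinned
    serine-rich region at 447-468 identical across the family, and a
    3-residue YDG signature window at 64-66.
    """
    clades = [
        ("Mammalia", "Mammalia", 6),
        ("Aves", "Aves", 6),
        ("Archelosauria", "Testudines_Crocodilia", 6),
        ("Amphibia", "Amphibia", 6),
        ("Actinopterygii", "Actinopterygii", 6),
    ]
    nest = "(({Mammalia},({Aves},{Archelosauria}):0.05,{Amphibia}):0.08,{Actinopterygii})Gnathostomata;"
    newick, groups = _clade_newick(clades, nest)

    phi = SiteConstraint(SET, HYDROPHOBIC)
    free = SiteConstraint(FREE)
    # the annotated window runs three residues past the last anchor; those
    # tail positions are slow-evolving (like the real logos) which also
    # keeps the window edge unambiguous for the aligner
    tail = SiteConstraint(SET, AMINO_ACIDS)
    nes_sites = [phi, free, free, phi, free, free, phi, free, phi, tail, tail, tail]
    srr_motif = "SSSESLLDELLSSPSSSVPSES"  # pinned; serine-rich like the real SRR
    srr_sites = [SiteConstraint(FIXED, c) for c in srr_motif]
    sig_sites = [SiteConstraint(INHERIT) for _ in range(3)]
    return SimulationConfig(
        newick=newick,
        root_length=500,
        windows=[
            WindowSpec("signature", 64, 66, sig_sites, root_motif="YDG"),
            WindowSpec("NES", 150, 161, nes_sites),
            WindowSpec("SRR", 447, 468, srr_sites),
        ],
        site_rate=0.5,
        indel_rate=indel_rate,
        subfamily="IRF5",
        taxon_groups=groups,
        seed=seed,
    )


def default_bird_config(
    seed: int = 0,
    subfamily: str = "IRF5",
    indel_rate: float = 0.02,
    include_cuckoo_homoplasy: bool = False,
) -> SimulationConfig:
    """58-species bird family for the signature-motif survey.

    For IRF5 the signature transitions are planted on the named stem
    branches — YDG->FDG into Neoaves, FDG->LDG into Passeriformes,
    LDG->VDG into Passeridae — nested and homoplasy-free, so 13 species
    keep YDG (Palaeognathae + Galloanserae), 30 show FDG, 10 LDG and 5
    VDG. For IRF6 no transitions are planted and YDG is universal. The
    optional cuckoo flag plants an additional independent FDG->LDG on one
    Neoaves tip (homoplasy; off by default).
    """
    clades = [
        ("Palaeognathae", "Aves", 5),
        ("Galloanserae", "Aves", 8),
        ("Neoavian", "Aves", 30),
        ("Passerida", "Aves", 10),
        ("Passeridae", "Aves", 5),
    ]
    nest = (
        "({Palaeognathae},({Galloanserae},({Neoavian},({Passerida},{Passeridae})"
        "Passeriformes:0.06)Neoaves:0.06):0.05)Aves;"
    )
    newick, groups = _clade_newick(clades, nest)
    sig_sites = [SiteConstraint(INHERIT) for _ in range(3)]
    transitions: list[PlantedTransition] = []
    if subfamily == "IRF5":
        transitions = [
            PlantedTransition("Neoaves", "signature", "YDG", "FDG"),
            PlantedTransition("Passeriformes", "signature", "FDG", "LDG"),
            PlantedTransition("Passeridae", "signature", "LDG", "VDG"),
        ]
        if include_cuckoo_homoplasy:
            transitions.append(
                PlantedTransition("Neoavian_sp01", "signature", "FDG", "LDG")
            )
    return SimulationConfig(
        newick=newick,
        root_length=130,
        windows=[WindowSpec("signature", 64, 66, sig_sites, root_motif="YDG")],
        site_rate=0.6,
        indel_rate=indel_rate,
        transitions=transitions,
        subfamily=subfamily,
        taxon_groups=groups,
        seed=seed,
    )


def synthetic_interface_records(
    seed: int = 0,
) -> dict[str, dict[str, ProteinRecord]]:
    """Synthetic stand-in for the STAT2/IRF9 interface sequence panel.

    Real accession-anchored records (mouse/human STAT2 and IRF9 plus two
    cartilaginous-fish candidates) cannot be bundled, so this builds
    synthetic sequences that reproduce the panel's documented geometry:
    F at STAT2 position 174; L/A/F/Q at IRF9 positions 274/276/283/285;
    increasing divergence (and scattered indels away from the interface)
    toward the fish pairs; and an X at the residue homologous to IRF9
    reference position 258 in the shark-like record, mimicking a
    single-'n' CDS insertion, for the consensus sanitization path. Keys: pair name ("mouse", "human",
    "stingray", "shark") -> role ("STAT2" | "IRF9") -> record.
    """
    rng = np.random.default_rng(seed)
    contacts = {"STAT2": {174: "F"}, "IRF9": {274: "L", 276: "A", 283: "F", 285: "Q"}}
    lengths = {"STAT2": 320, "IRF9": 400}
    base: dict[str, str] = {}
    for role, L in lengths.items():
        seq = list(rng.choice(list(AMINO_ACIDS), size=L))
        for pos, aa in contacts[role].items():
            seq[pos - 1] = aa
        if role == "IRF9":
            seq[257] = "S"  # consensus residue behind the shark record's X
        base[role] = "".join(seq)

    divergence = {"mouse": 0.0, "human": 0.08, "stingray": 0.25, "shark": 0.25}
    panel: dict[str, dict[str, ProteinRecord]] = {}
    for species, p in divergence.items():
        panel[species] = {}
        for role, L in lengths.items():
            seq = list(base[role])
            protected = set(contacts[role]) | {258}
            for pos0 in range(L):
                if pos0 + 1 in protected:
                    continue
                if rng.random() < p:
                    seq[pos0] = str(rng.choice(list(AMINO_ACIDS)))
            # the undetermined residue is planted before the indels so it
            # sits at the position homologous to reference position 258
            if species == "shark" and role == "IRF9":
                seq[257] = "X"
            # short indels far from the interface, fish pairs only
            if p >= 0.2:
                del seq[L - 8 : L - 5]
                seq[10:10] = list(rng.choice(list(AMINO_ACIDS), size=2))
            panel[species][role] = ProteinRecord(
                id=f"{species}_{role}",
                sequence="".join(seq),
                species=species,
                subfamily=role,
                accession=f"SYN_{species}_{role}",
            )
    return panel


# ---------------------------------------------------------------------------
# Fixture emission


def emit_fixture(
    records: list[ProteinRecord],
    truth: SyntheticTruth,
    newick: str,
    outdir: str | Path,
    prefix: str = "family",
) -> dict[str, Path]:
    """Write FASTA + metadata TSV + newick + truth JSON, loadable by seq_io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{prefix}.fasta",
        "metadata": outdir / f"{prefix}.meta.tsv",
        "tree": outdir / f"{prefix}.nwk",
        "truth": outdir / f"{prefix}.truth.json",
    }
    write_fasta(records, paths["fasta"])
    meta = pd.DataFrame(
        [
            {
                "seq_id": r.id,
                "species": r.species,
                "taxon_group": r.taxon_group,
                "subfamily": r.subfamily,
                "accession": r.accession,
            }
            for r in records
        ]
    )
    write_metadata(meta, paths["metadata"])
    paths["tree"].write_text(newick + ("\n" if not newick.endswith("\n") else ""))
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    return paths


def load_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_dict(json.loads(Path(path).read_text()))
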