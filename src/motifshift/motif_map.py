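"""DBD signature-motif extraction, clade tallies, and parsimony histories.

The IRF5/6 subfamily carries a diagnostic 3-residue motif in the
DNA-binding domain — YDG in most vertebrates, shifted to FDG, LDG and
VDG in nested bird lineages. The motif is located positionally, by
lifting the reference motif coordinates onto each ortholog, never by
searching for the literal string: a derived variant must still be found
at the homologous position.

Substitution histories on the species taxonomy are inferred by unit-cost
(Fitch-style) parsimony, generalized to multifurcating trees. The
implementation is a Sankoff dynamic program over the observed state set,
which also counts the optimal labelings exactly so uniqueness can be
reported rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .align_anchor import LiftedRegion

#: default named motif classes; anything else is "other"
DEFAULT_CLASSES = ("YDG", "FDG", "LDG", "VDG")


@dataclass
class MotifAssignment:
    seq_id: str
    motif: str
    class_label: str
    position: int | None
    species: str = ""
    missing: bool = False


@dataclass
class Transition:
    parent: str
    child: str
    from_state: str
    to_state: str


@dataclass
class ParsimonyResult:
    min_changes: int
    node_states: dict[str, set[str]]  # per-node optimal-root-state candidates
    labeling: dict[str, str]  # one optimal labeling, node label -> state
    transitions: list[Transition]
    is_unique: bool
    n_optimal_labelings: int


def extract_signature(
    lifted: LiftedRegion, classes: tuple[str, ...] = DEFAULT_CLASSES
) -> MotifAssignment:
    """Classify the lifted 3-residue signature window of one ortholog."""
    if lifted.status != "complete":
        return MotifAssignment(
            seq_id=lifted.query_id, motif=lifted.subsequence, class_label="other",
            position=lifted.q_start, missing=True,
        )
    if len(lifted.subsequence) != 3:
        raise ValueError(
            f"signature window for {lifted.query_id!r} has length "
            f"{len(lifted.subsequence)}, expected 3"
        )
    motif = lifted.subsequence.upper()
    label = motif if motif in classes else "other"
    return MotifAssignment(
        seq_id=lifted.query_id, motif=motif, class_label=label,
        position=lifted.q_start,
    )


# ---------------------------------------------------------------------------
# Clade tallies


def _node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


def tally_by_clade(
    assignments: list[MotifAssignment],
    tree: dendropy.Tree,
    clade_labels: list[str],
) -> pd.DataFrame:
    """Species counts per (clade x motif class).

    Each assignment's species must be a tree leaf. A species under nested
    requested clades is counted in each of them, so rows are per-clade
    totals like a figure's per-lineage counts, not a partition.
    """
    leaf_by_species: dict[str, dendropy.Node] = {}
    for leaf in tree.leaf_node_iter():
        label = _node_label(leaf)
        if label:
            leaf_by_species[label] = leaf
    missing = sorted(
        {a.species for a in assignments} - set(leaf_by_species)
    )
    if missing:
        raise ValueError(f"species not found in tree: {missing}")

    clade_nodes: dict[str, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        label = _node_label(node)
        if label in clade_labels:
            clade_nodes[label] = node
    absent = [c for c in clade_labels if c not in clade_nodes]
    if absent:
        raise ValueError(f"clade labels not found in tree: {absent}")

    classes = sorted({a.class_label for a in assignments})
    rows = []
    for clade in clade_labels:
        members = {
            _node_label(l) for l in clade_nodes[clade].leaf_iter()
        }
        counts = {cls: 0 for cls in classes}
        for a in assignments:
            if a.species in members:
                counts[a.class_label] += 1
        rows.append({"clade": clade, **counts})
    return pd.DataFrame(rows).set_index("clade")


# ---------------------------------------------------------------------------
# Parsimony


@dataclass
class _NodeDP:
    label: str
    cost: dict[str, float] = field(default_factory=dict)
    count: dict[str, int] = field(default_factory=dict)


def _ensure_labels(tree: dendropy.Tree) -> dict[dendropy.Node, str]:
    """Stable label per node; internal nodes without names get n<index>."""
    labels = {}
    counter = 0
    for node in tree.preorder_node_iter():
        label = _node_label(node)
        if not label:
            label = f"n{counter}"
        counter += 1
        labels[node] = label
    return labels


def parsimony_states(
    tree: dendropy.Tree, leaf_states: dict[str, str]
) -> ParsimonyResult:
    """Minimum-change history of a discrete character on a rooted tree.

    Unit substitution cost between any two distinct states; polytomies
    handled natively (the DP sums over children, no binary assumption).
    One optimal labeling is reported deterministically: among equally
    optimal child states, the one with the strictly cheapest subtree is
    preferred (placing changes as close to the root as possible, which
    recovers a stepwise derived history over late parallel jumps), then
    the parent's state, then the alphabetically first. ``is_unique`` is
    exact — the number of optimal labelings is counted by the same DP.
    """
    labels = _ensure_labels(tree)
    leaves = [n for n in tree.leaf_node_iter()]
    unlabeled = [labels[n] for n in leaves if labels[n] not in leaf_states]
    if unlabeled:
        raise ValueError(f"leaves without a state: {sorted(unlabeled)}")
    states = sorted(set(leaf_states.values()))
    INF = float("inf")

    dp: dict[dendropy.Node, _NodeDP] = {}
    for node in tree.postorder_node_iter():
        entry = _NodeDP(label=labels[node])
        if node.is_leaf():
            obs = leaf_states[labels[node]]
            for s in states:
                entry.cost[s] = 0.0 if s == obs else INF
                entry.count[s] = 1 if s == obs else 0
        else:
            for s in states:
                total, ways = 0.0, 1
                for child in node.child_nodes():
                    cdp = dp[child]
                    best = min(
                        cdp.cost[t] + (0 if t == s else 1) for t in states
                    )
                    nways = sum(
                        cdp.count[t]
                        for t in states
                        if cdp.cost[t] + (0 if t == s else 1) == best
                    )
                    total += best
                    ways *= nways
                entry.cost[s] = total
                entry.count[s] = ways
        dp[node] = entry

    root = tree.seed_node
    min_changes = min(dp[root].cost[s] for s in states)
    n_optimal = sum(
        dp[root].count[s] for s in states if dp[root].cost[s] == min_changes
    )
    root_candidates = {s for s in states if dp[root].cost[s] == min_changes}

    # root ties: majority leaf state, then the state of the earliest leaf
    # in tree order (in practice the outgroup side), for determinism
    leaf_order = [leaf_states[labels[n]] for n in leaves]
    state_count = {s: leaf_order.count(s) for s in states}
    first_index = {s: leaf_order.index(s) for s in states}

    # deterministic top-down traceback
    labeling: dict[str, str] = {}
    transitions: list[Transition] = []

    def pick(entry: _NodeDP, cands: list[str], prefer: str | None) -> str:
        cheapest = min(entry.cost[t] for t in cands)
        cands = [t for t in cands if entry.cost[t] == cheapest]
        if prefer is not None and prefer in cands:
            return prefer
        return sorted(cands)[0]

    order: list[tuple[dendropy.Node, str | None]] = [(root, None)]
    while order:
        node, parent_state = order.pop()
        entry = dp[node]
        if parent_state is None:
            cands = sorted(
                (s for s in states if entry.cost[s] == min_changes),
                key=lambda s: (-state_count[s], first_index[s]),
            )[:1]
        else:
            best = min(
                entry.cost[t] + (0 if t == parent_state else 1) for t in states
            )
            cands = [
                t
                for t in states
                if entry.cost[t] + (0 if t == parent_state else 1) == best
            ]
        state = pick(entry, cands, parent_state)
        labeling[entry.label] = state
        if parent_state is not None and state != parent_state:
            parent_label = labels[node.parent_node]
            transitions.append(
                Transition(parent_label, entry.label, parent_state, state)
            )
        for child in node.child_nodes():
            order.append((child, state))

    node_states = {labels[root]: root_candidates}
    return ParsimonyResult(
        min_changes=int(min_changes),
        node_states=node_states,
        labeling=labeling,
        transitions=sorted(
            transitions, key=lambda t: (t.parent, t.child)
        ),
        is_unique=(n_optimal == 1),
        n_optimal_labelings=int(n_optimal),
    )
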