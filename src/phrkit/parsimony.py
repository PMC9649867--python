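"""Parsimony analysis of DNA-repair activity over the cryptochrome/photolyase family.

Each tip (a collapsed CPF clade) carries an activity state built from two
binary traits: CPD repair and 6-4 photoproduct repair. The module counts
minimum character changes on a rooted tree (Fitch/Hartigan, correct on
polytomies), reconstructs ancestral states and per-branch gain/loss events
via Hartigan most-parsimonious-reconstruction state sets with prefer-parent
resolution, and compares candidate rootings under an asymmetric
(Dollo-like) Sankoff cost model — unordered Fitch scores are invariant
under rerooting, so only an asymmetric model makes "fewest changes across
evolution" decidable between rootings.

Also ships a desk-scale distance pipeline (p-distance + neighbor joining)
so trees can be built offline from an alignment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import skbio

from .records import Msa

__all__ = [
    "ActivityStates",
    "EventReport",
    "parse_newick",
    "write_newick",
    "reroot",
    "fitch_count",
    "sankoff_cost",
    "compare_rootings",
    "reconstruct_events",
    "pdistance_matrix",
    "nj_tree",
    "cpf_clade_tree",
]

# activity state -> (cpd repair, 6-4 repair)
STATE_TRAITS = {
    "CPD": (1, 0),
    "SIX4": (0, 1),
    "DUAL": (1, 1),
    "CRY_NONE": (0, 0),
}


@dataclass(frozen=True)
class ActivityStates:
    """Tip -> activity state over {CPD, SIX4, DUAL, CRY_NONE}."""

    states: dict

    def __post_init__(self) -> None:
        for tip, s in self.states.items():
            if s not in STATE_TRAITS:
                raise ValueError(f"tip {tip!r}: unknown state {s!r}")

    def trait(self, name: str) -> dict:
        idx = {"cpd": 0, "six4": 1}[name]
        return {tip: STATE_TRAITS[s][idx] for tip, s in self.states.items()}

    def composite(self) -> dict:
        """Binary composite trait: CPD activity lost AND 6-4 activity gained."""
        return {tip: int(STATE_TRAITS[s] == (0, 1)) for tip, s in self.states.items()}


def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True, rooting="force-rooted")
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def _leafset(node) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _find_edge(tree: dendropy.Tree, edge):
    """Locate the edge subtending a tip (str) or a clade (iterable of tips)."""
    want = frozenset([edge]) if isinstance(edge, str) else frozenset(edge)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if _leafset(node) == want:
            return node.edge
    raise ValueError(f"no edge subtends {sorted(want)}")


def reroot(tree: dendropy.Tree, edge) -> dendropy.Tree:
    """Return a new tree rooted on the branch identified by ``edge``
    (a tip label or an iterable of tip labels naming a clade); the root
    bisects the chosen branch, leaving the unrooted topology unchanged."""
    new = tree.clone(depth=1)
    target = _find_edge(new, edge)
    length = target.length
    new.is_rooted = True
    new.reroot_at_edge(target, update_bipartitions=False,
                       length1=None if length is None else length / 2.0,
                       length2=None if length is None else length / 2.0)
    # drop a degree-2 old root left behind by the re-rooting, if any
    new.suppress_unifurcations()
    return new


def _tip_state(node, states: dict):
    label = node.taxon.label if node.taxon else None
    if label not in states:
        raise ValueError(f"no state given for tip {label!r}")
    return states[label]


def _hartigan_up(tree: dendropy.Tree, states: dict) -> int:
    """Bottom-up Hartigan pass; annotates VU/VL sets, returns min change count."""
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.VU = frozenset([_tip_state(node, states)])
            node.VL = frozenset()
        else:
            votes: dict = {}
            for child in node.child_nodes():
                for s in child.VU:
                    votes[s] = votes.get(s, 0) + 1
            k = max(votes.values())
            node.VU = frozenset(s for s, v in votes.items() if v == k)
            node.VL = frozenset(s for s, v in votes.items() if v == k - 1)
            changes += len(node.child_nodes()) - k
    return changes


def fitch_count(tree: dendropy.Tree, states: dict) -> int:
    """Minimum number of unordered state changes on a rooted tree
    (Hartigan's generalization of Fitch, valid for polytomies)."""
    return _hartigan_up(tree, states)


def sankoff_cost(tree: dendropy.Tree, states: dict, cost: dict,
                 origin_state=None) -> float:
    """Minimum weighted change count under an asymmetric cost matrix.

    ``cost`` maps (from_state, to_state) to a non-negative cost. With
    ``origin_state=None`` the root state is free (minimized over). When an
    ``origin_state`` is given, the root is treated as descending from an
    implicit ancestor in that state and the stem transition is charged too —
    this is what makes scores of alternative rootings comparable under an
    asymmetric model, since otherwise rooting inside a derived group simply
    converts expensive gains into cheap losses. Directed: the result depends
    on the rooting whenever the matrix is asymmetric.
    """
    alphabet = sorted({s for pair in cost for s in pair} | set(states.values()))
    inf = float("inf")
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            obs = _tip_state(node, states)
            node.SK = {s: (0.0 if s == obs else inf) for s in alphabet}
        else:
            node.SK = {}
            for s in alphabet:
                total = 0.0
                for child in node.child_nodes():
                    total += min(cost.get((s, t), 0.0 if s == t else inf) + child.SK[t]
                                 for t in alphabet)
                node.SK[s] = total
    root = tree.seed_node.SK
    if origin_state is None:
        return min(root.values())
    return min(cost.get((origin_state, s), 0.0 if s == origin_state else inf) + c
               for s, c in root.items())


def _binary_cost(gain: float, loss: float) -> dict:
    return {(0, 0): 0.0, (1, 1): 0.0, (0, 1): gain, (1, 0): loss}


DEFAULT_TRAIT_ORIGINS = {"cpd": None, "six4": 0}


def compare_rootings(tree: dendropy.Tree, candidate_edges, states: ActivityStates,
                     gain_cost: float = 2.0, loss_cost: float = 1.0,
                     trait_origins: dict | None = None) -> tuple[pd.DataFrame, list]:
    """Score candidate root placements by total asymmetric parsimony cost.

    For each candidate edge the tree is rerooted there and the Sankoff cost
    of the CPD trait plus the 6-4 trait is computed with gain cost
    ``gain_cost`` > loss cost ``loss_cost`` (complex-trait gain is the
    expensive move). By default the derived 6-4 trait is anchored absent at
    an implicit origin above the root — the capability whose independent
    gains are being counted cannot be primitively present, and without that
    anchor any rooting inside a 6-4 clade scores lower by simply inheriting
    the trait. The CPD root state is left free, so whether CPD repair is
    ancestral is inferred, not assumed. Returns (table, argmin list); ties
    are all listed.
    """
    if not candidate_edges:
        raise ValueError("candidate edge list is empty")
    origins = DEFAULT_TRAIT_ORIGINS if trait_origins is None else trait_origins
    cost = _binary_cost(gain_cost, loss_cost)
    rows = []
    for edge in candidate_edges:
        rooted = reroot(tree, edge)
        score = sum(sankoff_cost(rooted, states.trait(t), cost,
                                 origin_state=origins.get(t))
                    for t in ("cpd", "six4"))
        rows.append({"root": edge if isinstance(edge, str) else "+".join(sorted(edge)),
                     "score": score})
    table = pd.DataFrame(rows)
    best = table.score.min()
    argmin = table.loc[table.score == best, "root"].tolist()
    return table, argmin


@dataclass
class EventReport:
    """Per-branch trait transitions and per-trait gain/loss tallies."""

    events: list = field(default_factory=list)  # (trait, branch, from, to)
    gains: dict = field(default_factory=dict)
    losses: dict = field(default_factory=dict)
    fitch_minimum: dict = field(default_factory=dict)
    ancestral: dict = field(default_factory=dict)  # trait -> {branch label -> state}

    @property
    def total_score(self) -> int:
        return sum(self.fitch_minimum.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["trait", "branch", "from_state", "to_state"])


def _branch_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return "+".join(sorted(_leafset(node)))


def _mpr_resolve(tree: dendropy.Tree, states: dict) -> dict:
    """Hartigan MPR state sets resolved top-down, preferring the parent state."""
    _hartigan_up(tree, states)
    assignment: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.MPR = node.VU
            choice = min(node.MPR, key=repr)
        else:
            node.MPR = node.VU | (node.VL & {node.parent_node.assigned})
            parent = node.parent_node.assigned
            choice = parent if parent in node.MPR else min(node.VU, key=repr)
        node.assigned = choice
        assignment[node] = choice
    return assignment


def reconstruct_events(tree: dendropy.Tree, states: ActivityStates,
                       traits: dict | None = None) -> EventReport:
    """Reconstruct per-trait ancestral states and branch events on a rooted tree.

    ``traits`` defaults to the two elementary binary traits plus the
    composite "lost CPD and gained 6-4" trait. Each branch where a trait's
    resolved state flips is one event; the number of independent gains is
    the number of 0->1 flip branches (each starts a maximal subtree carrying
    the trait).
    """
    if traits is None:
        traits = {"cpd": states.trait("cpd"), "six4": states.trait("six4"),
                  "lost_cpd_gained_six4": states.composite()}
    report = EventReport()
    for name, tip_states in traits.items():
        report.fitch_minimum[name] = fitch_count(tree, tip_states)
        assignment = _mpr_resolve(tree, tip_states)
        gains = losses = 0
        anc = {}
        for node, state in assignment.items():
            anc[_branch_label(node)] = state
            if node.parent_node is None:
                continue
            parent = assignment[node.parent_node]
            if parent != state:
                report.events.append((name, _branch_label(node), parent, state))
                if (parent, state) == (0, 1):
                    gains += 1
                elif (parent, state) == (1, 0):
                    losses += 1
        report.gains[name] = gains
        report.losses[name] = losses
        report.ancestral[name] = anc
    return report


def pdistance_matrix(msa: Msa) -> skbio.DistanceMatrix:
    """Pairwise p-distance (mismatches / columns where neither is gapped)."""
    n = msa.n_rows
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa.rows[i], msa.rows[j]
            pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not pairs:
                raise ValueError(f"no shared columns between {msa.ids[i]} and {msa.ids[j]}")
            d = sum(1 for x, y in pairs if x != y) / len(pairs)
            mat[i, j] = mat[j, i] = d
    return skbio.DistanceMatrix(mat, ids=msa.ids)


def nj_tree(matrix: skbio.DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining; exact topology recovery on additive matrices."""
    arr = matrix.data
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix is not symmetric")
    sk = skbio.tree.nj(matrix)
    buf = io.StringIO()
    sk.write(buf, format="newick")
    return parse_newick(buf.getvalue())


# --- text-encoded CPF clade topology -------------------------------------
#
# Collapsed-clade tree of the cryptochrome/photolyase family as stated in
# the source genome/phylogeny analysis: the bifunctional CPD/(6-4) clade is
# sister to class II CPD photolyases, that pair is sister to the FeS-BCPs,
# the three together (an all-prokaryote clade) are sister to the remaining
# CPF clades, and SPL is the outgroup/root candidate family. The internal
# arrangement of the remaining ("rest") clades is not fixed by the text and
# is configurable here.

CPF_DEFAULT_REST = ("(((CPD_I,CPD_III),(plant_CRY,plant_PHR2)),"
                    "(ssDNA_PHR,(animal_CRY,eukaryotic_6_4)))")

CPF_ACTIVITY = {
    "SPL": "CPD",
    "CPD_I": "CPD",
    "CPD_II": "CPD",
    "CPD_III": "CPD",
    "plant_CRY": "CRY_NONE",
    "plant_PHR2": "CPD",
    "ssDNA_PHR": "CPD",
    "animal_CRY": "CRY_NONE",
    "eukaryotic_6_4": "SIX4",
    "FeS_BCP": "SIX4",
    "bifunctional": "DUAL",
}


def cpf_clade_tree(rest: str = CPF_DEFAULT_REST) -> tuple[dendropy.Tree, ActivityStates]:
    """The collapsed CPF clade tree (rooted at SPL) with repair-activity states."""
    newick = f"(SPL,({rest},((bifunctional,CPD_II),FeS_BCP)));"
    return parse_newick(newick), ActivityStates(dict(CPF_ACTIVITY))
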