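"""Dollo parsimony mapping of binary characters on a fixed rooted tree.

Under the Dollo principle a character is gained exactly once and may be lost
repeatedly.  On a rooted tree the minimal reconstruction is unique: the gain
sits at the most recent common ancestor of the state-1 leaves, and one loss
is placed on the branch to every maximal subtree inside that clade that
contains no state-1 leaf.  Leaves scored NA contribute neither to gain
placement nor to losses (an all-NA subtree is reported as unknown, not as a
loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd


def node_id(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label.replace(" ", "_")
    if node.label:
        return node.label.replace(" ", "_")
    return f"node{id(node) % 10**6}"


def ensure_node_labels(tree: dendropy.Tree) -> None:
    """Give unlabeled internal nodes stable preorder ids."""
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.taxon is None and not node.label:
            node.label = f"n{i}"


@dataclass
class DolloMap:
    character_id: str
    gain: str | None  # node id of the single gain, None if absent everywhere
    losses: list[str] = field(default_factory=list)  # branch = id of child node
    unknown: list[str] = field(default_factory=list)  # all-NA subtrees
    states: dict[str, int] = field(default_factory=dict)  # node id -> 0/1

    @property
    def n_losses(self) -> int:
        return len(self.losses)


def _leaf_states(tree: dendropy.Tree, states) -> dict[dendropy.Node, int | None]:
    out = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label.replace(" ", "_")
        if label not in states:
            raise KeyError(f"no state for leaf {label!r}")
        out[leaf] = states[label]
    return out


def dollo_map(states, tree: dendropy.Tree, character_id: str = "char") -> DolloMap:
    """Unique loss-minimal single-gain reconstruction of a binary character.

    ``states`` maps leaf labels to 1, 0, or None (NA).
    """
    ensure_node_labels(tree)
    leaf_state = _leaf_states(tree, states)

    ones: dict[dendropy.Node, int] = {}
    known: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = leaf_state[node]
            ones[node] = 1 if s == 1 else 0
            known[node] = 0 if s is None else 1
        else:
            ones[node] = sum(ones[ch] for ch in node.child_nodes())
            known[node] = sum(known[ch] for ch in node.child_nodes())

    result = DolloMap(character_id=character_id, gain=None)
    if ones[tree.seed_node] == 0:
        result.states = {node_id(n): 0 for n in tree.preorder_node_iter()}
        return result

    # gain at the MRCA of state-1 leaves: deepest node whose subtree holds all
    gain = tree.seed_node
    total = ones[tree.seed_node]
    while True:
        carriers = [ch for ch in gain.child_nodes() if ones[ch] > 0]
        if len(carriers) == 1 and ones[carriers[0]] == total:
            gain = carriers[0]
        else:
            break
    result.gain = node_id(gain)

    state: dict[str, int] = {node_id(n): 0 for n in tree.preorder_node_iter()}

    def descend(node):
        state[node_id(node)] = 1
        for ch in node.child_nodes():
            if ones[ch] > 0:
                descend(ch)
            elif known[ch] == 0:
                result.unknown.append(node_id(ch))
            else:
                result.losses.append(node_id(ch))

    descend(gain)
    result.states = state

    # replay check: the reconstruction must reproduce every observed leaf state
    for leaf, s in leaf_state.items():
        if s is not None:
            assert state[node_id(leaf)] == s, f"replay mismatch at {node_id(leaf)}"
    return result


def map_ir_losses(ir_presence, tree: dendropy.Tree) -> DolloMap:
    """Dollo map of IR presence/absence; losses reported by clade label."""
    m = dollo_map(ir_presence, tree, character_id="IR_presence")
    return m


def loss_clades(m: DolloMap, tree: dendropy.Tree) -> dict[str, list[str]]:
    """For each loss branch, the leaf labels of the subtree below it."""
    ensure_node_labels(tree)
    by_id = {node_id(n): n for n in tree.preorder_node_iter()}
    out = {}
    for nid in m.losses:
        node = by_id[nid]
        out[nid] = sorted(lf.taxon.label.replace(" ", "_")
                          for lf in node.leaf_iter())
    return out


def branch_event_table(maps: list[DolloMap], tree: dendropy.Tree) -> pd.DataFrame:
    """Per-branch tallies of character gains and losses (branch = child node id)."""
    ensure_node_labels(tree)
    rows = {node_id(n): {"gains": 0, "losses": 0, "gain_chars": [], "loss_chars": []}
            for n in tree.preorder_node_iter()}
    for m in maps:
        if m.gain is not None:
            rows[m.gain]["gains"] += 1
            rows[m.gain]["gain_chars"].append(m.character_id)
        for nid in m.losses:
            rows[nid]["losses"] += 1
            rows[nid]["loss_chars"].append(m.character_id)
    df = pd.DataFrame(
        [{"branch": nid, "gains": r["gains"], "losses": r["losses"],
          "gain_chars": ";".join(r["gain_chars"]), "loss_chars": ";".join(r["loss_chars"])}
         for nid, r in rows.items()]
    ).set_index("branch")
    return df


def pair_characters(orders, min_share: int = 2):
    """Binary adjacency characters (taxon -> 0/1) from signed gene orders."""
    from .gene_order import canonical_pairs

    per_taxon = {o.taxon: canonical_pairs(o) for o in orders}
    all_pairs = sorted({p for ps in per_taxon.values() for p in ps}, key=str)
    chars = {}
    for p in all_pairs:
        col = {t: (1 if p in ps else 0) for t, ps in per_taxon.items()}
        if sum(col.values()) >= min_share:
            chars[str(p)] = col
    return chars
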