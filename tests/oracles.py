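"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: breadth-first search
over the inversion graph for reversal distances, O(n^2) diagonal scans for
maximal repeats, direct sign-change counting for sidedness, and exhaustive
internal-state enumeration for Dollo parsimony.
"""

from collections import deque
from itertools import product

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def bfs_reversal_distances(m: int) -> dict[tuple[int, ...], int]:
    """Distance from every signed permutation of 1..m to the identity."""
    ident = tuple(range(1, m + 1))
    dist = {ident: 0}
    queue = deque([ident])
    while queue:
        p = queue.popleft()
        for i in range(m):
            for j in range(i, m):
                q = p[:i] + tuple(-x for x in reversed(p[i:j + 1])) + p[j + 1:]
                if q not in dist:
                    dist[q] = dist[p] + 1
                    queue.append(q)
    return dist


def sidedness_by_sign_changes(signs: list[int]) -> int:
    """Circular sided-block count = number of sign changes (min 1)."""
    n = len(signs)
    changes = sum(1 for i in range(n) if signs[i] != signs[i - 1])
    return changes if changes else 1


def brute_force_repeats(seq: str, min_len: int) -> set[tuple]:
    """All maximal forward/palindromic repeated pairs by full diagonal scans."""
    n = len(seq)
    out = set()
    # forward: diagonal shift d
    for d in range(1, n):
        x = 0
        while x + d < n:
            if seq[x] == seq[x + d]:
                x0 = x
                while x + d < n and seq[x] == seq[x + d]:
                    x += 1
                if x - x0 >= min_len:
                    out.add(((x0, x), (x0 + d, x + d), "forward"))
            else:
                x += 1
        # (pairs are recorded once with A left of B)
    # palindromic: anti-diagonal s = xa + xb, matching seq[x] == comp(seq[s-x])
    for s in range(2 * n - 1):  # s = position sum of paired bases
        lo = max(0, s - n + 1)
        x = lo
        while x <= s and x < n:
            y = s - x
            if y < n and seq[x] == _COMP.get(seq[y], "?"):
                x0 = x
                while x <= s and x < n and seq[x] == _COMP.get(seq[s - x], "?"):
                    x += 1
                a = (x0, x)
                b = (s - (x - 1), s - x0 + 1)
                if x - x0 >= min_len and a != b:
                    pair = tuple(sorted((a, b)))
                    out.add((pair[0], pair[1], "palindromic"))
            else:
                x += 1
    return out


def dollo_min_losses(tree, leaf_states: dict[str, int | None]) -> int | None:
    """Exhaustive minimum loss count over single-gain assignments.

    Enumerates 0/1 states for every internal node (and NA leaf); an
    assignment is admissible when at most one edge gains (0 -> 1, the root
    being born in its own state counts as the gain when 1).  Returns None
    when no state-1 leaf exists.
    """
    nodes = list(tree.preorder_node_iter())
    fixed = {}
    free = []
    any_one = False
    for node in nodes:
        if node.is_leaf():
            label = node.taxon.label.replace(" ", "_")
            s = leaf_states[label]
            if s is None:
                free.append(node)
            else:
                fixed[node] = s
                any_one = any_one or s == 1
        else:
            free.append(node)
    if not any_one:
        return None
    best = None
    for combo in product((0, 1), repeat=len(free)):
        state = dict(fixed)
        state.update(zip(free, combo))
        gains = 1 if state[tree.seed_node] == 1 else 0
        losses = 0
        ok = True
        for node in nodes:
            for ch in node.child_nodes():
                if state[node] == 0 and state[ch] == 1:
                    gains += 1
                    if gains > 1:
                        ok = False
                        break
                elif state[node] == 1 and state[ch] == 0:
                    losses += 1
            if not ok:
                break
        if ok and (best is None or losses < best):
            best = losses
    return best


def losses_identifiable(tree, states: dict[str, int], planted: set[str]) -> bool:
    """Planted loss branches are recoverable by single-gain parsimony iff
    (a) every planted branch lies strictly inside the MRCA clade of the
    remaining state-1 leaves (a loss clade hanging outside it is read as
    'never gained'), and (b) each planted branch's parent clade retains a
    state-1 leaf (sibling losses otherwise collapse into one deeper event)."""
    def label_of(node):
        return (node.taxon.label if node.taxon else node.label or "").replace(" ", "_")

    def leaf_labels(node):
        return [label_of(lf) for lf in node.leaf_iter()]

    ones = {l for l, s in states.items() if s == 1}
    if not ones:
        return False
    mrca = tree.seed_node
    while True:
        carriers = [ch for ch in mrca.child_nodes()
                    if ones & set(leaf_labels(ch))]
        if len(carriers) == 1 and ones <= set(leaf_labels(carriers[0])):
            mrca = carriers[0]
        else:
            break
    inside = {label_of(n) for n in mrca.preorder_iter()} - {label_of(mrca)}
    for node in tree.preorder_node_iter():
        label = label_of(node)
        if label in planted:
            if label not in inside:
                return False
            parent = node.parent_node
            if parent is None or not any(states[l] == 1 for l in leaf_labels(parent)):
                return False
    return True


def random_tree(rng, n_leaves: int, allow_polytomy: bool = False):
    """A random rooted tree over leaves L1..Ln (binary unless allowed)."""
    import dendropy

    labels = [f"L{i + 1}" for i in range(n_leaves)]
    rng.shuffle(labels)

    def build(group):
        if len(group) == 1:
            return group[0]
        max_parts = min(len(group), 3 if allow_polytomy else 2)
        k = 2 if max_parts == 2 else int(rng.integers(2, max_parts + 1))
        cuts = sorted(rng.choice(range(1, len(group)), size=k - 1, replace=False))
        parts, prev = [], 0
        for c in list(cuts) + [len(group)]:
            parts.append(group[prev:c])
            prev = c
        return "(" + ",".join(build(p) for p in parts) + ")"

    newick = build(labels) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted",
                             suppress_internal_node_taxa=True)
    return tree
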