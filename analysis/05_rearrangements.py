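"""Pairwise reversal distances across the simulated clade.

Exact Hannenhalli-Pevzner inversion distances between all collapsed gene
orders, checked against the planted event counts: the distance between two
tips can never exceed the number of inversions separating them on the tree.
"""

import dendropy

from common import RESULTS, load_bundle
from plastarch import extract_signed_gene_order, find_inverted_repeat
from plastarch import pairwise_distance_matrix
from plastarch.dollo import ensure_node_labels, node_id


def _path_inversions(tree, log, a, b):
    pdm = {}
    nodes = {node_id(n): n for n in tree.preorder_node_iter()}
    na, nb = nodes[a], nodes[b]
    mrca = tree.mrca(taxa=[na.taxon, nb.taxon])
    count = 0
    for tip in (na, nb):
        node = tip
        while node is not mrca:
            count += sum(1 for e in log.events_on_branch(node_id(node))
                         if e["type"] == "inversion")
            node = node.parent_node
    return count


def main():
    genomes, log = load_bundle()
    orders = []
    for g in genomes:
        ann = find_inverted_repeat(g.sequence, min_len=1000,
                                   features=g.gene_features())
        orders.append(extract_signed_gene_order(g, gene_filter=None,
                                                collapse_ir=True, ir=ann))
    dm = pairwise_distance_matrix(orders)
    out = RESULTS / "05_distance_matrix.tsv"
    dm.to_csv(out, sep="\t")
    print(dm.to_string())

    tree = dendropy.Tree.get(data=log.tree_newick, schema="newick",
                             rooting="force-rooted",
                             suppress_internal_node_taxa=True)
    ensure_node_labels(tree)
    taxa = list(dm.index)
    violations = 0
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            k = _path_inversions(tree, log, a, b)
            if dm.loc[a, b] > k:
                violations += 1
    print(f"\nmax distance {dm.values.max()}; "
          f"distance <= planted inversion count on all "
          f"{len(taxa) * (len(taxa) - 1) // 2} pairs "
          f"({violations} violations)")
    assert violations == 0
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
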