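"""Signed gene orders: sidedness and shared adjacencies.

Collapses one IR copy per genome, computes the sidedness index
C_s = (n - n_SB)/(n - 1) per tip, and builds the shared signed gene-pair
presence/absence matrix across the clade.
"""

import pandas as pd

from common import RESULTS, load_bundle
from plastarch import (extract_signed_gene_order, find_inverted_repeat,
                       shared_pair_matrix, sidedness_index)


def main():
    genomes, _ = load_bundle()
    orders = []
    rows = []
    for g in genomes:
        ann = find_inverted_repeat(g.sequence, min_len=1000,
                                   features=g.gene_features())
        o = extract_signed_gene_order(g, gene_filter=None, collapse_ir=True, ir=ann)
        orders.append(o)
        r = sidedness_index(o)
        rows.append({"taxon": o.taxon, "n": r.n, "n_sb": r.n_sb,
                     "Cs": round(r.cs, 4)})
    df = pd.DataFrame(rows).set_index("taxon")
    df.to_csv(RESULTS / "04_sidedness.tsv", sep="\t")
    print(df.to_string())
    print(f"\nC_s spans {df.Cs.min():.3f}-{df.Cs.max():.3f} across the clade")

    matrix = shared_pair_matrix(orders, min_share=5)
    matrix.to_tsv(RESULTS / "04_pair_matrix.tsv")
    print(f"{len(matrix.pairs)} gene pairs shared by >= 5 tips; "
          f"wrote {RESULTS}/04_sidedness.tsv and 04_pair_matrix.tsv")


if __name__ == "__main__":
    main()
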