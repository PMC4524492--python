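"""Small-repeat landscape of each simulated genome.

All maximal exact forward and palindromic repeats >= 30 bp (the large IR
excluded), masked non-overlappingly: repeated fraction, distinct-element
size histogram, and G+C of repeated vs unique sequence.
"""

import pandas as pd

from common import RESULTS, load_bundle
from plastarch import find_inverted_repeat, find_maximal_repeats, mask_and_summarize


def main():
    genomes, _ = load_bundle()
    rows = []
    for g in genomes:
        ann = find_inverted_repeat(g.sequence, min_len=1000,
                                   features=g.gene_features())
        hits = find_maximal_repeats(g.sequence, min_len=30, exclude_ir=ann)
        s = mask_and_summarize(g.sequence, hits)
        rows.append({"taxon": g.taxon,
                     "masked_percent": round(s.masked_percent, 2),
                     "n_elements": s.n_elements,
                     "gc_repeat": round(s.gc_repeat, 2) if s.masked_bp else None,
                     "gc_unique": round(s.gc_unique, 2),
                     **s.size_class_counts})
    df = pd.DataFrame(rows).set_index("taxon")
    out = RESULTS / "07_repeat_landscape.tsv"
    df.to_csv(out, sep="\t")
    print(df.to_string())
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
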