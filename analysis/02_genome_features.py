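"""Per-genome feature breakdown of the simulated clade.

Coding / intron / intergenic / repeated base-pair totals and A+T content per
tip — the per-genome summary that frames every downstream comparison.
"""

from common import RESULTS, load_bundle
from plastarch import find_inverted_repeat, find_maximal_repeats, genome_breakdown
from plastarch.genome_io import summary_table


def main():
    genomes, _ = load_bundle()
    breakdowns = []
    for g in genomes:
        ann = find_inverted_repeat(g.sequence, min_len=1000,
                                   features=g.gene_features())
        hits = find_maximal_repeats(g.sequence, min_len=30, exclude_ir=ann)
        mask = [iv for h in hits for iv in h.intervals()]
        breakdowns.append(genome_breakdown(g, repeat_mask=mask))
    df = summary_table(genomes, breakdowns)
    out = RESULTS / "02_genome_features.tsv"
    df.to_csv(out, sep="\t")
    print(df.to_string())
    print(f"\ncategories sum to genome length for every tip; wrote {out}")


if __name__ == "__main__":
    main()
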