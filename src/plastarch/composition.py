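"""Nucleotide composition: whole-genome A+T and G+C by codon position."""

from __future__ import annotations

from dataclasses import dataclass

_GC = frozenset("GCgc")
_UNAMBIG = frozenset("ACGTacgt")


@dataclass
class CodonGC:
    gc1: float
    gc2: float
    gc3: float
    n_codons: int

    def overall(self) -> float:
        return (self.gc1 + self.gc2 + self.gc3) / 3.0


def at_content(seq: str) -> float:
    """(A+T)/(A+C+G+T) x 100; ambiguity codes excluded from both sides."""
    if not seq:
        raise ValueError("empty sequence")
    tot = gc = 0
    for b in seq:
        if b in _UNAMBIG:
            tot += 1
            if b in _GC:
                gc += 1
    if tot == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * (tot - gc) / tot


def gc_by_codon_position(cds_list: list[str],
                         names: list[str] | None = None) -> CodonGC:
    """G+C fraction at codon positions 1/2/3 over a CDS concatenation.

    Every sequence must be in frame (length divisible by 3); ambiguity codes
    are excluded from both numerator and denominator at their position.
    """
    if not cds_list:
        raise ValueError("no coding sequences")
    gc = [0, 0, 0]
    tot = [0, 0, 0]
    n_codons = 0
    for idx, cds in enumerate(cds_list):
        if len(cds) % 3 != 0:
            name = names[idx] if names else f"sequence #{idx}"
            raise ValueError(f"{name}: length {len(cds)} not divisible by 3")
        n_codons += len(cds) // 3
        for i, b in enumerate(cds):
            if b in _UNAMBIG:
                p = i % 3
                tot[p] += 1
                if b in _GC:
                    gc[p] += 1
    if min(tot) == 0:
        raise ValueError("no unambiguous bases at some codon position")
    g1, g2, g3 = (100.0 * g / t for g, t in zip(gc, tot))
    return CodonGC(gc1=g1, gc2=g2, gc3=g3, n_codons=n_codons)


def coding_sequences(genome) -> tuple[list[str], list[str]]:
    """Extract in-frame CDS strings (5'->3') from an annotated genome."""
    from .ir import revcomp

    seqs, names = [], []
    for f in genome.gene_features():
        if f.kind != "CDS":
            continue
        parts = [genome.sequence[s:e] for s, e in f.spans]
        s = "".join(parts)
        if f.strand < 0:
            s = revcomp(s)
        seqs.append(s)
        names.append(f.symbol)
    return seqs, names
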