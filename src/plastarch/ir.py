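"""Inverted-repeat detection and quadripartite architecture.

The large IR is located as the longest pair of exact, non-overlapping,
reverse-complementary segments (seeded on shared k-mers against the reverse
complement and extended maximally).  The two single-copy segments between
the copies are named by length: LSC (longer) and SSC (shorter).  Intervals
are 0-based half-open; an interval with start > end wraps the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .fixtures import RDNA_OPERON
from .genome_io import GenomeRecord

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def interval_len(iv: tuple[int, int], n: int) -> int:
    s, e = iv
    return e - s if e >= s else n - s + e


def interval_contains(iv: tuple[int, int], sub: tuple[int, int], n: int) -> bool:
    """Does circular interval ``iv`` contain interval ``sub`` entirely?"""
    s, e = iv
    a, b = sub
    if e < s:
        e += n
    if b < a:
        b += n
    for shift in (0, n):
        if s <= a + shift and b + shift <= e:
            return True
    return False


def interval_overlap(iv: tuple[int, int], sub: tuple[int, int], n: int) -> int:
    """Overlap length between two circular intervals."""
    def segs(t):
        s, e = t
        return [(s, e)] if e >= s else [(s, n), (0, e)]

    tot = 0
    for s1, e1 in segs(iv):
        for s2, e2 in segs(sub):
            tot += max(0, min(e1, e2) - max(s1, s2))
    return tot


@dataclass
class IRAnnotation:
    ira: tuple[int, int]
    irb: tuple[int, int]
    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ir_len: int
    contains_rdna: bool = False
    genome_len: int = 0

    def validate(self, seq: str) -> None:
        n = len(seq)
        assert seq[self.ira[0]:self.ira[1]] == revcomp(seq[self.irb[0]:self.irb[1]]), \
            "IR copies are not exact reverse complements"
        assert (2 * self.ir_len + interval_len(self.lsc, n)
                + interval_len(self.ssc, n) == n), "quadripartite lengths do not sum"
        assert interval_len(self.lsc, n) >= interval_len(self.ssc, n)


def _seed_pairs(seq: str, k: int):
    """Candidate (i, j) with seq[i:i+k] == revcomp(seq[j:j+k])."""
    n = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    rc = revcomp(seq)
    for p in range(n - k + 1):
        kmer = rc[p:p + k]
        if kmer in index:
            j = n - p - k
            for i in index[kmer]:
                if i < j:
                    yield i, j


def find_inverted_repeat(seq: str, min_len: int = 1000, k: int = 25,
                         features=None) -> IRAnnotation | None:
    """Locate the large IR; ``None`` when no candidate reaches ``min_len``.

    Ties in length prefer the candidate whose copies contain *rrs* (the IR
    normally encodes the rRNA operon), then the leftmost IRA start.
    Candidates whose maximally extended copies overlap are rejected.
    """
    n = len(seq)
    if n <= 2 * min_len:
        return None
    k = min(k, min_len)
    seen_diag: dict[int, list[tuple[int, int]]] = {}
    candidates: list[tuple[int, int, int, int]] = []
    for i, j in _seed_pairs(seq, k):
        diag = i + j + k  # a0 + b1 is invariant under palindromic extension
        covered = any(a0 <= i and i + k <= a1 for a0, a1 in seen_diag.get(diag, ()))
        if covered:
            continue
        a0, a1, b0, b1 = i, i + k, j, j + k
        while a1 < n and b0 > 0 and seq[a1] == revcomp(seq[b0 - 1]):
            a1 += 1
            b0 -= 1
        while a0 > 0 and b1 < n and seq[a0 - 1] == revcomp(seq[b1]):
            a0 -= 1
            b1 += 1
        seen_diag.setdefault(diag, []).append((a0, a1))
        if a1 - a0 < min_len:
            continue
        if a1 > b0:  # copies overlap: one long palindrome, not a separated IR
            log.info("overlapping inverted copies at %d-%d/%d-%d skipped", a0, a1, b0, b1)
            continue
        candidates.append((a0, a1, b0, b1))
    if not candidates:
        return None

    rrs_spans = []
    if features is not None:
        rrs_spans = [(f.start, f.end) for f in features if f.symbol == "rrs"]

    def contains_rrs(c):
        a0, a1, b0, b1 = c
        return any(a0 <= s and e <= a1 or b0 <= s and e <= b1 for s, e in rrs_spans)

    best_len = max(c[1] - c[0] for c in candidates)
    top = [c for c in candidates if c[1] - c[0] == best_len]
    top.sort(key=lambda c: (not contains_rrs(c), c[0]))
    a0, a1, b0, b1 = top[0]

    inner = (a1, b0)
    outer = (b1 % n, a0)
    if interval_len(inner, n) >= interval_len(outer, n):
        lsc, ssc = inner, outer
    else:
        lsc, ssc = outer, inner
    ann = IRAnnotation(ira=(a0, a1), irb=(b0, b1), lsc=lsc, ssc=ssc,
                       ir_len=a1 - a0, contains_rdna=bool(rrs_spans) and contains_rrs(top[0]),
                       genome_len=n)
    ann.validate(seq)
    return ann


@dataclass
class PartitionProfile:
    """Per-gene region assignment against the ancestral partition pattern."""

    assignments: list[tuple[str, str, str]]  # (symbol, region, ancestral_side)
    deviations: list[str] = field(default_factory=list)

    def region_of(self, symbol: str) -> str:
        for sym, region, _ in self.assignments:
            if sym == symbol:
                return region
        raise KeyError(symbol)


def classify_partitioning(g: GenomeRecord, ir: IRAnnotation,
                          reference: dict[str, str] | None = None) -> PartitionProfile:
    """Assign each gene to IR / LSC / SSC and flag ancestral-side deviations.

    A gene lying entirely within an IR copy is IR; a gene spanning an IR/SC
    junction is assigned to the single-copy side it reaches into.
    """
    if reference is None:
        from .fixtures import load_ancestral_sides
        reference = load_ancestral_sides()
    n = len(g.sequence)
    seen: dict[str, str] = {}
    for f in g.gene_features():
        span = (f.start, f.end)
        if f.symbol in seen:
            continue
        if interval_contains(ir.ira, span, n) or interval_contains(ir.irb, span, n):
            region = "IR"
        else:
            lsc_ov = interval_overlap(ir.lsc, span, n)
            ssc_ov = interval_overlap(ir.ssc, span, n)
            region = "LSC" if lsc_ov >= ssc_ov else "SSC"
        seen[f.symbol] = region
    assignments = []
    deviations = []
    for sym, region in seen.items():
        side = reference.get(sym, "unassigned")
        assignments.append((sym, region, side))
        if (side == "lsc_side" and region == "SSC") or (side == "ssc_side" and region == "LSC"):
            deviations.append(sym)
    return PartitionProfile(assignments=assignments, deviations=sorted(deviations))


@dataclass
class OperonReport:
    genes: tuple[str, ...]
    breakpoints: list[tuple[str, str]]
    orientation: str  # toward_SSC | toward_LSC | mixed | not_applicable


def rdna_operon_check(o, genome: GenomeRecord | None = None,
                      ir: IRAnnotation | None = None,
                      spacer_max: int = 3000) -> OperonReport:
    """Check integrity and orientation of the rDNA operon
    rrs - trnI(gau) - trnA(ugc) - rrl - rrf.

    An internal adjacency is broken when the two genes are not adjacent in
    the collapsed gene order, not colinear in sign, or (when coordinates are
    available) separated by more than ``spacer_max`` bp.
    """
    idx = {g: i for i, (g, _) in enumerate(o.genes)}
    sign = {g: s for g, s in o.genes}
    missing = [g for g in RDNA_OPERON if g not in idx]
    if missing:
        raise ValueError(f"rDNA operon gene(s) missing from order: {missing}")
    n = o.n
    breakpoints = []
    for g1, g2 in zip(RDNA_OPERON, RDNA_OPERON[1:]):
        p1, p2, s1, s2 = idx[g1], idx[g2], sign[g1], sign[g2]
        forward = (p2 == (p1 + 1) % n) and s1 > 0 and s2 > 0
        reverse = (p1 == (p2 + 1) % n) and s1 < 0 and s2 < 0
        intact = forward or reverse
        if intact and genome is not None:
            f1 = [f for f in genome.gene_features() if f.symbol == g1]
            f2 = [f for f in genome.gene_features() if f.symbol == g2]
            if f1 and f2:
                gaps = [min(abs(a.start - b.end), abs(b.start - a.end),
                            len(genome.sequence) - abs(a.start - b.end))
                        for a in f1 for b in f2]
                if min(gaps) > spacer_max:
                    intact = False
        if not intact:
            breakpoints.append((g1, g2))
    signs = [sign[g] for g in RDNA_OPERON]
    if ir is None or genome is None:
        orientation = "not_applicable"
    elif breakpoints and len(set(signs)) > 1:
        orientation = "mixed"
    else:
        orientation = _operon_orientation(genome, ir, signs)
    return OperonReport(genes=RDNA_OPERON, breakpoints=breakpoints, orientation=orientation)


def _operon_orientation(genome: GenomeRecord, ir: IRAnnotation, signs) -> str:
    """Does transcription (rrs -> rrf) run toward the SSC or the LSC?

    Decided inside the IR copy that holds the operon: the operon's 3' end
    (rrf) is compared against the two junctions of that copy.
    """
    n = len(genome.sequence)
    feats = {f.symbol: f for f in genome.gene_features()
             if f.symbol in ("rrs", "rrf")
             and (interval_contains(ir.ira, (f.start, f.end), n)
                  or interval_contains(ir.irb, (f.start, f.end), n))}
    if "rrs" not in feats or "rrf" not in feats:
        return "not_applicable"
    rrf = feats["rrf"]
    in_ira = interval_contains(ir.ira, (rrf.start, rrf.end), n)
    # the inner single-copy segment sits between IRA's right end and IRB's
    # left end; the SSC therefore touches IRA's right junction iff it is the
    # inner segment (and IRB's right junction iff it is the outer one)
    ssc_is_inner = ir.ssc == (ir.ira[1], ir.irb[0])
    ssc_on_right = ssc_is_inner if in_ira else not ssc_is_inner
    heading_right = rrf.strand > 0  # + strand: rrs -> rrf runs left to right
    return "toward_SSC" if heading_right == ssc_on_right else "toward_LSC"


def junction_table(ir: IRAnnotation, genome: GenomeRecord) -> "pd.DataFrame":
    """The four junction positions with their flanking genes (TSV-ready)."""
    import pandas as pd

    n = len(genome.sequence)
    junctions = {
        "J_LA": ir.ira[0], "J_AS": ir.ira[1] % n,
        "J_SB": ir.irb[0], "J_BL": ir.irb[1] % n,
    }
    feats = sorted(genome.gene_features(), key=lambda f: f.start)
    rows = []
    for name, pos in junctions.items():
        left = next((f.symbol for f in reversed(feats) if f.end <= pos), feats[-1].symbol)
        right = next((f.symbol for f in feats if f.start >= pos), feats[0].symbol)
        rows.append({"junction": name, "position": pos, "gene_left": left, "gene_right": right})
    return pd.DataFrame(rows).set_index("junction")


def regions_bed(ir: IRAnnotation, chrom: str) -> str:
    """IR/LSC/SSC coordinates as BED text (0-based, half-open)."""
    lines = []
    n = ir.genome_len
    for name, iv in (("IRA", ir.ira), ("IRB", ir.irb), ("LSC", ir.lsc), ("SSC", ir.ssc)):
        s, e = iv
        if e >= s:
            lines.append(f"{chrom}\t{s}\t{e}\t{name}")
        else:  # wrapped region emitted as two BED lines
            lines.append(f"{chrom}\t{s}\t{n}\t{name}")
            lines.append(f"{chrom}\t0\t{e}\t{name}")
    return "\n".join(lines) + "\n"
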