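"""Maximal exact repeat landscape of a plastome.

Finds all maximal exact repeated pairs of length >= a cutoff, both forward
(direct) and palindromic (the second copy is the reverse complement of the
first), by seeding on shared ``min_len``-mers and extending maximally —
every maximal pair of length >= L contains a shared L-mer, so seeding at the
cutoff is complete.  Hits are then masked non-overlappingly to summarise the
repeated fraction, a six-bin size histogram of distinct elements, and the
G+C content of repeated versus unique sequence.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .ir import IRAnnotation, interval_contains, revcomp

SIZE_CLASSES = ((30, 39), (40, 59), (60, 89), (90, 149), (150, 249), (250, None))


@dataclass(frozen=True)
class RepeatHit:
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    kind: str  # forward | palindromic
    length: int

    def intervals(self):
        return (self.interval_a, self.interval_b)


@dataclass
class RepeatSummary:
    genome_bp: int
    masked_bp: int
    masked_percent: float
    size_class_counts: dict[str, int]
    gc_repeat: float
    gc_unique: float
    gc_genome: float
    n_hits: int
    n_elements: int


def _verify(seq: str, hit: RepeatHit) -> None:
    a = seq[hit.interval_a[0]:hit.interval_a[1]]
    b = seq[hit.interval_b[0]:hit.interval_b[1]]
    if hit.kind == "forward":
        assert a == b, "forward hit fails identity"
    else:
        assert a == revcomp(b), "palindromic hit fails revcomp identity"
    # maximality: one-base extension on either side must break identity
    (a0, a1), (b0, b1) = hit.interval_a, hit.interval_b
    n = len(seq)
    if hit.kind == "forward":
        assert a0 == 0 or b0 == 0 or seq[a0 - 1] != seq[b0 - 1], "left-extensible"
        assert a1 == n or b1 == n or seq[a1] != seq[b1], "right-extensible"
    else:
        assert a0 == 0 or b1 == n or seq[a0 - 1] != revcomp(seq[b1]), "left-extensible"
        assert a1 == n or b0 == 0 or seq[a1] != revcomp(seq[b0 - 1]), "right-extensible"


def find_maximal_repeats(seq: str, min_len: int = 30,
                         exclude_ir: IRAnnotation | None = None,
                         kinds: tuple[str, ...] = ("forward", "palindromic"),
                         verify: bool = True) -> list[RepeatHit]:
    """All maximal exact forward/palindromic repeated pairs >= ``min_len``.

    With ``exclude_ir``, pairs whose two intervals both lie inside the IR
    copies are dropped (the IR itself is one giant palindromic repeat and is
    reported separately by the architecture stage).
    """
    seq = seq.upper()
    n = len(seq)
    if n < min_len:
        return []
    k = min_len
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)

    hits: set[RepeatHit] = set()

    if "forward" in kinds:
        done: dict[int, list[tuple[int, int]]] = {}  # diag j-i -> maximal a-intervals
        for positions in index.values():
            if len(positions) < 2:
                continue
            for ai in range(len(positions)):
                for bi in range(ai + 1, len(positions)):
                    i, j = positions[ai], positions[bi]
                    diag = j - i
                    if any(a0 <= i and i + k <= a1 for a0, a1 in done.get(diag, ())):
                        continue
                    a0, a1, b0, b1 = i, i + k, j, j + k
                    while a0 > 0 and b0 > 0 and seq[a0 - 1] == seq[b0 - 1]:
                        a0 -= 1
                        b0 -= 1
                    while a1 < n and b1 < n and seq[a1] == seq[b1]:
                        a1 += 1
                        b1 += 1
                    done.setdefault(diag, []).append((a0, a1))
                    hits.add(RepeatHit((a0, a1), (b0, b1), "forward", a1 - a0))

    if "palindromic" in kinds:
        rc = revcomp(seq)
        done_p: dict[int, list[tuple[int, int]]] = {}  # antidiag a0+b1 -> a-intervals
        for p in range(n - k + 1):
            kmer = rc[p:p + k]
            if kmer not in index:
                continue
            j = n - p - k  # forward-strand start of the reverse-complement copy
            for i in index[kmer]:
                if i > j:
                    continue
                diag = i + j + k
                if any(a0 <= i and i + k <= a1 for a0, a1 in done_p.get(diag, ())):
                    continue
                a0, a1, b0, b1 = i, i + k, j, j + k
                while a1 < n and b0 > 0 and seq[a1] == revcomp(seq[b0 - 1]):
                    a1 += 1
                    b0 -= 1
                while a0 > 0 and b1 < n and seq[a0 - 1] == revcomp(seq[b1]):
                    a0 -= 1
                    b1 += 1
                done_p.setdefault(diag, []).append((a0, a1))
                if (a0, a1) == (b0, b1):
                    continue  # a perfect self-palindrome is not a repeated pair
                if (b0, b1) < (a0, a1):
                    (a0, a1), (b0, b1) = (b0, b1), (a0, a1)
                hits.add(RepeatHit((a0, a1), (b0, b1), "palindromic", a1 - a0))

    out = []
    for h in hits:
        if h.length < min_len:
            continue
        if exclude_ir is not None:
            ir_zone = lambda iv: (interval_contains(exclude_ir.ira, iv, n)
                                  or interval_contains(exclude_ir.irb, iv, n))
            if ir_zone(h.interval_a) and ir_zone(h.interval_b):
                continue
        if verify:
            _verify(seq, h)
        out.append(h)
    return sorted(out, key=lambda h: (h.interval_a, h.interval_b, h.kind))


def _gc(seq_arr: np.ndarray, mask: np.ndarray) -> float:
    sel = seq_arr[mask]
    acgt = np.isin(sel, list(b"ACGT"))
    if not acgt.any():
        return float("nan")
    gc = np.isin(sel, list(b"GC")).sum()
    return 100.0 * gc / acgt.sum()


def mask_and_summarize(seq: str, hits: list[RepeatHit]) -> RepeatSummary:
    """Mask the union of hit intervals and summarise the repeat landscape.

    Distinct elements for the size histogram are the merged components of
    overlapping hit intervals, grouped by exact sequence identity (an
    exact-match simplification of repeat-family clustering).
    """
    seq = seq.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = np.zeros(n, dtype=bool)
    intervals = []
    for h in hits:
        for s, e in h.intervals():
            if not (0 <= s < e <= n):
                raise ValueError(f"interval ({s},{e}) outside genome of {n} bp")
            mask[s:e] = True
            intervals.append((s, e))
    masked_bp = int(mask.sum())
    # merged components of overlapping intervals
    comps = []
    for s, e in sorted(intervals):
        if comps and s <= comps[-1][1]:
            comps[-1] = (comps[-1][0], max(comps[-1][1], e))
        else:
            comps.append((s, e))
    elements = {seq[s:e] for s, e in comps}
    counts = Counter()
    for el in elements:
        counts[_size_class(len(el))] += 1
    gc_rep = _gc(arr, mask)
    gc_uni = _gc(arr, ~mask)
    gc_gen = _gc(arr, np.ones(n, dtype=bool))
    # length-weighted recombination identity
    if masked_bp and masked_bp < n:
        recombined = (masked_bp * gc_rep + (n - masked_bp) * gc_uni) / n
        assert math.isclose(recombined, gc_gen, abs_tol=1e-9)
    return RepeatSummary(
        genome_bp=n, masked_bp=masked_bp,
        masked_percent=100.0 * masked_bp / n if n else 0.0,
        size_class_counts={_class_label(lo, hi): counts.get(_class_label(lo, hi), 0)
                           for lo, hi in SIZE_CLASSES},
        gc_repeat=gc_rep, gc_unique=gc_uni, gc_genome=gc_gen,
        n_hits=len(hits), n_elements=len(elements))


def _class_label(lo: int, hi: int | None) -> str:
    return f"{lo}-{hi}" if hi else f">={lo}"


def _size_class(length: int) -> str:
    for lo, hi in SIZE_CLASSES:
        if lo <= length and (hi is None or length <= hi):
            return _class_label(lo, hi)
    return _class_label(*SIZE_CLASSES[0])  # sub-cutoff lengths cannot occur


def hits_table(hits: list[RepeatHit], chrom: str = "genome"):
    """BED-pair style table (chrom, startA, endA, startB, endB, kind, length)."""
    import pandas as pd

    return pd.DataFrame([
        {"chrom": chrom, "startA": h.interval_a[0], "endA": h.interval_a[1],
         "startB": h.interval_b[0], "endB": h.interval_b[1],
         "kind": h.kind, "length": h.length}
        for h in hits
    ])
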