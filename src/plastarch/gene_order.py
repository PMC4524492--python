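"""Signed circular gene orders, sidedness, and gene-adjacency matrices.

A plastome's architecture is summarised as a circular permutation of gene
symbols, each carrying a strand sign; one IR copy is collapsed so every
symbol appears at most once.  The sidedness index

    C_s = (n - n_SB) / (n - 1)

measures strand clustering, where n_SB is the number of maximal runs
("sided blocks") of adjacent same-strand genes; C_s = 1 when all genes lie
on one strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import fixtures
from .genome_io import GenomeRecord

log = logging.getLogger(__name__)


@dataclass
class SignedGeneOrder:
    taxon: str
    genes: list[tuple[str, int]]  # (symbol, +1/-1) in circular order

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"{self.taxon}: empty gene order")
        if any(s not in (1, -1) for _, s in self.genes):
            raise ValueError("signs must be +/-1")

    @property
    def n(self) -> int:
        return len(self.genes)

    def symbols(self) -> set[str]:
        return {g for g, _ in self.genes}

    def reflected(self) -> "SignedGeneOrder":
        """The same circle read in the opposite direction."""
        return SignedGeneOrder(self.taxon, [(g, -s) for g, s in reversed(self.genes)])


@dataclass
class SidednessResult:
    n: int
    n_sb: int
    cs: float


@dataclass(frozen=True)
class AdjacencyPair:
    """A strand-agnostic signed gene adjacency.

    The pair (x, y) and its reflection (-y, -x) describe the same physical
    adjacency; the canonical representative is the lexicographically smaller
    of the two renderings.
    """

    left: tuple[str, int]
    right: tuple[str, int]

    @staticmethod
    def _render(g: tuple[str, int]) -> str:
        return ("+" if g[1] > 0 else "-") + g[0]

    def __str__(self) -> str:
        return f"{self._render(self.left)}|{self._render(self.right)}"

    @classmethod
    def canonical(cls, left: tuple[str, int], right: tuple[str, int]) -> "AdjacencyPair":
        a = (left, right)
        b = ((right[0], -right[1]), (left[0], -left[1]))
        key = lambda p: (cls._render(p[0]), cls._render(p[1]))
        return cls(*min(a, b, key=key))


def extract_signed_gene_order(g: GenomeRecord, gene_filter: set[str] | None = None,
                              collapse_ir: bool = True, ir=None) -> SignedGeneOrder:
    """Read the signed circular gene order off an annotated genome.

    Only one IR copy is kept: with ``collapse_ir`` and an IR annotation,
    features inside IRB are dropped; any residual duplicated symbol keeps its
    first occurrence clockwise from position 0 (logged).
    """
    feats = sorted(g.gene_features(), key=lambda f: (f.start, f.end))
    if gene_filter is not None:
        feats = [f for f in feats if f.symbol in gene_filter]
    if collapse_ir and ir is not None:
        from .ir import interval_contains
        n = len(g.sequence)
        feats = [f for f in feats
                 if not interval_contains(ir.irb, (f.start, f.end), n)]
    genes: list[tuple[str, int]] = []
    seen: set[str] = set()
    for f in feats:
        if f.symbol in seen:
            log.info("%s: duplicate %s outside IR, keeping first occurrence",
                     g.taxon, f.symbol)
            continue
        seen.add(f.symbol)
        genes.append((f.symbol, f.strand))
    if not genes:
        raise ValueError(f"{g.taxon}: no genes left after filtering")
    return SignedGeneOrder(taxon=g.taxon, genes=genes)


def sidedness_index(o: SignedGeneOrder, circular: bool = True) -> SidednessResult:
    """Sided-block count and C_s = (n - n_SB)/(n - 1)."""
    n = o.n
    if n < 2:
        raise ValueError("sidedness needs at least two genes")
    signs = [s for _, s in o.genes]
    n_sb = 1 + sum(1 for a, b in zip(signs, signs[1:]) if a != b)
    if circular and n_sb > 1 and signs[0] == signs[-1]:
        n_sb -= 1  # first and last runs merge around the circle
    cs = (n - n_sb) / (n - 1)
    assert 1 <= n_sb <= n and 0.0 <= cs <= 1.0
    return SidednessResult(n=n, n_sb=n_sb, cs=cs)


def canonical_pairs(o: SignedGeneOrder, circular: bool = True) -> set[AdjacencyPair]:
    """All adjacent signed gene couples, in canonical form."""
    pairs = set()
    genes = o.genes
    m = len(genes) if circular else len(genes) - 1
    for i in range(m):
        pairs.add(AdjacencyPair.canonical(genes[i], genes[(i + 1) % len(genes)]))
    return pairs


@dataclass
class PairMatrix:
    """Binary presence of shared adjacencies (rows) per taxon (columns).

    Cell values: 1 pair present, 0 absent though both genes exist in the
    taxon, NA one of the two genes is missing from the genome.
    """

    table: pd.DataFrame
    pairs: list[AdjacencyPair] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="NA")


def shared_pair_matrix(orders: list[SignedGeneOrder], min_share: int = 5) -> PairMatrix:
    """Adjacency presence/absence matrix, restricted to pairs shared by
    at least ``min_share`` taxa."""
    if min_share < 2:
        raise ValueError("min_share must be >= 2")
    if len(orders) < 2:
        raise ValueError("need at least two gene orders")
    per_taxon = {o.taxon: canonical_pairs(o) for o in orders}
    symbol_sets = {o.taxon: o.symbols() for o in orders}
    counts: dict[AdjacencyPair, int] = {}
    for ps in per_taxon.values():
        for p in ps:
            counts[p] = counts.get(p, 0) + 1
    kept = sorted((p for p, c in counts.items() if c >= min_share), key=str)
    taxa = sorted(per_taxon)
    data = {}
    for t in taxa:
        col = []
        for p in kept:
            if p in per_taxon[t]:
                col.append(1)
            elif p.left[0] in symbol_sets[t] and p.right[0] in symbol_sets[t]:
                col.append(0)
            else:
                col.append(pd.NA)
        data[t] = col
    table = pd.DataFrame(data, index=[str(p) for p in kept], dtype="Int64")
    return PairMatrix(table=table, pairs=kept)


def core_gene_set(genomes: list[GenomeRecord]) -> set[str]:
    """Intersection of gene symbols over the complete genomes."""
    if not genomes:
        raise ValueError("no genomes")
    core: set[str] | None = None
    for g in genomes:
        if not g.complete:
            log.warning("%s: incomplete genome excluded from core gene set", g.taxon)
            continue
        syms = {f.symbol for f in g.gene_features()}
        core = syms if core is None else core & syms
    if core is None:
        raise ValueError("no complete genomes")
    return core


def write_grimm(orders: list[SignedGeneOrder], path: str | Path) -> None:
    """Write gene orders as grimm-style text: `>taxon` then signed symbols."""
    with open(path, "w") as fh:
        for o in orders:
            fh.write(f">{o.taxon}\n")
            fh.write(" ".join(("+" if s > 0 else "-") + g for g, s in o.genes) + "\n")


def read_grimm(path: str | Path) -> list[SignedGeneOrder]:
    orders = []
    taxon = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                taxon = line[1:].strip()
            else:
                genes = []
                for tok in line.split():
                    sign = -1 if tok[0] == "-" else 1
                    genes.append((tok.lstrip("+-"), sign))
                orders.append(SignedGeneOrder(taxon=taxon, genes=genes))
    return orders


def core91_filter() -> set[str]:
    return set(fixtures.load_core91())
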