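"""Synthetic plastome evolution along a rooted tree.

An ancestral circular genome with quadripartite architecture
(LSC - IRA - SSC - IRB, the rDNA operon inside the IR transcribed toward the
SSC) evolves along a tree under five event types: segmental inversions, IR
boundary shifts in both directions (expansion absorbs single-copy genes into
both IR copies; contraction releases them), irreversible IR loss, and
insertion of small direct/palindromic repeats.  Every event is recorded in a
truth log that replays deterministically to bit-identical tips.

The simulator targets architecture, not homology: gene sequences are random
codons at a target composition, which is all the downstream gene-order, IR,
repeat and composition analyses need.

Genomes are modelled as alternating spacer/gene units per region; the IRB
region is always *derived* as the mirror of IRA, so the two IR copies are
exact reverse complements by construction.  Sequence realization is separate
from (and much more expensive than) architectural evolution, so large event
sweeps can run at gene-order level only.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from . import fixtures
from .dollo import ensure_node_labels, node_id
from .gene_order import SignedGeneOrder
from .genome_io import GeneFeature, GenomeRecord
from .ir import IRAnnotation, revcomp

RDNA = fixtures.RDNA_OPERON

DEFAULT_RATES = {
    "inversion": 1.0,
    "ir_expand": 0.3,
    "ir_contract": 0.3,
    "ir_loss": 0.15,
    "repeat_insert": 1.0,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic clade.

    Defaults emulate a down-scaled plastome: 40 genes (8 in the IR, of which
    5 form the rDNA operon), ~45 kb, AT-rich (65%), with per-branch Poisson
    event rates.  ``seed`` is mandatory.
    """

    seed: int
    n_genes: int = 40
    ir_gene_count: int = 8
    ssc_gene_count: int = 4
    genome_length_target: int = 45_000
    at_percent: float = 65.0
    rates: dict = field(default_factory=lambda: dict(DEFAULT_RATES))
    repeat_len_mean: float = 60.0
    repeat_len_min: int = 30
    strand_persistence: float = 0.75

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("event rates must be >= 0")
        if self.ir_gene_count not in (0,) and self.ir_gene_count < 5:
            raise ValueError("an IR must hold at least the 5 rDNA operon genes")

    def to_dict(self) -> dict:
        return {k: (dict(v) if isinstance(v, dict) else v)
                for k, v in self.__dict__.items()}


@dataclass
class GeneUnit:
    symbol: str
    kind: str  # CDS | tRNA | rRNA
    strand: int
    seq: str  # forward-strand text at current orientation

    def mirrored(self) -> "GeneUnit":
        return GeneUnit(self.symbol, self.kind, -self.strand, revcomp(self.seq))


@dataclass
class Region:
    """Alternating spacer/gene block: spacers[0] g0 spacers[1] g1 ... spacers[-1]."""

    genes: list[GeneUnit]
    spacers: list[str]

    def __post_init__(self):
        assert len(self.spacers) == len(self.genes) + 1

    def text(self) -> str:
        parts = [self.spacers[0]]
        for g, sp in zip(self.genes, self.spacers[1:]):
            parts.append(g.seq)
            parts.append(sp)
        return "".join(parts)

    def mirrored(self) -> "Region":
        return Region(genes=[g.mirrored() for g in reversed(self.genes)],
                      spacers=[revcomp(s) for s in reversed(self.spacers)])

    def invert(self, i: int, j: int) -> None:
        """In-place inversion of genes i..j (inclusive) with internal spacers."""
        assert 0 <= i <= j < len(self.genes)
        seg = [g.mirrored() for g in reversed(self.genes[i:j + 1])]
        self.genes[i:j + 1] = seg
        inner = [revcomp(s) for s in reversed(self.spacers[i + 1:j + 1])]
        self.spacers[i + 1:j + 1] = inner


@dataclass
class Architecture:
    has_ir: bool
    lsc: Region
    ira: Region | None = None
    ssc: Region | None = None

    def regions(self) -> dict[str, Region]:
        if self.has_ir:
            return {"lsc": self.lsc, "ira": self.ira, "ssc": self.ssc}
        return {"all": self.lsc}

    def gene_order(self, taxon: str = "sim") -> SignedGeneOrder:
        genes = []
        for name in ("lsc", "ira", "ssc") if self.has_ir else ("lsc",):
            region = getattr(self, name if name != "all" else "lsc")
            if region is None:
                continue
            genes.extend((g.symbol, g.strand) for g in region.genes)
        return SignedGeneOrder(taxon=taxon, genes=genes)

    def to_dict(self) -> dict:
        def reg(r):
            return {"genes": [[g.symbol, g.kind, g.strand, g.seq] for g in r.genes],
                    "spacers": list(r.spacers)}
        return {"has_ir": self.has_ir, "lsc": reg(self.lsc),
                "ira": reg(self.ira) if self.has_ir else None,
                "ssc": reg(self.ssc) if self.has_ir else None}

    @classmethod
    def from_dict(cls, d: dict) -> "Architecture":
        def reg(rd):
            return Region(genes=[GeneUnit(*g) for g in rd["genes"]],
                          spacers=list(rd["spacers"]))
        return cls(has_ir=d["has_ir"], lsc=reg(d["lsc"]),
                   ira=reg(d["ira"]) if d["has_ir"] else None,
                   ssc=reg(d["ssc"]) if d["has_ir"] else None)


# ---------------------------------------------------------------- sequences

def rand_seq(rng: np.random.Generator, length: int, at_percent: float) -> str:
    if length <= 0:
        return ""
    p_at = at_percent / 100.0
    bases = np.array(list("ATGC"))
    probs = [p_at / 2, p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2]
    return "".join(rng.choice(bases, size=length, p=probs))


def make_cds(rng: np.random.Generator, n_codons: int,
             gc_by_pos: tuple[float, float, float]) -> str:
    """Random in-frame CDS hitting per-codon-position GC targets."""
    out = []
    for gc in gc_by_pos:
        is_gc = rng.random(n_codons) < gc
        col = np.where(is_gc,
                       np.array(list("GC"))[rng.integers(0, 2, n_codons)],
                       np.array(list("AT"))[rng.integers(0, 2, n_codons)])
        out.append(col)
    codons = np.stack(out, axis=1).reshape(-1)
    return "".join(codons)


_GENE_LENGTHS = {"tRNA": 72, "rrs": 1200, "rrl": 2400, "rrf": 120}


def _gene_unit(rng, symbol: str, kind: str, strand: int, at: float) -> GeneUnit:
    if kind == "CDS":
        n_cod = int(rng.integers(100, 300))
        gc = (1 - at / 100.0)
        seq = "ATG" + make_cds(rng, n_cod, (gc, gc, max(0.05, gc - 0.2)))
    else:
        length = _GENE_LENGTHS.get(symbol, _GENE_LENGTHS["tRNA"])
        seq = rand_seq(rng, length, at)
    if strand < 0:
        seq = revcomp(seq)
    return GeneUnit(symbol=symbol, kind=kind, strand=strand, seq=seq)


# ----------------------------------------------------------------- ancestor

def make_ancestor(cfg: SimConfig, rng: np.random.Generator | None = None) -> Architecture:
    """Build the ancestral quadripartite genome.

    The rDNA operon sits at the SSC-adjacent end of IRA on the + strand, so
    it is transcribed toward the SSC; SSC genes are drawn from the genes that
    ancestrally flank the operon on the SSC side, giving the reference
    partitioning pattern by construction.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    core = fixtures.load_core91()
    sides = fixtures.load_ancestral_sides()
    at = cfg.at_percent
    kinds = {s: ("rRNA" if s in ("rrs", "rrl", "rrf")
                 else "tRNA" if s.startswith("trn") else "CDS") for s in core}

    ssc_pool = [s for s in core if sides.get(s) == "ssc_side"]
    lsc_pool = [s for s in core if sides.get(s) == "lsc_side"]
    has_ir = cfg.ir_gene_count >= 5
    n_ir_extra = max(0, cfg.ir_gene_count - 5) if has_ir else 0
    n_ssc = min(cfg.ssc_gene_count, len(ssc_pool)) if has_ir else 0
    n_lsc = cfg.n_genes - (cfg.ir_gene_count if has_ir else 5) - n_ssc
    if n_lsc < 1 or n_lsc + n_ir_extra > len(lsc_pool):
        raise ValueError("infeasible gene counts for the packaged core gene pool")

    ir_extra = lsc_pool[:n_ir_extra]
    lsc_syms = lsc_pool[n_ir_extra:n_ir_extra + n_lsc]
    ssc_syms = ssc_pool[:n_ssc]

    def strands(n):
        out, cur = [], 1 if rng.random() < 0.5 else -1
        for _ in range(n):
            if rng.random() > cfg.strand_persistence:
                cur = -cur
            out.append(cur)
        return out

    def build(symbols, strand_list):
        return [_gene_unit(rng, s, kinds[s], st, at)
                for s, st in zip(symbols, strand_list)]

    if has_ir:
        ira_genes = build(ir_extra, strands(len(ir_extra))) + \
            [_gene_unit(rng, s, kinds[s], 1, at) for s in RDNA]
        lsc_genes = build(lsc_syms, strands(n_lsc))
        ssc_genes = build(ssc_syms, strands(n_ssc))
    else:
        symbols = lsc_syms + list(RDNA) + ssc_syms
        lsc_genes = build(symbols, strands(len(symbols)))
        ira_genes, ssc_genes = [], []

    gene_bp = sum(len(g.seq) for g in lsc_genes + ssc_genes) \
        + 2 * sum(len(g.seq) for g in ira_genes)
    n_spacers = len(lsc_genes) + len(ssc_genes) + 2 + 2 * (len(ira_genes) + 1)
    deficit = cfg.genome_length_target - gene_bp
    if deficit < 2 * n_spacers:
        raise ValueError(f"genome_length_target {cfg.genome_length_target} too small "
                         f"for {gene_bp} bp of genes")
    mean_sp = deficit / n_spacers

    def spacers(n):
        lens = np.maximum(2, rng.poisson(mean_sp, size=n))
        return [rand_seq(rng, int(l), at) for l in lens]

    if has_ir:
        arch = Architecture(
            has_ir=True,
            lsc=Region(lsc_genes, spacers(len(lsc_genes) + 1)),
            ira=Region(ira_genes, spacers(len(ira_genes) + 1)),
            ssc=Region(ssc_genes, spacers(len(ssc_genes) + 1)),
        )
    else:
        arch = Architecture(has_ir=False,
                            lsc=Region(lsc_genes, spacers(len(lsc_genes) + 1)))
    return arch


# -------------------------------------------------------------- realization

def realize(arch: Architecture, taxon: str = "sim",
            accession: str = "") -> tuple[GenomeRecord, IRAnnotation | None]:
    """Render an architecture as an annotated circular genome.

    Junction guard: the first base of each single-copy block is adjusted if
    it would extend the IR identity by one base, so the planted IR is exactly
    maximal and detection recovers its coordinates precisely.
    """
    blocks: list[tuple[str, Region]] = [("lsc", arch.lsc)]
    if arch.has_ir:
        blocks += [("ira", arch.ira), ("ssc", arch.ssc), ("irb", arch.ira.mirrored())]
    chars: list[str] = []
    features: list[GeneFeature] = []
    bounds: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, region in blocks:
        start = pos
        chars.append(region.spacers[0])
        pos += len(region.spacers[0])
        for g, sp in zip(region.genes, region.spacers[1:]):
            features.append(GeneFeature(raw_name=g.symbol, symbol=g.symbol,
                                        kind=g.kind, strand=g.strand,
                                        spans=[(pos, pos + len(g.seq))]))
            chars.append(g.seq)
            pos += len(g.seq)
            chars.append(sp)
            pos += len(sp)
        bounds[name] = (start, pos)
    seq = list("".join(chars))
    n = len(seq)

    ann = None
    if arch.has_ir:
        a0, a1 = bounds["ira"]
        b0, b1 = bounds["irb"]
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        # inner junction: first SSC base must not extend the palindrome
        if seq[a1] == comp[seq[b0 - 1]]:
            seq[a1] = next(b for b in "ACGT" if b != comp[seq[b0 - 1]])
        # outer junction (circular): genome start vs IRB end
        if seq[0] == comp[seq[n - 1]]:
            seq[0] = next(b for b in "ACGT" if b != comp[seq[n - 1]])
        inner = (a1, b0)
        outer = (b1 % n, a0)
        inner_len = b0 - a1
        outer_len = n - b1 + a0
        lsc, ssc = ((inner, outer) if inner_len >= outer_len else (outer, inner))
        ann = IRAnnotation(ira=(a0, a1), irb=(b0, b1), lsc=lsc, ssc=ssc,
                           ir_len=a1 - a0, contains_rdna=True, genome_len=n)
    record = GenomeRecord(taxon=taxon, sequence="".join(seq), circular=True,
                          complete=True, accession=accession, features=features)
    if ann is not None:
        ann.validate(record.sequence)
    return record, ann


# ------------------------------------------------------------------ events

def _apply_inversion(arch: Architecture, ev: dict) -> None:
    arch.regions()[ev["region"]].invert(ev["i"], ev["j"])


def _apply_ir_expand(arch: Architecture, ev: dict) -> None:
    assert arch.has_ir
    if ev["side"] == "lsc":
        g = arch.lsc.genes.pop()
        s_last = arch.lsc.spacers.pop()
        arch.ira.genes.insert(0, g)
        arch.ira.spacers[0] = s_last + arch.ira.spacers[0]
        arch.ira.spacers.insert(0, "")
    else:
        g = arch.ssc.genes.pop(0)
        s_first = arch.ssc.spacers.pop(0)
        arch.ira.genes.append(g)
        arch.ira.spacers[-1] = arch.ira.spacers[-1] + s_first
        arch.ira.spacers.append("")


def _apply_ir_contract(arch: Architecture, ev: dict) -> None:
    assert arch.has_ir
    if ev["side"] == "lsc":
        g = arch.ira.genes.pop(0)
        lead = arch.ira.spacers.pop(0)
        arch.lsc.spacers[-1] = arch.lsc.spacers[-1] + lead
        arch.lsc.genes.append(g)
        arch.lsc.spacers.append("")
    else:
        g = arch.ira.genes.pop()
        trail = arch.ira.spacers.pop()
        arch.ssc.spacers[0] = trail + arch.ssc.spacers[0]
        arch.ssc.genes.insert(0, g)
        arch.ssc.spacers.insert(0, "")


def _apply_ir_loss(arch: Architecture, ev: dict) -> None:
    assert arch.has_ir
    lsc, ira, ssc = arch.lsc, arch.ira, arch.ssc
    genes = lsc.genes + ira.genes + ssc.genes
    spacers = (lsc.spacers[:-1]
               + [lsc.spacers[-1] + ira.spacers[0]] + ira.spacers[1:-1]
               + [ira.spacers[-1] + ssc.spacers[0]] + ssc.spacers[1:])
    arch.lsc = Region(genes, spacers)
    arch.ira = None
    arch.ssc = None
    arch.has_ir = False


def _apply_repeat_insert(arch: Architecture, ev: dict) -> None:
    region = arch.regions()[ev["region"]]
    idx, off = ev["spacer_index"], ev["offset"]
    sp = region.spacers[idx]
    region.spacers[idx] = sp[:off] + ev["seq"] + sp[off:]


_APPLY = {
    "inversion": _apply_inversion,
    "ir_expand": _apply_ir_expand,
    "ir_contract": _apply_ir_contract,
    "ir_loss": _apply_ir_loss,
    "repeat_insert": _apply_repeat_insert,
}


def apply_event(arch: Architecture, ev: dict) -> None:
    _APPLY[ev["type"]](arch, ev)


def _sample_event(arch: Architecture, etype: str, cfg: SimConfig,
                  rng: np.random.Generator) -> dict | None:
    """Parameterize one event on the current architecture; None if infeasible."""
    if etype == "inversion":
        regions = {name: r for name, r in arch.regions().items() if len(r.genes) >= 2}
        if not regions:
            return None
        names = sorted(regions)
        weights = np.array([len(regions[n].genes) for n in names], dtype=float)
        name = rng.choice(names, p=weights / weights.sum())
        ng = len(regions[name].genes)
        # avoid the full-circle segment: reflecting the whole molecule is a no-op
        max_span = ng - 1 if not arch.has_ir else ng
        while True:
            i, j = sorted(rng.integers(0, ng, size=2))
            if j - i + 1 <= max(1, max_span):
                break
        return {"type": etype, "region": str(name), "i": int(i), "j": int(j)}
    if etype in ("ir_expand", "ir_contract", "ir_loss") and not arch.has_ir:
        return None
    if etype == "ir_expand":
        sides = [s for s, reg in (("lsc", arch.lsc), ("ssc", arch.ssc))
                 if len(reg.genes) >= 2]
        if not sides:
            return None
        return {"type": etype, "side": str(rng.choice(sides))}
    if etype == "ir_contract":
        sides = []
        if len(arch.ira.genes) > 5 and arch.ira.genes[0].symbol not in RDNA:
            sides.append("lsc")
        if len(arch.ira.genes) > 5 and arch.ira.genes[-1].symbol not in RDNA:
            sides.append("ssc")
        if not sides:
            return None
        return {"type": etype, "side": str(rng.choice(sides))}
    if etype == "ir_loss":
        return {"type": etype}
    if etype == "repeat_insert":
        length = cfg.repeat_len_min + int(rng.exponential(
            max(1.0, cfg.repeat_len_mean - cfg.repeat_len_min)))
        donors = []
        for name, region in arch.regions().items():
            for gi, g in enumerate(region.genes):
                if len(g.seq) >= length:
                    donors.append((name, "gene", gi))
            for si, sp in enumerate(region.spacers):
                if len(sp) >= length:
                    donors.append((name, "spacer", si))
        if not donors:
            return None
        dname, dkind, di = donors[rng.integers(0, len(donors))]
        region = arch.regions()[dname]
        src = region.genes[di].seq if dkind == "gene" else region.spacers[di]
        start = int(rng.integers(0, len(src) - length + 1))
        segment = src[start:start + length]
        if rng.random() < 0.5:
            segment = revcomp(segment)
            kind = "palindromic"
        else:
            kind = "forward"
        targets = [(name, si) for name, region in arch.regions().items()
                   for si in range(len(region.spacers))
                   if not (dname == name and dkind == "spacer" and si == di)]
        tname, tsi = targets[rng.integers(0, len(targets))]
        t_sp = arch.regions()[tname].spacers[tsi]
        off = int(rng.integers(0, len(t_sp) + 1))
        return {"type": etype, "region": str(tname), "spacer_index": int(tsi),
                "offset": off, "seq": segment, "kind": kind, "length": length,
                "source": [str(dname), str(dkind), int(di), start]}
    raise KeyError(etype)


# ------------------------------------------------------------------- evolve

@dataclass
class TruthLog:
    config: dict
    tree_newick: str
    ancestor: dict
    events: list[dict]  # each carries "branch" = child-node id
    tip_ids: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLog":
        return cls(**json.loads(Path(path).read_text()))

    def events_on_branch(self, branch: str) -> list[dict]:
        return [e for e in self.events if e["branch"] == branch]

    def ir_loss_branches(self) -> list[str]:
        return [e["branch"] for e in self.events if e["type"] == "ir_loss"]


def evolve(ancestor: Architecture, tree: dendropy.Tree, cfg: SimConfig,
           rng: np.random.Generator | None = None
           ) -> tuple[dict[str, Architecture], TruthLog]:
    """Evolve the ancestor along every branch of a rooted tree.

    Event counts per branch are Poisson at the configured rates (scaled by
    branch length when present); IR loss is irreversible.  Returns the tip
    architectures keyed by taxon plus the replayable truth log.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ensure_node_labels(tree)
    arch_at: dict[dendropy.Node, Architecture] = {tree.seed_node: ancestor}
    events: list[dict] = []
    etypes = sorted(cfg.rates)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_arch = arch_at[node.parent_node]
        arch = copy.deepcopy(parent_arch)
        scale = node.edge.length if node.edge.length else 1.0
        pending: list[str] = []
        for et in etypes:
            count = rng.poisson(cfg.rates.get(et, 0.0) * scale)
            if et == "ir_loss":
                count = min(count, 1)
            pending.extend([et] * count)
        rng.shuffle(pending)
        branch = node_id(node)
        for et in pending:
            ev = _sample_event(arch, et, cfg, rng)
            if ev is None:
                continue
            ev["branch"] = branch
            apply_event(arch, ev)
            events.append(ev)
        arch_at[node] = arch
    tips = {node_id(lf): arch_at[lf] for lf in tree.leaf_node_iter()}
    log = TruthLog(config=cfg.to_dict(),
                   tree_newick=tree.as_string(schema="newick").strip(),
                   ancestor=ancestor.to_dict(),
                   events=events, tip_ids=sorted(tips))
    return tips, log


def replay(log: TruthLog) -> dict[str, Architecture]:
    """Re-apply the recorded events from the ancestor; bit-identical tips."""
    tree = dendropy.Tree.get(data=log.tree_newick, schema="newick",
                             rooting="force-rooted",
                             suppress_internal_node_taxa=True)
    ensure_node_labels(tree)
    arch_at = {tree.seed_node: Architecture.from_dict(log.ancestor)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        arch = copy.deepcopy(arch_at[node.parent_node])
        for ev in log.events_on_branch(node_id(node)):
            apply_event(arch, ev)
        arch_at[node] = arch
    tips = {node_id(lf): arch_at[lf] for lf in tree.leaf_node_iter()}
    missing = set(log.tip_ids) ^ set(tips)
    if missing:
        raise ValueError(f"truth log does not match tree tips: {sorted(missing)}")
    return tips


def write_bundle(tips: dict[str, Architecture], log: TruthLog,
                 outdir: str | Path) -> None:
    """Emit GenBank + FASTA per tip, the tree, and the truth log."""
    from .genome_io import write_genbank

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for taxon, arch in sorted(tips.items()):
        rec, _ = realize(arch, taxon=taxon)
        write_genbank(rec, outdir / f"{taxon}.gb")
        with open(outdir / f"{taxon}.fasta", "w") as fh:
            fh.write(f">{taxon}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i:i + 70] + "\n")
    (outdir / "tree.nwk").write_text(log.tree_newick + "\n")
    log.to_json(outdir / "truth.json")


def balanced_tree(n_tips: int, branch_length: float = 1.0) -> dendropy.Tree:
    """A simple balanced rooted test tree with tips t1..tn."""
    labels = [f"t{i + 1}" for i in range(n_tips)]
    newick = _balanced_newick(labels, branch_length) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted",
                             suppress_internal_node_taxa=True)
    ensure_node_labels(tree)
    return tree


def _balanced_newick(labels: list[str], bl: float) -> str:
    if len(labels) == 1:
        return f"{labels[0]}:{bl}"
    mid = len(labels) // 2
    left = _balanced_newick(labels[:mid], bl)
    right = _balanced_newick(labels[mid:], bl)
    return f"({left},{right}):{bl}"
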