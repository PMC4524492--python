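"""GenBank/FASTA ingestion and the internal annotated-genome model.

Coordinates are 0-based, half-open throughout.  On circular molecules a
feature may wrap the origin; wrapped features are represented by exon
sub-intervals that jump backwards across the origin (end of sequence -> 0),
and the gap is *not* counted as an intron.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import fixtures

log = logging.getLogger(__name__)

STANDARD_KINDS = ("CDS", "tRNA", "rRNA")

_TRN_RE = re.compile(r"^trn(f?[A-Za-z]{1,2})[-_(]?([ACGTUacgtu]{3})\)?$")


class ParseError(ValueError):
    pass


@dataclass
class GeneFeature:
    """One annotated gene locus (possibly multi-exon, possibly origin-wrapping)."""

    raw_name: str
    symbol: str
    kind: str  # CDS | tRNA | rRNA | intron | other
    strand: int  # +1 / -1
    spans: list[tuple[int, int]]  # exon intervals, 0-based half-open, genomic order
    intron_spans: list[tuple[int, int]] = field(default_factory=list)
    part_index: int = 1
    qualifiers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in (1, -1):
            raise ValueError(f"{self.symbol}: strand must be +/-1")
        if not self.spans or any(e <= s for s, e in self.spans):
            raise ValueError(f"{self.symbol}: every exon span needs length >= 1")
        if self.part_index < 1:
            raise ValueError("part_index >= 1")

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def end(self) -> int:
        return self.spans[-1][1]

    def length(self) -> int:
        return sum(e - s for s, e in self.spans)


@dataclass
class GenomeRecord:
    taxon: str
    sequence: str
    circular: bool = True
    complete: bool = True
    accession: str = ""
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if not self.taxon:
            raise ValueError("taxon label must be nonempty")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.spans:
                if not (0 <= s < n and 0 < e <= n):
                    raise ValueError(f"{f.symbol}: span ({s},{e}) outside genome of {n} bp")

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind in STANDARD_KINDS]


@dataclass
class GenomeBreakdown:
    coding_bp: int
    intron_bp: int
    intergenic_bp: int
    repeat_bp: int
    at_percent: float
    gene_count: int
    groupI_count: int
    groupII_count: int


_SYNONYMS: dict[str, str] | None = None
_KNOWN_CASE: dict[str, str] | None = None


def _tables():
    global _SYNONYMS, _KNOWN_CASE
    if _SYNONYMS is None:
        _SYNONYMS = fixtures.load_synonyms()
        known = list(fixtures.load_core91()) + list(_SYNONYMS.values())
        _KNOWN_CASE = {s.lower(): s for s in known}
    return _SYNONYMS, _KNOWN_CASE


def normalize_symbol(raw_name: str) -> str:
    """Map synonym spellings to one canonical gene symbol.

    Known synonyms come from a packaged editable table; tRNA names in any of
    the common spellings (trnI-GAU, trnI_gau, trnI(gau)) are rewritten to the
    ``trnX(nnn)`` convention with the anticodon in lowercase (T -> u).
    Unknown names pass through lowercased, so the mapping is lossless and
    idempotent.
    """
    syn, known_case = _tables()
    name = raw_name.strip()
    if name in syn:
        return syn[name]
    m = _TRN_RE.match(name)
    if m:
        aa, anticodon = m.groups()
        aa = aa[0].upper() + aa[1:] if not aa.startswith("f") else "Mf"
        anticodon = anticodon.lower().replace("t", "u")
        cand = f"trn{aa}({anticodon})"
        return syn.get(cand, known_case.get(cand.lower(), cand))
    if name.lower() in known_case:
        return known_case[name.lower()]
    return name.lower()


def _location_spans(loc, seq_len: int, circular: bool) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Exon spans in genomic order plus inferred intron spans."""
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    spans = [(int(p.start), int(p.end)) for p in parts]
    # Biopython orders CompoundLocation parts 5'->3'; put them in genomic order
    # for intron inference but remember origin wraps.
    introns = []
    ordered = sorted(spans)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 > e1:
            introns.append((e1, s2))
        elif s2 < e1:
            raise ParseError(f"overlapping exons in location {loc}")
    # wrap detection: a 5'->3' part sequence that jumps from the end to 0
    if circular and spans != ordered and spans != ordered[::-1]:
        # origin-wrapping join: the 'intron' spanning the origin is spurious
        wrap_gap = (ordered[-1][1], ordered[0][0] + seq_len)
        introns = [iv for iv in introns if iv != wrap_gap]
    return spans, introns


def parse_genbank(path: str | Path) -> GenomeRecord:
    """Parse one GenBank flat file into a :class:`GenomeRecord`.

    gene/CDS/tRNA/rRNA features are resolved to strand plus exon spans;
    introns are inferred from multi-exon locations.  Duplicate features with
    identical symbol and span are deduplicated with a warning.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ParseError(f"{path}: malformed GenBank record: {exc}") from exc
    circular = rec.annotations.get("topology", "linear") == "circular"
    seq = str(rec.seq).upper()
    feats: list[GeneFeature] = []
    seen: set[tuple] = set()
    for f in rec.features:
        if f.type in STANDARD_KINDS or f.type == "intron":
            raw = (f.qualifiers.get("gene") or f.qualifiers.get("locus_tag")
                   or f.qualifiers.get("product") or [f.type])[0]
            strand = f.location.strand or 1
            spans, introns = _location_spans(f.location, len(seq), circular)
            key = (f.type, raw, tuple(spans), strand)
            if key in seen:
                log.warning("%s: duplicate feature %s %s dropped", path.name, f.type, raw)
                continue
            seen.add(key)
            kind = f.type if f.type in STANDARD_KINDS else "intron"
            feats.append(GeneFeature(raw_name=raw, symbol=normalize_symbol(raw),
                                     kind=kind, strand=int(strand), spans=spans,
                                     intron_spans=introns,
                                     qualifiers={k: v[0] for k, v in f.qualifiers.items()
                                                 if k in ("note", "intron_type", "part")}))
    if not feats:
        log.warning("%s: record has no gene features", path.name)
    feats.sort(key=lambda f: (f.start, f.end))
    _assign_part_indices(feats)
    taxon = rec.annotations.get("organism") or rec.name or path.stem
    return GenomeRecord(taxon=taxon.replace(" ", "_"), sequence=seq, circular=circular,
                        complete=True, accession=rec.id or "", features=feats)


def _assign_part_indices(feats: list[GeneFeature]) -> None:
    by_symbol: dict[tuple, int] = {}
    for f in feats:
        key = (f.symbol, f.kind)
        by_symbol[key] = by_symbol.get(key, 0) + 1
        f.part_index = by_symbol[key]


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Emit a GenBank flat file that :func:`parse_genbank` round-trips."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.accession or genome.taxon,
                    name=genome.taxon[:16], description=genome.taxon)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    rec.annotations["organism"] = genome.taxon
    for f in genome.features:
        parts = [SimpleLocation(s, e, f.strand) for s, e in f.spans]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(
            parts if f.strand == 1 else parts[::-1])
        rec.features.append(SeqFeature(loc, type=f.kind if f.kind in STANDARD_KINDS else "misc_feature",
                                       qualifiers={"gene": [f.raw_name]}))
    SeqIO.write([rec], str(path), "genbank")


def at_fraction(seq: str) -> float:
    counts = {b: seq.count(b) for b in "ACGT"}
    tot = sum(counts.values())
    return 100.0 * (counts["A"] + counts["T"]) / tot if tot else float("nan")


def genome_breakdown(g: GenomeRecord, repeat_mask=None,
                     intron_orfs_as_coding: bool = False) -> GenomeBreakdown:
    """Partition every genomic position into coding / intron / intergenic.

    Priority on overlap is coding > intron > intergenic, so the three
    categories always sum to the genome length.  Intron-encoded ORFs count as
    intron sequence unless ``intron_orfs_as_coding`` is set.
    """
    n = len(g.sequence)
    label = np.zeros(n, dtype=np.uint8)  # 0 intergenic, 1 intron, 2 coding
    gI = gII = 0
    for f in g.features:
        if f.kind == "intron":
            note = (f.qualifiers.get("intron_type") or f.qualifiers.get("note") or "").lower()
            if "group i" in note and "group ii" not in note:
                gI += 1
            elif "group ii" in note:
                gII += 1
            for s, e in f.spans:
                label[s:e] = np.maximum(label[s:e], 1)
            continue
        if f.kind not in STANDARD_KINDS:
            continue
        coding = intron_orfs_as_coding or f.qualifiers.get("part") != "intron_orf"
        for s, e in f.intron_spans:
            label[s:e] = np.maximum(label[s:e], 1)
        for s, e in f.spans:
            label[s:e] = np.maximum(label[s:e], 2 if coding else 1)
    coding_bp = int((label == 2).sum())
    intron_bp = int((label == 1).sum())
    intergenic_bp = n - coding_bp - intron_bp
    repeat_bp = 0
    if repeat_mask is not None:
        mask = np.zeros(n, dtype=bool)
        for s, e in repeat_mask:
            s, e = s % n, e
            mask[s:min(e, n)] = True
            if e > n:
                mask[: e - n] = True
        repeat_bp = int(mask.sum())
    out = GenomeBreakdown(coding_bp=coding_bp, intron_bp=intron_bp,
                          intergenic_bp=intergenic_bp, repeat_bp=repeat_bp,
                          at_percent=at_fraction(g.sequence),
                          gene_count=len({f.symbol for f in g.gene_features()}),
                          groupI_count=gI, groupII_count=gII)
    assert out.coding_bp + out.intron_bp + out.intergenic_bp == n
    return out


def detect_fragmented_genes(g: GenomeRecord, ir=None) -> list[tuple[str, int]]:
    """Symbols annotated in >= 2 parts not explained by IR duplication."""
    groups: dict[str, list[GeneFeature]] = {}
    for f in g.gene_features():
        groups.setdefault(f.symbol, []).append(f)
    out = []
    for symbol, fs in groups.items():
        if len(fs) < 2:
            continue
        if ir is not None and len(fs) == 2:
            from .ir import interval_contains
            a, b = sorted(fs, key=lambda f: f.start)
            if (interval_contains(ir.ira, (a.start, a.end), len(g.sequence))
                    and interval_contains(ir.irb, (b.start, b.end), len(g.sequence))):
                continue  # the second copy is the IR duplicate
        out.append((symbol, len(fs)))
    return sorted(out)


def summary_table(genomes: list[GenomeRecord], breakdowns: list[GenomeBreakdown]) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for g, b in zip(genomes, breakdowns):
        rows.append({
            "taxon": g.taxon, "accession": g.accession, "length": len(g.sequence),
            "at_percent": round(b.at_percent, 1), "genes": b.gene_count,
            "introns_gI": b.groupI_count, "introns_gII": b.groupII_count,
            "coding_bp": b.coding_bp, "intron_bp": b.intron_bp,
            "intergenic_bp": b.intergenic_bp, "repeat_bp": b.repeat_bp,
        })
    return pd.DataFrame(rows).set_index("taxon")
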