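"""Packaged study data: genome metadata table, reference tree, core gene set.

Four small plain-text fixtures ship with the package:

``table1``
    Per-genome metadata for the 38 pedinophycean/trebouxiophycean plastomes
    (accession, A+T%, genome/IR/LSC/SSC lengths, gene and intron counts,
    small-repeat percentage, IR flags, completeness).
``tree``
    The rooted 38-taxon reference phylogeny (Newick).  Nodes whose resolution
    could not be corroborated are stored as polytomies (see the manifest).
``core91``
    The 91 standard genes shared by all completely sequenced genomes.
``ancestral_sides``
    For each core gene, its side relative to the rDNA operon in the ancestral
    (prasinophyte/streptophyte-like) quadripartite partitioning pattern.

Fixture integrity is guarded by SHA-256 checksums in ``data/manifest.json``;
structural invariants (leaf counts, the 2*IR + LSC + SSC = genome identity)
are asserted at load time.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import dendropy
import pandas as pd

_DATA_FILES = {
    "table1": "table1.tsv",
    "tree": "tree_fig1.nwk",
    "core91": "core91.tsv",
    "ancestral_sides": "ancestral_sides.tsv",
    "synonyms": "synonyms.tsv",
}


class FixtureError(RuntimeError):
    pass


def _read_bytes(filename: str) -> bytes:
    return resources.files("plastarch.data").joinpath(filename).read_bytes()


def _checksum(raw: bytes) -> str:
    return hashlib.sha256(raw).hexdigest()


def _manifest() -> dict:
    return json.loads(_read_bytes("manifest.json"))


def _load_raw(name: str) -> bytes:
    if name not in _DATA_FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_DATA_FILES)}")
    fname = _DATA_FILES[name]
    raw = _read_bytes(fname)
    expect = _manifest()["checksums"][fname]
    got = _checksum(raw)
    if got != expect:
        raise FixtureError(f"checksum mismatch for {fname}: {got} != {expect}")
    return raw


def load_table1() -> pd.DataFrame:
    """Load and validate the per-genome metadata table."""
    import io

    raw = _load_raw("table1")
    df = pd.read_csv(io.BytesIO(raw), sep="\t", dtype={"accession": str})
    df = df.set_index("taxon", drop=False)
    if len(df) != 38:
        raise FixtureError(f"expected 38 genomes, found {len(df)}")
    # an annotated IR length implies the IR-structure flag
    has_len = df["ir_bp"].notna()
    if not (df.loc[has_len, "ir_structure"] == 1).all():
        raise FixtureError("ir_bp present without ir_structure flag")
    # every rDNA-encoding IR is an IR structure
    if not (df.loc[df["ir_rdna"] == 1, "ir_structure"] == 1).all():
        raise FixtureError("ir_rdna set without ir_structure")
    # quadripartite identity on complete rows with all four lengths
    full = df[(df["complete"] == 1) & df[["ir_bp", "lsc_bp", "ssc_bp"]].notna().all(axis=1)]
    bad = full[2 * full["ir_bp"] + full["lsc_bp"] + full["ssc_bp"] != full["genome_bp"]]
    if len(bad):
        raise FixtureError(f"quadripartite identity fails for {list(bad.index)}")
    return df


def load_tree() -> dendropy.Tree:
    """Load the rooted 38-leaf reference tree."""
    raw = _load_raw("tree").decode()
    tree = dendropy.Tree.get(data=raw, schema="newick", rooting="force-rooted",
                             suppress_internal_node_taxa=True)
    leaves = {lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()}
    table_taxa = set(load_table1().index)
    if leaves != table_taxa:
        missing = table_taxa ^ leaves
        raise FixtureError(f"tree/table taxon mismatch: {sorted(missing)}")
    return tree


def load_core91() -> list[str]:
    """The 91 genes shared by all completely sequenced study genomes."""
    import io

    df = pd.read_csv(io.BytesIO(_load_raw("core91")), sep="\t")
    symbols = df["symbol"].tolist()
    if len(symbols) != 91 or len(set(symbols)) != 91:
        raise FixtureError(f"core gene list has {len(symbols)} entries, expected 91")
    return symbols


def load_ancestral_sides() -> dict[str, str]:
    """Map each core gene to its ancestral side relative to the rDNA operon."""
    import io

    df = pd.read_csv(io.BytesIO(_load_raw("ancestral_sides")), sep="\t")
    sides = dict(zip(df["symbol"], df["ancestral_side"]))
    allowed = {"rdna", "ssc_side", "lsc_side"}
    if not set(sides.values()) <= allowed:
        raise FixtureError("invalid ancestral_side value")
    return sides


def load_synonyms() -> dict[str, str]:
    import io

    df = pd.read_csv(io.BytesIO(_load_raw("synonyms")), sep="\t")
    return dict(zip(df["raw"], df["symbol"]))


def load_fixture(name: str):
    """Dispatch loader: name in {table1, tree, core91, ancestral_sides}."""
    loaders = {
        "table1": load_table1,
        "tree": load_tree,
        "core91": load_core91,
        "ancestral_sides": load_ancestral_sides,
        "synonyms": load_synonyms,
    }
    if name not in loaders:
        raise KeyError(f"unknown fixture {name!r}")
    return loaders[name]()


RDNA_OPERON = ("rrs", "trnI(gau)", "trnA(ugc)", "rrl", "rrf")
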