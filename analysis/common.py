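"""Shared plumbing for the numbered analysis drivers.

The simulated clade bundle (GenBank + FASTA + tree + truth log) is bulky, so
it lives under scratch/; the tables every driver derives from it go to
results/.  Any driver can regenerate the bundle deterministically.
"""

from pathlib import Path

import numpy as np

from plastarch import simulate as sim

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "sim_clade"
RESULTS = ROOT / "results"

SEED = 2015
N_TIPS = 10


def study_config() -> sim.SimConfig:
    """The study conditions of the synthetic clade: a 40-gene, ~45 kb,
    AT-rich quadripartite plastome evolving under inversions, IR boundary
    shifts, repeated IR losses and small-repeat insertions."""
    return sim.SimConfig(seed=SEED)


def ensure_bundle() -> Path:
    RESULTS.mkdir(exist_ok=True)
    if (SCRATCH / "truth.json").exists():
        return SCRATCH
    cfg = study_config()
    rng = np.random.default_rng(cfg.seed)
    ancestor = sim.make_ancestor(cfg, rng)
    tree = sim.balanced_tree(N_TIPS)
    tips, log = sim.evolve(ancestor, tree, cfg, rng)
    sim.write_bundle(tips, log, SCRATCH)
    return SCRATCH


def load_bundle():
    from plastarch.genome_io import parse_genbank

    bundle = ensure_bundle()
    genomes = [parse_genbank(p) for p in sorted(bundle.glob("*.gb"))]
    log = sim.TruthLog.from_json(bundle / "truth.json")
    return genomes, log
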