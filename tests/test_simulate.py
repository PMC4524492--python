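"""The synthetic plastome evolver and its truth log."""

import copy

import numpy as np
import pytest

from plastarch import ir as ir_mod
from plastarch import rearrangement as ra
from plastarch import simulate as sim


class TestAncestor:
    def test_invariants_by_construction(self, ancestor, ancestor_realized):
        rec, ann = ancestor_realized
        ann.validate(rec.sequence)  # exact revcomp + length partition
        assert ann.contains_rdna

    def test_seed_is_mandatory(self):
        with pytest.raises(TypeError):
            sim.SimConfig()

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            sim.SimConfig(seed=1, rates={"inversion": -1})

    def test_infeasible_length_target_rejected(self):
        with pytest.raises(ValueError):
            sim.make_ancestor(sim.SimConfig(seed=1, genome_length_target=5000))

    def test_at_composition_near_target(self, ancestor_realized):
        from plastarch.composition import at_content

        rec, _ = ancestor_realized
        assert abs(at_content(rec.sequence) - 65.0) < 5.0


class TestEvolve:
    def test_zero_rates_leave_tips_identical(self, ancestor):
        cfg = sim.SimConfig(seed=2, rates={k: 0.0 for k in sim.DEFAULT_RATES})
        tree = sim.balanced_tree(4)
        tips, log = sim.evolve(ancestor, tree, cfg)
        assert log.events == []
        anc_seq = sim.realize(ancestor, "x")[0].sequence
        for t, arch in tips.items():
            assert sim.realize(arch, "x")[0].sequence == anc_seq

    def test_single_inversion_distance_one(self, ancestor):
        cfg = sim.SimConfig(seed=3)
        child = copy.deepcopy(ancestor)
        ev = sim._sample_event(child, "inversion", cfg, np.random.default_rng(5))
        sim.apply_event(child, ev)
        d = ra.reversal_distance(ancestor.gene_order("p"), child.gene_order("c"))
        assert d.d == 1

    def test_ir_copies_stay_identical_under_events(self, ancestor):
        cfg = sim.SimConfig(seed=4)
        rng = np.random.default_rng(4)
        arch = copy.deepcopy(ancestor)
        for etype in ["inversion", "ir_expand", "inversion", "ir_contract",
                      "repeat_insert", "inversion"]:
            ev = sim._sample_event(arch, etype, cfg, rng)
            if ev is not None:
                sim.apply_event(arch, ev)
        rec, ann = sim.realize(arch, "evolved")
        if ann is not None:
            ann.validate(rec.sequence)

    def test_expansion_duplicates_absorbed_gene(self, ancestor):
        arch = copy.deepcopy(ancestor)
        moved = arch.lsc.genes[-1].symbol
        sim.apply_event(arch, {"type": "ir_expand", "side": "lsc"})
        rec, _ = sim.realize(arch, "x")
        assert sum(f.symbol == moved for f in rec.gene_features()) == 2

    def test_contraction_reverses_expansion(self, ancestor):
        arch = copy.deepcopy(ancestor)
        before = arch.gene_order().genes
        sim.apply_event(arch, {"type": "ir_expand", "side": "ssc"})
        sim.apply_event(arch, {"type": "ir_contract", "side": "ssc"})
        assert arch.gene_order().genes == before

    def test_ir_loss_is_irreversible(self, ancestor):
        cfg = sim.SimConfig(seed=5)
        arch = copy.deepcopy(ancestor)
        sim.apply_event(arch, {"type": "ir_loss"})
        assert not arch.has_ir
        rng = np.random.default_rng(1)
        for etype in ("ir_loss", "ir_expand", "ir_contract"):
            assert sim._sample_event(arch, etype, cfg, rng) is None

    def test_repeat_insert_found_by_detector(self, ancestor):
        cfg = sim.SimConfig(seed=8, repeat_len_mean=80.0)
        rng = np.random.default_rng(8)
        arch = copy.deepcopy(ancestor)
        ev = None
        while ev is None:
            ev = sim._sample_event(arch, "repeat_insert", cfg, rng)
        sim.apply_event(arch, ev)
        rec, ann = sim.realize(arch, "rep")
        from plastarch.repeats import find_maximal_repeats

        hits = find_maximal_repeats(rec.sequence, min_len=30, exclude_ir=ann)
        assert any(h.length >= ev["length"] for h in hits)


class TestTruthLog:
    def test_replay_is_bit_identical(self, ancestor):
        cfg = sim.SimConfig(seed=11)
        tree = sim.balanced_tree(6)
        tips, log = sim.evolve(ancestor, tree, cfg)
        tips2 = sim.replay(log)
        for t in tips:
            assert sim.realize(tips[t], t)[0].sequence == \
                sim.realize(tips2[t], t)[0].sequence

    def test_different_seeds_differ(self, ancestor):
        tree = sim.balanced_tree(4)
        _, log1 = sim.evolve(ancestor, tree, sim.SimConfig(seed=1))
        _, log2 = sim.evolve(ancestor, tree, sim.SimConfig(seed=2))
        assert log1.events != log2.events

    def test_replay_after_json_round_trip(self, tmp_path, ancestor):
        cfg = sim.SimConfig(seed=12)
        tree = sim.balanced_tree(4)
        tips, log = sim.evolve(ancestor, tree, cfg)
        p = tmp_path / "truth.json"
        log.to_json(p)
        log2 = sim.TruthLog.from_json(p)
        tips2 = sim.replay(log2)
        for t in tips:
            assert sim.realize(tips[t], t)[0].sequence == \
                sim.realize(tips2[t], t)[0].sequence

    def test_mismatched_log_rejected(self, ancestor):
        cfg = sim.SimConfig(seed=13)
        tree = sim.balanced_tree(4)
        _, log = sim.evolve(ancestor, tree, cfg)
        log.tip_ids = log.tip_ids + ["phantom_tip"]
        with pytest.raises(ValueError):
            sim.replay(log)


class TestWriteBundle:
    def test_bundle_files_and_reparse(self, tmp_path, ancestor):
        cfg = sim.SimConfig(seed=14)
        tree = sim.balanced_tree(3)
        tips, log = sim.evolve(ancestor, tree, cfg)
        sim.write_bundle(tips, log, tmp_path)
        assert sorted(p.name for p in tmp_path.glob("*.gb")) == \
            [f"t{i}.gb" for i in (1, 2, 3)]
        assert (tmp_path / "tree.nwk").exists() and (tmp_path / "truth.json").exists()
        from plastarch.genome_io import parse_genbank

        rec = parse_genbank(tmp_path / "t1.gb")
        assert rec.sequence == sim.realize(tips["t1"], "t1")[0].sequence
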