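"""Decoder: mate merging, chain parsing, statuses, truth-ledger validation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seqzip as sz
from seqzip.decode import (
    AMBIGUOUS,
    ASSIGNED,
    NEAR_COGNATE,
    SWITCHED,
    UNASSIGNED,
)
from seqzip.simulate import random_dna


class TestMergePairs:
    def test_error_free_reconstruction_356nt(self):
        rng = np.random.default_rng(1)
        product = random_dna(356, rng)
        r1 = product[:250]
        r2 = sz.reverse_complement(product)[:250]
        merged = sz.merge_pairs(r1, r2)
        assert merged is not None
        assert merged.sequence == product
        assert merged.overlap_len == 144
        assert merged.n_overlap_mismatches == 0

    def test_disjoint_halves_fail(self):
        rng = np.random.default_rng(2)
        r1 = random_dna(100, rng)
        r2 = random_dna(100, rng)
        assert sz.merge_pairs(r1, r2) is None

    def test_merged_length_identity_random_products(self):
        """len(merged) = l1 + l2 - overlap against the known product length."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(260, 490))  # keeps the true overlap >= min_overlap
            product = random_dna(n, rng)
            r1 = product[:250]
            r2 = sz.reverse_complement(product)[:250]
            merged = sz.merge_pairs(r1, r2)
            assert merged is not None
            assert len(merged.sequence) == len(r1) + len(r2) - merged.overlap_len == n

    @given(st.integers(min_value=260, max_value=480), st.integers(min_value=0, max_value=2**31 - 1))
    def test_merge_identity_property(self, n, seed):
        rng = np.random.default_rng(seed)
        product = random_dna(n, rng)
        r1, r2 = product[:250], sz.reverse_complement(product)[:250]
        merged = sz.merge_pairs(r1, r2)
        assert merged is not None and merged.sequence == product

    def test_mismatch_tolerance_resolves_to_r1(self):
        rng = np.random.default_rng(5)
        product = random_dna(300, rng)
        r1 = product[:250]
        suffix = list(sz.reverse_complement(product)[:250])
        # corrupt one base inside the overlap of r2
        suffix[100] = {"A": "C", "C": "A", "G": "T", "T": "G"}[suffix[100]]
        merged = sz.merge_pairs(r1, "".join(suffix))
        assert merged is not None
        assert merged.n_overlap_mismatches == 1
        assert merged.sequence == product  # r1 wins inside the overlap


class TestAssignment:
    def test_error_free_read_assigned_exactly(self, small_model, small_pool):
        idx = sz.build_product_index(small_model, small_pool)
        decoder = sz.Decoder(small_model, small_pool)
        for rec in idx:
            a = decoder.assign(rec.product_sequence)
            assert a.status == ASSIGNED
            assert a.isoform_key == rec.isoform_key

    def test_reverse_complement_orientation_assigned(self, small_model, small_pool):
        idx = sz.build_product_index(small_model, small_pool)
        decoder = sz.Decoder(small_model, small_pool)
        a = decoder.assign(sz.reverse_complement(idx[0].product_sequence))
        assert a.status == ASSIGNED and a.isoform_key == idx[0].isoform_key

    def test_cross_pool_read_flagged_switched(self, small_model, small_dual_pools):
        p1, p2 = small_dual_pools
        i1 = {r.isoform_key: r for r in sz.build_product_index(small_model, p1)}
        i2 = {r.isoform_key: r for r in sz.build_product_index(small_model, p2)}
        keys = sz.enumerate_isoforms(small_model)
        rec1, rec2 = i1[keys[0]], i2[keys[0]]
        # hand-built chimera: pool-1 prefix through the first separating
        # block, pool-2 suffix after it
        chain = rec1.ligamer_chain
        cut = chain.index("b1") + 1
        seq = "".join(p1.by_id[l].sequence for l in chain[:cut]) + "".join(
            p2.by_id[l].sequence for l in chain[cut:]
        )
        a = sz.Decoder(small_model, small_dual_pools).assign(seq)
        assert a.status == SWITCHED
        assert set(a.pools_observed) == {"pool1", "pool2"}

    def test_hybrid_barcode_arm_inconsistency_near_cognate(self, config):
        """A segment with variant X's arms around variant Y's barcode is the
        near-cognate signature."""
        model = sz.synth_gene(variants_per_cluster=[3], similarity=0.9, seed=41)
        pool = sz.plan_pool(model, config)
        idx = {r.isoform_key: r for r in sz.build_product_index(model, pool)}
        x, y = "c1.1", "c1.2"
        lx, ly = pool.get(x), pool.get(y)
        hybrid_segment = lx.arm_up + ly.spacer + lx.arm_down
        rec = idx[x]
        seq = idx[x].product_sequence.replace(lx.sequence, hybrid_segment)
        a = sz.Decoder(model, pool).assign(seq)
        assert a.status == NEAR_COGNATE

    def test_garbage_read_unassigned(self, small_model, small_pool):
        rng = np.random.default_rng(6)
        a = sz.Decoder(small_model, small_pool).assign(random_dna(300, rng))
        assert a.status == UNASSIGNED

    def test_identical_variant_arms_ambiguous_or_unique_by_barcode(self, config):
        """With unique barcodes even identical arms decode uniquely."""
        model = sz.synth_gene(variants_per_cluster=[2], similarity=1.0, seed=42)
        pool = sz.plan_pool(model, config)
        idx = sz.build_product_index(model, pool)
        decoder = sz.Decoder(model, pool)
        for rec in idx:
            a = decoder.assign(rec.product_sequence)
            assert a.status == ASSIGNED and a.isoform_key == rec.isoform_key


class TestTruthLedger:
    def test_error_free_accuracy_100pct_over_seeds(self, config):
        """Zero-error decoding equals the truth ledger exactly, across
        random models, pools and mixtures."""
        total = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            sizes = [int(rng.integers(2, 5)) for _ in range(int(rng.integers(1, 4)))]
            model = sz.synth_gene(variants_per_cluster=sizes, exon_length=60,
                                  block_length=60, seed=seed + 200)
            pools = sz.plan_dual_pools(model, config, barcode_seed=seed)
            keys = sz.enumerate_isoforms(model)
            props = {k: float(rng.integers(1, 10)) for k in keys[: min(4, len(keys))]}
            sim = sz.SimConfig(seed=seed, n_molecules=60, proportions=props)
            res = sz.run_simulation(model, pools, sim)
            table, assigns = sz.decode_pairs(res.reads, model, pools)
            tmap = dict(zip(res.truth["product_id"], res.truth["true_key"]))
            for a in assigns:
                total += 1
                assert a.status == ASSIGNED
                assert a.isoform_key == tmap[a.read_id]
        assert total == 30 * 60

    def test_robustness_accuracy_above_99pct_at_half_pct_error(self, config):
        """Regression bound: <=0.5% per-base error with 2 mismatches allowed
        per segment still decodes >=99% of reads correctly."""
        correct = total = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            sizes = [int(rng.integers(2, 5)) for _ in range(2)]
            model = sz.synth_gene(variants_per_cluster=sizes, exon_length=60,
                                  block_length=60, seed=seed + 300)
            pools = sz.plan_dual_pools(model, config, barcode_seed=seed)
            keys = sz.enumerate_isoforms(model)
            props = {k: 1.0 for k in keys[: min(4, len(keys))]}
            sim = sz.SimConfig(
                seed=seed, n_molecules=500, proportions=props, per_base_error=0.005
            )
            res = sz.run_simulation(model, pools, sim)
            _table, assigns = sz.decode_pairs(res.reads, model, pools)
            tmap = dict(zip(res.truth["product_id"], res.truth["true_key"]))
            for a in assigns:
                total += 1
                if a.status == ASSIGNED and a.isoform_key == tmap[a.read_id]:
                    correct += 1
        assert correct / total >= 0.99

    def test_recovered_proportions_within_multinomial_ci(self, small_model, small_dual_pools):
        """Decoding an error-free 100:10:1 mixture recovers the input
        proportions within 99% multinomial confidence intervals."""
        keys = sz.enumerate_isoforms(small_model)[:3]
        props = dict(zip(keys, (100.0, 10.0, 1.0)))
        sim = sz.SimConfig(seed=77, n_molecules=10_000, proportions=props)
        res = sz.run_simulation(small_model, small_dual_pools, sim)
        table, _ = sz.decode_pairs(res.reads, small_model, small_dual_pools)
        n = table.assigned_total
        total_w = sum(props.values())
        for k, w in props.items():
            p = w / total_w
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(table.counts.get(k, 0) / n - p) <= 2.576 * sd + 1e-12


class TestCountsAndReports:
    def test_conservation_of_statuses(self, small_model, small_dual_pools):
        keys = sz.enumerate_isoforms(small_model)[:3]
        sim = sz.SimConfig(
            seed=9,
            n_molecules=800,
            proportions={k: 1.0 for k in keys},
            switch_rate=0.05,
            per_base_error=0.01,
        )
        res = sz.run_simulation(small_model, small_dual_pools, sim)
        table, assigns = sz.decode_pairs(res.reads, small_model, small_dual_pools)
        assert table.total_reads == len(res.reads)
        assert sum(table.status_totals.values()) == len(assigns)
        assert table.assigned_total == table.status_totals.get(ASSIGNED, 0)

    def test_count_isoforms_tallies(self):
        assigns = [
            sz.Assignment("r1", ASSIGNED, "a"),
            sz.Assignment("r2", ASSIGNED, "a"),
            sz.Assignment("r3", ASSIGNED, "b"),
            sz.Assignment("r4", AMBIGUOUS),
        ]
        table = sz.count_isoforms(assigns, "s1")
        assert table.counts == {"a": 2, "b": 1}
        assert table.assigned_total == 3
        assert table.total_reads == 4

    def test_empty_input_empty_table(self):
        table = sz.count_isoforms([], "s1")
        assert table.counts == {} and table.total_reads == 0

    def test_count_table_tsv_round_trip(self, tmp_path):
        table = sz.CountTable("s1", {"a|b": 5, "c|d": 2}, {ASSIGNED: 7})
        path = tmp_path / "counts.tsv"
        table.to_tsv(path)
        back = sz.CountTable.from_tsv(path)
        assert back.counts == table.counts
        assert back.sample == "s1"

    def test_switch_report_zero_rate_zero_switched(self, small_model, small_dual_pools):
        keys = sz.enumerate_isoforms(small_model)[:2]
        sim = sz.SimConfig(seed=10, n_molecules=400, proportions={k: 1.0 for k in keys})
        res = sz.run_simulation(small_model, small_dual_pools, sim)
        _table, assigns = sz.decode_pairs(res.reads, small_model, small_dual_pools)
        rep = sz.switch_report(assigns)
        assert rep.applicable and rep.n_switched == 0

    def test_switch_report_rate_in_99ci(self, small_model, small_dual_pools):
        keys = sz.enumerate_isoforms(small_model)[:2]
        rate, n = 0.02, 10_000
        sim = sz.SimConfig(
            seed=11, n_molecules=n, proportions={k: 1.0 for k in keys}, switch_rate=rate
        )
        res = sz.run_simulation(small_model, small_dual_pools, sim)
        _table, assigns = sz.decode_pairs(res.reads, small_model, small_dual_pools)
        rep = sz.switch_report(assigns)
        sd = np.sqrt(rate * (1 - rate) / n)
        assert abs(rep.fraction - rate) <= 2.576 * sd
        assert all(set(p) == {"pool1", "pool2"} for p in rep.patterns)

    def test_single_pool_switch_report_not_applicable(self):
        rep = sz.switch_report([], dual_pool=False)
        assert not rep.applicable

    def test_barcode_map_covers_internals(self, small_dual_pools):
        bm = sz.barcode_map(small_dual_pools)
        p1, _ = small_dual_pools
        n_internal = sum(1 for l in p1.ligamers if l.kind == "internal")
        assert len(bm) == 2 * n_internal
        assert set(bm["pool_label"]) == {"pool1", "pool2"}
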