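"""Ligamer design: trimming oracles, barcodes, pool planning, screening."""

import numpy as np
import pytest

import seqzip as sz
from seqzip.design import (
    INTERNAL,
    TERMINAL_3P,
    TERMINAL_5P,
    covering_transcripts,
    ligamer_target_dg,
)
from seqzip.errors import (
    CapacityError,
    DesignError,
    InfeasibleDesignError,
)
from seqzip.simulate import random_dna
from seqzip.thermo import melting_temp, reverse_complement


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestTerminalDesign:
    def test_trim_matches_full_scan_oracle(self, config):
        """The designed arm is exactly what an exhaustive scan over every
        anchored arm length picks: the longest with Tm <= tm_max whose
        one-nt extension (if any) exceeds tm_max."""
        rng = _rng(1)
        for _ in range(30):
            region = random_dna(60, rng)
            lig = sz.design_terminal_ligamer(region, "b0", "five_prime", "TAIL", config)
            arm = lig.arm_up
            assert region.endswith(arm)
            assert melting_temp(arm, config.duplex) <= config.tm_max
            if len(arm) < len(region):
                extended = region[len(region) - len(arm) - 1 :]
                assert melting_temp(extended, config.duplex) > config.tm_max
            # oracle: scan all suffix lengths from the top
            expected = None
            for length in range(len(region), 1, -1):
                cand = region[len(region) - length :]
                if melting_temp(cand, config.duplex) <= config.tm_max:
                    expected = cand
                    break
            assert arm == expected

    def test_three_prime_is_prefix(self, config):
        region = random_dna(60, _rng(2))
        lig = sz.design_terminal_ligamer(region, "bN", "three_prime", "TAIL", config)
        assert region.startswith(lig.arm_up)
        assert lig.kind == TERMINAL_3P
        assert lig.sequence == lig.arm_up + "TAIL"

    def test_weak_region_returns_exhausted_flag(self, config):
        region = "AT" * 15  # full 30-mer still melts below 65 °C
        lig = sz.design_terminal_ligamer(region, "b0", "five_prime", "T" * 4, config)
        assert lig.arm_up == region
        assert "exhausted" in lig.flags

    def test_gc_rich_arm_shorter_than_at_rich(self, config):
        gc = sz.design_terminal_ligamer("GC" * 30, "g", "five_prime", "", config)
        at = sz.design_terminal_ligamer("ATTA" * 15, "a", "five_prime", "", config)
        assert len(gc.arm_up) < len(at.arm_up)

    def test_empty_region_errors(self, config):
        with pytest.raises(DesignError):
            sz.design_terminal_ligamer("", "b0", "five_prime", "", config)


class TestInternalDesign:
    def _targets(self, seed, n=60):
        rng = _rng(seed)
        seq = random_dna(n, rng)
        half = n // 2
        return (seq[:half], "x", 0), (seq[half:], "x", half)

    def test_matches_exhaustive_pair_oracle(self, config):
        """The arm pair equals the exhaustive enumeration of all feasible
        (len_up, len_down) pairs under both constraints, using the stated
        tie-break (longest upstream, then longest downstream)."""
        low, high = config.arm_tm_window
        found = 0
        for seed in range(40):
            up, down = self._targets(seed, 80)
            barcode = "ACGTACG"
            try:
                lig = sz.design_internal_ligamer(up, down, barcode, config)
            except InfeasibleDesignError:
                continue
            found += 1
            feasible = []
            for lu in range(config.min_arm_length, len(up[0]) + 1):
                if not low <= melting_temp(up[0][:lu], config.duplex) <= high:
                    continue
                for ld in range(config.min_arm_length, len(down[0]) + 1):
                    if not low <= melting_temp(down[0][len(down[0]) - ld :], config.duplex) <= high:
                        continue
                    if lu + ld + len(barcode) <= config.max_len:
                        feasible.append((lu, ld))
            assert feasible, "implementation found a pair the oracle did not"
            lu, ld = max(feasible)
            assert (len(lig.arm_up), len(lig.arm_down)) == (lu, ld)
            assert len(lig) <= config.max_len
        assert found >= 20  # the oracle must actually have been exercised

    def test_symmetric_targets_symmetric_arms(self, config):
        # identical moderately AT-rich 25-nt targets: feasible and symmetric
        seq = "ACCATTATTCCGGCATGATGAGGAT"
        lig = sz.design_internal_ligamer((seq, "u", 0), (seq, "d", 0), "ACGTACG", config)
        assert len(lig.arm_up) == len(lig.arm_down)

    def test_infeasible_length_bound(self, config):
        up = ("GC" * 15, "u", 0)
        down = ("CG" * 15, "d", 0)
        with pytest.raises(InfeasibleDesignError) as exc:
            sz.design_internal_ligamer(up, down, "A" * 45, config)
        assert exc.value.constraint == "max_len"

    def test_unreachable_tm_window(self, config):
        up = ("AT" * 10, "u", 0)  # never reaches 55 °C
        down = ("GCATGCATGCATGCATGCAT", "d", 0)
        with pytest.raises(InfeasibleDesignError) as exc:
            sz.design_internal_ligamer(up, down, "ACGTACG", config)
        assert exc.value.constraint == "arm_tm"


class TestBarcodes:
    def test_invariants(self):
        bs = sz.generate_barcodes(24, 7, min_hamming=3, seed=1)
        codes = bs.codes
        assert len(set(codes)) == 24
        assert all(len(c) == 7 for c in codes)
        for i, a in enumerate(codes):
            run = 1
            best = 1
            for x, y in zip(a, a[1:]):
                run = run + 1 if x == y else 1
                best = max(best, run)
            assert best <= 3
            for b in codes[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 3

    def test_reproducible_under_seed(self):
        a = sz.generate_barcodes(10, 7, seed=9).codes
        b = sz.generate_barcodes(10, 7, seed=9).codes
        assert a == b

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            sz.generate_barcodes(20, 1)

    def test_dual_pool_codes_differ(self, small_model, config):
        p1, p2 = sz.plan_dual_pools(small_model, config, barcode_seed=5)
        for lig1 in p1.ligamers:
            if lig1.kind == INTERNAL:
                lig2 = p2.get(lig1.id)
                assert lig1.spacer != lig2.spacer
                assert lig1.arms == lig2.arms  # only the code differs


class TestPoolPlanning:
    def test_fn1_like_pool_has_six_ligamers(self, config):
        pool = sz.plan_pool(sz.fn1_like_model(seed=0), config)
        assert len(pool) == 6
        kinds = [l.kind for l in pool.ligamers]
        assert kinds.count(TERMINAL_5P) == 1 and kinds.count(TERMINAL_3P) == 1

    def test_dscam_like_pool_has_97_ligamers(self, config):
        pool = sz.plan_pool(sz.dscam_like_model(seed=0), config)
        assert len(pool) == 97

    def test_single_constitutive_transcript_terminals_only(self, config):
        model = sz.GeneModel(
            "mono",
            (
                sz.ConstitutiveBlock("b0", random_dna(60, _rng(4))),
                sz.ConstitutiveBlock("b1", random_dna(60, _rng(5))),
            ),
        )
        pool = sz.plan_pool(model, config)
        assert len(pool) == 2

    def test_pool_size_formula_random_models(self, config):
        """len(pool) = 2 + n_variant_exons + n_separating_blocks."""
        rng = _rng(11)
        for seed in range(6):
            sizes = [int(rng.integers(1, 5)) for _ in range(int(rng.integers(1, 4)))]
            model = sz.synth_gene(
                variants_per_cluster=sizes, exon_length=60, block_length=60, seed=seed
            )
            pool = sz.plan_pool(model, config)
            n_sep = sum(
                1
                for r in model.regions[1:-1]
                if isinstance(r, sz.ConstitutiveBlock)
            )
            assert len(pool) == 2 + sum(sizes) + n_sep
            sz.validate_pool(pool, config)

    def test_variant_region_at_end_rejected(self, config):
        model = sz.GeneModel(
            "bad",
            (
                sz.ConstitutiveBlock("b0", random_dna(60, _rng(6))),
                sz.VariantRegion(
                    "c1", "cassette", (sz.Variant("c1.1", random_dna(60, _rng(7))),)
                ),
            ),
        )
        with pytest.raises(DesignError):
            sz.plan_pool(model, config)

    def test_design_deterministic_byte_identical(self, small_model, config):
        a = sz.pool_to_tsv(sz.plan_pool(small_model, config, barcode_seed=5))
        b = sz.pool_to_tsv(sz.plan_pool(small_model, config, barcode_seed=5))
        assert a == b

    def test_validator_passes_emitted_pools(self, config):
        for seed in range(4):
            model = sz.synth_gene(variants_per_cluster=[3, 2], seed=seed)
            sz.validate_pool(sz.plan_pool(model, config), config)


class TestSpecificityScreen:
    def test_distinct_variants_no_offtargets_positive_gaps(self, config):
        model = sz.synth_gene(variants_per_cluster=[3, 3], similarity=0.0, seed=21)
        pool = sz.plan_pool(model, config)
        report = sz.screen_pool_specificity(pool, model, config=config)
        assert (report["off_target_hits"] == 0).all()
        gaps = report.loc[report["gap"].notna(), "gap"]
        assert (gaps > 0).all()

    def test_identical_variants_gap_zero_flagged(self, config):
        model = sz.synth_gene(variants_per_cluster=[2], similarity=1.0, seed=22)
        # identical variants need distinct ids but share sequence
        pool = sz.plan_pool(model, config)
        report = sz.screen_pool_specificity(pool, model, config=config)
        gaps = report.loc[report["gap"].notna()]
        assert len(gaps) == 2
        assert (gaps["gap"] == 0).all()
        assert gaps["flagged"].all()

    def test_gap_equals_bruteforce_all_pairs(self, config):
        """Reported gaps equal a direct all-pairs free-energy computation."""
        model = sz.synth_gene(variants_per_cluster=[4], similarity=0.8, seed=23)
        pool = sz.plan_pool(model, config)
        report = sz.screen_pool_specificity(pool, model, config=config).set_index("ligamer_id")
        region = model.variant_regions[0]
        seqs = {v.id: v.sequence for v in region.variants}
        for vid in seqs:
            lig = pool.get(vid)
            cog = ligamer_target_dg(lig, seqs[vid], config)
            near = min(
                ligamer_target_dg(lig, seqs[w], config) for w in seqs if w != vid
            )
            assert report.loc[vid, "cognate_dg"] == pytest.approx(cog)
            assert report.loc[vid, "gap"] == pytest.approx(near - cog)

    def test_cognate_dg_well_below_zero(self, config):
        model = sz.synth_gene(variants_per_cluster=[3], seed=24)
        pool = sz.plan_pool(model, config)
        report = sz.screen_pool_specificity(pool, model, config=config)
        cog = report.loc[report["cognate_dg"].notna(), "cognate_dg"]
        assert (cog < -20).all()  # two in-window arms are strongly bound
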