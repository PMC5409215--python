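"""Pairwise r², LD decay, D' confidence intervals, Gabriel blocks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_gm
from oracles import dprime_ci_oracle, gabriel_blocks_oracle, pair_r2
from slafpop.ld_blocks import (
    HaplotypeBlockSet,
    dprime_ci,
    gabriel_blocks,
    ld_decay,
    ld_decay_scopes,
    pairwise_r2,
    summarize_blocks,
)
from slafpop.tables import block_table

nan = float("nan")


class TestPairwiseR2:
    def test_identical_columns_r2_one(self):
        d = np.tile([0.0, 1.0, 2.0, 0.0, 2.0, 1.0], (2, 1)).T
        gm = make_gm(d)
        tab = pairwise_r2(gm, "A01", maf_min=0.0)
        assert tab["r2"].iloc[0] == pytest.approx(1.0)

    def test_orthogonal_columns_r2_zero(self):
        d = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=float)
        tab = pairwise_r2(make_gm(d), "A01", maf_min=0.0)
        assert tab["r2"].iloc[0] == pytest.approx(0.0)

    def test_matches_explicit_loop_oracle_with_missing(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(30, 15)).astype(float)
        d[rng.random(d.shape) < 0.15] = nan
        gm = make_gm(d)
        tab = pairwise_r2(gm, "A01", maf_min=0.0)
        got = {(r.pos_i, r.pos_j): r.r2 for r in tab.itertuples()}
        pos = gm.markers["pos"].to_numpy()
        # markers with panel MAF 0 are pre-dropped; oracle applies same rule
        from oracles import col_maf

        keep = [j for j in range(15) if col_maf(d[:, j]) > 0.0]
        for a, b in itertools.combinations(keep, 2):
            expect = pair_r2(d[:, a], d[:, b])
            if expect is None:
                assert (pos[a], pos[b]) not in got
            else:
                assert got[pos[a], pos[b]] == pytest.approx(expect)

    def test_dosage_flip_invariance(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(40, 6)).astype(float)
        t1 = pairwise_r2(make_gm(d), "A01", maf_min=0.0)
        d2 = d.copy()
        d2[:, 2] = 2 - d2[:, 2]
        t2 = pairwise_r2(make_gm(d2), "A01", maf_min=0.0)
        pd.testing.assert_frame_equal(t1, t2)

    def test_max_distance_filter(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, size=(30, 10)).astype(float)
        gm = make_gm(d, positions=np.arange(1, 11) * 1000)
        tab = pairwise_r2(gm, "A01", max_distance_bp=2500, maf_min=0.0)
        assert (tab["distance"] <= 2500).all()


class TestDecay:
    def test_interpolated_crossing_example(self):
        pairs = pd.DataFrame(
            {"chrom": "A01", "pos_i": 1, "pos_j": 1,
             "distance": [10_000] * 2 + [50_000] * 2, "r2": [0.5, 0.5, 0.08, 0.08]}
        )
        curve = ld_decay(pairs, threshold=0.1, bin_width_bp=20_000)
        # bin centers 10 kb and 50 kb, means 0.5 and 0.08
        expect = 10_000 + 40_000 * (0.5 - 0.1) / (0.5 - 0.08)
        assert curve.decay_distance == pytest.approx(expect)

    def test_never_crossing_undefined(self):
        pairs = pd.DataFrame(
            {"chrom": "A01", "pos_i": 1, "pos_j": 2, "distance": [100, 5000],
             "r2": [1.0, 1.0]}
        )
        assert ld_decay(pairs, 0.1, 1000).decay_distance is None

    def test_decay_distance_monotone_in_threshold(self, panel):
        gm, _ = panel
        pairs = pairwise_r2(gm, "C01")
        d_high = ld_decay(pairs, threshold=0.3).decay_distance
        d_low = ld_decay(pairs, threshold=0.1).decay_distance
        if d_high is not None and d_low is not None:
            assert d_low >= d_high

    def test_scopes_pool_chromosomes(self, panel, small_genome):
        gm, _ = panel
        scopes = ld_decay_scopes(gm, small_genome.subgenomes)
        assert {"A01", "C01", "A", "C", "genome"} <= set(scopes)


class TestDprimeCi:
    @staticmethod
    def from_haplotypes(h1_counts, n_ind, rng):
        """Build dosage columns from haplotype frequencies."""
        haps = rng.choice(4, size=2 * n_ind, p=h1_counts)
        a1 = haps // 2
        a2 = haps % 2
        return (
            (a1[:n_ind] + a1[n_ind:]).astype(float),
            (a2[:n_ind] + a2[n_ind:]).astype(float),
        )

    def test_complete_ld_dprime_one(self):
        rng = np.random.default_rng(9)
        # only AB and ab haplotypes, equifrequent
        ci = None
        col_i, col_j = self.from_haplotypes([0.5, 0, 0, 0.5], 50, rng)
        ci = dprime_ci(col_i, col_j)
        assert ci is not None
        point, low, high = ci
        assert point == pytest.approx(1.0)
        assert high >= 0.99
        assert low >= 0.9  # complete LD: interval hugs 1

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(10)
        col_i, col_j = self.from_haplotypes([0.25, 0.25, 0.25, 0.25], 400, rng)
        point, low, high = dprime_ci(col_i, col_j)
        assert point < 0.15
        assert low < 0.1

    def test_insufficient_data_undefined(self):
        assert dprime_ci([0.0, 2.0, nan], [0.0, 2.0, nan]) is None

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.integers(0, 3, size=(40, 2)).astype(float)
        d[rng.random(d.shape) < 0.1] = nan
        got = dprime_ci(d[:, 0], d[:, 1])
        expect = dprime_ci_oracle(d[:, 0], d[:, 1])
        if expect is None:
            assert got is None
        else:
            assert got == pytest.approx(expect, abs=1e-9)


class TestGabrielBlocks:
    def test_perfect_ld_single_block(self):
        rng = np.random.default_rng(11)
        base = rng.integers(0, 2, size=(100, 2)).sum(axis=1).astype(float)
        d = np.column_stack([base] * 5)
        gm = make_gm(d, positions=[100, 200, 300, 400, 500])
        bs = gabriel_blocks(gm, "A01")
        assert len(bs) == 1
        row = bs.blocks.iloc[0]
        assert (row["first"], row["last"]) == (0, 4)
        assert row["length_bp"] == 400

    def test_independent_markers_no_blocks(self):
        rng = np.random.default_rng(12)
        d = (rng.integers(0, 2, size=(120, 8)) + rng.integers(0, 2, size=(120, 8))).astype(float)
        gm = make_gm(d)
        assert len(gabriel_blocks(gm, "A01")) == 0

    def test_matches_exhaustive_enumeration_oracle(self, small_genome):
        from slafpop.simulate import SimPopSpec, simulate_population

        spec = SimPopSpec(
            n_accessions=60, n_markers_per_chrom=12, k_true=1, fst=0.2,
            switch_rate_a=2e-5, switch_rate_c=2e-5, missing_rate=0.02, seed=21,
        )
        gm, _ = simulate_population(small_genome, spec)
        for chrom in gm.chroms:
            idx = gm.markers_on(chrom)
            sub = gm.take_markers(idx)
            bs = gabriel_blocks(gm, chrom)
            expect = gabriel_blocks_oracle(
                sub.dosages, sub.markers["pos"].to_numpy()
            )
            assert sorted(zip(bs.blocks["first"], bs.blocks["last"])) == expect

    def test_blocks_within_chromosome_and_disjoint(self, panel):
        gm, _ = panel
        idx = gm.markers_on("C01")[:15]
        sub = gm.take_markers(idx)
        bs = gabriel_blocks(sub, "C01")
        spans = sorted(zip(bs.blocks["first"], bs.blocks["last"]))
        for (a1, b1), (a2, b2) in zip(spans[:-1], spans[1:]):
            assert b1 < a2
        pos = sub.markers["pos"].to_numpy()
        assert bs.blocks["length_bp"].sum() <= pos.max() - pos.min()


class TestBlockSummary:
    @pytest.fixture(scope="class")
    def printed(self):
        per_chrom, total = block_table()
        return per_chrom, total

    def test_per_chromosome_frequency_arithmetic(self, printed):
        per_chrom, _ = printed
        summ = summarize_blocks(
            per_chrom.rename(columns={"block_length_bp": "total_length_bp"}),
            dict(zip(per_chrom["chrom"], per_chrom["chrom_length_bp"])),
            {c: c[0] for c in per_chrom["chrom"]},
        )
        got = dict(zip(summ["per_chrom"]["chrom"], summ["per_chrom"]["frequency_pct"]))
        for _, r in per_chrom.iterrows():
            assert got[r["chrom"]] == pytest.approx(r["frequency_pct"], abs=0.005)

    def test_subgenome_means_match_printed_aggregation(self, printed):
        per_chrom, _ = printed
        summ = summarize_blocks(
            per_chrom.rename(columns={"block_length_bp": "total_length_bp"}),
            dict(zip(per_chrom["chrom"], per_chrom["chrom_length_bp"])),
            {c: c[0] for c in per_chrom["chrom"]},
        )
        sub = summ["per_subgenome"].set_index("subgenome")
        assert sub.loc["A", "mean_n_blocks"] == pytest.approx(1208.5)
        assert sub.loc["A", "mean_frequency_pct"] == pytest.approx(10.28, abs=0.005)
        assert sub.loc["C", "mean_frequency_pct"] == pytest.approx(14.20, abs=0.005)

    def test_genome_row_matches_printed_total(self, printed):
        per_chrom, total = printed
        summ = summarize_blocks(
            per_chrom.rename(columns={"block_length_bp": "total_length_bp"}),
            dict(zip(per_chrom["chrom"], per_chrom["chrom_length_bp"])),
            {c: c[0] for c in per_chrom["chrom"]},
        )
        g = summ["genome"].iloc[0]
        assert g["n_blocks"] == total["n_blocks"].iloc[0]
        assert g["frequency_pct"] == pytest.approx(12.53, abs=0.005)

    def test_single_full_coverage_block_is_100pct(self):
        per = pd.DataFrame(
            {"chrom": ["A01"], "n_blocks": [1], "total_length_bp": [5000]}
        )
        summ = summarize_blocks(per, {"A01": 5000}, {"A01": "A"})
        assert summ["per_chrom"]["frequency_pct"].iloc[0] == 100.0

    def test_size_class_histogram(self):
        blocks = pd.DataFrame(
            {"chrom": "A01", "first": 0, "last": 1, "start_bp": 1,
             "end_bp": 1, "length_bp": [500, 5_000, 50_000, 500_000]}
        )
        hist = HaplotypeBlockSet(blocks).size_class_histogram()
        assert list(hist.values()) == [1, 1, 1, 1]
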