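"""Marker filtering, hotspots, window densities, rich regions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_gm
from oracles import col_integrity, col_maf, col_mutation_frequency
from slafpop.snp_stats import (
    call_hotspots,
    compare_rich_regions_by_ecotype,
    density_per_100kb,
    filter_markers,
    hotspot_counts_per_chrom,
    integrity,
    minor_allele_frequency,
    mutation_frequency,
    snp_rich_regions,
    windowed_snp_counts,
)

nan = float("nan")

dosage_columns = st.lists(
    st.sampled_from([0.0, 1.0, 2.0, nan]), min_size=1, max_size=40
).filter(lambda c: any(not math.isnan(g) for g in c))


class TestColumnStats:
    def test_maf_example(self):
        assert minor_allele_frequency([0, 0, 1, 2]) == pytest.approx(0.375)

    def test_maf_monomorphic(self):
        assert minor_allele_frequency([0, 0, 0, 0]) == 0.0

    def test_maf_all_missing_undefined(self):
        assert math.isnan(minor_allele_frequency([nan, nan]))

    @given(dosage_columns)
    def test_maf_matches_counting_oracle_and_bounds(self, col):
        got = minor_allele_frequency(col)
        assert got == pytest.approx(col_maf(col))
        assert 0.0 <= got <= 0.5

    def test_integrity_examples(self):
        assert integrity([0] * 8 + [nan] * 2) == pytest.approx(0.8)
        assert integrity([1, 2, 0]) == 1.0

    @given(dosage_columns)
    def test_integrity_matches_oracle(self, col):
        assert integrity(col) == pytest.approx(col_integrity(col))

    def test_mutation_frequency_boundary(self):
        assert mutation_frequency([1, 2, 2, 2, 0]) == pytest.approx(0.8)
        assert mutation_frequency([2, 2, 2, 2, 2]) == 1.0

    @given(dosage_columns)
    def test_mutation_frequency_matches_oracle(self, col):
        assert mutation_frequency(col) == pytest.approx(col_mutation_frequency(col))


class TestFilter:
    def test_strict_boundaries_removed(self):
        # marker 0: integrity exactly 0.8; marker 1: MAF exactly 0.05
        col_int = [1.0] * 8 + [nan, nan]
        col_maf_ = [1.0] + [0.0] * 9  # p = 1/20 = 0.05
        col_ok = [0.0, 1.0, 1.0, 2.0] + [1.0] * 6
        gm = make_gm(np.column_stack([col_int, col_maf_, col_ok]))
        kept = filter_markers(gm)
        assert kept.n_markers == 1
        assert kept.markers["pos"].tolist() == [300]

    def test_matches_per_marker_predicate_oracle(self, panel):
        gm, _ = panel
        kept = filter_markers(gm, 0.05, 0.8)
        expect = [
            j
            for j in range(gm.n_markers)
            if col_maf(gm.dosages[:, j]) > 0.05
            and col_integrity(gm.dosages[:, j]) > 0.8
        ]
        assert kept.markers["pos"].tolist() == gm.markers["pos"].iloc[expect].tolist()

    def test_monotone_in_thresholds(self, panel):
        gm, _ = panel
        base = filter_markers(gm, 0.05, 0.8).n_markers
        assert filter_markers(gm, 0.10, 0.8).n_markers <= base
        assert filter_markers(gm, 0.05, 0.9).n_markers <= base

    def test_accession_permutation_invariance(self, panel):
        gm, _ = panel
        rng = np.random.default_rng(0)
        perm = rng.permutation(gm.n_accessions)
        kept1 = filter_markers(gm)
        kept2 = filter_markers(gm.take_accessions(perm))
        assert kept1.markers["pos"].tolist() == kept2.markers["pos"].tolist()


class TestHotspots:
    def test_no_hotspots_at_half_frequency(self):
        gm = make_gm(np.tile([0.0, 0.0, 2.0, 2.0], (5, 1)).T)
        assert call_hotspots(gm, 0.8).size == 0

    def test_threshold_zero_catches_any_nonref(self):
        d = np.array([[0, 0, 0], [0, 1, 0], [0, 0, 0], [0, 0, 2]], dtype=float)
        gm = make_gm(d)
        assert call_hotspots(gm, 0.0).tolist() == [1, 2]

    def test_per_chromosome_counts_match_recount(self, panel):
        gm, _ = panel
        counts = hotspot_counts_per_chrom(gm, 0.8)
        chrom = gm.markers["chrom"].to_numpy()
        for c in gm.chroms:
            expect = sum(
                1
                for j in range(gm.n_markers)
                if chrom[j] == c and col_mutation_frequency(gm.dosages[:, j]) > 0.8
            )
            assert counts[c] == expect


class TestWindows:
    def test_assignment_example(self):
        gm = make_gm(np.ones((4, 3)), positions=[5, 150_000, 150_050])
        wc = windowed_snp_counts(gm, {"A01": 200_000}, 100_000)
        assert wc.windows["count"].tolist() == [1, 2]

    def test_counts_conserved(self, panel, small_genome):
        gm, _ = panel
        wc = windowed_snp_counts(gm, small_genome.lengths, 50_000)
        assert wc.total() == gm.n_markers

    def test_marker_beyond_length_rejected(self):
        gm = make_gm(np.ones((2, 1)), positions=[5000])
        with pytest.raises(ValueError, match="beyond"):
            windowed_snp_counts(gm, {"A01": 1000}, 100)

    @pytest.mark.parametrize(
        "n_snps,length_bp,expected",
        [
            (63_307, 238_690_000, 27),  # A-subgenome printed density
            (5_352, 17_400_000, 31),  # printed A10 density
        ],
    )
    def test_printed_density_arithmetic(self, n_snps, length_bp, expected):
        assert density_per_100kb(n_snps, length_bp) == expected


class TestRichRegions:
    def make_wc(self, counts, window=100_000):
        gm = make_gm(np.ones((2, 1)), positions=[1])
        lengths = {"A01": window * len(counts)}
        wc = windowed_snp_counts(gm, lengths, window)
        wc.windows["count"] = counts
        return wc

    def test_ceil_rule_selects_three_of_300(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=300)
        wc = self.make_wc(list(counts))
        regions = snp_rich_regions(wc, 0.01)
        assert regions.regions["snp_count"].sum() >= np.sort(counts)[-3:].sum()

    def test_adjacent_windows_merge(self):
        wc = self.make_wc([1, 9, 9, 1, 1, 1, 1, 1, 1, 1])
        regions = snp_rich_regions(wc, 0.2)
        assert len(regions) == 1
        row = regions.regions.iloc[0]
        assert (row["start"], row["end"], row["snp_count"]) == (100_000, 300_000, 18)

    def test_selection_equals_full_sort_oracle(self):
        rng = np.random.default_rng(2)
        counts = list(rng.integers(0, 100, size=157))
        wc = self.make_wc(counts)
        regions = snp_rich_regions(wc, 0.05)
        n_take = math.ceil(0.05 * len(counts))
        order = sorted(range(len(counts)), key=lambda i: (-counts[i], i))
        expect = sorted(order[:n_take])
        got = []
        for _, r in regions.regions.iterrows():
            got.extend(range(int(r["start"]) // 100_000, int(r["end"]) // 100_000))
        assert got == expect
        assert regions.regions["snp_count"].sum() == sum(counts[i] for i in expect)


class TestEcotypeContrast:
    def test_identical_subsets_same_presence(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(6, 60)).astype(float)
        d = np.vstack([d, d, d])  # three identical blocks
        eco = ["winter"] * 6 + ["semi-winter"] * 6 + ["spring"] * 6
        pos = np.sort(rng.choice(np.arange(1, 1_000_000), 60, replace=False))
        gm = make_gm(d, positions=pos, ecotype=eco)
        tab = compare_rich_regions_by_ecotype(gm, {"A01": 1_000_000}, 100_000, 0.1)
        assert (tab["winter"] == tab["semi-winter"]).all()
        assert (tab["winter"] == tab["spring"]).all()

    def test_private_polymorphism_present_only_there(self):
        # markers in the last window polymorphic only in winter accessions
        n_w, n_s = 8, 8
        rng = np.random.default_rng(4)
        shared = rng.integers(0, 3, size=(n_w + n_s, 20)).astype(float)
        private = np.zeros((n_w + n_s, 30))
        private[:n_w] = rng.integers(0, 3, size=(n_w, 30))
        d = np.hstack([shared, private])
        pos = np.concatenate(
            [np.sort(rng.choice(np.arange(1, 900_000), 20, replace=False)),
             np.sort(rng.choice(np.arange(900_001, 1_000_000), 30, replace=False))]
        )
        eco = ["winter"] * n_w + ["spring"] * n_s
        gm = make_gm(d, positions=pos, ecotype=eco)
        tab = compare_rich_regions_by_ecotype(gm, {"A01": 1_000_000}, 100_000, 0.1)
        last = tab[(tab["start"] >= 900_000)]
        assert len(last) == 1
        assert bool(last["winter"].iloc[0]) is True
        assert bool(last["spring"].iloc[0]) is False
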