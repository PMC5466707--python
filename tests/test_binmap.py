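"""Tests of bin construction, recombination fractions and the linkage map."""

import numpy as np
import pandas as pd
import pytest

import binmapper as bm
from binmapper.binmap import (BinSet, build_bins, construct_linkage_map,
                              flag_misplaced_bins, kosambi_cM, kosambi_r,
                              pairwise_r, pairwise_r_matrix, ril_correct,
                              snap_to_grid)
from binmapper.codes import A, B, H, NOCALL, symbols_to_calls


def _binset_from_symbols(columns, chrom="chr1", width=20_000):
    """Helper: bins at consecutive 20-kb intervals from symbol strings."""
    geno = np.vstack([symbols_to_calls(list(c)) for c in columns])
    bins = pd.DataFrame({
        "bin_id": np.arange(len(columns)),
        "chrom": chrom if isinstance(chrom, str) else chrom,
        "start": np.arange(len(columns)) * width,
        "end": (np.arange(len(columns)) + 1) * width,
    })
    return BinSet(bins=bins, genotypes=geno)


class TestBuildBins:
    def test_no_breakpoints_gives_one_bin_per_chromosome(self):
        snps = pd.DataFrame({"chrom": ["chr1"] * 4 + ["chr2"] * 4,
                             "pos": [10, 20, 30, 40] * 2})
        tracks = np.full((6, 8), A, dtype=np.int8)
        bp = pd.DataFrame(columns=["ril", "chrom", "midpoint"])
        bs = build_bins(bp, tracks, snps, {"chr1": 50_000, "chr2": 60_000})
        assert len(bs.bins) == 2
        assert bs.bins["end"].tolist() == [50_000, 60_000]

    def test_nearby_breakpoints_snap_to_one_grid_cell(self):
        # breakpoints at 149 kb and 151 kb both land in the 140-160 kb cell
        assert snap_to_grid(np.array([149_000, 151_000])).tolist() == [140_000, 140_000]
        snps = pd.DataFrame({"chrom": "chr1",
                             "pos": np.arange(1, 301) * 1000})
        tracks = np.full((2, 300), A, dtype=np.int8)
        tracks[0, 148:] = B   # RIL0 switches after 149 kb
        tracks[1, 150:] = B   # RIL1 switches after 151 kb
        bp = pd.DataFrame({"ril": [0, 1], "chrom": "chr1",
                           "midpoint": [149_000, 151_000]})
        bs = build_bins(bp, tracks, snps, {"chr1": 300_000})
        assert len(bs.bins) == 2
        assert bs.bins["start"].tolist() == [0, 140_000]

    def test_breakpoint_outside_chromosome_rejected(self):
        snps = pd.DataFrame({"chrom": ["chr1"], "pos": [10]})
        bp = pd.DataFrame({"ril": [0], "chrom": ["chr1"], "midpoint": [99_999_999]})
        with pytest.raises(ValueError):
            build_bins(bp, np.full((1, 1), A, dtype=np.int8), snps, {"chr1": 1000})

    def test_bins_partition_each_chromosome(self, binset, truth):
        for chrom, L in truth.chrom_lengths.items():
            sub = binset.bins[binset.bins["chrom"] == chrom].sort_values("start")
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == L
            assert (sub["start"].iloc[1:].to_numpy()
                    == sub["end"].iloc[:-1].to_numpy()).all()
            # 20-kb floor except possibly the terminal bin
            assert ((sub["end"] - sub["start"]).iloc[:-1] >= 20_000).all()

    def test_adjacent_bins_differ_in_genotype_column(self, binset):
        for chrom, grp in binset.bins.groupby("chrom"):
            idx = grp.sort_values("start").index.to_numpy()
            for i, j in zip(idx[:-1], idx[1:]):
                assert not np.array_equal(binset.genotypes[i], binset.genotypes[j])

    def test_rebinning_at_own_boundaries_is_idempotent(self, binset, tracks,
                                                       parents, truth):
        internal = binset.bins.groupby("chrom")["start"].apply(
            lambda s: s.iloc[1:]).reset_index()
        bp = pd.DataFrame({"ril": 0, "chrom": internal["chrom"],
                           "midpoint": internal["start"]})
        again = build_bins(bp, tracks, parents, truth.chrom_lengths)
        pd.testing.assert_frame_equal(binset.bins, again.bins)
        assert np.array_equal(binset.genotypes, again.genotypes)


class TestPairwiseR:
    def test_identical_columns_have_zero_r(self):
        col = symbols_to_calls(list("aabb"))
        assert pairwise_r(col, col, min_informative=2) == 0.0

    def test_one_discordant_line_in_four(self):
        c1 = symbols_to_calls(list("aabb"))
        c2 = symbols_to_calls(list("abbb"))
        assert pairwise_r(c1, c2, min_informative=2) == 0.25

    def test_het_and_missing_excluded(self):
        c1 = symbols_to_calls(list("ab-b"))
        c2 = symbols_to_calls(list("ahbb"))
        # informative pairs: positions 0 and 3, both concordant
        assert pairwise_r(c1, c2, min_informative=2) == 0.0

    def test_insufficient_data_gives_nan(self):
        c1 = symbols_to_calls(list("ab"))
        assert np.isnan(pairwise_r(c1, c1, min_informative=10))

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        G = rng.choice([NOCALL, A, B, H], p=[0.05, 0.45, 0.45, 0.05],
                       size=(8, 60)).astype(np.int8)
        M = pairwise_r_matrix(G)
        for i in range(8):
            for j in range(8):
                expected = pairwise_r(G[i], G[j])
                if np.isnan(expected):
                    assert np.isnan(M[i, j])
                else:
                    assert M[i, j] == pytest.approx(expected)


class TestKosambi:
    def test_zero_r_is_zero_distance(self):
        assert kosambi_cM(0.0) == 0.0

    def test_known_value_at_r_point_two(self):
        assert kosambi_cM(0.2) == pytest.approx(25 * np.log(1.4 / 0.6), abs=1e-12)
        assert kosambi_cM(0.2) == pytest.approx(21.182, abs=1e-3)

    def test_small_r_slope_is_100(self):
        assert kosambi_cM(0.01) == pytest.approx(1.0, abs=0.01)
        assert kosambi_cM(1e-6) / 1e-6 == pytest.approx(100.0, rel=1e-6)

    def test_round_trip_to_1e9(self):
        r = np.linspace(0, 0.49, 2000)
        assert np.max(np.abs(kosambi_r(kosambi_cM(r)) - r)) < 1e-9

    def test_monotone_increasing(self):
        r = np.linspace(0, 0.499, 500)
        assert (np.diff(kosambi_cM(r)) > 0).all()

    def test_rejects_r_at_half(self):
        with pytest.raises(ValueError):
            kosambi_cM(0.5)

    def test_ril_correction_halves_small_fractions(self):
        assert ril_correct(0.2) == pytest.approx(0.125)
        assert float(ril_correct(0.0)) == 0.0


class TestLinkageMap:
    def test_two_chromosomes_give_two_groups(self):
        cfg = bm.SimConfig(n_rils=80, chrom_lengths=(200_000, 200_000),
                           chrom_morgans=(0.8, 0.8), seed=14)
        truth = bm.simulate_ril_population(cfg)
        from binmapper.binmap import bins_from_segments

        bs = bins_from_segments(truth)
        lmap = construct_linkage_map(bs)
        assert lmap.n_groups == 2
        groups_by_chrom = {}
        for rec in lmap.table.itertuples(index=False):
            chrom = bs.bins.loc[bs.bins["bin_id"] == rec.bin_id, "chrom"].iloc[0]
            groups_by_chrom.setdefault(chrom, set()).add(rec.group)
        # no chromosome is split across groups
        assert all(len(g) == 1 for g in groups_by_chrom.values())

    def test_noise_free_order_recovers_physical_order(self, truth_binset):
        lmap = construct_linkage_map(truth_binset)
        assert lmap.n_groups == len(set(truth_binset.bins["chrom"]))
        for g, grp in lmap.table.groupby("group"):
            ordered = grp.sort_values("order")["bin_id"].to_numpy()
            phys = truth_binset.bins.set_index("bin_id").loc[ordered, "start"].to_numpy()
            assert (np.diff(phys) > 0).all() or (np.diff(phys) < 0).all()

    def test_default_simulation_gives_nine_groups(self, binset):
        lmap = construct_linkage_map(binset)
        assert lmap.n_groups == 9

    def test_total_length_between_meiotic_and_expanded_budget(self, binset, sim_config):
        # the observed RIL map expands the per-meiosis map by up to twofold
        lmap = construct_linkage_map(binset)
        meiotic = 100 * sum(sim_config.chrom_morgans)
        assert meiotic < lmap.total_cM() < 2.0 * meiotic

    def test_cumulative_distance_nondecreasing(self, binset):
        lmap = construct_linkage_map(binset)
        for _, grp in lmap.table.groupby("group"):
            cum = grp.sort_values("order")["cM_cumulative"].to_numpy()
            assert (np.diff(cum) >= 0).all()

    def test_more_recombinants_never_shrink_distance(self):
        base = list("aaaaaaaaaabbbbbbbbbb")
        c1 = symbols_to_calls(base)
        distances = []
        for n_rec in range(0, 5):
            other = base.copy()
            for i in range(n_rec):
                other[i] = "b"
            c2 = symbols_to_calls(other)
            distances.append(kosambi_cM(pairwise_r(c1, c2)))
        assert (np.diff(distances) > 0).all()


class TestMisplacedBins:
    def _gradient_binset(self, n_bins=12, n_rils=120, step=3):
        """Adjacent columns differ by `step` recombinant lines (r ~ step/n)."""
        rng = np.random.default_rng(5)
        cols = [rng.choice([A, B], size=n_rils).astype(np.int8)]
        for _ in range(n_bins - 1):
            nxt = cols[-1].copy()
            flip = rng.choice(n_rils, size=step, replace=False)
            nxt[flip] = np.where(nxt[flip] == A, B, A).astype(np.int8)
            cols.append(nxt)
        bins = pd.DataFrame({"bin_id": np.arange(n_bins), "chrom": "chr1",
                             "start": np.arange(n_bins) * 20_000,
                             "end": (np.arange(n_bins) + 1) * 20_000})
        return BinSet(bins=bins, genotypes=np.vstack(cols))

    def test_correct_order_yields_empty_report(self):
        bs = self._gradient_binset()
        assert len(flag_misplaced_bins(bs)) == 0

    def test_translocated_block_flagged_with_true_neighbour(self):
        bs = self._gradient_binset()
        # physically displace bin 2 to the far end of the chromosome
        bins = bs.bins.copy()
        bins.loc[2, ["start", "end"]] = [240_000, 260_000]
        bins = bins.sort_values("start").reset_index(drop=True)
        order = bins["bin_id"].to_numpy()
        shuffled = BinSet(bins=bins.assign(
            start=np.arange(len(bins)) * 20_000,
            end=(np.arange(len(bins)) + 1) * 20_000),
            genotypes=bs.genotypes[order])
        report = flag_misplaced_bins(shuffled)
        assert report["bin_id"].tolist() == [2]
        assert report["partner_bin"].iloc[0] in (1, 3)

    def test_block_on_wrong_chromosome_flagged_cross_group(self):
        bs = self._gradient_binset()
        rng = np.random.default_rng(9)
        other_cols = np.vstack([rng.choice([A, B], size=bs.n_rils).astype(np.int8)
                                for _ in range(4)])
        extra = pd.DataFrame({"bin_id": np.arange(12, 16), "chrom": "chr2",
                              "start": np.arange(4) * 20_000,
                              "end": (np.arange(4) + 1) * 20_000})
        # move bin 5 from chr1 into the middle of chr2
        bins = pd.concat([bs.bins, extra], ignore_index=True)
        bins.loc[5, "chrom"] = "chr2"
        bins.loc[5, ["start", "end"]] = [80_000, 100_000]
        combined = BinSet(bins=bins, genotypes=np.vstack([bs.genotypes, other_cols]))
        report = flag_misplaced_bins(combined)
        assert 5 in report["bin_id"].tolist()
        rec = report[report["bin_id"] == 5].iloc[0]
        assert rec["proposed_chrom"] == "chr1"
        assert rec["partner_bin"] in (4, 6)
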