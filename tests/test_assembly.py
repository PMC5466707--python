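"""Tests of scaffold anchoring, correction application and gap filling."""

import numpy as np
import pandas as pd
import pytest

import binmapper as bm
from binmapper.assembly import (anchor_scaffolds, apply_corrections, fill_gaps,
                                find_gaps, revcomp)
from binmapper.binmap import BinSet, bins_from_segments
from binmapper.codes import NOCALL


@pytest.fixture(scope="module")
def ref_binset():
    cfg = bm.SimConfig(seed=9)
    truth = bm.simulate_ril_population(cfg)
    return bins_from_segments(truth)


def _cut_scaffold(ref, chrom, lo, hi, name, reverse=False):
    sel = ref.bins[(ref.bins["chrom"] == chrom)
                   & (ref.bins["start"] >= lo) & (ref.bins["end"] <= hi)]
    idx = sel.index.to_numpy()
    sbins = sel.copy()
    if reverse:
        width = hi - lo
        sbins = sbins.iloc[::-1].reset_index(drop=True)
        new_start = width - (sel["end"].to_numpy()[::-1] - lo)
        new_end = width - (sel["start"].to_numpy()[::-1] - lo)
        sbins["start"], sbins["end"] = new_start, new_end
        idx = idx[::-1]
    else:
        sbins = sbins.reset_index(drop=True)
        sbins["start"] -= lo
        sbins["end"] -= lo
    sbins["chrom"] = name
    return BinSet(bins=sbins, genotypes=ref.genotypes[idx]), hi - lo


class TestAnchoring:
    def test_scaffold_returns_to_its_source_position(self, ref_binset):
        scaf, length = _cut_scaffold(ref_binset, "chr3", 100_000, 220_000, "s1")
        anchors, agp = anchor_scaffolds(scaf, {"s1": length}, ref_binset)
        rec = anchors.iloc[0]
        assert rec["chrom"] == "chr3"
        assert 100_000 <= rec["position"] < 220_000
        assert rec["orientation"] == "+"
        assert rec["best_r"] == 0.0

    def test_reversed_scaffold_gets_minus_orientation(self, ref_binset):
        scaf, length = _cut_scaffold(ref_binset, "chr3", 100_000, 220_000, "sR",
                                     reverse=True)
        anchors, _ = anchor_scaffolds(scaf, {"sR": length}, ref_binset)
        assert anchors["orientation"].iloc[0] == "-"

    def test_single_bin_scaffold_orientation_unknown(self, ref_binset):
        sel = ref_binset.bins[ref_binset.bins["chrom"] == "chr2"].iloc[[3]]
        scaf = BinSet(
            bins=sel.assign(chrom="s2", start=0, end=20_000).reset_index(drop=True),
            genotypes=ref_binset.genotypes[sel.index.to_numpy()])
        anchors, _ = anchor_scaffolds(scaf, {"s2": 20_000}, ref_binset)
        assert anchors["orientation"].iloc[0] == "unknown"
        assert anchors["chrom"].iloc[0] == "chr2"

    def test_unlinked_scaffold_left_unanchored(self, ref_binset):
        geno = np.full((1, ref_binset.n_rils), NOCALL, dtype=np.int8)
        scaf = BinSet(bins=pd.DataFrame({"bin_id": [0], "chrom": "sX",
                                         "start": [0], "end": [20_000]}),
                      genotypes=geno)
        anchors, agp = anchor_scaffolds(scaf, {"sX": 20_000}, ref_binset)
        assert anchors["chrom"].iloc[0] is None
        assert len(agp) == 0

    def test_agp_coordinates_reconstruct_lengths(self, ref_binset):
        s1, l1 = _cut_scaffold(ref_binset, "chr3", 100_000, 220_000, "a1")
        s2, l2 = _cut_scaffold(ref_binset, "chr3", 300_000, 400_000, "a2")
        both = BinSet(bins=pd.concat([s1.bins, s2.bins], ignore_index=True),
                      genotypes=np.vstack([s1.genotypes, s2.genotypes]))
        anchors, agp = anchor_scaffolds(both, {"a1": l1, "a2": l2}, ref_binset)
        comp = agp[agp["component_type"] == "W"]
        spacers = agp[agp["component_type"] == "U"]
        assert comp["component_id"].tolist() == ["a1", "a2"]
        assert len(spacers) == 1
        # object coordinates are contiguous and match component lengths
        assert (agp["object_end"] - agp["object_beg"] + 1).tolist() == [l1, 100, l2]
        assert agp["object_beg"].iloc[0] == 1
        assert (agp["object_beg"].iloc[1:].to_numpy()
                == agp["object_end"].iloc[:-1].to_numpy() + 1).all()


class TestCorrections:
    def test_empty_report_is_identity(self, ref_binset):
        corrected, lift = apply_corrections(
            ref_binset, pd.DataFrame(columns=["bin_id", "partner_bin",
                                              "proposed_chrom"]))
        merged = corrected.sort_values(["chrom", "start"]).reset_index(drop=True)
        orig = ref_binset.bins[["bin_id", "chrom", "start", "end"]].sort_values(
            ["chrom", "start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, orig, check_dtype=False)
        assert (lift["old_start"] == lift["new_start"]).all()

    def test_injected_shuffle_round_trips(self, ref_binset):
        # displace one bin, then apply the correction that moves it back
        bins = ref_binset.bins.copy().reset_index(drop=True)
        chr1 = bins[bins["chrom"] == "chr1"]
        moved = int(chr1["bin_id"].iloc[4])
        partner = int(chr1["bin_id"].iloc[3])
        # physically relocate `moved` to the end of chr1
        tail = int(chr1["end"].max())
        width = int(bins.loc[bins["bin_id"] == moved, "end"].iloc[0]
                    - bins.loc[bins["bin_id"] == moved, "start"].iloc[0])
        shuffled = bins.copy()
        removed_start = int(shuffled.loc[shuffled["bin_id"] == moved, "start"].iloc[0])
        on_chr1 = (shuffled["chrom"] == "chr1") & (shuffled["start"] > removed_start)
        shuffled.loc[on_chr1, ["start", "end"]] -= width
        shuffled.loc[shuffled["bin_id"] == moved, ["start", "end"]] = [tail - width, tail]
        shuffled_bs = BinSet(bins=shuffled, genotypes=ref_binset.genotypes)
        report = pd.DataFrame([{"bin_id": moved, "partner_bin": partner,
                                "proposed_chrom": "chr1"}])
        corrected, _ = apply_corrections(shuffled_bs, report)
        expected = bins[["bin_id", "chrom", "start", "end"]].sort_values(
            ["chrom", "start"]).reset_index(drop=True)
        got = corrected.sort_values(["chrom", "start"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expected, check_dtype=False)

    def test_liftover_is_a_bijection_over_bases(self, ref_binset):
        chr2 = ref_binset.bins[ref_binset.bins["chrom"] == "chr2"]
        report = pd.DataFrame([
            {"bin_id": int(chr2["bin_id"].iloc[5]),
             "partner_bin": int(chr2["bin_id"].iloc[0]), "proposed_chrom": "chr2"},
            {"bin_id": int(chr2["bin_id"].iloc[7]),
             "partner_bin": int(chr2["bin_id"].iloc[2]), "proposed_chrom": "chr2"},
        ])
        corrected, lift = apply_corrections(ref_binset, report)
        for chrom, grp in corrected.groupby("chrom"):
            grp = grp.sort_values("start")
            assert grp["start"].iloc[0] == 0
            assert (grp["start"].iloc[1:].to_numpy()
                    == grp["end"].iloc[:-1].to_numpy()).all()
        # lengths conserved bin by bin
        assert ((lift["new_end"] - lift["new_start"])
                == (lift["old_end"] - lift["old_start"])).all()

    def test_overlapping_moves_rejected(self, ref_binset):
        report = pd.DataFrame([
            {"bin_id": 3, "partner_bin": 8, "proposed_chrom": "chr1"},
            {"bin_id": 8, "partner_bin": 1, "proposed_chrom": "chr1"},
        ])
        with pytest.raises(ValueError):
            apply_corrections(ref_binset, report)


class TestGapFilling:
    def test_round_trip_restores_deleted_sequence(self, random_donor):
        target, truth = bm.simulate_fragmented_assembly(
            random_donor, bm.GapConfig(n_gaps=10), seed=2)
        filled, report = fill_gaps(target, random_donor)
        assert (report["status"] == "filled").all()
        assert filled["chr1"].upper() == random_donor["chr1"]
        # the fill, and only the fill, is lowercase
        n_lower = sum(c.islower() for c in filled["chr1"])
        assert n_lower == truth["deleted"].str.len().sum()

    def test_case_outside_fills_is_preserved(self, random_donor):
        target, _ = bm.simulate_fragmented_assembly(
            random_donor, {"chr1": [(50_000, 50_200)]}, seed=2)
        filled, _ = fill_gaps(target, random_donor)
        upper_in = sum(c.isupper() for c in target["chr1"]) - target["chr1"].count("N")
        upper_out = sum(c.isupper() for c in filled["chr1"])
        assert upper_out == upper_in

    def test_unrelated_donor_fills_nothing(self, random_donor):
        rng = np.random.default_rng(123)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        unrelated = {"chrU": bases[rng.integers(0, 4, 100_000)].tobytes().decode()}
        target, _ = bm.simulate_fragmented_assembly(
            random_donor, bm.GapConfig(n_gaps=5), seed=3)
        filled, report = fill_gaps(target, unrelated)
        assert (report["status"] == "unfilled_no_match").all()
        assert filled["chr1"] == target["chr1"]

    def test_repeated_flank_is_ambiguous(self):
        rng = np.random.default_rng(4)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        block = bases[rng.integers(0, 4, 2_000)].tobytes().decode()
        spacer = bases[rng.integers(0, 4, 3_000)].tobytes().decode()
        tail = bases[rng.integers(0, 4, 2_000)].tobytes().decode()
        donor = {"chr1": spacer + block + spacer + block + tail}
        # gap immediately after the second copy of `block`
        gap_at = len(spacer) * 2 + len(block) * 2
        target, _ = bm.simulate_fragmented_assembly(
            donor, {"chr1": [(gap_at, gap_at + 100)]}, seed=1)
        _, report = fill_gaps(target, donor)
        assert report["status"].iloc[0] == "unfilled_ambiguous"

    def test_flanks_on_different_sequences_discordant(self):
        rng = np.random.default_rng(6)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        left = bases[rng.integers(0, 4, 2_000)].tobytes().decode()
        right = bases[rng.integers(0, 4, 2_000)].tobytes().decode()
        target = {"t": left + "N" * 100 + right}
        donor = {"d1": left, "d2": right}
        _, report = fill_gaps(target, donor)
        assert report["status"].iloc[0] == "unfilled_discordant"

    def test_gap_at_sequence_edge_not_filled(self, random_donor):
        target = {"chr1": "N" * 100 + random_donor["chr1"][100:]}
        _, report = fill_gaps(target, random_donor)
        assert report["status"].iloc[0] == "unfilled_no_match"
        assert report["reason"].iloc[0] == "flank_at_sequence_edge"

    def test_abutting_flanks_close_gap_to_zero_length(self, random_donor):
        # insert Ns (rather than replace): donor flanks abut, fill length 0
        seq = random_donor["chr1"]
        target = {"chr1": seq[:10_000] + "N" * 50 + seq[10_000:]}
        filled, report = fill_gaps(target, random_donor)
        assert report["status"].iloc[0] == "filled"
        assert report["fill_len"].iloc[0] == 0
        assert filled["chr1"] == seq

    def test_reverse_complement_donor_still_fills(self, random_donor):
        target, truth = bm.simulate_fragmented_assembly(
            random_donor, {"chr1": [(100_000, 100_300)]}, seed=5)
        rc_donor = {"rc": revcomp(random_donor["chr1"])}
        filled, report = fill_gaps(target, rc_donor)
        assert report["status"].iloc[0] == "filled"
        assert report["strand"].iloc[0] == "-"
        assert filled["chr1"].upper() == random_donor["chr1"]

    def test_find_gaps_ignores_short_n_runs(self):
        assert find_gaps("ACGTNNNNNNNNNNACGT") == [(4, 14)]
        assert find_gaps("ACGTNNNNNACGT") == []
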