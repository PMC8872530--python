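"""Tests for the circular mitochondrial genome pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hairdna import mito, simulate
from hairdna.mito import (
    LiftedPlacement,
    MtPlacement,
    PlacementRejected,
    build_chimeric_reference,
    call_base_counts,
    compare_haplotypes,
    deduplicate,
    depth_length_stats,
    filter_placements,
    haplotype_diff,
    lift_placements,
    liftover_to_rcrs,
    pileup_and_call,
    place_reads_on_chimera,
    placements_from_sam,
    process_placements,
    rcrs_position,
    write_vcf,
)

RCRS_LEN = 16_569


@pytest.fixture(scope="module")
def rcrs_like():
    return simulate.random_mt_reference(RCRS_LEN, seed=50)


@pytest.fixture(scope="module")
def rcrs_chimera(rcrs_like):
    return build_chimeric_reference(rcrs_like)


# ---------------------------------------------------------------------------
# Chimeric reference construction


class TestChimericReference:
    def test_rcrs_scale_length(self, rcrs_chimera):
        assert len(rcrs_chimera.sequence) == 33_152

    def test_toy_circle_length(self):
        chim = build_chimeric_reference("A" * 100, rotation_origin=50)
        assert len(chim.sequence) == 214

    def test_second_copy_rotation_endpoints(self, rcrs_like, rcrs_chimera):
        seq = rcrs_chimera.sequence
        # second copy starts at reference position 8284 and ends at 8283
        assert seq[RCRS_LEN + 14] == rcrs_like[8284 - 1]
        assert seq[-1] == rcrs_like[8283 - 1]

    def test_spacer_is_all_n(self, rcrs_chimera):
        assert rcrs_chimera.sequence[RCRS_LEN : RCRS_LEN + 14] == "N" * 14

    def test_copy1_is_reference(self, rcrs_like, rcrs_chimera):
        assert rcrs_chimera.sequence[:RCRS_LEN] == rcrs_like

    def test_rotation_origin_validated(self):
        with pytest.raises(ValueError):
            build_chimeric_reference("ACGT" * 10, rotation_origin=41)


# ---------------------------------------------------------------------------
# Liftover


class TestLiftover:
    def test_copy1_maps_identically(self, rcrs_chimera):
        assert rcrs_position(1, rcrs_chimera) == 1
        assert rcrs_position(16_569, rcrs_chimera) == 16_569

    def test_first_base_of_copy2(self, rcrs_chimera):
        assert rcrs_position(16_584, rcrs_chimera) == 8284

    def test_last_base_of_copy2(self, rcrs_chimera):
        assert rcrs_position(33_152, rcrs_chimera) == 8283

    def test_origin_spanning_placement_splits(self, rcrs_chimera):
        pl = MtPlacement("r1", chimeric_start=24_865, length=10, mapping_quality=60)
        lifted = liftover_to_rcrs(pl, rcrs_chimera)
        assert lifted.start_rcrs == 16_565
        assert lifted.intervals == ((16_565, 16_569), (1, 5))
        assert lifted.is_origin_spanning

    def test_spacer_overlap_rejected(self, rcrs_chimera):
        pl = MtPlacement("r1", chimeric_start=16_565, length=10, mapping_quality=60)
        with pytest.raises(PlacementRejected, match="spacer"):
            liftover_to_rcrs(pl, rcrs_chimera)

    def test_out_of_bounds_rejected(self, rcrs_chimera):
        with pytest.raises(PlacementRejected):
            liftover_to_rcrs(
                MtPlacement("r1", chimeric_start=33_150, length=10, mapping_quality=60),
                rcrs_chimera,
            )

    @given(
        L=st.integers(40, 300),
        origin=st.integers(2, 39),
        data=st.data(),
    )
    @settings(max_examples=40, deadline=None)
    def test_round_trip_property(self, L, origin, data):
        """Every non-spacer chimeric position maps to one circular position
        and every circular position has exactly two chimeric preimages."""
        ref = simulate.random_mt_reference(L, seed=0)
        chim = build_chimeric_reference(ref, rotation_origin=origin, spacer_len=14)
        preimages = {}
        for q in range(1, 2 * L + 14 + 1):
            if L + 1 <= q <= L + 14:
                with pytest.raises(PlacementRejected):
                    rcrs_position(q, chim)
                continue
            r = rcrs_position(q, chim)
            assert 1 <= r <= L
            assert chim.sequence[q - 1] == ref[r - 1]
            preimages.setdefault(r, []).append(q)
        assert all(len(v) == 2 for v in preimages.values())
        assert len(preimages) == L


# ---------------------------------------------------------------------------
# Deduplication and filtering


def _lifted(read_id, start, length, mq=60, strand="+", L=1000):
    last = start + length - 1
    if last <= L:
        intervals = ((start, last),)
    else:
        intervals = ((start, L), (1, last - L))
    return LiftedPlacement(
        read_id=read_id,
        start_rcrs=start,
        length=length,
        mapping_quality=mq,
        intervals=intervals,
        strand=strand,
    )


class TestDeduplicate:
    def test_identical_placements_collapse(self):
        a = _lifted("a", 10, 50, mq=40)
        b = _lifted("b", 10, 50, mq=55)
        out = deduplicate([a, b])
        assert out == [b]  # highest mapping quality survives

    def test_mq_tie_broken_by_read_id(self):
        a = _lifted("zz", 10, 50)
        b = _lifted("aa", 10, 50)
        assert deduplicate([a, b]) == [b]

    def test_different_end_kept(self):
        a = _lifted("a", 10, 50)
        b = _lifted("b", 10, 51)
        assert len(deduplicate([a, b])) == 2

    def test_strand_distinguishes_fragments(self):
        a = _lifted("a", 10, 50, strand="+")
        b = _lifted("b", 10, 50, strand="-")
        assert len(deduplicate([a, b])) == 2

    def test_idempotent(self):
        pls = [_lifted(f"r{i}", 10 + i % 3, 50, mq=30 + i) for i in range(10)]
        once = deduplicate(pls)
        assert deduplicate(once) == once


class TestFilterPlacements:
    @pytest.mark.parametrize("mq,kept", [(29, False), (30, True), (60, True)])
    def test_boundary(self, mq, kept):
        out = filter_placements([_lifted("a", 1, 10, mq=mq)])
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        assert filter_placements([]) == []


class TestAccounting:
    def test_pipeline_conservation(self, rcrs_chimera):
        placements = [
            MtPlacement("good1", 100, 50, 60),
            MtPlacement("good2", 200, 50, 60),
            MtPlacement("dup_of_good2", 200, 50, 45),
            MtPlacement("lowmq", 300, 50, 10),
            MtPlacement("spacer", 16_565, 20, 60),
        ]
        retained, acc = process_placements(placements, rcrs_chimera)
        assert acc["n_input"] == 5
        assert acc["n_spacer_rejected"] == 1
        assert acc["n_mq_filtered"] == 1
        assert acc["n_duplicates_removed"] == 1
        assert acc["n_retained"] == 2 == len(retained)
        assert (
            acc["n_spacer_rejected"]
            + acc["n_mq_filtered"]
            + acc["n_duplicates_removed"]
            + acc["n_retained"]
            == acc["n_input"]
        )


# ---------------------------------------------------------------------------
# Consensus calling


class TestCallBaseCounts:
    def test_point_heteroplasmy_published_example(self):
        call, frac, het = call_base_counts({"T": 57, "C": 18})
        assert call == "Y" and het
        assert frac == pytest.approx(0.76)

    def test_low_minor_fraction_is_homoplasmic(self):
        call, frac, het = call_base_counts({"C": 53, "T": 1})
        assert call == "C" and not het
        assert frac == pytest.approx(53 / 54)

    def test_minor_read_count_threshold(self):
        # 1 of 8 reads is 12.5% > 10% but below the 2-read support floor
        call, _, het = call_base_counts({"G": 7, "A": 1})
        assert call == "G" and not het

    def test_zero_depth_is_no_call(self):
        call, frac, het = call_base_counts({})
        assert call == "" and not het and np.isnan(frac)

    def test_clean_substitution(self):
        call, frac, het = call_base_counts({"G": 10})
        assert call == "G" and frac == 1.0 and not het


class TestPileupAndDiff:
    def test_substitution_and_insertion_notation(self):
        ref = "ACGTACGTAC"  # L=10
        # reads carry G at position 5 (ref A); two of three support 3.1T
        pls = [
            LiftedPlacement(
                "r1", 1, 10, 60, ((1, 10),), sequence="ACGTGCGTAC"
            ),
            LiftedPlacement(
                "r2", 1, 10, 60, ((1, 10),),
                sequence="ACGTTGCGTAC",
                insertions=((3, 1, "T"),),
            ),
            LiftedPlacement(
                "r3", 1, 10, 60, ((1, 10),),
                sequence="ACGTTGCGTAC",
                insertions=((3, 1, "T"),),
            ),
        ]
        callset = pileup_and_call(pls, ref)
        assert callset.depth.sum() == 30
        diffs = haplotype_diff(callset, ref)
        assert "5G" in diffs
        assert "3.1T" in diffs

    def test_zero_depth_positions_not_reference_matched(self):
        ref = "ACGTACGTAC"
        pls = [LiftedPlacement("r1", 1, 4, 60, ((1, 4),), sequence="ACGT")]
        callset = pileup_and_call(pls, ref)
        assert list(callset.called_positions) == [1, 2, 3, 4]
        assert callset.consensus[5] == ""
        assert haplotype_diff(callset, ref) == []

    def test_heteroplasmy_rendered_with_iupac(self):
        ref = "A" * 20
        pls = [
            LiftedPlacement(f"t{i}", 10, 1, 60, ((10, 10),), sequence="T")
            for i in range(57)
        ] + [
            LiftedPlacement(f"c{i}", 10, 1, 60, ((10, 10),), sequence="C")
            for i in range(18)
        ]
        callset = pileup_and_call(pls, ref)
        assert callset.consensus[9] == "Y"
        assert callset.major_fraction[9] == pytest.approx(0.76)
        assert "10Y" in haplotype_diff(callset, ref)

    def test_vcf_output(self, tmp_path):
        ref = "ACGTACGTAC"
        pls = [
            LiftedPlacement("r1", 1, 10, 60, ((1, 10),), sequence="ACGTGCGTAC"),
            LiftedPlacement("r2", 1, 10, 60, ((1, 10),), sequence="ACGTGCGTAC"),
        ]
        callset = pileup_and_call(pls, ref)
        out = tmp_path / "calls.vcf"
        write_vcf(callset, ref, out)
        text = out.read_text()
        assert "##fileformat=VCFv4.2" in text
        assert "chrM\t5\t.\tA\tG\t.\tPASS\tDP=2" in text


class TestCompareHaplotypes:
    def test_identical_lists(self):
        cmp = compare_haplotypes(["263G", "315.1C"], ["315.1C", "263G"])
        assert cmp.n_differences == 0
        assert cmp.shared == ("263G", "315.1C")

    def test_restriction_to_jointly_called_positions(self):
        cmp = compare_haplotypes(
            ["100G", "200T"],
            ["100G"],
            called_a=range(1, 300),
            called_b=range(1, 150),  # 200 not called in b
        )
        assert cmp.n_differences == 0
        assert cmp.shared == ("100G",)


# ---------------------------------------------------------------------------
# Depth/length statistics


class TestDepthLengthStats:
    def test_single_read_mean_depth(self):
        ref = "A" * 100
        pls = [LiftedPlacement("r1", 1, 50, 60, ((1, 50),), sequence="A" * 50)]
        callset = pileup_and_call(pls, ref)
        stats = depth_length_stats(callset, pls)
        assert stats.depth_mean == pytest.approx(0.5)
        assert stats.depth_min == 0 and stats.depth_max == 1
        assert stats.mean_length == 50
        assert stats.length_hist == {50: 1}

    def test_range_endpoints_match_depth_vector(self, rcrs_like):
        rs = simulate.simulate_mt_reads(rcrs_like, depth_target=3, seed=51)
        chim = build_chimeric_reference(rcrs_like)
        retained, _ = process_placements(place_reads_on_chimera(rs, chim), chim)
        callset = pileup_and_call(retained, rcrs_like)
        stats = depth_length_stats(callset, retained)
        assert stats.depth_min == callset.depth.min()
        assert stats.depth_max == callset.depth.max()
        assert stats.n_reads == len(retained)

    def test_empty_placements_rejected(self):
        ref = "A" * 10
        callset = pileup_and_call([], ref)
        with pytest.raises(ValueError):
            depth_length_stats(callset, [])


# ---------------------------------------------------------------------------
# End-to-end recovery on a small circle


class TestEndToEnd:
    def test_haplotype_recovery_with_origin_spanning_reads(self):
        L = 3000
        ref = simulate.random_mt_reference(L, seed=52)
        nxt = {"A": "C", "C": "G", "G": "T", "T": "A"}
        subs = [f"{pos}{nxt[ref[pos - 1]]}" for pos in (97, 500, 1500, 2995)]
        haplotype = subs + ["315.1C", "524.1A", "524.2C"]
        rs = simulate.simulate_mt_reads(
            ref, haplotype, depth_target=50, mean_length=60, seed=53
        )
        assert any(r.is_origin_spanning for r in rs.reads)
        chim = build_chimeric_reference(ref, rotation_origin=1500)
        retained, acc = process_placements(place_reads_on_chimera(rs, chim), chim)
        assert acc["n_spacer_rejected"] == 0
        callset = pileup_and_call(retained, ref)
        assert sorted(haplotype_diff(callset, ref)) == sorted(haplotype)
        assert int(callset.heteroplasmic.sum()) == 0

    def test_terminal_deamination_stays_below_het_threshold(self):
        L = 3000
        ref = simulate.random_mt_reference(L, seed=54)
        rs = simulate.simulate_mt_reads(
            ref, depth_target=60, mean_length=60, deamination_rate=0.05, seed=55
        )
        chim = build_chimeric_reference(ref, rotation_origin=1500)
        retained, _ = process_placements(place_reads_on_chimera(rs, chim), chim)
        callset = pileup_and_call(retained, ref)
        assert int(callset.heteroplasmic.sum()) == 0
        assert haplotype_diff(callset, ref) == []


# ---------------------------------------------------------------------------
# SAM ingestion adapter


class TestSamAdapter:
    def _write_sam(self, path, chim):
        name, ln = "chrM_chimeric", len(chim.sequence)
        lines = [
            "@HD\tVN:1.6\tSO:unsorted",
            f"@SQ\tSN:{name}\tLN:{ln}",
            # simple 10M read at chimeric position 101
            f"ok\t0\t{name}\t101\t60\t10M\t*\t0\t0\tACGTACGTAC\t*",
            # read with a 1 bp insertion after its 5th aligned base
            f"ins\t16\t{name}\t201\t60\t5M1I4M\t*\t0\t0\tAAAAATCCCC\t*",
            # low mapping quality
            f"lowmq\t0\t{name}\t301\t10\t10M\t*\t0\t0\tACGTACGTAC\t*",
            # unmapped
            "nomap\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*",
            # deletion-containing read is skipped by the adapter
            f"hasdel\t0\t{name}\t401\t60\t4M2D4M\t*\t0\t0\tACGTACGT\t*",
        ]
        path.write_text("\n".join(lines) + "\n")

    def test_parse_and_liftover(self, tmp_path, rcrs_chimera):
        sam = tmp_path / "toy.sam"
        self._write_sam(sam, rcrs_chimera)
        placements, skipped = placements_from_sam(sam)
        by_id = {p.read_id: p for p in placements}
        assert set(by_id) == {"ok", "ins", "lowmq"}
        assert dict(skipped)["nomap"] == "unmapped"
        assert "hasdel" in dict(skipped)
        ok = by_id["ok"]
        assert ok.chimeric_start == 101 and ok.length == 10 and ok.strand == "+"
        ins = by_id["ins"]
        assert ins.length == 9 and ins.strand == "-"
        assert ins.insertions == ((205, 1, "T"),)
        lifted = liftover_to_rcrs(ins, rcrs_chimera)
        assert lifted.insertions == ((205, 1, "T"),)
        # whole-table processing applies the MQ filter
        retained, acc = process_placements(placements, rcrs_chimera)
        assert acc["n_mq_filtered"] == 1 and acc["n_retained"] == 2
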