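"""Contig assignment, segment merging, signature calls and genome summary."""

import numpy as np
import pytest

from mismap.detect import CMMResult
from mismap.errors import MismapError
from mismap.io.agp import AGPComponent
from mismap.segments import (
    MisassemblySegment,
    SignatureParams,
    assign_contigs,
    classify_signature,
    genome_error_summary,
    merge_adjacent,
    segment_table,
)
from mismap.types import GenotypePanel, MarkerRecord


def _agp_chain(chrom, parts):
    """Build a tiled AGP from (kind, length) tuples."""
    comps, beg = [], 1
    for pn, (kind, length) in enumerate(parts, start=1):
        cid = f"ctg{chrom}.{pn}" if kind == "contig" else None
        comps.append(AGPComponent(chrom, beg, beg + length - 1, pn, kind, cid))
        beg += length
    return comps


def _res(mid, chrom, pos, is_cmm, target=None):
    rule = "cross_chromosome" if (is_cmm and target) else (
        "long_distance" if is_cmm else "none")
    return CMMResult(
        MarkerRecord(mid, chrom, pos), is_cmm, rule, target_chrom=target
    )


class TestAssignContigs:
    AGP = _agp_chain("1", [("contig", 1000), ("gap", 100), ("contig", 1000)])

    def test_three_cmms_one_contig(self):
        results = [
            _res("a", "1", 100, True, "2"),
            _res("b", "1", 200, True, "2"),
            _res("c", "1", 900, True, "2"),
            _res("d", "1", 1500, False),
        ]
        cmcs, diag = assign_contigs(results, self.AGP)
        assert len(cmcs) == 1 and not diag
        assert sorted(cmcs[0].cmm_ids) == ["a", "b", "c"]
        assert cmcs[0].component.part_number == 1

    def test_cmm_in_gap_is_diagnosed_not_dropped(self):
        results = [_res("g", "1", 1050, True, "2")]
        cmcs, diag = assign_contigs(results, self.AGP)
        assert not cmcs
        assert diag[0]["marker_id"] == "g" and diag[0]["issue"] == "cmm_in_gap"

    def test_cmm_outside_assembly_raises(self):
        with pytest.raises(MismapError, match="outside"):
            assign_contigs([_res("x", "1", 99_999, True, "2")], self.AGP)
        with pytest.raises(MismapError, match="absent"):
            assign_contigs([_res("x", "7", 10, True, "2")], self.AGP)


class TestMergeAdjacent:
    def test_cmc_gap_cmc_merges_to_one_segment(self):
        agp = _agp_chain("1", [("contig", 1000), ("gap", 100), ("contig", 1000)])
        results = [
            _res("a", "1", 500, True, "2"),
            _res("b", "1", 1500, True, "2"),
        ]
        cmcs, _ = assign_contigs(results, agp)
        segs = merge_adjacent(cmcs, agp, results)
        assert len(segs) == 1
        assert len(segs[0].components) == 3
        assert (segs[0].span_start, segs[0].span_end) == (1, 2100)
        assert segs[0].alias == "R1"

    def test_intervening_contig_with_clean_markers_blocks_merge(self):
        agp = _agp_chain("1", [("contig", 1000)] * 3)
        results = [
            _res("a", "1", 500, True, "2"),
            _res("ok", "1", 1500, False),  # testable, not a CMM
            _res("b", "1", 2500, True, "2"),
        ]
        cmcs, _ = assign_contigs(results, agp)
        segs = merge_adjacent(cmcs, agp, results)
        assert len(segs) == 2

    def test_markerless_contig_is_gap_like(self):
        agp = _agp_chain("1", [("contig", 1000)] * 3)
        results = [
            _res("a", "1", 500, True, "2"),
            _res("b", "1", 2500, True, "2"),
        ]  # middle contig has no testable markers at all
        cmcs, _ = assign_contigs(results, agp)
        segs = merge_adjacent(cmcs, agp, results)
        assert len(segs) == 1 and len(segs[0].components) == 3

    def test_different_targets_do_not_merge(self):
        agp = _agp_chain("1", [("contig", 1000), ("gap", 100), ("contig", 1000)])
        results = [
            _res("a", "1", 500, True, "2"),
            _res("b", "1", 1500, True, "3"),
        ]
        cmcs, _ = assign_contigs(results, agp)
        assert len(merge_adjacent(cmcs, agp, results)) == 2

    def test_large_mixed_run_recovered_as_one_segment(self):
        # the paper-scale pattern: 35 adjacent components, 18 contigs + 17
        # gaps, all contig markers flagged toward one target chromosome
        parts = []
        for i in range(18):
            parts.append(("contig", 30_000))
            if i < 17:
                parts.append(("gap", 2_000))
        agp = _agp_chain("21", parts)
        results = []
        k = 0
        for comp in agp:
            if comp.is_gap:
                continue
            for off in (5_000, 15_000, 25_000):
                results.append(
                    _res(f"m{k}", "21", comp.object_beg + off, True, "5")
                )
                k += 1
        cmcs, _ = assign_contigs(results, agp)
        segs = merge_adjacent(cmcs, agp, results)
        assert len(segs) == 1
        seg = segs[0]
        assert len(seg.components) == 35
        assert sum(c.is_gap for c in seg.components) == 17
        assert len(seg.member_markers) == 54

    def test_no_cmms_yields_no_segments(self):
        agp = _agp_chain("1", [("contig", 1000)])
        results = [_res("a", "1", 500, False)]
        cmcs, _ = assign_contigs(results, agp)
        assert cmcs == [] and merge_adjacent(cmcs, agp, results) == []

    def test_segments_never_overlap(self, small_cohort):
        from mismap.detect import detect_all
        from mismap.qc import apply_qc

        panel, _ = apply_qc(small_cohort.panel("A", "reported"))
        results = detect_all(panel)
        cmcs, _ = assign_contigs(results, small_cohort.agp_reported)
        segs = merge_adjacent(cmcs, small_cohort.agp_reported, results)
        by_chrom: dict[str, list] = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append((s.span_start, s.span_end))
        for spans in by_chrom.values():
            spans.sort()
            for (a1, a2), (b1, b2) in zip(spans[:-1], spans[1:]):
                assert a2 < b1


def _ld_panel(member_pattern, flank_pattern, n=40, seed=0):
    """Panel with 10 'member' markers (positions 1-10 kb on chrom 1) and 5
    flank markers (100 kb away). Patterns control which members correlate
    with the flanks."""
    rng = np.random.default_rng(seed)
    base_member = rng.integers(0, 3, n).astype(float)
    base_flank = rng.integers(0, 3, n).astype(float)
    cols, markers = [], []
    for j in range(10):
        src = base_member if member_pattern[j] == "m" else base_flank
        noise = rng.integers(0, 3, n).astype(float)
        keep = rng.random(n) < 0.9
        cols.append(np.where(keep, src, noise))
        markers.append(MarkerRecord(f"mem{j}", "1", 1_000 + j * 1_000))
    for j in range(5):
        src = base_flank if flank_pattern[j] == "f" else rng.integers(0, 3, n).astype(float)
        cols.append(src)
        markers.append(MarkerRecord(f"fl{j}", "1", 100_000 + j * 1_000))
    return GenotypePanel(
        [f"s{i}" for i in range(n)], markers, np.column_stack(cols)
    )


class TestClassifySignature:
    def _segment(self, member_ids, cmm_ids, panel):
        members = [m for m in panel.markers if m.marker_id in member_ids]
        return MisassemblySegment(
            alias="R1",
            chrom="1",
            span_start=1,
            span_end=11_000,
            components=[AGPComponent("1", 1, 11_000, 1, "contig", "c1")],
            member_markers=members,
            cmm_ids=list(cmm_ids),
        )

    def test_single_marker_segment_is_missnp(self):
        panel = _ld_panel("m" * 10, "f" * 5)
        seg = self._segment(["mem0"], ["mem0"], panel)
        assert classify_signature(seg, panel) == "MisSNP"

    def test_all_cmm_no_local_ld_is_misseg(self):
        # members correlate with each other only; flanks are an unrelated block
        panel = _ld_panel("m" * 10, "f" * 5)
        ids = [f"mem{j}" for j in range(10)]
        seg = self._segment(ids, ids, panel)
        assert classify_signature(seg, panel) == "MisSeg"

    def test_mixture_with_flank_ld_is_pmiscon(self):
        # 4 members flagged; the other 6 share the flank haplotype block, so
        # they are locally consistent -> a partially misassembled contig
        panel = _ld_panel("mmmmffffff", "f" * 5)
        ids = [f"mem{j}" for j in range(10)]
        seg = self._segment(ids, ids[:4], panel)
        assert classify_signature(seg, panel) == "PMisCon"

    def test_high_cmm_fraction_but_conflicting_member_is_pmiscon(self):
        # 9/10 flagged (fraction 0.9 >= 0.8) but the unflagged member is in
        # strong LD with the flanks -> still PMisCon
        panel = _ld_panel("mmmmmmmmmf", "f" * 5)
        ids = [f"mem{j}" for j in range(10)]
        seg = self._segment(ids, ids[:9], panel)
        assert classify_signature(seg, panel) == "PMisCon"

    def test_no_testable_markers_raises(self):
        panel = _ld_panel("m" * 10, "f" * 5)
        seg = self._segment([], [], panel)
        seg.member_markers = [MarkerRecord("ghost", "1", 5_000)]
        with pytest.raises(MismapError, match="testable"):
            classify_signature(seg, panel)

    def test_signature_counts_partition_segments(self, small_cohort):
        from mismap.detect import detect_all
        from mismap.qc import apply_qc

        panel, _ = apply_qc(small_cohort.panel("A", "reported"))
        results = detect_all(panel)
        cmcs, _ = assign_contigs(results, small_cohort.agp_reported)
        segs = merge_adjacent(cmcs, small_cohort.agp_reported, results)
        for s in segs:
            s.signature = classify_signature(s, panel)
        table = segment_table(segs)
        assert table["signature"].notna().all()
        assert table["signature"].isin(["MisSNP", "MisSeg", "PMisCon"]).all()


class TestGenomeErrorSummary:
    def test_no_segments_all_zero(self):
        agp = _agp_chain("1", [("contig", 100_000_000)])
        out = genome_error_summary([], agp)
        assert out["global_fraction"] == 0.0
        assert out["n_segments"] == 0

    def test_one_percent_arithmetic(self):
        agp = _agp_chain("1", [("contig", 100_000_000)])
        seg = MisassemblySegment(
            "R1", "1", 10_000_001, 11_000_000,
            [AGPComponent("1", 10_000_001, 11_000_000, 1, "contig", "c")],
            [], ["x"],
        )
        out = genome_error_summary([seg], agp)
        assert out["global_fraction"] == pytest.approx(0.01)
        row = out["per_chrom"].set_index("chrom").loc["1"]
        assert row["fraction"] == pytest.approx(0.01)
        assert row["n_segments"] == 1

    def test_planted_spans_recovered_within_rounding(self, small_cohort):
        from mismap.detect import detect_all
        from mismap.qc import apply_qc

        panel, _ = apply_qc(small_cohort.panel("A", "reported"))
        results = detect_all(panel)
        cmcs, _ = assign_contigs(results, small_cohort.agp_reported)
        segs = merge_adjacent(cmcs, small_cohort.agp_reported, results)
        out = genome_error_summary(segs, small_cohort.agp_reported, n50=130_000)
        planted = sum(
            ev.dest_end - ev.dest_start + 1 for ev in small_cohort.events
        )
        total = sum(out["per_chrom"]["length_bp"])
        # segments are whole-contig-granular, so the reported fraction brackets
        # the planted marker span from above by at most the contig overhead
        assert planted / total <= out["global_fraction"] <= 5 * planted / total
        assert 0.0 <= out["cmc_fraction_below_n50"] <= 1.0
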