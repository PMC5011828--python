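"""From flagged markers to misassembled segments.

A Candidate Misassembled Contig (CMC) is any assembly contig holding at
least one CMM. Adjacent CMCs that share a target chromosome and are
separated only by gaps or marker-less contigs merge into one candidate
misassembled segment, which is then classified:

* MisSNP   - a single misplaced marker;
* MisSeg   - an (almost) fully misplaced run of contigs: nearly all member
  markers are CMMs and no member shows LD with the flanking region;
* PMisCon  - a contig mixing correctly and incorrectly placed markers.

The original screen relied on visual inspection of LD-decay plots to draw
these distinctions; here "no evidence of local LD" is quantified as the
maximum r2 between a member and non-member markers within a window around
the segment staying below ``local_r2_max``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import CMMResult
from .errors import MismapError
from .io.agp import AGPComponent, components_by_object
from .ld import r2_submatrix
from .types import GenotypePanel, MarkerRecord, chrom_sort_key

__all__ = [
    "SignatureParams",
    "CMC",
    "MisassemblySegment",
    "assign_contigs",
    "merge_adjacent",
    "classify_signature",
    "genome_error_summary",
    "segment_table",
]


@dataclass(frozen=True)
class SignatureParams:
    local_window_bp: int = 1_000_000
    local_r2_max: float = 0.2
    misseg_cmm_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.local_window_bp <= 0:
            raise ValueError("local_window_bp must be positive")
        if not 0.0 < self.local_r2_max < 1.0:
            raise ValueError("local_r2_max must be in (0, 1)")
        if not 0.0 < self.misseg_cmm_fraction <= 1.0:
            raise ValueError("misseg_cmm_fraction must be in (0, 1]")


@dataclass
class CMC:
    """A contig carrying one or more candidate misplaced markers."""

    component: AGPComponent
    markers_in_contig: list[MarkerRecord]
    cmm_ids: list[str]

    def __post_init__(self) -> None:
        if not self.cmm_ids:
            raise ValueError("a CMC must contain at least one CMM")

    @property
    def majority_cmm(self) -> bool:
        return len(self.cmm_ids) * 2 > len(self.markers_in_contig)


@dataclass
class MisassemblySegment:
    """A maximal run of merged components carrying a misassembly signature."""

    alias: str
    chrom: str
    span_start: int
    span_end: int
    components: list[AGPComponent]
    member_markers: list[MarkerRecord]
    cmm_ids: list[str]
    target_chrom: str | None = None
    signature: str | None = None  # MisSNP | MisSeg | PMisCon
    populations_detected: set[str] = field(default_factory=set)

    @property
    def span_bp(self) -> int:
        return self.span_end - self.span_start + 1

    @property
    def member_ids(self) -> list[str]:
        return [m.marker_id for m in self.member_markers]


def _locate(
    comps: list[AGPComponent], pos: int
) -> AGPComponent | None:
    begs = [c.object_beg for c in comps]
    i = int(np.searchsorted(begs, pos, side="right")) - 1
    if i < 0 or not comps[i].contains(pos):
        return None
    return comps[i]


def _modal_target(cmms: list[CMMResult]) -> str | None:
    """Modal target chromosome over CMM verdicts (own chromosome for the
    long-distance rule); deterministic tie-break by chromosome order."""
    votes = Counter(
        r.target_chrom if r.target_chrom is not None else r.focal.chrom
        for r in cmms
    )
    if not votes:
        return None
    best = max(votes.values())
    return sorted((c for c, k in votes.items() if k == best), key=chrom_sort_key)[0]


def assign_contigs(
    cmm_results: list[CMMResult],
    agp: list[AGPComponent],
    markers: list[MarkerRecord] | None = None,
) -> tuple[list[CMC], list[dict]]:
    """Map CMMs onto their contig of origin.

    ``markers`` is the full testable map used to enumerate each contig's
    markers (defaults to the focal records of the results). CMMs located in
    gap components are reported as diagnostics, never silently dropped; a
    CMM outside every assembly object raises.
    """
    if markers is None:
        markers = [r.focal for r in cmm_results]
    by_obj = components_by_object(agp)
    contig_markers: dict[tuple[str, int], list[MarkerRecord]] = {}
    for rec in markers:
        comps = by_obj.get(rec.chrom)
        comp = _locate(comps, rec.pos_bp) if comps else None
        if comp is not None and not comp.is_gap:
            contig_markers.setdefault((comp.object_id, comp.part_number), []).append(rec)

    cmcs: dict[tuple[str, int], CMC] = {}
    cmm_by_contig: dict[tuple[str, int], list[str]] = {}
    diagnostics: list[dict] = []
    for res in cmm_results:
        if not res.is_cmm:
            continue
        rec = res.focal
        comps = by_obj.get(rec.chrom)
        if comps is None:
            raise MismapError(
                f"CMM {rec.marker_id} on chromosome {rec.chrom!r} absent from AGP"
            )
        comp = _locate(comps, rec.pos_bp)
        if comp is None:
            raise MismapError(
                f"CMM {rec.marker_id} at {rec.chrom}:{rec.pos_bp} outside AGP tiling"
            )
        if comp.is_gap:
            diagnostics.append(
                {
                    "marker_id": rec.marker_id,
                    "chrom": rec.chrom,
                    "pos_bp": rec.pos_bp,
                    "issue": "cmm_in_gap",
                    "part_number": comp.part_number,
                }
            )
            continue
        cmm_by_contig.setdefault((comp.object_id, comp.part_number), []).append(
            rec.marker_id
        )
        cmcs.setdefault(
            (comp.object_id, comp.part_number),
            CMC(comp, contig_markers.get((comp.object_id, comp.part_number), []),
                cmm_by_contig[(comp.object_id, comp.part_number)]),
        )
    ordered = sorted(
        cmcs.values(),
        key=lambda c: (chrom_sort_key(c.component.object_id), c.component.object_beg),
    )
    return ordered, diagnostics


def merge_adjacent(
    cmcs: list[CMC],
    agp: list[AGPComponent],
    cmm_results: list[CMMResult],
) -> list[MisassemblySegment]:
    """Merge runs of adjacent CMCs into candidate misassembled segments.

    Two consecutive CMCs merge when every intervening component is a gap or
    a contig without testable markers (QC-emptied contigs count as gap-like),
    both are majority-CMM contigs, and their modal target chromosomes agree.
    Minority-CMM contigs (PMisCon candidates) always stand alone. Aliases
    R1, R2, ... are assigned in genome order per run.
    """
    by_obj = components_by_object(agp)
    res_by_id = {r.focal.marker_id: r for r in cmm_results}
    # testable-marker occupancy for all contigs, from the full result map
    occupied: dict[tuple[str, int], bool] = {}
    for res in cmm_results:
        rec = res.focal
        comps = by_obj.get(rec.chrom)
        comp = _locate(comps, rec.pos_bp) if comps else None
        if comp is not None and not comp.is_gap:
            occupied[(comp.object_id, comp.part_number)] = True

    def cmc_target(c: CMC) -> str | None:
        return _modal_target([res_by_id[i] for i in c.cmm_ids if i in res_by_id])

    runs: list[list[CMC]] = []
    for cmc in cmcs:
        if runs:
            prev = runs[-1][-1]
            if (
                cmc.component.object_id == prev.component.object_id
                and prev.majority_cmm
                and cmc.majority_cmm
                and cmc_target(prev) == cmc_target(cmc)
            ):
                between = [
                    comp
                    for comp in by_obj[cmc.component.object_id]
                    if prev.component.part_number
                    < comp.part_number
                    < cmc.component.part_number
                ]
                if all(
                    comp.is_gap
                    or not occupied.get((comp.object_id, comp.part_number), False)
                    for comp in between
                ):
                    runs[-1].append(cmc)
                    continue
        runs.append([cmc])

    segments: list[MisassemblySegment] = []
    for i, run in enumerate(runs, start=1):
        obj = run[0].component.object_id
        first, last = run[0].component, run[-1].component
        comps = [
            comp
            for comp in by_obj[obj]
            if first.part_number <= comp.part_number <= last.part_number
        ]
        members = [
            r.focal
            for r in cmm_results
            if r.focal.chrom == obj
            and first.object_beg <= r.focal.pos_bp <= last.object_end
        ]
        cmm_ids = [i_ for c in run for i_ in c.cmm_ids]
        segments.append(
            MisassemblySegment(
                alias=f"R{i}",
                chrom=obj,
                span_start=first.object_beg,
                span_end=last.object_end,
                components=comps,
                member_markers=members,
                cmm_ids=cmm_ids,
                target_chrom=_modal_target(
                    [res_by_id[i_] for i_ in cmm_ids if i_ in res_by_id]
                ),
            )
        )
    return segments


def classify_signature(
    segment: MisassemblySegment,
    panel: GenotypePanel,
    params: SignatureParams = SignatureParams(),
) -> str:
    """Assign MisSNP / MisSeg / PMisCon to a segment.

    A single-marker segment is a MisSNP. Otherwise the segment is a MisSeg
    when at least ``misseg_cmm_fraction`` of its testable members are CMMs
    and no non-CMM member shows r2 >= ``local_r2_max`` with a non-member
    marker within ``local_window_bp`` of the span (such local LD means the
    marker genuinely belongs there). Anything else is a PMisCon.
    """
    members = [m for m in segment.member_markers if m.marker_id in panel._index]
    if not members:
        raise MismapError(f"segment {segment.alias} has no testable markers")
    if len(members) == 1:
        return "MisSNP"
    cmm_set = set(segment.cmm_ids)
    frac = sum(m.marker_id in cmm_set for m in members) / len(members)
    if frac >= params.misseg_cmm_fraction:
        non_cmm = [m for m in members if m.marker_id not in cmm_set]
        if not _any_local_ld(segment, non_cmm, panel, params):
            return "MisSeg"
    return "PMisCon"


def _any_local_ld(
    segment: MisassemblySegment,
    members: list[MarkerRecord],
    panel: GenotypePanel,
    params: SignatureParams,
) -> bool:
    """True if any given member marker is in LD (r2 >= local_r2_max) with a
    non-member marker within the local window around the segment span."""
    if not members:
        return False
    member_ids = set(segment.member_ids)
    lo = segment.span_start - params.local_window_bp
    hi = segment.span_end + params.local_window_bp
    flank_idx = [
        j
        for j, rec in enumerate(panel.markers)
        if rec.chrom == segment.chrom
        and lo <= rec.pos_bp <= hi
        and rec.marker_id not in member_ids
    ]
    if not flank_idx:
        return False
    member_idx = [panel.marker_index(m.marker_id) for m in members]
    r2 = r2_submatrix(panel, np.array(member_idx), np.array(flank_idx))
    return bool(np.nanmax(r2, initial=0.0) >= params.local_r2_max)


def genome_error_summary(
    segments: list[MisassemblySegment],
    agp: list[AGPComponent],
    n50: int | None = None,
) -> dict:
    """Misassembled fraction of the assembly, per chromosome and globally."""
    by_obj = components_by_object(agp)
    lengths = {obj: comps[-1].object_end for obj, comps in by_obj.items()}
    span_by_chrom: dict[str, int] = {obj: 0 for obj in lengths}
    seg_count: dict[str, int] = {obj: 0 for obj in lengths}
    for seg in segments:
        span_by_chrom[seg.chrom] = span_by_chrom.get(seg.chrom, 0) + seg.span_bp
        seg_count[seg.chrom] = seg_count.get(seg.chrom, 0) + 1
    per_chrom = pd.DataFrame(
        {
            "chrom": sorted(lengths, key=chrom_sort_key),
        }
    )
    per_chrom["length_bp"] = [lengths[c] for c in per_chrom["chrom"]]
    per_chrom["misassembled_bp"] = [span_by_chrom[c] for c in per_chrom["chrom"]]
    per_chrom["fraction"] = per_chrom["misassembled_bp"] / per_chrom["length_bp"]
    per_chrom["n_segments"] = [seg_count[c] for c in per_chrom["chrom"]]
    total_len = int(per_chrom["length_bp"].sum())
    total_mis = int(per_chrom["misassembled_bp"].sum())
    cmc_sizes = [
        comp.length
        for seg in segments
        for comp in seg.components
        if not comp.is_gap
    ]
    out = {
        "global_fraction": total_mis / total_len if total_len else 0.0,
        "per_chrom": per_chrom,
        "n_segments": len(segments),
        "cmc_sizes": cmc_sizes,
    }
    if n50 is not None and cmc_sizes:
        out["cmc_fraction_below_n50"] = float(
            np.mean([s < n50 for s in cmc_sizes])
        )
    return out


def segment_table(segments: list[MisassemblySegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "alias": [s.alias for s in segments],
            "chrom": [s.chrom for s in segments],
            "span_start": [s.span_start for s in segments],
            "span_end": [s.span_end for s in segments],
            "n_components": [len(s.components) for s in segments],
            "n_gaps": [sum(c.is_gap for c in s.components) for s in segments],
            "n_markers": [len(s.member_markers) for s in segments],
            "n_cmm": [len(s.cmm_ids) for s in segments],
            "target_chrom": [s.target_chrom for s in segments],
            "signature": [s.signature for s in segments],
            "populations": [
                ",".join(sorted(s.populations_detected)) for s in segments
            ],
        }
    )
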