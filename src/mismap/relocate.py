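"""Estimating where a misassembled segment really belongs, and fixing the map.

The 5' coordinate of the true location is estimated by the position of the
tag marker with the highest r2 to the segment's most proximal CMM; the 3'
coordinate likewise for the most distal CMM. Tag markers that are segment
members themselves are excluded from candidacy (their reported coordinates
are the very thing under suspicion). Corrected positions are then drawn
uniformly (without replacement, order-preserving) from the open estimated
interval.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MismapError
from .ld import TagSet
from .segments import MisassemblySegment
from .types import MarkerRecord, chrom_sort_key

__all__ = [
    "RelocationEstimate",
    "ConcordanceRecord",
    "estimate_location",
    "concordance",
    "apply_relocation",
    "relocation_table",
]


@dataclass
class RelocationEstimate:
    segment_alias: str
    population: str
    target_chrom: str | None
    est_5p: int | None
    est_3p: int | None
    orientation: str  # "same" | "inverted" | "unknown"
    support: tuple[float, float] | None  # (r2 at 5', r2 at 3')
    status: str = "ok"  # or the reason the estimate was withheld

    @property
    def midpoint(self) -> float | None:
        if self.est_5p is None or self.est_3p is None:
            return None
        return 0.5 * (self.est_5p + self.est_3p)


@dataclass
class ConcordanceRecord:
    segment_alias: str
    pop_pair: tuple[str, str]
    same_target_chrom: bool
    delta_bp: int | None  # defined only when targets agree


def _pooled_target_tags(
    member_cmms: list[MarkerRecord],
    tag_sets: dict[str, TagSet],
    member_ids: set[str],
) -> tuple[str | None, dict[str, list[tuple[MarkerRecord, float]]]]:
    """Modal tag chromosome over all member CMMs' non-member tags, plus the
    per-CMM tag lists restricted to that chromosome."""
    votes: Counter[str] = Counter()
    per_cmm: dict[str, list[tuple[MarkerRecord, float]]] = {}
    for rec in member_cmms:
        ts = tag_sets.get(rec.marker_id)
        if ts is None:
            continue
        outside = [(t, r2) for t, r2 in ts.tags if t.marker_id not in member_ids]
        per_cmm[rec.marker_id] = outside
        votes.update(t.chrom for t, _ in outside)
    if not votes:
        return None, per_cmm
    best = max(votes.values())
    target = sorted((c for c, k in votes.items() if k == best), key=chrom_sort_key)[0]
    return target, per_cmm


def estimate_location(
    segment: MisassemblySegment,
    tag_sets: dict[str, TagSet],
    population: str = "pop",
    cluster_gap_bp: int = 10_000_000,
    ambiguity_fraction: float = 0.25,
) -> RelocationEstimate:
    """LD-based 5'/3' estimate of a segment's true location.

    The target chromosome is the modal chromosome across all member CMMs'
    tag markers. Tags on the target chromosome are clustered (gaps greater
    than ``cluster_gap_bp`` split clusters); if more than one cluster holds
    over ``ambiguity_fraction`` of the tags the estimate is withheld as
    ambiguous. Exact ties on r2 break toward the tag closest to the
    opposite estimate.
    """
    member_ids = set(segment.member_ids)
    cmm_set = set(segment.cmm_ids)
    member_cmms = sorted(
        (m for m in segment.member_markers if m.marker_id in cmm_set),
        key=lambda m: m.pos_bp,
    )
    withheld = RelocationEstimate(
        segment.alias, population, None, None, None, "unknown", None
    )
    if not member_cmms:
        withheld.status = "no_cmm_markers"
        return withheld
    target, per_cmm = _pooled_target_tags(member_cmms, tag_sets, member_ids)
    if target is None:
        withheld.status = "no_tags"
        return withheld
    pooled = sorted(
        {
            t.marker_id: t
            for tags in per_cmm.values()
            for t, _ in tags
            if t.chrom == target
        }.values(),
        key=lambda t: t.pos_bp,
    )
    clusters: list[list[MarkerRecord]] = [[pooled[0]]]
    for t in pooled[1:]:
        if t.pos_bp - clusters[-1][-1].pos_bp > cluster_gap_bp:
            clusters.append([])
        clusters[-1].append(t)
    big = [c for c in clusters if len(c) > ambiguity_fraction * len(pooled)]
    if len(big) > 1:
        withheld.status = "ambiguous_target"
        withheld.target_chrom = target
        return withheld
    main = max(clusters, key=len)
    allowed = {t.marker_id for t in main}

    def best_tag(
        rec: MarkerRecord, toward: int | None
    ) -> tuple[MarkerRecord, float] | None:
        cands = [
            (t, r2)
            for t, r2 in per_cmm.get(rec.marker_id, [])
            if t.chrom == target and t.marker_id in allowed
        ]
        if not cands:
            return None
        top = max(r2 for _, r2 in cands)
        tied = [(t, r2) for t, r2 in cands if r2 == top]
        if toward is None:
            tied.sort(key=lambda tr: tr[0].pos_bp)
        else:
            tied.sort(key=lambda tr: (abs(tr[0].pos_bp - toward), tr[0].pos_bp))
        return tied[0]

    proximal, distal = member_cmms[0], member_cmms[-1]
    prov5 = best_tag(proximal, None)
    prov3 = best_tag(distal, None)
    if prov5 is None or prov3 is None:
        withheld.status = "no_tags_on_target"
        withheld.target_chrom = target
        return withheld
    pick5 = best_tag(proximal, prov3[0].pos_bp)
    pick3 = best_tag(distal, pick5[0].pos_bp)
    raw5, raw3 = pick5[0].pos_bp, pick3[0].pos_bp
    if proximal.marker_id == distal.marker_id or raw5 == raw3:
        orientation = "unknown"
    elif raw5 > raw3:
        orientation = "inverted"
    else:
        orientation = "same"
    return RelocationEstimate(
        segment_alias=segment.alias,
        population=population,
        target_chrom=target,
        est_5p=min(raw5, raw3),
        est_3p=max(raw5, raw3),
        orientation=orientation,
        support=(pick5[1], pick3[1]),
    )


def concordance(
    est_a: RelocationEstimate, est_b: RelocationEstimate
) -> ConcordanceRecord:
    """Between-population agreement of two estimates for the same segment."""
    if est_a.status != "ok" or est_b.status != "ok":
        raise MismapError("concordance needs two present estimates")
    same = est_a.target_chrom == est_b.target_chrom
    delta = int(abs(est_a.midpoint - est_b.midpoint)) if same else None
    return ConcordanceRecord(
        est_a.segment_alias, (est_a.population, est_b.population), same, delta
    )


def apply_relocation(
    markers: list[MarkerRecord],
    segment: MisassemblySegment,
    estimate: RelocationEstimate,
    seed: int,
) -> tuple[list[MarkerRecord], pd.DataFrame]:
    """Reassign a segment's markers to uniformly resampled corrected positions.

    New integer positions are drawn without replacement from the open
    interval (est_5p, est_3p), sorted, and assigned to the segment markers
    in their current within-segment order, so local marker order survives
    the move. Non-segment markers are untouched. Deterministic given seed.
    """
    if estimate.status != "ok":
        raise MismapError(f"estimate withheld: {estimate.status}")
    member_ids = set(segment.member_ids)
    seg_markers = sorted(
        (m for m in markers if m.marker_id in member_ids), key=lambda m: m.pos_bp
    )
    k = len(seg_markers)
    n_slots = estimate.est_3p - estimate.est_5p - 1
    if n_slots < k:
        raise MismapError(
            f"interval ({estimate.est_5p}, {estimate.est_3p}) too small for {k} markers"
        )
    rng = np.random.default_rng(seed)
    offsets = np.sort(rng.choice(n_slots, size=k, replace=False))
    new_pos = {
        m.marker_id: int(estimate.est_5p + 1 + off)
        for m, off in zip(seg_markers, offsets)
    }
    audit_rows = []
    out: list[MarkerRecord] = []
    for m in markers:
        if m.marker_id in new_pos:
            moved = m.moved_to(estimate.target_chrom, new_pos[m.marker_id])
            out.append(moved)
            audit_rows.append(
                {
                    "marker_id": m.marker_id,
                    "old_chrom": m.chrom,
                    "old_pos_bp": m.pos_bp,
                    "new_chrom": moved.chrom,
                    "new_pos_bp": moved.pos_bp,
                    "segment_alias": segment.alias,
                }
            )
        else:
            out.append(m)
    return out, pd.DataFrame(audit_rows)


def relocation_table(estimates: list[RelocationEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "segment_alias": [e.segment_alias for e in estimates],
            "population": [e.population for e in estimates],
            "status": [e.status for e in estimates],
            "target_chrom": [e.target_chrom for e in estimates],
            "est_5p": [e.est_5p for e in estimates],
            "est_3p": [e.est_3p for e in estimates],
            "orientation": [e.orientation for e in estimates],
            "r2_5p": [e.support[0] if e.support else None for e in estimates],
            "r2_3p": [e.support[1] if e.support else None for e in estimates],
        }
    )
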