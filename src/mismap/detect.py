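"""Candidate Misplaced Marker (CMM) detection.

A focal SNP is flagged when its tag markers (r2 > 0.5) contradict its map
coordinates, by either of two rules applied in order:

Rule 1 (cross-chromosome): a single chromosome different from the focal's
holds strictly more than half of the tag markers.

Rule 2 (long-distance, tried only if Rule 1 does not fire): among tags on
the focal's own chromosome, those at >= 10 Mb strictly outnumber those at
< 10 Mb.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import TagSet, all_tag_sets
from .types import GenotypePanel, MarkerRecord

__all__ = [
    "DetectionParams",
    "CMMResult",
    "chrom_count_table",
    "classify_focal",
    "detect_all",
    "cmm_table",
    "consensus_across_populations",
]


@dataclass(frozen=True)
class DetectionParams:
    r2_tag_threshold: float = 0.5
    majority_fraction: float = 0.5
    long_distance_bp: int = 10_000_000
    min_tags: int = 1
    min_complete_pairs: int = 2
    chunk_size: int = 256

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_tag_threshold < 1.0:
            raise ValueError("r2_tag_threshold must be in (0, 1)")
        if not 0.0 < self.majority_fraction < 1.0:
            raise ValueError("majority_fraction must be in (0, 1)")
        if self.long_distance_bp <= 0:
            raise ValueError("long_distance_bp must be positive")


@dataclass
class CMMResult:
    """Verdict for one focal marker with its full evidence tables."""

    focal: MarkerRecord
    is_cmm: bool
    rule_fired: str  # "cross_chromosome" | "long_distance" | "none"
    chrom_counts: dict[str, int] = field(default_factory=dict)
    target_chrom: str | None = None
    long_count: int = 0
    short_count: int = 0
    n_tags: int = 0


def chrom_count_table(tagset: TagSet) -> dict[str, int]:
    """Tag-marker counts per (currently assigned) chromosome."""
    return dict(Counter(rec.chrom for rec, _r2 in tagset.tags))


def classify_focal(
    focal: MarkerRecord, tagset: TagSet, params: DetectionParams = DetectionParams()
) -> CMMResult:
    """Apply the two-rule decision procedure to one focal marker (pure)."""
    counts = chrom_count_table(tagset)
    total = len(tagset)
    same = [
        abs(rec.pos_bp - focal.pos_bp) for rec, _r2 in tagset.tags
        if rec.chrom == focal.chrom
    ]
    long_count = sum(d >= params.long_distance_bp for d in same)
    short_count = len(same) - long_count
    result = CMMResult(
        focal=focal,
        is_cmm=False,
        rule_fired="none",
        chrom_counts=counts,
        long_count=long_count,
        short_count=short_count,
        n_tags=total,
    )
    if total < max(params.min_tags, 1):
        return result
    # Rule 1: a strict majority of tags on one different chromosome. With a
    # majority fraction >= 0.5 at most one chromosome can qualify; a tie at
    # the maximum therefore never fires.
    winners = [c for c, k in counts.items() if k > params.majority_fraction * total]
    if winners:
        best = max(winners, key=lambda c: counts[c])
        if sum(counts[c] == counts[best] for c in winners) == 1 and best != focal.chrom:
            result.is_cmm = True
            result.rule_fired = "cross_chromosome"
            result.target_chrom = best
            return result
    # Rule 2: long-distance tags on the own chromosome strictly outnumber
    # short-distance ones.
    if long_count > short_count:
        result.is_cmm = True
        result.rule_fired = "long_distance"
        result.target_chrom = focal.chrom
    return result


def detect_all(
    panel: GenotypePanel,
    params: DetectionParams = DetectionParams(),
    tag_sets: list[TagSet] | None = None,
    markers: list[MarkerRecord] | None = None,
) -> list[CMMResult]:
    """Classify every marker of a QC-filtered panel.

    ``tag_sets`` may be passed to reuse a previous scan (tag membership
    depends only on genotypes). ``markers`` substitutes an alternative map
    with the same marker ids, e.g. a corrected map for re-screening: tags
    are then re-joined to the substituted coordinates.
    """
    if tag_sets is None:
        tag_sets = all_tag_sets(
            panel,
            threshold=params.r2_tag_threshold,
            min_complete=params.min_complete_pairs,
            chunk_size=params.chunk_size,
        )
    if len(tag_sets) != panel.n_markers:
        raise ValueError("tag_sets must align with panel markers")
    if markers is None:
        lookup = {m.marker_id: m for m in panel.markers}
    else:
        lookup = {m.marker_id: m for m in markers}
        missing = set(panel.marker_ids) - set(lookup)
        if missing:
            raise ValueError(f"substitute map lacks {len(missing)} panel markers")
    results = []
    for rec, ts in zip(panel.markers, tag_sets):
        focal = lookup[rec.marker_id]
        joined = TagSet(
            ts.focal_id,
            [(lookup[t.marker_id], r2) for t, r2 in ts.tags],
            ts.threshold,
        )
        results.append(classify_focal(focal, joined, params))
    return results


def cmm_table(results: list[CMMResult]) -> pd.DataFrame:
    """Flat result table (one row per focal marker)."""
    import json

    return pd.DataFrame(
        {
            "marker_id": [r.focal.marker_id for r in results],
            "chrom": [r.focal.chrom for r in results],
            "pos_bp": [r.focal.pos_bp for r in results],
            "is_cmm": [r.is_cmm for r in results],
            "rule": [r.rule_fired for r in results],
            "target_chrom": [r.target_chrom for r in results],
            "n_tags": [r.n_tags for r in results],
            "long_count": [r.long_count for r in results],
            "short_count": [r.short_count for r in results],
            "chrom_counts": [
                json.dumps(r.chrom_counts, sort_keys=True) for r in results
            ],
        }
    )


def consensus_across_populations(
    results_a: list[CMMResult], results_b: list[CMMResult]
) -> pd.DataFrame:
    """Per-marker CMM agreement between two independently screened panels.

    The marker universes may differ (population-specific MAF filtering): a
    marker absent from one panel is untestable there and is never treated
    as "not a CMM" in that population.
    """
    a = {r.focal.marker_id: r.is_cmm for r in results_a}
    b = {r.focal.marker_id: r.is_cmm for r in results_b}
    rows = []
    for mid in sorted(set(a) | set(b)):
        in_a, in_b = mid in a, mid in b
        cmm_a = a.get(mid, False)
        cmm_b = b.get(mid, False)
        if cmm_a and cmm_b:
            status = "both"
        elif cmm_a:
            status = "A_only"
        elif cmm_b:
            status = "B_only"
        else:
            status = "neither"
        rows.append(
            {
                "marker_id": mid,
                "status": status,
                "cmm_a": cmm_a if in_a else pd.NA,
                "cmm_b": cmm_b if in_b else pd.NA,
                "testable_a": in_a,
                "testable_b": in_b,
            }
        )
    return pd.DataFrame(rows)


def false_positive_rate(results: list[CMMResult]) -> float:
    """Fraction of screened markers flagged as CMM."""
    if not results:
        return float("nan")
    return float(np.mean([r.is_cmm for r in results]))
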