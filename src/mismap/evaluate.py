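"""Planted-event scoring of full pipeline replicates.

Runs simulate -> QC -> scan -> detect -> segment -> classify -> relocate ->
re-detect on one simulated cohort and scores every stage against the
simulator's truth table. Used by the validation suite and by the
results-reproduction script; it is also a worked example of driving the
whole library programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .detect import DetectionParams, detect_all
from .errors import MismapError
from .ld import all_tag_sets
from .qc import QCThresholds, apply_qc
from .relocate import apply_relocation, concordance, estimate_location
from .segments import (
    SignatureParams,
    assign_contigs,
    classify_signature,
    merge_adjacent,
)
from .simulate import POPULATIONS, SimConfig, SimCohort, simulate_cohort

__all__ = ["ReplicateScore", "score_replicate", "summarize_scores"]

_EXPECTED_SIGNATURE = {
    "move_segment": "MisSeg",
    "move_snp": "MisSNP",
    "partial_shuffle": "PMisCon",
}


@dataclass
class ReplicateScore:
    """Per-population stage scores for one simulated replicate."""

    seed: int
    # marker-level sensitivity on planted move_segment markers (per population)
    seg_sensitivity: dict[str, float] = field(default_factory=dict)
    # CMM rate when the same genotypes are classified under the *true* map
    false_positive_rate: dict[str, float] = field(default_factory=dict)
    # recovered signature per event type (None if no matching segment)
    signatures: dict[str, dict[str, str | None]] = field(default_factory=dict)
    # relocation of the move_segment event
    overlap: dict[str, bool] = field(default_factory=dict)
    midpoint_error_bp: dict[str, float] = field(default_factory=dict)
    spacing_bp: dict[str, float] = field(default_factory=dict)
    # round trip: segment CMM count after correction vs background
    roundtrip_background: dict[str, bool] = field(default_factory=dict)
    post_rate: dict[str, float] = field(default_factory=dict)
    # cross-population consensus on the move_segment markers
    both_rate: float = float("nan")
    target_concordant: bool | None = None


def score_replicate(
    seed: int,
    sim: SimConfig | None = None,
    qc: QCThresholds | None = None,
    det: DetectionParams | None = None,
    sig: SignatureParams | None = None,
) -> ReplicateScore:
    """Simulate one cohort under ``seed`` and score every pipeline stage."""
    cfg = sim if sim is not None else SimConfig()
    cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
    qc = qc or QCThresholds()
    det = det or DetectionParams()
    sig = sig or SignatureParams()
    cohort = simulate_cohort(cfg)
    score = ReplicateScore(seed=seed)
    results_by_pop = {}
    estimates = {}
    for pop in POPULATIONS:
        _score_population(cohort, pop, qc, det, sig, score, results_by_pop, estimates)

    ev = _event(cohort, "move_segment")
    flagged = {
        pop: {
            r.focal.marker_id
            for r in results_by_pop[pop]
            if r.is_cmm and r.focal.marker_id in set(ev.marker_ids)
        }
        for pop in POPULATIONS
    }
    testable_both = [
        m
        for m in ev.marker_ids
        if all(
            m in {r.focal.marker_id for r in results_by_pop[pop]}
            for pop in POPULATIONS
        )
    ]
    if testable_both:
        score.both_rate = float(
            np.mean([all(m in flagged[pop] for pop in POPULATIONS) for m in testable_both])
        )
    if all(pop in estimates for pop in POPULATIONS):
        rec = concordance(estimates["A"], estimates["B"])
        score.target_concordant = rec.same_target_chrom
    return score


def _event(cohort: SimCohort, event_type: str):
    return next(e for e in cohort.events if e.event_type == event_type)


def _score_population(cohort, pop, qc, det, sig, score, results_by_pop, estimates):
    panel, _report = apply_qc(cohort.panel(pop, "reported"), qc)
    tag_sets = all_tag_sets(
        panel, threshold=det.r2_tag_threshold,
        min_complete=det.min_complete_pairs, chunk_size=det.chunk_size,
    )
    tag_dict = {t.focal_id: t for t in tag_sets}
    results = detect_all(panel, det, tag_sets=tag_sets)
    results_by_pop[pop] = results
    by_id = {r.focal.marker_id: r for r in results}

    ev_seg = _event(cohort, "move_segment")
    testable = [m for m in ev_seg.marker_ids if m in by_id]
    score.seg_sensitivity[pop] = (
        float(np.mean([by_id[m].is_cmm for m in testable])) if testable else float("nan")
    )

    # false positives: same genotypes and tag sets, classified under the
    # uncorrupted (true) map
    res_true = detect_all(panel, det, tag_sets=tag_sets, markers=cohort.assembly.markers)
    score.false_positive_rate[pop] = float(np.mean([r.is_cmm for r in res_true]))

    cmcs, _diag = assign_contigs(results, cohort.agp_reported)
    segments = merge_adjacent(cmcs, cohort.agp_reported, results)
    for seg in segments:
        seg.signature = classify_signature(seg, panel, sig)
        seg.populations_detected.add(pop)

    score.signatures[pop] = {}
    for ev in cohort.events:
        match = [s for s in segments if set(ev.marker_ids) & set(s.cmm_ids)]
        best = max(match, key=lambda s: len(set(ev.marker_ids) & set(s.cmm_ids))) \
            if match else None
        score.signatures[pop][ev.event_type] = best.signature if best else None
        if ev.event_type != "move_segment" or best is None:
            continue
        est = estimate_location(best, tag_dict, pop)
        if est.status != "ok":
            score.overlap[pop] = False
            score.midpoint_error_bp[pop] = float("inf")
            continue
        estimates[pop] = est
        score.overlap[pop] = not (
            est.est_3p < ev.source_start or est.est_5p > ev.source_end
        )
        score.midpoint_error_bp[pop] = abs(
            est.midpoint - 0.5 * (ev.source_start + ev.source_end)
        )
        pos = np.sort(panel.positions[panel.chroms == ev.source_chrom])
        score.spacing_bp[pop] = float(np.median(np.diff(pos)))

        # round trip: correct the map, re-classify, compare with background
        try:
            corrected, _audit = apply_relocation(
                panel.markers, best, est, seed=cohort.config.seed
            )
        except MismapError:  # degenerate (point) interval cannot host markers
            score.roundtrip_background[pop] = False
            score.post_rate[pop] = float("nan")
            continue
        res_corr = detect_all(panel, det, tag_sets=tag_sets, markers=corrected)
        by_corr = {r.focal.marker_id: r for r in res_corr}
        seg_ids = [m for m in best.member_ids if m in by_corr]
        k = sum(by_corr[m].is_cmm for m in seg_ids)
        score.post_rate[pop] = k / len(seg_ids) if seg_ids else float("nan")
        bg = max(score.false_positive_rate[pop], 1e-9)
        # indistinguishable from background: one-sided binomial test at 5 %
        score.roundtrip_background[pop] = bool(
            binomtest(k, len(seg_ids), bg, alternative="greater").pvalue >= 0.05
        )


def summarize_scores(scores: list[ReplicateScore]) -> dict:
    """Pool replicate scores into the headline rates."""
    pops = POPULATIONS

    def pooled(attr):
        return [getattr(s, attr)[p] for s in scores for p in pops
                if p in getattr(s, attr)]

    sig_rate = {}
    for ev_type, want in _EXPECTED_SIGNATURE.items():
        got = [
            s.signatures[p].get(ev_type) == want
            for s in scores for p in pops if p in s.signatures
        ]
        sig_rate[ev_type] = float(np.mean(got))
    mid_ratio = [
        s.midpoint_error_bp[p] / (2 * s.spacing_bp[p])
        for s in scores for p in pops
        if p in s.midpoint_error_bp and p in s.spacing_bp
    ]
    n_cases = len(scores) * len(pops)
    return {
        "sensitivity": float(np.nanmean(pooled("seg_sensitivity"))),
        "false_positive_rate": float(np.nanmean(pooled("false_positive_rate"))),
        "signature_rate": sig_rate,
        "overlap_rate": float(np.sum(pooled("overlap")) / n_cases),
        "midpoint_ok_rate": float(
            (np.sum(np.asarray(mid_ratio) <= 1.0) if mid_ratio else 0) / n_cases
        ),
        "roundtrip_rate": float(np.sum(pooled("roundtrip_background")) / n_cases),
        "both_rate": float(np.nanmean([s.both_rate for s in scores])),
        "target_concordant_rate": float(
            np.mean([bool(s.target_concordant) for s in scores])
        ),
        "n_replicates": len(scores),
    }
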