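"""Marker- and sample-level quality control.

The cascade mirrors common SNP-array practice: sample call rate, then
GRM-based relatedness pruning, then per-marker call rate, minor allele
frequency, and an exact Hardy-Weinberg test. Thresholds default to the
values used for BovineHD-style panels (call rate >= 0.95 per marker and
>= 0.90 per sample, MAF > 0.03, HWE p > 1e-8, pairwise relatedness < 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd

from .errors import QCError
from .types import GenotypePanel

__all__ = [
    "QCThresholds",
    "QCReport",
    "marker_stats",
    "hwe_exact_p",
    "grm",
    "rel_cutoff_prune",
    "apply_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    marker_call_rate_min: float = 0.95
    maf_min: float = 0.03
    hwe_p_min: float = 1e-8
    sample_call_rate_min: float = 0.90
    rel_cutoff: float = 0.4

    def __post_init__(self) -> None:
        for name in ("marker_call_rate_min", "maf_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.hwe_p_min < 1.0:
            # hwe_p_min == 0 is allowed to disable the filter entirely
            if self.hwe_p_min != 0.0:
                raise ValueError(f"hwe_p_min must be in [0, 1), got {self.hwe_p_min}")


@dataclass
class QCReport:
    """Per-marker and per-sample QC statistics plus removal accounting."""

    marker_table: pd.DataFrame
    sample_table: pd.DataFrame
    counts: dict = field(default_factory=dict)

    def summary(self) -> str:
        c = self.counts
        return (
            f"samples {c['samples_in']} -> {c['samples_out']} "
            f"(call rate -{c['samples_fail_call_rate']}, "
            f"relatedness -{c['samples_fail_relatedness']}); "
            f"markers {c['markers_in']} -> {c['markers_out']} "
            f"(call rate -{c['markers_fail_call_rate']}, "
            f"maf -{c['markers_fail_maf']}, hwe -{c['markers_fail_hwe']})"
        )


def marker_stats(panel: GenotypePanel) -> pd.DataFrame:
    """Call rate, MAF and genotype counts per marker.

    MAF is computed from allele counts over non-missing genotypes and is NaN
    (undefined) for all-missing markers.
    """
    if panel.n_markers == 0:
        raise ValueError("empty panel")
    X = panel.dosages
    obs = np.isfinite(X)
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / panel.n_samples
    with np.errstate(invalid="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * n_obs)  # frequency of the counted allele
    maf = np.where(n_obs > 0, np.minimum(p, 1.0 - p), np.nan)
    return pd.DataFrame(
        {
            "marker_id": panel.marker_ids,
            "chrom": panel.chroms,
            "pos_bp": panel.positions,
            "call_rate": call_rate,
            "maf": maf,
            "n_aa": (X == 2.0).sum(axis=0),
            "n_ab": (X == 1.0).sum(axis=0),
            "n_bb": (X == 0.0).sum(axis=0),
            "n_missing": panel.n_samples - n_obs,
        }
    )


@lru_cache(maxsize=200_000)
def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one. Computed
    in exact integer arithmetic (probability weights are integers), so the
    returned p equals the enumeration value to float precision.

    A zero total (no genotyped samples) returns 1.0 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    # weight(h) proportional to P(n_ab = h | na, nb): multinomial x 2^h
    weights: dict[int, int] = {}
    for h in range(na % 2, min(na, nb) + 1, 2):
        weights[h] = comb(n, h) * comb(n - h, (na - h) // 2) * (1 << h)
    w_obs = weights[n_ab]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, sum(weights.values())))


def grm(panel: GenotypePanel) -> np.ndarray:
    """Variance-standardised genomic relationship matrix.

    G_ij = mean over usable (polymorphic) markers where both samples are
    genotyped of (x_i - 2p)(x_j - 2p) / (2p(1-p)); p is the counted-allele
    frequency in the panel. Missing genotypes are handled pairwise-complete.
    """
    if panel.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    X = panel.dosages
    obs = np.isfinite(X)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * n_obs)
    usable = (n_obs > 0) & (p > 0.0) & (p < 1.0)
    if not usable.any():
        raise ValueError("no polymorphic markers for GRM")
    Xu = X[:, usable]
    pu = p[usable]
    Z = (Xu - 2.0 * pu) / np.sqrt(2.0 * pu * (1.0 - pu))
    W = np.isfinite(Xu)
    Z = np.where(W, Z, 0.0)
    num = Z @ Z.T
    cnt = W.astype(np.float64) @ W.astype(np.float64).T
    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.where(cnt > 0, num / cnt, np.nan)
    return G


def rel_cutoff_prune(
    G: np.ndarray, cutoff: float, call_rates: np.ndarray | None = None
) -> np.ndarray:
    """Greedy pruning of related samples; returns a boolean keep-mask.

    While any kept off-diagonal entry >= cutoff remains, the sample in the
    most violating pairs is dropped; ties go to the lower call rate, then to
    the later sample index. The result has no remaining pair >= cutoff.
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if G.shape != (n, n):
        raise ValueError("G must be square")
    keep = np.ones(n, dtype=bool)
    if not np.isfinite(cutoff):
        return keep
    if call_rates is None:
        call_rates = np.ones(n)
    viol = (G >= cutoff) & ~np.eye(n, dtype=bool) & np.isfinite(G)
    while True:
        active = viol & keep[:, None] & keep[None, :]
        counts = active.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = counts.max()
        cands = np.flatnonzero(counts == worst)
        low_cr = cands[call_rates[cands] == call_rates[cands].min()]
        keep[low_cr.max()] = False
    assert not (viol & keep[:, None] & keep[None, :]).any()
    return keep


def apply_qc(
    panel: GenotypePanel, thresholds: QCThresholds = QCThresholds()
) -> tuple[GenotypePanel, QCReport]:
    """Run the full cascade and return the filtered panel plus a report.

    Order: sample call rate -> relatedness prune -> marker call rate -> MAF
    -> HWE. Marker statistics for the marker-level filters are computed on
    the retained samples. Each removed item carries exactly one reason (the
    first failing filter).
    """
    t = thresholds
    n0, m0 = panel.n_samples, panel.n_markers

    sample_cr = np.isfinite(panel.dosages).mean(axis=1) if m0 else np.ones(n0)
    sample_reason = np.array([""] * n0, dtype=object)
    sample_reason[sample_cr < t.sample_call_rate_min] = "low_call_rate"
    kept_idx = np.flatnonzero(sample_reason == "")
    working = panel.subset_samples(kept_idx)

    if np.isfinite(t.rel_cutoff) and working.n_samples >= 2:
        G = grm(working)
        keep = rel_cutoff_prune(
            G, t.rel_cutoff, np.isfinite(working.dosages).mean(axis=1)
        )
        sample_reason[kept_idx[~keep]] = "relatedness"
        working = working.subset_samples(np.flatnonzero(keep))

    stats = marker_stats(working) if working.n_samples else marker_stats(panel)
    reason = np.array([""] * m0, dtype=object)
    cr_fail = stats["call_rate"].to_numpy() < t.marker_call_rate_min
    reason[cr_fail & (reason == "")] = "call_rate"
    maf = stats["maf"].to_numpy()
    if t.maf_min > 0:  # keep requires maf strictly above the threshold
        maf_fail = ~np.isfinite(maf) | (maf <= t.maf_min)
        reason[maf_fail & (reason == "")] = "maf"
    if t.hwe_p_min > 0:
        for j in np.flatnonzero(reason == ""):
            p = hwe_exact_p(
                int(stats.at[j, "n_aa"]), int(stats.at[j, "n_ab"]), int(stats.at[j, "n_bb"])
            )
            if p <= t.hwe_p_min:
                reason[j] = "hwe"
    stats["fail_reason"] = reason

    marker_keep = np.flatnonzero(reason == "")
    filtered = working.subset_markers(marker_keep)

    sample_table = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "call_rate": sample_cr,
            "fail_reason": sample_reason,
        }
    )
    counts = {
        "samples_in": n0,
        "samples_out": filtered.n_samples,
        "samples_fail_call_rate": int((sample_reason == "low_call_rate").sum()),
        "samples_fail_relatedness": int((sample_reason == "relatedness").sum()),
        "markers_in": m0,
        "markers_out": filtered.n_markers,
        "markers_fail_call_rate": int((reason == "call_rate").sum()),
        "markers_fail_maf": int((reason == "maf").sum()),
        "markers_fail_hwe": int((reason == "hwe").sum()),
    }
    report = QCReport(stats, sample_table, counts)
    if filtered.n_samples == 0 or filtered.n_markers == 0:
        raise QCError("QC removed all samples or markers", report=report)
    return filtered, report
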