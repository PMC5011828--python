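"""Genome-wide genotype-correlation LD (r squared).

r2 between two markers is the squared Pearson correlation of their dosage
vectors (0/1/2 copies of the counted allele) over samples genotyped at both
markers. No phasing is involved anywhere. The all-pairs scan is evaluated in
column chunks of exact integer-valued cross products, so chunked and
pairwise evaluation agree to the last bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GenotypePanel, MarkerRecord

__all__ = [
    "LDScan",
    "TagSet",
    "r2_pair",
    "focal_scan",
    "tag_markers",
    "all_tag_sets",
    "r2_submatrix",
]

DEFAULT_TAG_THRESHOLD = 0.5


@dataclass
class LDScan:
    """All defined r2 values of one focal marker against the rest of a panel."""

    focal_id: str
    entries: list[tuple[str, float, int]]  # (marker_id, r2, n_complete_pairs)


@dataclass
class TagSet:
    """Markers in high LD (r2 strictly above ``threshold``) with one focal SNP."""

    focal_id: str
    tags: list[tuple[MarkerRecord, float]]
    threshold: float = DEFAULT_TAG_THRESHOLD

    def __len__(self) -> int:
        return len(self.tags)


def _r2_cross(
    A: np.ndarray, B: np.ndarray, min_complete: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """r2 between every column of A and every column of B (NaN = missing).

    Returns (r2, n) matrices of shape (A columns, B columns); undefined
    entries (fewer than ``min_complete`` complete pairs, or a constant
    vector on the complete subset) are NaN. All sums of integer dosages are
    exact in float64, so the result does not depend on chunking.
    """
    WA = np.isfinite(A)
    WB = np.isfinite(B)
    A0 = np.where(WA, A, 0.0)
    B0 = np.where(WB, B, 0.0)
    WAf = WA.astype(np.float64)
    WBf = WB.astype(np.float64)
    N = WAf.T @ WBf
    Sx = A0.T @ WBf
    Sy = WAf.T @ B0
    Sxy = A0.T @ B0
    Sxx = (A0 * A0).T @ WBf
    Syy = WAf.T @ (B0 * B0)
    cov = N * Sxy - Sx * Sy
    vx = N * Sxx - Sx * Sx
    vy = N * Syy - Sy * Sy
    defined = (N >= max(min_complete, 2)) & (vx > 0) & (vy > 0)
    r2 = np.full(N.shape, np.nan)
    np.divide(cov * cov, vx * vy, out=r2, where=defined)
    return r2, N


def r2_pair(
    g_focal: np.ndarray, g_other: np.ndarray, min_complete: int = 2
) -> float:
    """r2 of two dosage vectors over pairwise-complete samples (NaN if undefined)."""
    x = np.asarray(g_focal, dtype=np.float64).ravel()
    y = np.asarray(g_other, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    r2, _ = _r2_cross(x[:, None], y[:, None], min_complete)
    return float(r2[0, 0])


def r2_submatrix(
    panel: GenotypePanel,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    min_complete: int = 2,
) -> np.ndarray:
    """On-demand r2 block between two marker index sets of one panel."""
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    r2, _ = _r2_cross(panel.dosages[:, idx_a], panel.dosages[:, idx_b], min_complete)
    return r2


def focal_scan(
    panel: GenotypePanel,
    focal_id: str,
    min_complete: int = 2,
    chunk_size: int | None = None,
) -> LDScan:
    """r2 of one focal marker against every other marker in the panel.

    The focal marker must be polymorphic on its genotyped samples (QC should
    have removed monomorphic markers). Undefined pairs are omitted.
    """
    j = panel.marker_index(focal_id)
    col = panel.dosages[:, j]
    obs = col[np.isfinite(col)]
    if obs.size == 0 or (obs == obs[0]).all():
        raise ValueError(f"focal marker {focal_id!r} is monomorphic")
    entries: list[tuple[str, float, int]] = []
    m = panel.n_markers
    step = chunk_size or m
    for lo in range(0, m, step):
        hi = min(lo + step, m)
        r2, n = _r2_cross(col[:, None], panel.dosages[:, lo:hi], min_complete)
        for k in range(hi - lo):
            if lo + k != j and np.isfinite(r2[0, k]):
                entries.append(
                    (panel.markers[lo + k].marker_id, float(r2[0, k]), int(n[0, k]))
                )
    return LDScan(focal_id, entries)


def tag_markers(
    scan: LDScan,
    markers_by_id: dict[str, MarkerRecord],
    threshold: float = DEFAULT_TAG_THRESHOLD,
) -> TagSet:
    """Filter a scan to tag markers with r2 strictly above ``threshold``."""
    tags: list[tuple[MarkerRecord, float]] = []
    for marker_id, r2, _n in scan.entries:
        if r2 > threshold:
            if marker_id not in markers_by_id:
                raise KeyError(f"scan marker {marker_id!r} missing from map")
            tags.append((markers_by_id[marker_id], r2))
    return TagSet(scan.focal_id, tags, threshold)


def all_tag_sets(
    panel: GenotypePanel,
    threshold: float = DEFAULT_TAG_THRESHOLD,
    min_complete: int = 2,
    chunk_size: int = 256,
) -> list[TagSet]:
    """Tag sets for every marker of the panel via the chunked all-pairs scan.

    Returns one TagSet per panel marker (tags joined to the panel's own map).
    This is the map-independent half of the detection procedure: tag
    membership depends only on genotypes, so the same tag sets can be
    re-classified under alternative marker maps.
    """
    m = panel.n_markers
    X = panel.dosages
    out: list[TagSet] = []
    for lo in range(0, m, chunk_size):
        hi = min(lo + chunk_size, m)
        r2, _ = _r2_cross(X[:, lo:hi], X, min_complete)
        for k in range(hi - lo):
            row = r2[k]
            hits = np.flatnonzero(row > threshold)
            tags = [
                (panel.markers[t], float(row[t])) for t in hits if t != lo + k
            ]
            out.append(TagSet(panel.markers[lo + k].marker_id, tags, threshold))
    return out
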