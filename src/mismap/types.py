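"""Core in-memory containers: marker maps and diploid genotype panels.

Coordinates are 1-based inclusive throughout the package (BIM/AGP/VCF
convention); conversion to 0-based half-open happens only at the BED
export boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = ["MarkerRecord", "GenotypePanel", "chrom_sort_key"]


def chrom_sort_key(chrom: str) -> tuple:
    """Natural ordering for chromosome names: numeric names first ("1" < "2" < "10"),
    then lexicographic for the rest ("MT", "X", ...)."""
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


@dataclass(frozen=True)
class MarkerRecord:
    """One SNP on the marker map.

    pos_bp is the 1-based physical coordinate on ``chrom``. ``allele_a`` is the
    counted allele (dosage = number of copies of allele_a), ``allele_b`` the
    other allele; both optional because some map sources carry no alleles.
    """

    marker_id: str
    chrom: str
    pos_bp: int
    allele_a: str | None = None
    allele_b: str | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(
                f"marker {self.marker_id}: pos_bp must be >= 1, got {self.pos_bp}"
            )

    def moved_to(self, chrom: str, pos_bp: int) -> "MarkerRecord":
        return replace(self, chrom=chrom, pos_bp=pos_bp)


class GenotypePanel:
    """samples x markers dosage matrix over {0, 1, 2, missing} plus a marker map.

    Dosages are stored as float64 with NaN for missing calls; every finite
    entry must be 0, 1 or 2. The marker map is an ordered list of
    :class:`MarkerRecord` aligned with the matrix columns.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        markers: Sequence[MarkerRecord],
        dosages: np.ndarray,
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.float64)
        if dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x markers matrix")
        if dosages.shape != (len(sample_ids), len(markers)):
            raise ValueError(
                f"dosage matrix shape {dosages.shape} does not match "
                f"{len(sample_ids)} samples x {len(markers)} markers"
            )
        finite = dosages[np.isfinite(dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        ids = [m.marker_id for m in markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker ids in map")
        self.sample_ids: list[str] = list(sample_ids)
        self.markers: list[MarkerRecord] = list(markers)
        self.dosages: np.ndarray = dosages
        self._index: dict[str, int] = {mid: i for i, mid in enumerate(ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos_bp for m in self.markers], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([m.chrom for m in self.markers], dtype=object)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in panel") from None

    # -- derived panels ------------------------------------------------------
    def subset_samples(self, index: Iterable[int] | np.ndarray) -> "GenotypePanel":
        idx = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        return GenotypePanel(
            [self.sample_ids[i] for i in idx], self.markers, self.dosages[idx, :]
        )

    def subset_markers(self, index: Iterable[int] | np.ndarray) -> "GenotypePanel":
        idx = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        return GenotypePanel(
            self.sample_ids, [self.markers[i] for i in idx], self.dosages[:, idx]
        )

    def with_markers(self, markers: Sequence[MarkerRecord]) -> "GenotypePanel":
        """Same genotypes under a different map (ids must match column-wise)."""
        if [m.marker_id for m in markers] != self.marker_ids:
            raise ValueError("replacement map must keep marker ids and order")
        return GenotypePanel(self.sample_ids, markers, self.dosages)

    def sorted_by_map(self) -> "GenotypePanel":
        """Canonical marker order: (chromosome, position, marker_id)."""
        order = sorted(
            range(self.n_markers),
            key=lambda i: (
                chrom_sort_key(self.markers[i].chrom),
                self.markers[i].pos_bp,
                self.markers[i].marker_id,
            ),
        )
        return self.subset_markers(order)

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.markers == other.markers
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GenotypePanel({self.n_samples} samples x {self.n_markers} markers)"
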