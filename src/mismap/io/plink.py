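"""PLINK 1 binary (BED/BIM/FAM) reader and writer.

The .bed payload is SNP-major v1.00: three magic bytes 0x6c 0x1b 0x01 followed
by ceil(n_samples/4) bytes per marker. Each byte packs four samples, two bits
each, least-significant pair first:

    00  homozygous A1   -> dosage 2 (dosage counts the BIM A1 allele)
    01  missing         -> NaN
    10  heterozygous    -> dosage 1
    11  homozygous A2   -> dosage 0
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import FormatError
from ..types import GenotypePanel, MarkerRecord

__all__ = ["read_plink", "write_plink"]

_MAGIC = b"\x6c\x1b\x01"

# 256-entry lookup: byte -> four dosages (LSB pair = first sample).
_CODE_TO_DOSE = np.array([2.0, np.nan, 1.0, 0.0])
_BYTE_LUT = np.empty((256, 4), dtype=np.float64)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _CODE_TO_DOSE[(_b >> (2 * _k)) & 0b11]
_DOSE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def _read_bim(bim_path) -> list[MarkerRecord]:
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str, "a1": str, "a2": str},
    )
    return [
        MarkerRecord(r.marker_id, r.chrom, int(r.pos), r.a1, r.a2)
        for r in bim.itertuples()
    ]


def _read_fam(fam_path) -> list[str]:
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise FormatError(f"{fam_path}: FAM needs at least 2 columns")
    return list(fam.iloc[:, 1])


def read_plink(bed_path, bim_path, fam_path) -> GenotypePanel:
    """Read a BED/BIM/FAM trio into a :class:`GenotypePanel`."""
    markers = _read_bim(bim_path)
    sample_ids = _read_fam(fam_path)
    raw = Path(bed_path).read_bytes()
    if raw[:3] != _MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes (not SNP-major bed v1.00)")
    n, m = len(sample_ids), len(markers)
    bytes_per_marker = math.ceil(n / 4)
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_marker * m:
        raise FormatError(
            f"{bed_path}: payload is {payload.size} bytes, expected "
            f"{bytes_per_marker * m} for {n} samples x {m} markers"
        )
    decoded = _BYTE_LUT[payload.reshape(m, bytes_per_marker)]  # m x bpm x 4
    dosages = decoded.reshape(m, bytes_per_marker * 4)[:, :n].T
    return GenotypePanel(sample_ids, markers, np.ascontiguousarray(dosages))


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write ``prefix``.bed/.bim/.fam in canonical (chrom, pos, id) marker order."""
    panel = panel.sorted_by_map()
    prefix = Path(prefix)
    n, m = panel.n_samples, panel.n_markers
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for rec in panel.markers:
            fh.write(
                f"{rec.chrom}\t{rec.marker_id}\t0\t{rec.pos_bp}\t"
                f"{rec.allele_a or 'A'}\t{rec.allele_b or 'B'}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in panel.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    bytes_per_marker = math.ceil(n / 4)
    out = np.zeros((m, bytes_per_marker), dtype=np.uint8)
    dos = panel.dosages
    for j in range(m):
        col = dos[:, j]
        for i in range(n):
            code = 0b01 if np.isnan(col[i]) else _DOSE_TO_CODE[col[i]]
            out[j, i // 4] |= code << (2 * (i % 4))
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(out.tobytes())
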