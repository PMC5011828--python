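"""VCF ingestion (via cyvcf2) and minimal VCFv4.2 export.

Dosage is the ALT-allele count of a diploid GT call; half calls and
non-diploid calls become missing. Multi-allelic records are dropped with a
warning because the screen is defined on biallelic SNPs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from ..errors import FormatError
from ..types import GenotypePanel, MarkerRecord, chrom_sort_key

__all__ = ["read_vcf", "write_vcf"]

log = logging.getLogger(__name__)


def read_vcf(vcf_path) -> GenotypePanel:
    """Read a diploid GT-bearing VCF into a :class:`GenotypePanel`.

    The counted allele (``allele_a``) is ALT, so dosages match a PLINK panel
    written by :func:`mismap.io.plink.write_plink` with A1 = ALT.
    """
    vcf = VCF(str(vcf_path), gts012=False)
    try:
        vcf.get_header_type("GT")
    except KeyError:
        raise FormatError(f"{vcf_path}: no GT FORMAT field in header") from None
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise FormatError(f"{vcf_path}: VCF has no sample columns")
    markers: list[MarkerRecord] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        col = np.full(len(sample_ids), np.nan)
        for i, call in enumerate(var.genotypes):
            alleles = call[:-1]  # last element is the phased flag
            if len(alleles) != 2 or alleles[0] < 0 or alleles[1] < 0:
                continue  # non-diploid or half/no call -> missing
            col[i] = float(alleles[0] + alleles[1])
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        markers.append(MarkerRecord(mid, var.CHROM, var.POS, var.ALT[0], var.REF))
        columns.append(col)
    if n_multi:
        log.warning("%s: dropped %d multi-allelic record(s)", vcf_path, n_multi)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(sample_ids), 0))
    )
    return GenotypePanel(sample_ids, markers, dosages)


_GT = {2.0: "1/1", 1.0: "0/1", 0.0: "0/0"}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as an uncompressed VCFv4.2, records in canonical order."""
    panel = panel.sorted_by_map()
    chrom_len: dict[str, int] = {}
    for rec in panel.markers:
        chrom_len[rec.chrom] = max(chrom_len.get(rec.chrom, 0), rec.pos_bp)
    with open(Path(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mismap\n")
        for chrom in sorted(chrom_len, key=chrom_sort_key):
            fh.write(f"##contig=<ID={chrom},length={chrom_len[chrom] + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j, rec in enumerate(panel.markers):
            ref = rec.allele_b or "A"
            alt = rec.allele_a or "B"
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in panel.dosages[:, j]
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos_bp}\t{rec.marker_id}\t{ref}\t{alt}"
                f"\t.\t.\t.\tGT\t{calls}\n"
            )
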