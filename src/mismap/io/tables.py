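"""Result-table output: TSVs plus a BED track of misassembled segments.

All TSVs are written with a fixed float format and explicit column order so
that identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "interval_to_bed",
    "bed_to_interval",
    "write_table",
    "read_table",
    "write_results",
]

FLOAT_FORMAT = "%.10g"


def interval_to_bed(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [start-1, end)."""
    if start_1based < 1 or end_1based < start_1based:
        raise ValueError(f"bad 1-based interval [{start_1based}, {end_1based}]")
    return start_1based - 1, end_1based


def bed_to_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    """Inverse of :func:`interval_to_bed`."""
    if bed_start < 0 or bed_end <= bed_start:
        raise ValueError(f"bad BED interval [{bed_start}, {bed_end})")
    return bed_start + 1, bed_end


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
                 lineterminator="\n", na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  segments: pd.DataFrame | None = None) -> list[Path]:
    """Write every named table as ``<name>.tsv``; a segment table additionally
    yields ``segments.bed`` (chrom, 0-based start, half-open end, alias).

    Empty tables produce headers-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        path = out_dir / f"{name}.tsv"
        write_table(frame, path)
        written.append(path)
    if segments is not None:
        path = out_dir / "segments.bed"
        with open(path, "w") as fh:
            for row in segments.itertuples():
                b0, b1 = interval_to_bed(int(row.span_start), int(row.span_end))
                fh.write(f"{row.chrom}\t{b0}\t{b1}\t{row.alias}\n")
        written.append(path)
    return written
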