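"""AGP v2.0 assembly-structure parsing, validation and writing.

An AGP file describes how each assembled object (here: a chromosome) tiles
into ordered contig and gap components. Component types W/A/D/F/G/O/P are
sequence contigs; N and U are gaps. Object coordinates are 1-based inclusive
and must tile [1..L] without holes or overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from ..errors import FormatError
from ..types import chrom_sort_key

__all__ = ["AGPComponent", "read_agp", "write_agp", "components_by_object"]

_CONTIG_CODES = set("WADFGOP")
_GAP_CODES = set("NU")


@dataclass(frozen=True)
class AGPComponent:
    """One line of an AGP file, normalised to contig/gap semantics."""

    object_id: str
    object_beg: int
    object_end: int
    part_number: int
    component_type: str  # "contig" | "gap"
    component_id: str | None = None  # contigs only
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.object_beg > self.object_end:
            raise FormatError(
                f"{self.object_id} part {self.part_number}: "
                f"object_beg {self.object_beg} > object_end {self.object_end}"
            )
        if self.component_type not in ("contig", "gap"):
            raise FormatError(f"bad component_type {self.component_type!r}")
        if self.component_type == "contig" and not self.component_id:
            raise FormatError("contig component without a component_id")

    @property
    def length(self) -> int:
        return self.object_end - self.object_beg + 1

    def contains(self, pos: int) -> bool:
        return self.object_beg <= pos <= self.object_end

    @property
    def is_gap(self) -> bool:
        return self.component_type == "gap"


def read_agp(agp_path) -> list[AGPComponent]:
    """Parse and validate an AGP v2.0 file; raises FormatError on bad tiling."""
    components: list[AGPComponent] = []
    with open(Path(agp_path)) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{agp_path}:{ln}: expected >= 6 tab columns")
            obj, beg, end, part, ctype = fields[:5]
            try:
                beg, end, part = int(beg), int(end), int(part)
            except ValueError as exc:
                raise FormatError(f"{agp_path}:{ln}: non-integer coordinate") from exc
            if ctype in _CONTIG_CODES:
                comp = AGPComponent(
                    obj, beg, end, part, "contig",
                    component_id=fields[5],
                    orientation=fields[8] if len(fields) > 8 else "+",
                )
            elif ctype in _GAP_CODES:
                comp = AGPComponent(obj, beg, end, part, "gap")
            else:
                raise FormatError(f"{agp_path}:{ln}: unknown component type {ctype!r}")
            components.append(comp)
    validate_tiling(components, source=str(agp_path))
    return components


def components_by_object(components) -> dict[str, list[AGPComponent]]:
    by_obj: dict[str, list[AGPComponent]] = {}
    for comp in components:
        by_obj.setdefault(comp.object_id, []).append(comp)
    for comps in by_obj.values():
        comps.sort(key=lambda c: c.part_number)
    return by_obj


def validate_tiling(components, source: str = "AGP") -> None:
    """Every object must tile [1..L] contiguously in part-number order."""
    for obj, comps in components_by_object(components).items():
        expect = 1
        for comp in comps:
            if comp.object_beg != expect:
                raise FormatError(
                    f"{source}: object {obj} part {comp.part_number} starts at "
                    f"{comp.object_beg}, expected {expect} (holes/overlaps)"
                )
            expect = comp.object_end + 1


def write_agp(components, path) -> None:
    """Write components as AGP v2.0 (contigs as W, gaps as N/scaffold)."""
    validate_tiling(components, source="write_agp input")
    by_obj = components_by_object(components)
    with open(Path(path), "w") as fh:
        fh.write("##agp-version	2.0\n")
        for obj in sorted(by_obj, key=chrom_sort_key):
            for c in by_obj[obj]:
                if c.is_gap:
                    fh.write(
                        f"{obj}\t{c.object_beg}\t{c.object_end}\t{c.part_number}"
                        f"\tN\t{c.length}\tscaffold\tyes\tpaired-ends\n"
                    )
                else:
                    fh.write(
                        f"{obj}\t{c.object_beg}\t{c.object_end}\t{c.part_number}"
                        f"\tW\t{c.component_id}\t1\t{c.length}\t{c.orientation}\n"
                    )
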