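"""Two-population genotype simulator with planted map corruption.

The generator emulates the study design the detector is built for: two
genetically divergent populations genotyped on a shared SNP panel over an
AGP-structured reference, with LD that decays with true physical distance.
Haplotypes are mosaics of a small founder pool (Li-Stephens-style copying
with switch probability 1 - exp(-rate * distance) between adjacent markers);
founders themselves carry distance-decaying allelic correlation from a
thresholded Gaussian AR(1) process, so population LD decays smoothly from
high values between close markers to a low between-founder background. This
is an LD emulation with direct control of the decay scale, not a demographic
model.

Corruption edits only the *reported* marker map and AGP - genotypes always
reflect true positions - and every affected marker is recorded in a truth
table, so detection, signature classification and relocation can all be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import MismapError
from .io.agp import AGPComponent, write_agp
from .io.plink import write_plink
from .io.tables import write_table
from .io.vcf import write_vcf
from .types import GenotypePanel, MarkerRecord, chrom_sort_key

__all__ = [
    "SimConfig",
    "PlantedEvent",
    "SimCohort",
    "simulate_haplotypes",
    "simulate_population",
    "plant_misassembly",
    "default_event_plan",
    "simulate_cohort",
    "make_fixture_suite",
]

POPULATIONS = ("A", "B")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults describe the desk-scale stand-in for a two-breed HD-array
    cohort: 2 chromosomes of 20 Mb carrying 1000 markers each (~19 kb
    spacing), 200 diploid samples per population, founder pools of 30
    haplotypes half-shared between populations, and a copying/correlation
    rate giving r2 ~ 0.5 at a few hundred kb and background beyond ~5 Mb.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 20_000_000
    n_markers_per_chrom: int = 1000
    n_founder_haplotypes: int = 200
    divergence: float = 0.5  # fraction of founders shared between populations
    copying_switch_rate: float = 2e-7  # per bp; also the founder AR(1) decay rate
    maf_floor: float = 0.05
    missing_rate: float = 0.002
    n_samples: int = 200  # per population
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length_bp, self.n_markers_per_chrom,
               self.n_founder_haplotypes, self.n_samples) <= 0:
            raise ValueError("size parameters must be positive")
        for name in ("divergence", "maf_floor", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.copying_switch_rate < 0:
            raise ValueError("copying_switch_rate must be >= 0")


@dataclass
class PlantedEvent:
    """One deliberate corruption of the reported map.

    ``source_*`` is the true location of the affected markers, ``dest_*``
    the wrong location the corrupted map reports. ``source_parts`` (for
    move_segment) and ``dest_component`` / ``source_component`` identify the
    AGP machinery involved.
    """

    event_type: str  # move_segment | move_snp | partial_shuffle
    source_chrom: str
    source_start: int
    source_end: int
    dest_chrom: str
    marker_ids: list[str]
    dest_start: int | None = None
    dest_end: int | None = None
    source_parts: tuple[int, int] | None = None  # move_segment: part range
    dest_after_part: int | None = None  # move_segment: insert after this part
    source_component: str | None = None  # partial_shuffle
    dest_component: str | None = None  # move_snp / partial_shuffle
    dest_offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.event_type not in ("move_segment", "move_snp", "partial_shuffle"):
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.marker_ids:
            raise ValueError("event with no affected markers")
        if (
            self.dest_chrom == self.source_chrom
            and self.dest_start is not None
            and not (self.dest_end < self.source_start or self.dest_start > self.source_end)
        ):
            raise ValueError("source and destination intervals must be disjoint")


@dataclass
class Assembly:
    """True assembly: tiling, marker map and each marker's home contig."""

    components: list[AGPComponent]
    markers: list[MarkerRecord]
    marker_home: dict[str, tuple[str, int]]  # marker_id -> (component_id, offset)
    reserved_contigs: list[str]  # deliberately marker-free contigs


@dataclass
class SimCohort:
    """Everything a pipeline run (and its scoring) needs."""

    config: SimConfig
    assembly: Assembly
    markers_reported: list[MarkerRecord]
    agp_reported: list[AGPComponent]
    events: list[PlantedEvent]
    truth: pd.DataFrame
    dosages: dict[str, np.ndarray]  # population -> samples x markers (true order)
    kept: dict[str, np.ndarray]  # population -> kept marker indices (MAF floor)

    def panel(self, population: str, which: str = "reported") -> GenotypePanel:
        """Genotype panel for one population under the reported or true map."""
        if which == "reported":
            source = {m.marker_id: m for m in self.markers_reported}
        elif which == "true":
            source = {m.marker_id: m for m in self.assembly.markers}
        else:
            raise ValueError("which must be 'reported' or 'true'")
        idx = self.kept[population]
        records = [source[self.assembly.markers[j].marker_id] for j in idx]
        sample_ids = [f"{population}{i:04d}" for i in range(self.config.n_samples)]
        return GenotypePanel(sample_ids, records, self.dosages[population][:, idx])


# --------------------------------------------------------------------------
# assembly construction
# --------------------------------------------------------------------------

def _build_assembly(cfg: SimConfig, rng: np.random.Generator) -> Assembly:
    components: list[AGPComponent] = []
    markers: list[MarkerRecord] = []
    marker_home: dict[str, tuple[str, int]] = {}
    reserved: list[str] = []
    for c in range(1, cfg.n_chromosomes + 1):
        chrom = str(c)
        parts: list[tuple[str, int, str | None]] = []  # (kind, length, comp_id)
        pos = 0
        ci = 0
        while pos < cfg.chrom_length_bp:
            ci += 1
            if ci % 8 == 0:  # short, deliberately marker-free contig
                length = int(rng.integers(5_000, 15_000))
                comp_id = f"ctg{chrom}.{ci}"
                reserved.append(comp_id)
            else:
                length = int(rng.integers(60_000, 200_000))
                comp_id = f"ctg{chrom}.{ci}"
            length = min(length, cfg.chrom_length_bp - pos)
            parts.append(("contig", length, comp_id))
            pos += length
            if pos >= cfg.chrom_length_bp:
                break
            gap = int(min(rng.integers(500, 5_000), cfg.chrom_length_bp - pos))
            parts.append(("gap", gap, None))
            pos += gap
        beg = 1
        for pn, (kind, length, comp_id) in enumerate(parts, start=1):
            components.append(
                AGPComponent(chrom, beg, beg + length - 1, pn, kind, comp_id)
            )
            beg += length

        # markers on a jittered grid over the usable (non-reserved) contig space
        usable = [
            comp
            for comp in components
            if comp.object_id == chrom
            and not comp.is_gap
            and comp.component_id not in reserved
        ]
        total = sum(comp.length for comp in usable)
        spacing = total / cfg.n_markers_per_chrom
        cum = np.concatenate([[0], np.cumsum([comp.length for comp in usable])])
        taken: set[int] = set()
        for i in range(cfg.n_markers_per_chrom):
            x = (i + 0.5 + float(rng.uniform(-0.3, 0.3))) * spacing
            x = min(max(x, 0.0), total - 1.0)
            k = int(np.searchsorted(cum, x, side="right")) - 1
            comp = usable[k]
            offset = int(x - cum[k])
            gpos = comp.object_beg + offset
            while gpos in taken:  # keep positions unique
                gpos += 1
                offset += 1
            taken.add(gpos)
            mid = f"snp_{chrom}_{i:05d}"
            markers.append(MarkerRecord(mid, chrom, gpos, "C", "A"))
            marker_home[mid] = (comp.component_id, offset)
    markers.sort(key=lambda m: (chrom_sort_key(m.chrom), m.pos_bp, m.marker_id))
    return Assembly(components, markers, marker_home, reserved)


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def simulate_haplotypes(
    cfg: SimConfig, markers: list[MarkerRecord], seed_seq: np.random.SeedSequence
) -> dict[str, np.ndarray]:
    """Founder pool plus copied sample haplotypes for both populations.

    Returns ``{"founders": (F, M), "A": (2n, M), "B": (2n, M)}`` over the
    markers in map order; founder pools of the two populations overlap by
    ``round(divergence * n_founder_haplotypes)`` founders.
    """
    rng = np.random.default_rng(seed_seq)
    K = cfg.n_founder_haplotypes
    shared = int(round(cfg.divergence * K))
    total = 2 * K - shared
    M = len(markers)
    founders = np.empty((total, M), dtype=np.int8)
    positions = np.array([m.pos_bp for m in markers])
    chroms = np.array([m.chrom for m in markers], dtype=object)

    for chrom in dict.fromkeys(chroms):  # preserves map order
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        m = idx.size
        # Founder latents follow an AR(1) along the map; the per-marker allele
        # frequency follows its own AR(1) so that markers in strong LD also
        # have matched frequencies (real LD blocks contain near-duplicate
        # "tag SNP" pairs; independent frequencies would cap attainable r2).
        z = np.empty((total, m))
        u = np.empty(m)
        z[:, 0] = rng.standard_normal(total)
        u[0] = rng.standard_normal()
        for j in range(1, m):
            a = np.exp(-cfg.copying_switch_rate * (pos[j] - pos[j - 1]))
            z[:, j] = a * z[:, j - 1] + np.sqrt(1 - a * a) * rng.standard_normal(total)
            u[j] = a * u[j - 1] + np.sqrt(1 - a * a) * rng.standard_normal()
        # Marginally uniform on (0.2, 0.8): SNP arrays are ascertained for
        # common variants, and a tighter range keeps regional frequency
        # drift from parking whole blocks below the MAF floor.
        q = 0.2 + 0.6 * norm.cdf(u)
        founders[:, idx] = (z < norm.ppf(q)).astype(np.int8)

    pools = {"A": np.arange(K), "B": np.arange(K - shared, total)}
    out: dict[str, np.ndarray] = {"founders": founders}
    for pop in POPULATIONS:
        pool = pools[pop]
        H = 2 * cfg.n_samples
        haps = np.empty((H, M), dtype=np.int8)
        for chrom in dict.fromkeys(chroms):
            idx = np.flatnonzero(chroms == chrom)
            pos = positions[idx]
            cur = pool[rng.integers(pool.size, size=H)]
            haps[:, idx[0]] = founders[cur, idx[0]]
            for j in range(1, idx.size):
                p_switch = 1.0 - np.exp(
                    -cfg.copying_switch_rate * (pos[j] - pos[j - 1])
                )
                sw = rng.random(H) < p_switch
                if sw.any():
                    cur[sw] = pool[rng.integers(pool.size, size=int(sw.sum()))]
                haps[:, idx[j]] = founders[cur, idx[j]]
        out[pop] = haps
    return out


def simulate_population(
    cfg: SimConfig, haps: np.ndarray, seed_seq: np.random.SeedSequence
) -> tuple[np.ndarray, np.ndarray]:
    """Diploid dosages with missingness, plus the kept-marker index (MAF floor).

    Dosage = sum of two consecutive haplotypes; missing calls are i.i.d.;
    markers whose realised MAF (over non-missing calls) falls below
    ``maf_floor`` are dropped from the emitted panel.
    """
    rng = np.random.default_rng(seed_seq)
    dos = (haps[0::2, :] + haps[1::2, :]).astype(np.float64)
    if cfg.missing_rate > 0:
        dos[rng.random(dos.shape) < cfg.missing_rate] = np.nan
    n_obs = np.isfinite(dos).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * n_obs)
    maf = np.where(n_obs > 0, np.minimum(p, 1 - p), 0.0)
    kept = np.flatnonzero(maf >= cfg.maf_floor)
    return dos, kept


# --------------------------------------------------------------------------
# planting corruption
# --------------------------------------------------------------------------

def _check_disjoint(events: list[PlantedEvent]) -> None:
    seen_markers: set[str] = set()
    seen_components: set[str] = set()
    for ev in events:
        comps = set(
            filter(None, [ev.source_component, ev.dest_component])
        )
        if ev.event_type == "move_segment":
            comps.add(f"__run__{ev.source_chrom}:{ev.source_parts}")
        if seen_markers & set(ev.marker_ids) or seen_components & comps:
            raise MismapError("planted events overlap in markers or components")
        seen_markers |= set(ev.marker_ids)
        seen_components |= comps


def plant_misassembly(
    assembly: Assembly, events: list[PlantedEvent]
) -> tuple[list[MarkerRecord], list[AGPComponent], pd.DataFrame]:
    """Apply planted events to produce the corrupted (reported) map and AGP.

    Genotypes are never touched: LD keeps reflecting true positions. Returns
    the reported marker map (same ids/order as the true map), the reported
    AGP, and a truth table of every affected marker.
    """
    _check_disjoint(events)
    # mutable per-chromosome part model: (kind, length, component_id)
    model: dict[str, list[list]] = {}
    for comp in assembly.components:
        model.setdefault(comp.object_id, []).append(
            [comp.component_type, comp.length, comp.component_id]
        )
    home = dict(assembly.marker_home)

    for ev in events:
        if ev.event_type == "move_segment":
            p_lo, p_hi = ev.source_parts
            src = model[ev.source_chrom]
            run = src[p_lo - 1 : p_hi]
            run_len = sum(part[1] for part in run)
            src[p_lo - 1 : p_hi] = [["gap", run_len, None]]
            dst = model[ev.dest_chrom]
            dst[ev.dest_after_part : ev.dest_after_part] = run
        elif ev.event_type == "move_snp":
            home[ev.marker_ids[0]] = (ev.dest_component, ev.dest_offsets[0])
        elif ev.event_type == "partial_shuffle":
            for mid, off in zip(ev.marker_ids, ev.dest_offsets):
                home[mid] = (ev.dest_component, off)

    # recompute absolute coordinates
    agp_reported: list[AGPComponent] = []
    comp_beg: dict[str, int] = {}
    comp_chrom: dict[str, str] = {}
    for chrom in sorted(model, key=chrom_sort_key):
        beg = 1
        for pn, (kind, length, comp_id) in enumerate(model[chrom], start=1):
            agp_reported.append(
                AGPComponent(chrom, beg, beg + length - 1, pn, kind, comp_id)
            )
            if comp_id is not None:
                comp_beg[comp_id] = beg
                comp_chrom[comp_id] = chrom
            beg += length

    reported: list[MarkerRecord] = []
    for rec in assembly.markers:
        comp_id, offset = home[rec.marker_id]
        reported.append(
            replace(rec, chrom=comp_chrom[comp_id], pos_bp=comp_beg[comp_id] + offset)
        )
    rep_by_id = {m.marker_id: m for m in reported}

    rows = []
    for ev in events:
        affected = [rep_by_id[mid] for mid in ev.marker_ids]
        ev.dest_start = min(m.pos_bp for m in affected)
        ev.dest_end = max(m.pos_bp for m in affected)
        true_by_id = {m.marker_id: m for m in assembly.markers}
        for mid in ev.marker_ids:
            rows.append(
                {
                    "marker_id": mid,
                    "event_type": ev.event_type,
                    "true_chrom": true_by_id[mid].chrom,
                    "true_pos_bp": true_by_id[mid].pos_bp,
                    "reported_chrom": rep_by_id[mid].chrom,
                    "reported_pos_bp": rep_by_id[mid].pos_bp,
                    "source_start": ev.source_start,
                    "source_end": ev.source_end,
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "marker_id", "event_type", "true_chrom", "true_pos_bp",
            "reported_chrom", "reported_pos_bp", "source_start", "source_end",
        ],
    )
    return reported, agp_reported, truth


# --------------------------------------------------------------------------
# default event plan: one event of each signature class
# --------------------------------------------------------------------------

def _contig_marker_counts(assembly: Assembly) -> dict[str, list[MarkerRecord]]:
    by_comp: dict[str, list[MarkerRecord]] = {}
    for rec in assembly.markers:
        comp_id, _ = assembly.marker_home[rec.marker_id]
        by_comp.setdefault(comp_id, []).append(rec)
    return by_comp


def default_event_plan(
    assembly: Assembly, rng: np.random.Generator, cfg: SimConfig
) -> list[PlantedEvent]:
    """One move_segment (chr1->chr2), one move_snp (chr2->chr1 reserved
    contig) and one partial_shuffle (chr1 contig -> chr2 contig), placed in
    disjoint regions away from chromosome ends."""
    try:
        return _default_event_plan(assembly, rng, cfg)
    except StopIteration:
        raise MismapError(
            "could not place the default planted events at this configuration; "
            "use explicit events or a larger/denser genome"
        ) from None


def _default_event_plan(
    assembly: Assembly, rng: np.random.Generator, cfg: SimConfig
) -> list[PlantedEvent]:
    L = cfg.chrom_length_bp
    comps = {
        chrom: [c for c in assembly.components if c.object_id == chrom]
        for chrom in ("1", "2")
    }
    by_comp = _contig_marker_counts(assembly)
    used_components: set[str] = set()
    used_markers: set[str] = set()
    events: list[PlantedEvent] = []

    def contig_ok(c: AGPComponent) -> bool:
        return not c.is_gap and c.component_id not in used_components

    # --- move_segment: a run of contigs+gaps with 8-12 markers, chr1 -> chr2
    c1 = comps["1"]
    run = None
    for start in rng.permutation(len(c1)):
        comp = c1[start]
        if comp.is_gap or not (0.15 * L < comp.object_beg < 0.45 * L):
            continue
        n_mark = 0
        end = start
        while end < len(c1) and n_mark < 6:
            part = c1[end]
            if not part.is_gap:
                if part.component_id in assembly.reserved_contigs:
                    break
                n_mark += len(by_comp.get(part.component_id, []))
            end += 1
        if 6 <= n_mark <= 10 and end <= len(c1) and not c1[end - 1].is_gap:
            run = (start, end - 1, n_mark)
            break
    if run is None:
        raise MismapError("could not place a move_segment event; adjust config")
    start, end, _ = run
    run_comps = c1[start : end + 1]
    seg_markers = [
        m.marker_id
        for part in run_comps
        if not part.is_gap
        for m in by_comp.get(part.component_id, [])
    ]
    for part in run_comps:
        if not part.is_gap:
            used_components.add(part.component_id)
    used_markers |= set(seg_markers)
    c2 = comps["2"]
    dest_after = next(
        c
        for c in c2
        if not c.is_gap and c.object_end > 0.55 * L and c.object_end < 0.85 * L
    )
    events.append(
        PlantedEvent(
            event_type="move_segment",
            source_chrom="1",
            source_start=run_comps[0].object_beg,
            source_end=run_comps[-1].object_end,
            dest_chrom="2",
            marker_ids=sorted(seg_markers),
            source_parts=(run_comps[0].part_number, run_comps[-1].part_number),
            dest_after_part=dest_after.part_number,
        )
    )
    used_components.add(dest_after.component_id)

    # --- move_snp: one chr2 marker -> a marker-free contig on chr1
    snp = next(
        m
        for m in assembly.markers
        if m.chrom == "2"
        and 0.10 * L < m.pos_bp < 0.35 * L
        and m.marker_id not in used_markers
    )
    dest_free = next(
        c
        for c in comps["1"]
        if not c.is_gap
        and c.component_id in assembly.reserved_contigs
        and 0.55 * L < c.object_beg < 0.90 * L
        and contig_ok(c)
    )
    events.append(
        PlantedEvent(
            event_type="move_snp",
            source_chrom="2",
            source_start=snp.pos_bp,
            source_end=snp.pos_bp,
            dest_chrom="1",
            marker_ids=[snp.marker_id],
            dest_component=dest_free.component_id,
            dest_offsets=[dest_free.length // 2],
        )
    )
    used_components.add(dest_free.component_id)
    used_markers.add(snp.marker_id)

    # --- partial_shuffle: half of a chr1 contig's markers -> a chr2 contig
    src_contig = next(
        c
        for c in comps["1"]
        if not c.is_gap
        and contig_ok(c)
        and 0.60 * L < c.object_beg < 0.90 * L
        and len(by_comp.get(c.component_id, [])) >= 6
    )
    src_marks = sorted(
        by_comp[src_contig.component_id], key=lambda m: m.pos_bp
    )
    moved = src_marks[: len(src_marks) // 2]
    dest_contig = next(
        c
        for c in comps["2"]
        if not c.is_gap
        and contig_ok(c)
        and 0.10 * L < c.object_beg < 0.40 * L
        and len(by_comp.get(c.component_id, [])) >= 2
        and not any(m.marker_id in used_markers for m in by_comp[c.component_id])
    )
    native_offsets = {
        assembly.marker_home[m.marker_id][1] for m in by_comp[dest_contig.component_id]
    }
    offsets: list[int] = []
    while len(offsets) < len(moved):
        off = int(rng.integers(0, dest_contig.length))
        if off not in native_offsets and off not in offsets:
            offsets.append(off)
    offsets.sort()
    events.append(
        PlantedEvent(
            event_type="partial_shuffle",
            source_chrom="1",
            source_start=moved[0].pos_bp,
            source_end=moved[-1].pos_bp,
            dest_chrom="2",
            marker_ids=[m.marker_id for m in moved],
            source_component=src_contig.component_id,
            dest_component=dest_contig.component_id,
            dest_offsets=offsets,
        )
    )
    return events


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig, events: list[PlantedEvent] | None = None,
                    plant: bool = True) -> SimCohort:
    """Simulate both populations and (optionally) plant one event of each type.

    Fully deterministic under ``cfg.seed``: assembly layout, founder pool,
    copying paths, missingness and event placement all derive from it.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_asm, s_hap, s_missA, s_missB, s_events = ss.spawn(5)
    assembly = _build_assembly(cfg, np.random.default_rng(s_asm))
    haps = simulate_haplotypes(cfg, assembly.markers, s_hap)
    dosages: dict[str, np.ndarray] = {}
    kept: dict[str, np.ndarray] = {}
    for pop, s_miss in zip(POPULATIONS, (s_missA, s_missB)):
        dosages[pop], kept[pop] = simulate_population(cfg, haps[pop], s_miss)
    if plant and events is None:
        events = default_event_plan(assembly, np.random.default_rng(s_events), cfg)
    elif not plant:
        events = []
    reported, agp_reported, truth = plant_misassembly(assembly, events)
    return SimCohort(
        config=cfg,
        assembly=assembly,
        markers_reported=reported,
        agp_reported=agp_reported,
        events=events,
        truth=truth,
        dosages=dosages,
        kept=kept,
    )


def make_fixture_suite(out_dir, seed: int, cfg: SimConfig | None = None) -> SimCohort:
    """Write a complete on-disk fixture: PLINK + VCF per population, reported
    AGP, truth table and event metadata; one planted event of each type."""
    cfg = replace(cfg or SimConfig(), seed=seed)
    cohort = simulate_cohort(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pop in POPULATIONS:
        panel = cohort.panel(pop, "reported")
        write_plink(panel, out / f"pop{pop}")
        write_vcf(panel, out / f"pop{pop}.vcf")
    write_agp(cohort.agp_reported, out / "assembly.agp")
    write_table(cohort.truth, out / "truth.tsv")
    true_map = pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in cohort.assembly.markers],
            "chrom": [m.chrom for m in cohort.assembly.markers],
            "pos_bp": [m.pos_bp for m in cohort.assembly.markers],
        }
    )
    write_table(true_map, out / "true_map.tsv")
    with open(out / "events.json", "w") as fh:
        json.dump(
            [
                {
                    "event_type": ev.event_type,
                    "source_chrom": ev.source_chrom,
                    "source_start": ev.source_start,
                    "source_end": ev.source_end,
                    "dest_chrom": ev.dest_chrom,
                    "dest_start": ev.dest_start,
                    "dest_end": ev.dest_end,
                    "n_markers": len(ev.marker_ids),
                    "marker_ids": ev.marker_ids,
                }
                for ev in cohort.events
            ],
            fh,
            indent=2,
        )
    return cohort
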