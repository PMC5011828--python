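"""End-to-end orchestration: QC -> scan/detect -> segments -> relocate -> report.

Every run writes, per population, the QC report, the CMM table, the segment
table (+ BED track), the relocation table and a corrected marker map, then a
cross-population consensus table and a JSON manifest with every parameter,
so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .detect import cmm_table, consensus_across_populations, detect_all
from .errors import MismapError
from .io.agp import read_agp
from .io.plink import read_plink
from .io.tables import write_results, write_table
from .io.vcf import read_vcf
from .ld import all_tag_sets
from .qc import apply_qc
from .relocate import apply_relocation, estimate_location, relocation_table
from .segments import (
    assign_contigs,
    classify_signature,
    genome_error_summary,
    merge_adjacent,
    segment_table,
)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "summarize"]


def _load_panel(pop):
    if pop.vcf:
        return read_vcf(pop.vcf)
    return read_plink(
        pop.plink_prefix + ".bed", pop.plink_prefix + ".bim", pop.plink_prefix + ".fam"
    )


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MismapError:
                raise
            except Exception as exc:  # annotate unexpected failures with the stage
                raise MismapError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages for every population and write all artifacts.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    agp = read_agp(config.agp_path)
    manifest: dict = {
        "tool": "mismap",
        "version": __version__,
        "agp_path": str(config.agp_path),
        "relocation_seed": config.relocation_seed,
        "qc": config.qc.__dict__,
        "detection": config.detection.__dict__,
        "signature": config.signature.__dict__,
        "populations": {},
    }
    results_by_pop: dict[str, list] = {}
    for pop in config.populations:
        results_by_pop[pop.label] = _run_population(
            pop, agp, config, out_dir / pop.label, manifest
        )
    if len(config.populations) >= 2:
        a, b = config.populations[0].label, config.populations[1].label
        consensus = consensus_across_populations(results_by_pop[a], results_by_pop[b])
        write_table(consensus, out_dir / f"consensus_{a}_{b}.tsv")
        manifest["consensus"] = {
            "populations": [a, b],
            "counts": consensus["status"].value_counts().to_dict(),
        }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_population(pop, agp, config: RunConfig, pop_dir: Path, manifest: dict):
    log.info("population %s: loading genotypes", pop.label)
    panel = _stage("load")(_load_panel)(pop)
    if config.chromosomes is not None:
        allowed = set(config.chromosomes)
        keep = [i for i, m in enumerate(panel.markers) if m.chrom in allowed]
        panel = panel.subset_markers(keep)
    log.info("population %s: QC on %d samples x %d markers",
             pop.label, panel.n_samples, panel.n_markers)
    panel, report = _stage("qc")(apply_qc)(panel, config.qc)
    log.info("population %s: %s", pop.label, report.summary())

    det = config.detection
    tag_sets = _stage("ld_scan")(all_tag_sets)(
        panel, threshold=det.r2_tag_threshold,
        min_complete=det.min_complete_pairs, chunk_size=det.chunk_size,
    )
    results = _stage("detect")(detect_all)(panel, det, tag_sets=tag_sets)
    n_cmm = sum(r.is_cmm for r in results)
    log.info("population %s: %d CMMs among %d markers", pop.label, n_cmm, len(results))

    cmcs, gap_diag = _stage("segments")(assign_contigs)(results, agp)
    segments = _stage("segments")(merge_adjacent)(cmcs, agp, results)
    for seg in segments:
        seg.signature = classify_signature(seg, panel, config.signature)
        seg.populations_detected.add(pop.label)

    tag_dict = {t.focal_id: t for t in tag_sets}
    estimates = []
    corrected = list(panel.markers)
    audits = []
    for seg in segments:
        est = _stage("relocate")(estimate_location)(seg, tag_dict, pop.label)
        estimates.append(est)
        if est.status != "ok":
            continue
        try:
            corrected, audit = apply_relocation(
                corrected, seg, est, seed=config.relocation_seed
            )
            audits.append(audit)
        except MismapError as exc:
            est.status = f"not_applied: {exc}"

    seg_df = segment_table(segments)
    summary = genome_error_summary(segments, agp)
    corrected_df = pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in corrected],
            "chrom": [m.chrom for m in corrected],
            "pos_bp": [m.pos_bp for m in corrected],
            "orig_chrom": [m.chrom for m in panel.markers],
            "orig_pos_bp": [m.pos_bp for m in panel.markers],
        }
    )
    tables = {
        "qc_markers": report.marker_table,
        "qc_samples": report.sample_table,
        "cmm": cmm_table(results),
        "segments": seg_df,
        "relocations": relocation_table(estimates),
        "corrected_map": corrected_df,
        "gap_diagnostics": pd.DataFrame(
            gap_diag, columns=["marker_id", "chrom", "pos_bp", "issue", "part_number"]
        ),
        "chrom_summary": summary["per_chrom"],
    }
    write_results(tables, pop_dir, segments=seg_df)
    manifest["populations"][pop.label] = {
        "qc": report.counts,
        "n_cmm": int(n_cmm),
        "n_cmc": len(cmcs),
        "n_segments": len(segments),
        "signatures": seg_df["signature"].value_counts().to_dict(),
        "misassembled_fraction": summary["global_fraction"],
    }
    return results


def summarize(out_dir) -> str:
    """Human-readable run summary recomputed from the written tables."""
    out_dir = Path(out_dir)
    with open(out_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    lines = [f"mismap {manifest['version']} run summary"]
    for label, info in manifest["populations"].items():
        lines.append(f"\npopulation {label}:")
        lines.append(f"  QC: {info['qc']['samples_out']}/{info['qc']['samples_in']} "
                     f"samples, {info['qc']['markers_out']}/{info['qc']['markers_in']} markers kept")
        cmm = pd.read_csv(out_dir / label / "cmm.tsv", sep="\t")
        per_chrom = cmm[cmm["is_cmm"]].groupby("chrom").size()
        lines.append(f"  CMMs: {info['n_cmm']} "
                     f"({', '.join(f'chr{c}: {n}' for c, n in per_chrom.items())})")
        segs = pd.read_csv(out_dir / label / "segments.tsv", sep="\t")
        n = len(segs)
        if n:
            parts = []
            for sig_name, k in segs["signature"].value_counts().items():
                parts.append(f"{sig_name}: {k} ({100.0 * k / n:.2f} %)")
            lines.append(f"  segments: {n} ({'; '.join(parts)})")
            lines.append(
                f"  segment span: median {int(segs.eval('span_end-span_start+1').median())} bp, "
                f"max {int(segs.eval('span_end-span_start+1').max())} bp"
            )
        else:
            lines.append("  segments: 0")
        lines.append(
            f"  misassembled genome fraction: {100.0 * info['misassembled_fraction']:.4f} %"
        )
    if "consensus" in manifest:
        c = manifest["consensus"]
        counts = ", ".join(f"{k}: {v}" for k, v in sorted(c["counts"].items()))
        lines.append(f"\nconsensus ({' vs '.join(c['populations'])}): {counts}")
    return "\n".join(lines)
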