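"""End-to-end pipeline: detect → PSI → differential test → characterize.

One :func:`run_pipeline` call takes a cohort on disk (reference FASTA, GTF,
sample sheet pointing at per-sample junction tables) and writes the full
report bundle: events, PSI matrix, differential results, significant
events, event-type summary, cryptic-distance histogram, canonical and
cryptic acceptor motif matrices, per-event site annotations, and a
machine-readable run manifest (effective parameters plus SHA-256 of every
output). Outputs are byte-identical across reruns with the same inputs and
configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .io import (
    GeneModel,
    SampleSheet,
    read_annotation,
    read_fasta,
    read_junction_table,
    read_sample_sheet,
    write_psi_matrix,
)
from .events import (
    AltSpliceEvent,
    a3ss_event,
    a5ss_event,
    build_psi_matrix,
    detect_events,
    events_to_frame,
    exon_skip_event,
    plurality_class,
    summarize_event_types,
)
from .diffsplice import DiffSpliceConfig, differential_test, significant_events
from .sites import (
    BRANCHPOINT_WINDOW,
    PPT_WINDOW,
    SS_WINDOW,
    characterize_events,
    cryptic_distance,
    distance_histogram,
    extract_ss_windows,
    motif_profile,
    window_offsets,
)

logger = logging.getLogger("crypticsplice")

PRESETS = {
    "mouse_kpc": {"delta_psi_min": 0.1, "p_max": 0.01},
    "pan_cancer": {"delta_psi_min": 0.05, "p_max": 1e-10},
}


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for the diagnostic."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Paths, preset and parameters for one pipeline run.

    ``preset`` ('mouse_kpc' or 'pan_cancer') selects the significance
    threshold pair; explicitly set values always win over the preset.
    """

    genome: str
    annotation: str
    sample_sheet: str
    output_dir: str
    dialect: str = "simple_tsv"
    preset: str = "mouse_kpc"
    diff: DiffSpliceConfig = field(default_factory=DiffSpliceConfig)
    ss_window: tuple[int, int] = SS_WINDOW
    ppt_window: tuple[int, int] = PPT_WINDOW
    branchpoint_window: tuple[int, int] = BRANCHPOINT_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise PipelineError("config", f"unknown preset {self.preset!r}")
        self.ss_window = tuple(self.ss_window)
        self.ppt_window = tuple(self.ppt_window)
        self.branchpoint_window = tuple(self.branchpoint_window)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        diff_data = data.pop("diff", {})
        data.update({k: v for k, v in overrides.items() if v is not None})
        preset = data.get("preset", "mouse_kpc")
        if preset not in PRESETS:
            raise PipelineError("config", f"unknown preset {preset!r}")
        diff = DiffSpliceConfig(**{**PRESETS[preset], **diff_data})
        return cls(diff=diff, **data)

    @classmethod
    def for_cohort_dir(
        cls, cohort_dir: str | Path, output_dir: str | Path, preset: str = "mouse_kpc",
        **diff_overrides,
    ) -> "PipelineConfig":
        """Config pointing at a directory written by ``write_cohort``."""
        cohort_dir = Path(cohort_dir)
        diff = DiffSpliceConfig(
            **{**PRESETS.get(preset, PRESETS["mouse_kpc"]), **diff_overrides}
        )
        return cls(
            genome=str(cohort_dir / "genome.fa"),
            annotation=str(cohort_dir / "annotation.gtf"),
            sample_sheet=str(cohort_dir / "sample_sheet.tsv"),
            output_dir=str(output_dir),
            preset=preset,
            diff=diff,
        )


@dataclass
class ReportBundle:
    """In-memory results of one pipeline run, plus output paths."""

    events: list[AltSpliceEvent]
    psi: pd.DataFrame
    totals: pd.DataFrame
    results: pd.DataFrame
    significant_ids: list[str]
    event_type_summary: pd.DataFrame
    site_annotations: pd.DataFrame
    histogram_table: pd.DataFrame
    mode_bin: tuple[int, int] | None
    motif_canonical: pd.DataFrame | None
    motif_cryptic: pd.DataFrame | None
    summary: dict
    paths: dict[str, Path]


def load_cohort_inputs(
    config: PipelineConfig,
) -> tuple[dict, list[GeneModel], SampleSheet, list]:
    try:
        genome = read_fasta(config.genome)
    except (OSError, ValueError) as exc:
        raise PipelineError("load_genome", f"{config.genome}: {exc}") from exc
    try:
        genes = read_annotation(config.annotation)
    except (OSError, ValueError) as exc:
        raise PipelineError("load_annotation", f"{config.annotation}: {exc}") from exc
    try:
        sheet = read_sample_sheet(config.sample_sheet)
    except (OSError, ValueError) as exc:
        raise PipelineError("load_sample_sheet", f"{config.sample_sheet}: {exc}") from exc
    base = Path(config.sample_sheet).parent
    junctions = []
    for s in sheet.samples:
        path = Path(s.path)
        if not path.is_absolute():
            path = base / path
        try:
            junctions.extend(
                read_junction_table(path, dialect=config.dialect, sample_id=s.sample_id)
            )
        except (OSError, ValueError) as exc:
            raise PipelineError("load_junctions", f"{path}: {exc}") from exc
    return genome, genes, sheet, junctions


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and write the report bundle to ``output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, sheet, junctions = load_cohort_inputs(config)

    try:
        events = detect_events(junctions, genes)
        psi_matrix = build_psi_matrix(
            events, junctions, sheet.sample_ids, min_coverage=config.diff.min_coverage
        )
    except ValueError as exc:
        raise PipelineError("detect", str(exc)) from exc

    try:
        results = differential_test(psi_matrix.psi, sheet.groups, config.diff)
        sig_ids = significant_events(results)
    except ValueError as exc:
        raise PipelineError("diffsplice", str(exc)) from exc

    try:
        type_summary = summarize_event_types(events, sig_ids)
        sig_a3ss = [
            e for e in events if e.event_id in set(sig_ids) and e.event_type == "A3SS"
        ]
        annotations = characterize_events(
            sig_a3ss, genome, genes,
            ppt_window=config.ppt_window,
            branchpoint_window=config.branchpoint_window,
        )
        distances = [cryptic_distance(e) for e in sig_a3ss]
        hist = distance_histogram(distances)
        upstream = [e for e in sig_a3ss if cryptic_distance(e) >= 1]
        motif_can = motif_cry = None
        if upstream:
            offs = window_offsets(config.ss_window)
            canonical_seqs = extract_ss_windows(upstream, "canonical", genome, config.ss_window)
            cryptic_seqs = extract_ss_windows(upstream, "cryptic", genome, config.ss_window)
            if canonical_seqs:
                motif_can = motif_profile(list(canonical_seqs.values()), offs).to_frame()
            if cryptic_seqs:
                motif_cry = motif_profile(list(cryptic_seqs.values()), offs).to_frame()
    except ValueError as exc:
        raise PipelineError("characterize", str(exc)) from exc

    summary = {
        "crypticsplice_version": __version__,
        "preset": config.preset,
        "seed": config.seed,
        "n_samples": len(sheet.samples),
        "samples": sheet.sample_ids,
        "n_wt": len(sheet.group_ids("WT")),
        "n_mut": len(sheet.group_ids("MUT")),
        "n_events": len(events),
        "n_tested": int(results["p"].notna().sum()),
        "n_significant": len(sig_ids),
        "event_type_counts": type_summary["n_total"].to_dict(),
        "significant_event_type_counts": type_summary["n_significant"].to_dict(),
        "plurality_significant_class": plurality_class(type_summary),
        "distance_mode_bin": list(hist.mode_bin) if hist.mode_bin else None,
        "mean_ppt_canonical": _nanmean(annotations, "ppt_canonical"),
        "mean_ppt_cryptic": _nanmean(annotations, "ppt_cryptic"),
        "mean_bp_a_canonical": _nanmean(annotations, "bp_a_canonical"),
        "mean_bp_a_cryptic": _nanmean(annotations, "bp_a_cryptic"),
        "nmd_flags": (
            annotations["nmd_flag"].value_counts().to_dict() if len(annotations) else {}
        ),
        "effective_parameters": {
            "diff": asdict(config.diff),
            "ss_window": list(config.ss_window),
            "ppt_window": list(config.ppt_window),
            "branchpoint_window": list(config.branchpoint_window),
            "dialect": config.dialect,
        },
    }

    try:
        paths = _write_bundle(
            outdir, events, psi_matrix, results, sig_ids, type_summary,
            annotations, hist, motif_can, motif_cry, summary,
        )
    except OSError as exc:
        raise PipelineError("write_report", str(exc)) from exc

    logger.info(
        "pipeline done: %d events, %d significant (%s preset)",
        len(events), len(sig_ids), config.preset,
    )
    return ReportBundle(
        events=events,
        psi=psi_matrix.psi,
        totals=psi_matrix.totals,
        results=results,
        significant_ids=sig_ids,
        event_type_summary=type_summary,
        site_annotations=annotations,
        histogram_table=hist.table,
        mode_bin=hist.mode_bin,
        motif_canonical=motif_can,
        motif_cryptic=motif_cry,
        summary=summary,
        paths=paths,
    )


def _nanmean(df: pd.DataFrame, column: str) -> float | None:
    if not len(df) or df[column].dropna().empty:
        return None
    return float(df[column].mean())


def _write_bundle(
    outdir, events, psi_matrix, results, sig_ids, type_summary, annotations,
    hist, motif_can, motif_cry, summary,
) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        paths[name] = path

    emit("events.tsv", lambda p: events_to_frame(events).to_csv(p, sep="\t", na_rep="NA"))
    emit("psi_matrix.tsv", lambda p: write_psi_matrix(psi_matrix.psi, p))
    emit("psi_totals.tsv", lambda p: write_psi_matrix(psi_matrix.totals, p))
    emit(
        "diff_results.tsv",
        lambda p: results.to_csv(p, sep="\t", na_rep="NA", index_label="event_id"),
    )
    emit(
        "significant_events.tsv",
        lambda p: results.loc[sig_ids].to_csv(p, sep="\t", na_rep="NA", index_label="event_id"),
    )
    emit("event_type_summary.tsv", lambda p: type_summary.to_csv(p, sep="\t"))
    emit(
        "distance_histogram.tsv",
        lambda p: hist.table.to_csv(p, sep="\t", index=False),
    )
    emit(
        "site_annotations.tsv",
        lambda p: annotations.to_csv(p, sep="\t", na_rep="NA"),
    )
    if motif_can is not None:
        emit("motif_canonical.tsv", lambda p: motif_can.to_csv(p, sep="\t", na_rep="NA"))
    if motif_cry is not None:
        emit("motif_cryptic.tsv", lambda p: motif_cry.to_csv(p, sep="\t", na_rep="NA"))
    emit("summary.json", lambda p: p.write_text(json.dumps(summary, indent=2) + "\n"))

    manifest = {
        "crypticsplice_version": __version__,
        "parameters": summary["effective_parameters"],
        "seed": summary["seed"],
        "outputs": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(paths.items())
        },
    }
    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["run_manifest.json"] = manifest_path
    return paths


# ---------------------------------------------------------------------------
# events TSV round-trip (for staged CLI use)
# ---------------------------------------------------------------------------


def events_from_frame(
    df: pd.DataFrame, gene_models: Sequence[GeneModel] | None = None
) -> list[AltSpliceEvent]:
    """Rebuild event objects from the events TSV.

    A3SS/A5SS events are fully determined by their coordinates; exon_skip
    events need the annotation to recover their flanking introns and are
    skipped (with a log entry) when ``gene_models`` is not given.
    """
    by_transcript: dict[str, list[GeneModel]] = {}
    for g in gene_models or []:
        by_transcript.setdefault(g.gene_id, []).append(g)
    out: list[AltSpliceEvent] = []
    n_skipped = 0
    for event_id, row in df.iterrows():
        if row["type"] == "A3SS":
            out.append(
                a3ss_event(
                    row["gene_id"], row["chrom"], row["strand"],
                    int(row["shared_site"]), int(row["canonical"]), int(row["alternative"]),
                )
            )
        elif row["type"] == "A5SS":
            out.append(
                a5ss_event(
                    row["gene_id"], row["chrom"], row["strand"],
                    int(row["shared_site"]), int(row["canonical"]), int(row["alternative"]),
                )
            )
        else:
            skipped = (int(row["skipped_exon_start"]), int(row["skipped_exon_end"]))
            rebuilt = None
            for t in by_transcript.get(row["gene_id"], []):
                introns = t.introns
                for i in range(1, len(t.exons) - 1):
                    if t.exons[i] == skipped:
                        rebuilt = exon_skip_event(
                            row["gene_id"], row["chrom"], row["strand"],
                            introns[i - 1], introns[i], skipped,
                        )
                        break
                if rebuilt:
                    break
            if rebuilt:
                out.append(rebuilt)
            else:
                n_skipped += 1
    if n_skipped:
        logger.warning(
            "%d exon_skip events could not be rebuilt without annotation", n_skipped
        )
    return out
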