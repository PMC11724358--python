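"""End-to-end orchestration: screen -> correct -> rescreen -> annotate ->
classify -> write outputs."""

from __future__ import annotations

import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, DEFAULT_CONFIG
from .io_formats import (GenomeStore, RawVariantRecord, read_fasta,
                         read_variant_vcf, write_outputs)
from .mechanism_classifier import (MechanismSummary, chromosome_density,
                                   find_baseline, fit_dual_poisson,
                                   histogram_from_lengths)
from .repeat_filter import repeat_screen_raw, rescreen_corrected
from .signature_annotation import SignatureAnnotation, annotate_variants
from .variant_correction import CorrectedVariant, correct_variant, tally_classes

log = logging.getLogger(__name__)

# worker-process globals (set by the pool initializer)
_W: dict = {}


def _init_worker(ref: GenomeStore, query: GenomeStore, cfg: RunConfig) -> None:
    _W["ref"], _W["query"], _W["cfg"] = ref, query, cfg


def _correct_one(raw: RawVariantRecord) -> CorrectedVariant:
    return correct_variant(raw, _W["ref"], _W["query"], _W["cfg"])


@dataclass
class RunResult:
    raw_records: list[RawVariantRecord]
    raw_repetitive_ids: list[str]
    corrected: list[CorrectedVariant]
    corrected_repetitive_ids: list[str]
    annotations: list[SignatureAnnotation]
    baseline: int
    summary: MechanismSummary
    tallies: dict[str, int]
    class_rows: list[tuple[str, str]] = field(default_factory=list)
    paths: dict = field(default_factory=dict)


def correct_all(records: list[RawVariantRecord], ref: GenomeStore,
                query: GenomeStore, cfg: RunConfig) -> list[CorrectedVariant]:
    """Correct every record; per-variant work is a pure function of
    (record, genomes, config), so worker count never changes the output."""
    if cfg.workers <= 1 or len(records) < 2:
        _init_worker(ref, query, cfg)
        return [_correct_one(r) for r in records]
    with ProcessPoolExecutor(
            max_workers=cfg.workers, initializer=_init_worker,
            initargs=(ref, query, cfg)) as pool:
        chunk = max(1, len(records) // (cfg.workers * 4))
        return list(pool.map(_correct_one, records, chunksize=chunk))


def run_pipeline(ref: GenomeStore | str | Path, query: GenomeStore | str | Path,
                 vcf_path: str | Path | None = None,
                 records: list[RawVariantRecord] | None = None,
                 cfg: RunConfig = DEFAULT_CONFIG,
                 outdir: str | Path | None = None,
                 make_plots: bool = False) -> RunResult:
    """Run the full pipeline and (optionally) write the output bundle."""
    if not isinstance(ref, GenomeStore):
        ref = read_fasta(ref)
    if not isinstance(query, GenomeStore):
        query = read_fasta(query)
    if records is None:
        if vcf_path is None:
            raise ValueError("either vcf_path or records is required")
        records = read_variant_vcf(vcf_path, cfg.min_sv_size)
    log.info("stage ingest: %d raw variants", len(records))

    # first-pass repeat screen on raw calls
    clean_raw: list[RawVariantRecord] = []
    raw_rep_ids: list[str] = []
    for r in records:
        if repeat_screen_raw(r, ref, cfg=cfg).is_repetitive:
            raw_rep_ids.append(r.id)
        else:
            clean_raw.append(r)
    log.info("stage repeat-screen: %d repetitive, %d kept",
             len(raw_rep_ids), len(clean_raw))

    corrected = correct_all(clean_raw, ref, query, cfg)
    log.info("stage correct: %s", tally_classes(corrected, len(raw_rep_ids)))

    kept, rep2 = rescreen_corrected(corrected, ref, query, cfg)
    rep2_ids = [v.id for v in rep2]
    n_repeat = len(raw_rep_ids) + len(rep2_ids)
    tallies = tally_classes(kept, n_repeat)
    log.info("stage rescreen: %s", tallies)

    annotatable = [v for v in kept if v.klass != "EXCEPTION"]
    annotations, baseline = annotate_variants(annotatable, ref, query, cfg)
    log.info("stage annotate: %d annotations, baseline %d bp",
             len(annotations), baseline)

    lengths = [a.hom_len for a in annotations
               if a.variant.klass in ("INS", "DEL")
               and a.mechanism in ("TMEJ", "SSA")]
    hist = histogram_from_lengths(lengths)
    summary = fit_dual_poisson(hist, baseline, cfg)
    summary.chrom_density = chromosome_density(annotations, ref, cfg=cfg)

    class_map = {v.id: v.klass for v in kept}
    for vid in raw_rep_ids + rep2_ids:
        class_map[vid] = "REPEAT"
    class_rows = [(r.id, class_map[r.id]) for r in records]

    result = RunResult(
        raw_records=records, raw_repetitive_ids=raw_rep_ids,
        corrected=corrected, corrected_repetitive_ids=rep2_ids,
        annotations=annotations, baseline=baseline, summary=summary,
        tallies=tallies, class_rows=class_rows,
    )
    if outdir is not None:
        result.paths = write_bundle(result, cfg, outdir, make_plots)
    return result


def write_bundle(result: RunResult, cfg: RunConfig, outdir: str | Path,
                 make_plots: bool = False) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_outputs(result.annotations, result.class_rows,
                          outdir / "variants")
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(result.summary.to_dict(), indent=2))
    paths["summary"] = summary_path
    meta_path = outdir / "run_meta.json"
    meta_path.write_text(json.dumps({
        "version": __version__,
        "config": cfg.to_dict(),
        "tallies": result.tallies,
        "baseline": result.baseline,
    }, indent=2))
    paths["meta"] = meta_path
    if make_plots:
        from .plots import plot_bundle
        paths.update(plot_bundle(result, outdir))
    return paths
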