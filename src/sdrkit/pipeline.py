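"""End-to-end read processing: parse -> correct -> assign -> tally -> QC.

This is thin orchestration over the stage modules; each stage remains
individually callable.  Reads enter as (read_id, barcode_read, payload_read)
triples (or FASTQ pair paths); the result bundles the stripped matrices,
per-cell QC records, correction audit and exclusion counters that jointly
conserve the input read count.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .barcode_schema import BarcodeSchema, Backbone, ReferenceRecord, Whitelist, enumerate_backbones
from .barcode_correction import (
    SAMPLE_BC_WINDOW_EXTRA,
    correct_fixed_bc,
    correct_sample_bc,
)
from .quantify_qc import (
    CellQcRecord,
    CountMatrix,
    ProcessedRead,
    TallyResult,
    assign_target,
    call_cells,
    demux_and_flag_doublets,
    strip_contamination,
    tally_matrices,
)
from .read_parser import (
    ReadRecord,
    Scoring,
    calibrate_score_threshold,
    filter_by_score,
    read_fastq,
    segment_reads,
)

__all__ = ["PipelineConfig", "LibraryResult", "RunResult", "process_library", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    scoring: Scoring = Scoring()
    calibration_reads: int = 10_000
    manual_score_threshold: float | None = None
    min_identity: float = 0.8
    min_assign_len: int = 40
    cell_method: str = "knee"  # or "manual"
    cell_threshold: int | None = None
    purity_min: float = 0.8
    umi_window_extra: int = 0  # reserved; UMI taken as fixed-length slice


@dataclass
class LibraryResult:
    """Corrected, target-assigned reads of one modality plus bookkeeping."""

    processed: list[ProcessedRead]
    payloads: dict[str, str]  # read_id -> payload sequence (target-assigned reads)
    score_threshold: float
    excluded: collections.Counter
    audit: list[dict]


def _read_pairs_from_fastq(r1_path, r2_path):
    for rec1, rec2 in zip(read_fastq(r1_path), read_fastq(r2_path)):
        if rec1.read_id != rec2.read_id:
            raise ValueError(f"unpaired FASTQ records: {rec1.read_id} vs {rec2.read_id}")
        yield rec1.read_id, rec1.sequence, rec2.sequence


def process_library(
    read_pairs: Iterable[tuple[str, str, str]],
    schema: BarcodeSchema,
    whitelists: Mapping[str, Whitelist],
    references: Sequence[ReferenceRecord],
    config: PipelineConfig = PipelineConfig(),
) -> LibraryResult:
    """Parse, score-filter, barcode-correct and target-assign one library.

    The barcode read is segmented against all backbones; the payload read is
    assigned to the custom references.  Barcode corrections are memoised by
    observed string, and an audit row is recorded per corrected segment.
    """
    backbones = enumerate_backbones(schema)
    pairs = list(read_pairs)
    records = [ReadRecord(rid, r1) for rid, r1, _ in pairs]
    payload_by_id = {rid: r2 for rid, _, r2 in pairs}

    segmented, parse_failed = segment_reads(records, backbones, config.scoring)
    excluded: collections.Counter = collections.Counter()
    excluded["parse_fail"] = len(parse_failed)

    if config.manual_score_threshold is not None:
        threshold = config.manual_score_threshold
    else:
        scores = [s.normalized_score for s in segmented[: config.calibration_reads]]
        threshold = calibrate_score_threshold(scores, config.calibration_reads)
    kept, discarded = filter_by_score(segmented, threshold)
    excluded["score_fail"] = len(discarded)

    refs = [r for r in references if r.modality == schema.modality]
    umi_len = None
    if schema.modality == "RNA":
        umi_len = schema.segment("umi").allowed_lengths[0]

    processed: list[ProcessedRead] = []
    payloads: dict[str, str] = {}
    audit: list[dict] = []
    wl1 = whitelists[schema.segment("bc1").whitelist_id]
    wl2 = whitelists[schema.segment("bc2").whitelist_id]
    wl_sample = None
    if schema.modality == "RNA":
        wl_sample = whitelists[schema.segment("sample_bc").whitelist_id]

    for seg in kept:
        res1 = correct_fixed_bc(seg.segments["bc1"], wl1)
        res2 = correct_fixed_bc(seg.segments["bc2"], wl2)
        for name, res in (("bc1", res1), ("bc2", res2)):
            audit.append(
                {"read_id": seg.read_id, "segment": name, "observed": res.observed,
                 "corrected": res.corrected or "", "distance": res.distance,
                 "reason": res.reason}
            )
        cell_bc = None
        if res1.corrected and res2.corrected:
            cell_bc = res1.corrected + res2.corrected
        sample_bc = umi = None
        if schema.modality == "RNA":
            # window runs past the segment into the UMI: insertions shift
            # the true barcode end rightward
            tail = seg.segments["umi"] + seg.payload
            window = seg.segments["sample_bc"] + tail[:SAMPLE_BC_WINDOW_EXTRA]
            res_s = correct_sample_bc(window, wl_sample)
            audit.append(
                {"read_id": seg.read_id, "segment": "sample_bc", "observed": window,
                 "corrected": res_s.corrected or "", "distance": res_s.distance,
                 "reason": res_s.reason}
            )
            sample_bc = res_s.corrected
            umi_region = seg.segments["umi"] + seg.payload
            umi = umi_region[:umi_len] or None
        payload = payload_by_id[seg.read_id]
        target = assign_target(payload, refs, config.min_identity, config.min_assign_len)
        processed.append(
            ProcessedRead(
                read_id=seg.read_id, cell_bc=cell_bc, sample_bc=sample_bc,
                umi=umi, target=target, modality=schema.modality,
            )
        )
        if target is not None:
            payloads[seg.read_id] = payload
    return LibraryResult(
        processed=processed, payloads=payloads, score_threshold=threshold,
        excluded=excluded, audit=audit,
    )


@dataclass
class RunResult:
    gdna: CountMatrix
    rna: CountMatrix
    qc: list[CellQcRecord]
    tally: TallyResult
    cell_threshold: float
    score_thresholds: dict[str, float]
    excluded: collections.Counter
    audit: list[dict]
    # (cell_bc, target, payload) triples of kept cells, for per-cell genotyping
    genotyping_reads: list[tuple[str, str, str]]


def run_pipeline(
    gdna_pairs: Iterable[tuple[str, str, str]],
    rna_pairs: Iterable[tuple[str, str, str]],
    schema_gdna: BarcodeSchema,
    schema_rna: BarcodeSchema,
    whitelists: Mapping[str, Whitelist],
    references: Sequence[ReferenceRecord],
    config: PipelineConfig = PipelineConfig(),
) -> RunResult:
    """Process both libraries and run cell QC through contamination
    stripping.  Exclusion counters plus matrix totals conserve input reads."""
    lib_g = process_library(gdna_pairs, schema_gdna, whitelists, references, config)
    lib_r = process_library(rna_pairs, schema_rna, whitelists, references, config)

    tally = tally_matrices(lib_g.processed + lib_r.processed)
    cells, cell_thr = call_cells(
        tally.reads_per_cell, config.cell_method, config.cell_threshold
    )
    qc_cells = demux_and_flag_doublets(
        tally.rna_reads_by_cell_sample, cells, tally.reads_per_cell, config.purity_min
    )
    non_cells = sorted(set(tally.reads_per_cell) - cells)
    qc = qc_cells + [
        CellQcRecord(bc, tally.reads_per_cell[bc], None, None, False, False)
        for bc in non_cells
    ]
    gdna, rna, removed = strip_contamination(tally.gdna, tally.rna, qc_cells)

    excluded = lib_g.excluded + lib_r.excluded + tally.excluded
    kept_cells = {r.cell_bc for r in qc_cells if not r.is_doublet and not r.unassignable}
    excluded["non_cell_or_doublet_reads"] = sum(
        n for bc, n in tally.reads_per_cell.items() if bc not in kept_cells
    )
    excluded["contamination_umis"] = removed

    genotyping_reads = [
        (read.cell_bc, read.target, lib_g.payloads[read.read_id])
        for read in lib_g.processed
        if read.cell_bc in kept_cells and read.target is not None
    ]

    return RunResult(
        gdna=gdna, rna=rna, qc=qc, tally=tally, cell_threshold=cell_thr,
        score_thresholds={"gDNA": lib_g.score_threshold, "RNA": lib_r.score_threshold},
        excluded=excluded, audit=lib_g.audit + lib_r.audit,
        genotyping_reads=genotyping_reads,
    )
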