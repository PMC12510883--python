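"""Backbone alignment of barcode reads, score calibration and filtering.

Each read is aligned semi-globally against every candidate backbone (the
backbone fully, the read from its start; the read may run past the backbone
into payload).  Scores are length-normalised so that reads hitting
different-length backbones are comparable: the score deficit below the
backbone's maximum is divided by one fixed per-library reference length
(the longest backbone), so a read with k edits scores the same no matter
which backbone variant it followed (normalising by each backbone's own
length would leave the k-edit score bands offset between linker-length
variants, and a single adaptive threshold would split them).  A perfect
read scores exactly the match score.  The winning backbone maximises the
normalised score; ties go to the shorter backbone, then the lower backbone
id.  An adaptive pass/fail threshold is calibrated from the first reads of
a library as mean minus two standard deviations of their normalised scores.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._align import BatchAlignment, Scoring, fit_template_batch
from .barcode_schema import Backbone

__all__ = [
    "ReadRecord",
    "SegmentedRead",
    "Scoring",
    "ParseError",
    "align_read_to_backbones",
    "segment_reads",
    "calibrate_score_threshold",
    "filter_by_score",
    "read_fastq",
]

DEFAULT_LENGTH_SLACK = 5
CALIBRATION_READS = 10_000


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: str | None = None


@dataclass
class SegmentedRead:
    """One read after backbone alignment.

    ``normalized_score`` = match_score - (max_score - raw_score) / L_ref,
    where max_score is the chosen backbone's perfect score and L_ref the
    longest backbone template length in the library; it equals the match
    score for a perfect read and never exceeds it.
    """

    read_id: str
    backbone_id: int
    raw_score: int
    normalized_score: float
    segments: dict[str, str]
    payload: str


def read_fastq(path) -> Iterable[ReadRecord]:
    """Iterate a (possibly gzipped) FASTQ file."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield ReadRecord(entry.name, entry.sequence, entry.quality)


def _exact_match(read: str, backbone: Backbone) -> bool:
    """True when the read begins with the backbone template verbatim at every
    fixed (non-wildcard) position."""
    t = backbone.template
    if len(read) < len(t):
        return False
    for i, c in enumerate(t):
        if c != "N" and read[i] != c:
            return False
    return True


def _segments_from_boundaries(
    read: str, backbone: Backbone, boundaries: np.ndarray
) -> tuple[dict[str, str], str]:
    segments = {}
    for name, (a, b) in backbone.segment_spans.items():
        segments[name] = read[int(boundaries[a]) : int(boundaries[b])]
    payload = read[int(boundaries[len(backbone)]) :]
    return segments, payload


def segment_reads(
    reads: Sequence[ReadRecord],
    backbones: Sequence[Backbone],
    scoring: Scoring = Scoring(),
    length_slack: int = DEFAULT_LENGTH_SLACK,
    chunk_size: int = 4000,
) -> tuple[list[SegmentedRead], list[str]]:
    """Segment a batch of reads; returns (segmented, failed_read_ids).

    Reads shorter than the shortest backbone minus ``length_slack`` are parse
    failures.  Reads whose fixed linker positions match some backbone verbatim
    take a fast path (their optimal score is the maximum achievable, so the
    full dynamic program is redundant); the rest are aligned in vectorised
    chunks against every backbone.
    """
    if not backbones:
        raise ParseError("no backbones supplied")
    order = sorted(backbones, key=lambda b: (len(b), b.backbone_id))
    min_len = len(order[0])
    l_ref = float(len(order[-1]))  # longest backbone: the shared normaliser
    failed: list[str] = []
    out: list[SegmentedRead | None] = [None] * len(reads)
    dp_indices: list[int] = []

    for idx, read in enumerate(reads):
        if len(read.sequence) < min_len - length_slack:
            failed.append(read.read_id)
            continue
        hit = None
        for bb in order:
            if _exact_match(read.sequence, bb):
                hit = bb
                break
        if hit is None:
            dp_indices.append(idx)
            continue
        boundaries = np.arange(len(hit) + 1)
        segments, payload = _segments_from_boundaries(read.sequence, hit, boundaries)
        out[idx] = SegmentedRead(
            read_id=read.read_id,
            backbone_id=hit.backbone_id,
            raw_score=len(hit) * scoring.match,
            normalized_score=float(scoring.match),
            segments=segments,
            payload=payload,
        )

    for start in range(0, len(dp_indices), chunk_size):
        chunk = dp_indices[start : start + chunk_size]
        seqs = [reads[i].sequence for i in chunk]
        results: list[BatchAlignment] = [
            fit_template_batch(seqs, bb.template, scoring) for bb in order
        ]
        norm = np.stack(
            [
                scoring.match - (len(bb) * scoring.match - res.scores) / l_ref
                for res, bb in zip(results, order)
            ],
            axis=1,
        )
        # order[] is already sorted by (length, id): argmax's first-winner
        # rule implements the tie-break.
        best = norm.argmax(axis=1)
        for row, idx in enumerate(chunk):
            k = int(best[row])
            bb, res = order[k], results[k]
            segments, payload = _segments_from_boundaries(
                reads[idx].sequence, bb, res.boundaries[row]
            )
            out[idx] = SegmentedRead(
                read_id=reads[idx].read_id,
                backbone_id=bb.backbone_id,
                raw_score=int(res.scores[row]),
                normalized_score=float(norm[row, k]),
                segments=segments,
                payload=payload,
            )

    return [s for s in out if s is not None], failed


def align_read_to_backbones(
    read: ReadRecord,
    backbones: Sequence[Backbone],
    scoring: Scoring = Scoring(),
    length_slack: int = DEFAULT_LENGTH_SLACK,
) -> SegmentedRead | None:
    """Align one read against all backbones; None marks a parse failure."""
    segmented, failed = segment_reads([read], backbones, scoring, length_slack)
    return segmented[0] if segmented else None


def calibrate_score_threshold(
    first_scores: Sequence[float], n: int = CALIBRATION_READS
) -> float:
    """Threshold = mean - 2 * sample standard deviation of the first ``n``
    normalised scores."""
    scores = list(first_scores[:n])
    if len(scores) < 2:
        raise ParseError(
            "fewer than 2 scores available for calibration; set a manual threshold"
        )
    mean = statistics.fmean(scores)
    sd = statistics.stdev(scores)
    return mean - 2.0 * sd


def filter_by_score(
    reads: Sequence[SegmentedRead], threshold: float
) -> tuple[list[SegmentedRead], list[SegmentedRead]]:
    """Keep reads with normalised score >= threshold (boundary inclusive)."""
    if not np.isfinite(threshold):
        raise ParseError("threshold must be finite")
    kept = [r for r in reads if r.normalized_score >= threshold]
    discarded = [r for r in reads if r.normalized_score < threshold]
    return kept, discarded
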