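"""Target assignment, dual count matrices, cell calling, demultiplexing,
doublet flagging, contamination removal and output writing.

The gDNA matrix counts reads per cell x amplicon (genomic DNA carries no
UMI); the RNA matrix counts deduplicated UMIs per (cell, sample barcode) x
gene.  Cells are called on total reads per cell barcode via a knee point on
the log-log barcode-rank curve (or a manual threshold).  Each cell is
assigned to its majority sample barcode; cells whose majority share of RNA
reads falls below a purity threshold are flagged as doublets, and reads from
minority sample barcodes are stripped as contamination.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import scipy.io
import scipy.sparse
import yaml

from .barcode_schema import ReferenceRecord
from .umi_dedup import dedup_umis

__all__ = [
    "ProcessedRead",
    "CountMatrix",
    "CellQcRecord",
    "QcError",
    "assign_target",
    "tally_matrices",
    "TallyResult",
    "call_cells",
    "demux_and_flag_doublets",
    "strip_contamination",
    "write_outputs",
    "read_count_matrix",
    "load_target_assignments",
]


class QcError(ValueError):
    pass


@dataclass(frozen=True)
class ProcessedRead:
    """A read after parsing, barcode correction and target assignment."""

    read_id: str
    cell_bc: str | None  # corrected BC1+BC2 concatenation, None if uncorrectable
    sample_bc: str | None  # RNA only
    umi: str | None  # RNA only
    target: str | None
    modality: str


@dataclass
class CountMatrix:
    """Sparse non-negative integer matrix, cells (or cell/sample pairs) x
    features, tagged with its modality."""

    modality: str
    rows: list[str]
    cols: list[str]
    m: scipy.sparse.csr_matrix

    @classmethod
    def from_counts(
        cls, modality: str, counts: Mapping[tuple[str, str], int],
        rows: Sequence[str] | None = None, cols: Sequence[str] | None = None,
    ) -> "CountMatrix":
        rows = sorted({r for r, _ in counts} if rows is None else rows)
        cols = sorted({c for _, c in counts} if cols is None else cols)
        ri = {r: i for i, r in enumerate(rows)}
        ci = {c: i for i, c in enumerate(cols)}
        m = scipy.sparse.dok_matrix((len(rows), len(cols)), dtype=np.int64)
        for (r, c), v in counts.items():
            if v:
                m[ri[r], ci[c]] = v
        return cls(modality, list(rows), list(cols), m.tocsr())

    def to_dict(self) -> dict[tuple[str, str], int]:
        coo = self.m.tocoo()
        return {
            (self.rows[i], self.cols[j]): int(v)
            for i, j, v in zip(coo.row, coo.col, coo.data)
        }

    def subset_rows(self, keep: Iterable[str]) -> "CountMatrix":
        keep = [r for r in self.rows if r in set(keep)]
        idx = [self.rows.index(r) for r in keep]
        return CountMatrix(self.modality, keep, list(self.cols), self.m[idx].tocsr())

    @property
    def total(self) -> int:
        return int(self.m.sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.modality == other.modality
            and self.to_dict() == other.to_dict()
        )


@dataclass
class CellQcRecord:
    cell_bc: str
    total_reads: int
    max_sample_bc: str | None
    purity: float | None
    is_cell: bool
    is_doublet: bool
    unassignable: bool = False


def assign_target(
    payload: str,
    references: Sequence[ReferenceRecord],
    min_identity: float = 0.8,
    min_len: int = 40,
) -> str | None:
    """Assign a payload to the best-matching reference by semi-global
    alignment; None when no reference passes identity/length thresholds or
    the best hit is not unique."""
    if not references:
        raise QcError("no references supplied")
    if len(payload) < min_len:
        return None
    best_name, best_dist, tie = None, None, False
    for ref in references:
        d = edlib.align(payload, ref.sequence, mode="HW", task="distance")["editDistance"]
        if best_dist is None or d < best_dist:
            best_name, best_dist, tie = ref.target_name, d, False
        elif d == best_dist:
            tie = True
    identity = 1.0 - best_dist / len(payload)
    if tie or identity < min_identity:
        return None
    return best_name


@dataclass
class TallyResult:
    gdna: CountMatrix  # cells x amplicons, read counts
    rna: CountMatrix  # "cell|sample" x genes, deduplicated UMI counts
    rna_reads_by_cell_sample: dict[tuple[str, str], int]
    reads_per_cell: dict[str, int]  # gDNA + RNA reads per cell barcode
    excluded: collections.Counter  # reason -> read count


RNA_ROW_SEP = "|"


def tally_matrices(reads: Iterable[ProcessedRead]) -> TallyResult:
    """Tally the gDNA read matrix and the RNA deduplicated-UMI matrix.

    Reads lacking a corrected cell barcode, sample barcode (RNA) or target
    are excluded and counted by reason.
    """
    gdna_counts: collections.Counter = collections.Counter()
    umi_groups: dict[tuple[str, str, str], collections.Counter] = collections.defaultdict(
        collections.Counter
    )
    rna_reads: collections.Counter = collections.Counter()
    reads_per_cell: collections.Counter = collections.Counter()
    excluded: collections.Counter = collections.Counter()
    for read in reads:
        if read.cell_bc is None:
            excluded["bc_fail"] += 1
            continue
        if read.modality == "RNA" and (read.sample_bc is None or read.umi is None):
            excluded["bc_fail"] += 1
            continue
        if read.target is None:
            excluded["target_fail"] += 1
            continue
        reads_per_cell[read.cell_bc] += 1
        if read.modality == "gDNA":
            gdna_counts[(read.cell_bc, read.target)] += 1
        else:
            umi_groups[(read.cell_bc, read.sample_bc, read.target)][read.umi] += 1
            rna_reads[(read.cell_bc, read.sample_bc)] += 1
    rna_counts = {
        (f"{cell}{RNA_ROW_SEP}{sample}", gene): dedup_umis(umis)
        for (cell, sample, gene), umis in umi_groups.items()
    }
    return TallyResult(
        gdna=CountMatrix.from_counts("gDNA", gdna_counts),
        rna=CountMatrix.from_counts("RNA", rna_counts),
        rna_reads_by_cell_sample=dict(rna_reads),
        reads_per_cell=dict(reads_per_cell),
        excluded=excluded,
    )


def call_cells(
    reads_per_cell: Mapping[str, int],
    method: str = "knee",
    threshold: int | None = None,
) -> tuple[set[str], float]:
    """Select cell-containing barcodes by total read count.

    Knee mode ranks barcodes by count and locates, on the log10(rank) vs
    log10(count) curve, the point of maximum perpendicular distance to the
    chord between the first and last points; the threshold is then the
    count at the last point before the steepest consecutive log-drop at or
    past the knee, so that a cell population with counting noise is kept
    through its tail down to the cliff.  Manual mode keeps barcodes with
    count >= threshold.  Returns (cell barcodes, threshold used).
    """
    if method == "manual":
        if threshold is None:
            raise QcError("manual mode requires a threshold")
        return {bc for bc, n in reads_per_cell.items() if n >= threshold}, float(threshold)
    if method != "knee":
        raise QcError(f"unknown cell-calling method {method!r}")
    if len(reads_per_cell) < 10:
        raise QcError("knee mode needs at least 10 barcodes")
    counts = np.array(sorted(reads_per_cell.values(), reverse=True), dtype=float)
    if counts[0] == counts[-1]:
        raise QcError("all barcode counts equal; use manual mode")
    x = np.log10(np.arange(1, len(counts) + 1))
    y = np.log10(np.maximum(counts, 1.0))
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    # perpendicular distance of each point to the chord
    dist = np.abs(chord[0] * (p0[1] - y) - (p0[0] - x) * chord[1]) / norm
    knee = int(dist.argmax())
    if knee < len(counts) - 1:
        # steepest drop at or past the knee marks the population boundary
        drops = np.diff(y[knee:])
        knee = knee + int(drops.argmin())
    thr = counts[knee]
    return {bc for bc, n in reads_per_cell.items() if n >= thr}, float(thr)


def demux_and_flag_doublets(
    rna_reads_by_cell_sample: Mapping[tuple[str, str], int],
    cells: Iterable[str],
    reads_per_cell: Mapping[str, int] | None = None,
    purity_min: float = 0.8,
) -> list[CellQcRecord]:
    """Assign each called cell to its majority sample barcode and flag
    doublets by purity (majority-sample RNA reads / total RNA reads)."""
    by_cell: dict[str, dict[str, int]] = collections.defaultdict(dict)
    for (cell, sample), n in rna_reads_by_cell_sample.items():
        by_cell[cell][sample] = by_cell[cell].get(sample, 0) + n
    records = []
    for cell in sorted(set(cells)):
        samples = by_cell.get(cell, {})
        total_rna = sum(samples.values())
        total = (reads_per_cell or {}).get(cell, total_rna)
        if total_rna == 0:
            records.append(
                CellQcRecord(cell, total, None, None, True, False, unassignable=True)
            )
            continue
        # argmax with lexicographic tie-break
        max_sample = min(samples, key=lambda s: (-samples[s], s))
        purity = samples[max_sample] / total_rna
        records.append(
            CellQcRecord(
                cell_bc=cell,
                total_reads=total,
                max_sample_bc=max_sample,
                purity=purity,
                is_cell=True,
                is_doublet=purity < purity_min,
            )
        )
    return records


def strip_contamination(
    gdna: CountMatrix,
    rna: CountMatrix,
    qc: Sequence[CellQcRecord],
) -> tuple[CountMatrix, CountMatrix, int]:
    """Remove contaminating RNA entries and drop non-cell/doublet rows.

    RNA entries whose sample barcode differs from the cell's majority sample
    are zeroed; doublet and unassignable cells are dropped from both
    matrices; the RNA matrix collapses to one row per cell.  Totals are
    strictly non-increasing.  Returns (gdna, rna, contamination UMIs removed
    from kept cells); UMIs lost with dropped rows are not counted as
    contamination.
    """
    keep = {
        r.cell_bc: r.max_sample_bc
        for r in qc
        if r.is_cell and not r.is_doublet and not r.unassignable
    }
    gdna_out = gdna.subset_rows(keep)
    rna_counts: dict[tuple[str, str], int] = {}
    removed = 0
    for (row, gene), v in rna.to_dict().items():
        if RNA_ROW_SEP in row:
            cell, sample = row.rsplit(RNA_ROW_SEP, 1)
        else:  # already-stripped matrix: rows are plain cells
            cell, sample = row, keep.get(row)
        if cell not in keep:
            continue
        if sample == keep[cell]:
            rna_counts[(cell, gene)] = rna_counts.get((cell, gene), 0) + v
        else:
            removed += v
    rna_out = CountMatrix.from_counts(
        "RNA", rna_counts, rows=sorted(keep), cols=rna.cols
    )
    return gdna_out, rna_out, removed


# ---------------------------------------------------------------------------
# Outputs


def _write_matrix(outdir: Path, prefix: str, matrix: CountMatrix) -> None:
    scipy.io.mmwrite(str(outdir / f"{prefix}_matrix.mtx"), matrix.m.tocoo())
    (outdir / f"{prefix}_barcodes.tsv").write_text(
        "".join(r + "\n" for r in matrix.rows)
    )
    (outdir / f"{prefix}_features.tsv").write_text(
        "".join(c + "\n" for c in matrix.cols)
    )


def read_count_matrix(outdir, prefix: str, modality: str) -> CountMatrix:
    outdir = Path(outdir)
    m = scipy.io.mmread(str(outdir / f"{prefix}_matrix.mtx"))
    m = scipy.sparse.csr_matrix(m, dtype=np.int64)
    rows = (outdir / f"{prefix}_barcodes.tsv").read_text().splitlines()
    cols = (outdir / f"{prefix}_features.tsv").read_text().splitlines()
    if m.shape == (0, 0) and (rows or cols):
        m = scipy.sparse.csr_matrix((len(rows), len(cols)), dtype=np.int64)
    return CountMatrix(modality, rows, cols, m)


QC_COLUMNS = [
    "cell_bc", "total_reads", "max_sample_bc", "purity", "is_cell",
    "is_doublet", "unassignable",
]
AUDIT_COLUMNS = ["read_id", "segment", "observed", "corrected", "distance", "reason"]


def write_outputs(
    outdir,
    gdna: CountMatrix,
    rna: CountMatrix,
    qc: Sequence[CellQcRecord],
    audit: Sequence[Mapping] = (),
    run_params: Mapping | None = None,
) -> None:
    """Write Matrix Market matrices with row/column TSVs per modality, the
    per-cell QC table, the barcode-correction audit and a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_matrix(outdir, "gdna", gdna)
    _write_matrix(outdir, "rna", rna)
    with open(outdir / "cells_qc.tsv", "w") as fh:
        fh.write("\t".join(QC_COLUMNS) + "\n")
        for r in qc:
            purity = "" if r.purity is None else f"{r.purity:.6f}"
            fh.write(
                "\t".join(
                    [r.cell_bc, str(r.total_reads), r.max_sample_bc or "", purity,
                     str(int(r.is_cell)), str(int(r.is_doublet)), str(int(r.unassignable))]
                )
                + "\n"
            )
    with open(outdir / "correction_audit.tsv", "w") as fh:
        fh.write("\t".join(AUDIT_COLUMNS) + "\n")
        for row in audit:
            fh.write("\t".join(str(row.get(c, "")) for c in AUDIT_COLUMNS) + "\n")
    if run_params is not None:
        with open(outdir / "run_log.yaml", "w") as fh:
            yaml.safe_dump(dict(run_params), fh, sort_keys=True)


def load_target_assignments(path) -> dict[str, str | None]:
    """Ingest pre-aligned reads (SAM/BAM) as a read-id -> target-name map.

    Primary alignments only; unmapped reads map to None.  Lets an external
    aligner against the custom per-target references stand in for the
    internal assigner.
    """
    import pysam

    assignments: dict[str, str | None] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                continue
            assignments[aln.query_name] = None if aln.is_unmapped else aln.reference_name
    return assignments
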