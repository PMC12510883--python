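"""Barcode read architecture, whitelists, amplicon panels and alignment references.

A composite barcode read is an ordered run of segments: cell barcodes
(delivered in two parts, BC1 and BC2), fixed-sequence linkers that may come
in several lengths, an optional sample barcode and UMI, and finally the
payload (the amplified gDNA or cDNA fragment).  Because linkers can have
several allowed lengths, the set of concrete "backbones" a read can follow
is the cartesian product of the per-segment length choices; reads are later
aligned against every backbone to find the best fit.

Alignment references are built per target: gDNA references are the genomic
span of each amplicon (minus-strand targets reverse-complemented), RNA
references run from the primer-binding site through the end of the poly(A)
tail.
"""

from __future__ import annotations

import gzip
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Segment",
    "BarcodeSchema",
    "Whitelist",
    "AmpliconTarget",
    "ReferenceRecord",
    "Backbone",
    "SchemaError",
    "enumerate_backbones",
    "build_gdna_reference",
    "build_rna_reference",
    "read_panel_tsv",
    "write_panel_tsv",
    "read_whitelist",
    "write_whitelist",
    "write_references_fasta",
    "read_references_fasta",
    "write_references_gtf",
    "reverse_complement",
]

SEGMENT_ROLES = ("cell_bc", "linker", "sample_bc", "umi", "payload")
WILDCARD = "N"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class SchemaError(ValueError):
    """Raised for invalid barcode schemas, panels or whitelists."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Segment:
    """One element of the barcode read layout.

    ``allowed_lengths`` is a non-empty set of lengths; linkers with more than
    one allowed length must provide one ``fixed_sequences`` entry per length.
    """

    name: str
    role: str
    allowed_lengths: tuple[int, ...]
    whitelist_id: str | None = None
    fixed_sequences: Mapping[int, str] | None = None

    def __post_init__(self):
        if self.role not in SEGMENT_ROLES:
            raise SchemaError(f"segment {self.name!r}: unknown role {self.role!r}")
        lengths = tuple(sorted(set(self.allowed_lengths)))
        if not lengths and self.role != "payload":
            raise SchemaError(f"segment {self.name!r}: no allowed lengths")
        if any(l <= 0 for l in lengths):
            raise SchemaError(f"segment {self.name!r}: lengths must be positive")
        object.__setattr__(self, "allowed_lengths", lengths)
        if self.role == "linker":
            if self.fixed_sequences is None:
                raise SchemaError(f"linker {self.name!r}: fixed_sequences required")
            for l in lengths:
                seq = self.fixed_sequences.get(l)
                if seq is None or len(seq) != l:
                    raise SchemaError(
                        f"linker {self.name!r}: missing/mis-sized fixed sequence for length {l}"
                    )
        elif self.role in ("cell_bc", "sample_bc") and self.whitelist_id is None:
            raise SchemaError(f"segment {self.name!r}: {self.role} requires a whitelist")

    @property
    def is_variable(self) -> bool:
        return len(self.allowed_lengths) > 1


@dataclass(frozen=True)
class BarcodeSchema:
    """Ordered segment layout of a barcode read for one modality."""

    modality: str
    segments: tuple[Segment, ...]

    def __post_init__(self):
        if self.modality not in ("gDNA", "RNA"):
            raise SchemaError(f"unknown modality {self.modality!r}")
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs or segs[-1].role != "payload":
            raise SchemaError("payload must be the final segment")
        if any(s.role == "payload" for s in segs[:-1]):
            raise SchemaError("payload must appear exactly once, last")
        if self.modality == "gDNA":
            for s in segs:
                if s.role in ("sample_bc", "umi"):
                    raise SchemaError("gDNA schema must not contain sample_bc or umi segments")
        names = [s.name for s in segs]
        if len(set(names)) != len(names):
            raise SchemaError("segment names must be unique")

    @property
    def backbone_segments(self) -> tuple[Segment, ...]:
        """All segments except the trailing payload."""
        return self.segments[:-1]

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class Backbone:
    """One concrete backbone: a template string with 'N' wildcards at
    barcode/UMI positions and a map from segment name to its interval."""

    backbone_id: int
    modality: str
    template: str
    segment_spans: Mapping[str, tuple[int, int]]
    segment_lengths: Mapping[str, int]

    def __len__(self) -> int:
        return len(self.template)


def enumerate_backbones(schema: BarcodeSchema) -> list[Backbone]:
    """Enumerate one backbone per combination of variable-segment lengths.

    Backbones are ordered by (length, lexicographic length-vector) so that
    ids are deterministic; ties between equally scoring backbones downstream
    resolve to shorter templates, then lower ids.
    """
    segs = schema.backbone_segments
    if not segs:
        raise SchemaError("schema has no backbone segments")
    choices = [seg.allowed_lengths for seg in segs]
    combos = sorted(itertools.product(*choices), key=lambda c: (sum(c), c))
    backbones = []
    for bid, combo in enumerate(combos):
        parts: list[str] = []
        spans: dict[str, tuple[int, int]] = {}
        lengths: dict[str, int] = {}
        pos = 0
        for seg, length in zip(segs, combo):
            if seg.role == "linker":
                parts.append(seg.fixed_sequences[length])
            else:
                parts.append(WILDCARD * length)
            spans[seg.name] = (pos, pos + length)
            lengths[seg.name] = length
            pos += length
        backbones.append(
            Backbone(
                backbone_id=bid,
                modality=schema.modality,
                template="".join(parts),
                segment_spans=spans,
                segment_lengths=lengths,
            )
        )
    return backbones


@dataclass(frozen=True)
class Whitelist:
    id: str
    barcodes: tuple[str, ...]

    def __post_init__(self):
        bcs = tuple(self.barcodes)
        if not bcs:
            raise SchemaError(f"whitelist {self.id!r} is empty")
        if len(set(bcs)) != len(bcs):
            raise SchemaError(f"whitelist {self.id!r} has duplicate barcodes")
        lengths = {len(b) for b in bcs}
        if len(lengths) != 1:
            raise SchemaError(f"whitelist {self.id!r} mixes barcode lengths {lengths}")
        for b in bcs:
            if set(b) - set("ACGT"):
                raise SchemaError(f"whitelist {self.id!r}: non-ACGT barcode {b!r}")
        object.__setattr__(self, "barcodes", bcs)

    @property
    def length(self) -> int:
        return len(self.barcodes[0])

    def __contains__(self, bc: str) -> bool:
        return bc in set(self.barcodes)


@dataclass(frozen=True)
class AmpliconTarget:
    """One panel entry: a named genomic span with its PCR primers."""

    name: str
    modality: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    fwd_primer: str
    rev_primer: str

    def __post_init__(self):
        if self.modality not in ("gDNA", "RNA"):
            raise SchemaError(f"target {self.name!r}: unknown modality {self.modality!r}")
        if not (0 <= self.start < self.end):
            raise SchemaError(f"target {self.name!r}: invalid span {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise SchemaError(f"target {self.name!r}: strand must be + or -")
        if not self.fwd_primer or not self.rev_primer:
            raise SchemaError(f"target {self.name!r}: primers must be non-empty")


@dataclass(frozen=True)
class ReferenceRecord:
    target_name: str
    modality: str
    sequence: str
    source_span: tuple[str, int, int, str]

    def __post_init__(self):
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            raise SchemaError(f"reference {self.target_name!r}: non-ACGTN characters")
        object.__setattr__(self, "sequence", seq)


def build_gdna_reference(
    panel: Sequence[AmpliconTarget], genome: Mapping[str, str]
) -> list[ReferenceRecord]:
    """Extract one reference per gDNA target from its chromosomal span.

    Minus-strand targets are reverse-complemented so that every record reads
    in amplicon (sequencing) orientation.
    """
    records = []
    for target in panel:
        if target.modality != "gDNA":
            continue
        if target.chrom not in genome:
            raise SchemaError(f"target {target.name!r}: chromosome {target.chrom!r} not in genome")
        chrom_seq = genome[target.chrom]
        if target.end > len(chrom_seq):
            raise SchemaError(
                f"target {target.name!r}: span [{target.start},{target.end}) exceeds "
                f"{target.chrom} length {len(chrom_seq)}"
            )
        seq = chrom_seq[target.start : target.end]
        if target.strand == "-":
            seq = reverse_complement(seq)
        records.append(
            ReferenceRecord(
                target_name=target.name,
                modality="gDNA",
                sequence=seq,
                source_span=(target.chrom, target.start, target.end, target.strand),
            )
        )
    return records


def build_rna_reference(
    target: AmpliconTarget,
    transcript_model: tuple[str, int],
    polya_length: int = 20,
) -> ReferenceRecord:
    """Build an RNA reference: transcript suffix from the primer-binding site
    through the transcript 3' end.

    If the transcript annotation carries no explicit poly(A) tail (the suffix
    does not end in at least ten A's), a fixed ``polya_length`` stub is
    appended so the reference remains finite but poly(A)-terminated.
    """
    transcript, offset = transcript_model
    if not (0 <= offset < len(transcript)):
        raise SchemaError(
            f"target {target.name!r}: primer offset {offset} outside transcript "
            f"of length {len(transcript)}"
        )
    suffix = transcript[offset:]
    if len(suffix) < 10:
        warnings.warn(
            f"target {target.name!r}: reference is only {len(suffix)} bases long",
            stacklevel=2,
        )
    if polya_length > 0 and not suffix.endswith("A" * min(10, polya_length)):
        suffix = suffix + "A" * polya_length
    return ReferenceRecord(
        target_name=target.name,
        modality="RNA",
        sequence=suffix,
        source_span=(target.chrom, target.start, target.end, target.strand),
    )


# ---------------------------------------------------------------------------
# External formats

PANEL_COLUMNS = ["name", "modality", "chrom", "start", "end", "strand", "fwd_primer", "rev_primer"]


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_panel_tsv(path) -> list[AmpliconTarget]:
    targets = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PANEL_COLUMNS:
            raise SchemaError(f"panel header {header} != expected {PANEL_COLUMNS}")
        for line in fh:
            if not line.strip():
                continue
            vals = dict(zip(PANEL_COLUMNS, line.rstrip("\n").split("\t")))
            targets.append(
                AmpliconTarget(
                    name=vals["name"],
                    modality=vals["modality"],
                    chrom=vals["chrom"],
                    start=int(vals["start"]),
                    end=int(vals["end"]),
                    strand=vals["strand"],
                    fwd_primer=vals["fwd_primer"],
                    rev_primer=vals["rev_primer"],
                )
            )
    return targets


def write_panel_tsv(path, panel: Iterable[AmpliconTarget]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for t in panel:
            fh.write(
                "\t".join(
                    [t.name, t.modality, t.chrom, str(t.start), str(t.end), t.strand,
                     t.fwd_primer, t.rev_primer]
                )
                + "\n"
            )


def read_whitelist(path, whitelist_id: str | None = None) -> Whitelist:
    """Plain text whitelist, one barcode per line; gzip accepted."""
    wid = whitelist_id or str(path)
    with _open_text(path) as fh:
        barcodes = tuple(line.strip().upper() for line in fh if line.strip())
    return Whitelist(id=wid, barcodes=barcodes)


def write_whitelist(path, whitelist: Whitelist) -> None:
    with _open_text(path, "wt") as fh:
        for bc in whitelist.barcodes:
            fh.write(bc + "\n")


def write_references_fasta(path, records: Iterable[ReferenceRecord], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.target_name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_references_fasta(path, modality: str = "gDNA") -> list[ReferenceRecord]:
    records = []
    name, chunks = None, []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append(
                        ReferenceRecord(name, modality, "".join(chunks), (name, 0, sum(map(len, chunks)), "+"))
                    )
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append(
            ReferenceRecord(name, modality, "".join(chunks), (name, 0, sum(map(len, chunks)), "+"))
        )
    return records


def schema_to_dict(schema: BarcodeSchema) -> dict:
    return {
        "modality": schema.modality,
        "segments": [
            {
                "name": s.name,
                "role": s.role,
                "allowed_lengths": list(s.allowed_lengths),
                **({"whitelist_id": s.whitelist_id} if s.whitelist_id else {}),
                **(
                    {"fixed_sequences": {int(k): v for k, v in s.fixed_sequences.items()}}
                    if s.fixed_sequences
                    else {}
                ),
            }
            for s in schema.segments
        ],
    }


def schema_from_dict(data: Mapping) -> BarcodeSchema:
    segments = tuple(
        Segment(
            name=s["name"],
            role=s["role"],
            allowed_lengths=tuple(s["allowed_lengths"]),
            whitelist_id=s.get("whitelist_id"),
            fixed_sequences={int(k): v for k, v in s["fixed_sequences"].items()}
            if s.get("fixed_sequences")
            else None,
        )
        for s in data["segments"]
    )
    return BarcodeSchema(modality=data["modality"], segments=segments)


def write_schemas_yaml(path, schemas: Sequence[BarcodeSchema]) -> None:
    import yaml

    with _open_text(path, "wt") as fh:
        yaml.safe_dump([schema_to_dict(s) for s in schemas], fh, sort_keys=False)


def read_schemas_yaml(path) -> list[BarcodeSchema]:
    import yaml

    with _open_text(path) as fh:
        return [schema_from_dict(d) for d in yaml.safe_load(fh)]


def write_references_gtf(path, records: Iterable[ReferenceRecord]) -> None:
    """One feature per target, coordinates on the per-target reference itself
    (for use with external aligners that index the custom FASTA)."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            attrs = f'gene_id "{rec.target_name}"; transcript_id "{rec.target_name}";'
            for feature in ("gene", "transcript", "exon"):
                fh.write(
                    "\t".join(
                        [rec.target_name, "sdrkit", feature, "1", str(len(rec.sequence)),
                         ".", "+", ".", attrs]
                    )
                    + "\n"
                )
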