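"""Synthetic targeted single-cell DNA+RNA read generator with ground truth.

Emulates the composite barcode read structure (cell BC1, variable-length
linker, cell BC2, constant linker, then — RNA only — sample BC and UMI),
PCR duplication, per-base substitution/insertion/deletion errors, per-allele
dropout at heterozygous loci, rare spurious-allele (noise) events, ambient
contamination and cell doublets.  Every emitted read carries a provenance
row, so each pipeline stage can be checked against exact truth.

A naive allele-count diploid genotype caller ships here as a fixture to
produce merged per-cell VCFs for the genotype analytics; it is test
scaffolding, not part of the processing pipeline.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
import yaml

from .barcode_schema import (
    AmpliconTarget,
    BarcodeSchema,
    ReferenceRecord,
    Segment,
    Whitelist,
    build_gdna_reference,
    build_rna_reference,
)
from .genotype_analysis import VariantKey

__all__ = [
    "SimulationConfig",
    "SimulatedAssay",
    "TruthTables",
    "SimulatedReads",
    "simulate_cells",
    "synthesize_reads",
    "inject_errors",
    "generate_whitelist",
    "write_fastq_pair",
    "call_genotypes_naive",
    "write_merged_vcf",
]

BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic run.

    Defaults describe a small targeted experiment: a few hundred cells over
    a handful of samples, a compact panel with genomic amplicons carrying
    one variant each, moderate read depth and realistic short-read error
    rates (set to zero here; noisy scenarios override them explicitly).
    """

    n_cells: int = 300
    n_samples: int = 3
    doublet_rate: float = 0.0
    bc1_size: int = 96
    bc2_size: int = 96
    sample_bc_size: int = 12
    bc_length: int = 9
    sample_bc_length: int = 8
    umi_length: int = 8
    n_gdna_targets: int = 8
    n_rna_targets: int = 8
    amplicon_length: int = 160
    transcript_length: int = 260
    primer_offset: int = 80
    mean_gdna_reads_per_amplicon: float = 20.0
    mean_rna_molecules_per_gene: float = 4.0
    mean_reads_per_molecule: float = 3.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    ado_rate: float = 0.0
    noise_rate: float = 0.0
    ambient_fraction: float = 0.0
    alt_allele_freq: float = 0.3
    r1_length: int = 75
    r2_length: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("sub_rate", "ins_rate", "del_rate", "ado_rate", "noise_rate",
                     "ambient_fraction", "doublet_rate", "alt_allele_freq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be within [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def generate_whitelist(
    rng: np.random.Generator,
    wid: str,
    size: int,
    length: int,
    min_distance: int = 3,
    max_tries: int = 200_000,
) -> Whitelist:
    """Draw random barcodes with pairwise Levenshtein distance >=
    ``min_distance`` (separation makes single-edit correction unambiguous)."""
    accepted: list[str] = []
    tries = 0
    while len(accepted) < size:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not build whitelist {wid!r}: {len(accepted)}/{size} after {tries} tries"
            )
        cand = _random_seq(rng, length)
        ok = all(
            edlib.align(cand, bc, mode="NW", task="distance", k=min_distance - 1)["editDistance"]
            == -1
            for bc in accepted
        )
        if ok:
            accepted.append(cand)
    return Whitelist(id=wid, barcodes=tuple(accepted))


@dataclass
class SimulatedAssay:
    """The designed assay: whitelists, schemas, panel, genome, references."""

    whitelists: dict[str, Whitelist]
    schema_rna: BarcodeSchema
    schema_gdna: BarcodeSchema
    panel: list[AmpliconTarget]
    genome: dict[str, str]
    transcripts: dict[str, tuple[str, int]]
    references_gdna: list[ReferenceRecord]
    references_rna: list[ReferenceRecord]
    variants: dict[str, VariantKey]  # variant id -> key
    variant_offsets: dict[str, int]  # variant id -> 0-based offset in its amplicon
    variant_amplicon: dict[str, str]
    locus_class: dict[str, str]  # variant id -> "het" | "ref" | "segregating"

    @property
    def references(self) -> list[ReferenceRecord]:
        return self.references_gdna + self.references_rna


def _build_linkers(rng: np.random.Generator, lengths: Sequence[int]) -> dict[int, str]:
    return {l: _random_seq(rng, l) for l in lengths}


def build_assay(config: SimulationConfig) -> SimulatedAssay:
    """Design the synthetic assay deterministically from the config seed."""
    rng = np.random.default_rng([config.seed % (2**31), 11])
    wl_bc1 = generate_whitelist(rng, "bc1", config.bc1_size, config.bc_length, 3)
    wl_bc2 = generate_whitelist(rng, "bc2", config.bc2_size, config.bc_length, 3)
    # extra separation on the sample whitelist: the margin rule under free
    # divergence sees two UMI bases of context past the barcode
    wl_sample = generate_whitelist(
        rng, "sample", config.sample_bc_size, config.sample_bc_length, 4
    )
    linker1 = _build_linkers(rng, (14, 15, 16, 17))
    linker2 = _build_linkers(rng, (15,))
    seg_bc1 = Segment("bc1", "cell_bc", (config.bc_length,), whitelist_id="bc1")
    seg_l1 = Segment("linker1", "linker", tuple(linker1), fixed_sequences=linker1)
    seg_bc2 = Segment("bc2", "cell_bc", (config.bc_length,), whitelist_id="bc2")
    seg_l2 = Segment("linker2", "linker", (15,), fixed_sequences=linker2)
    seg_sample = Segment("sample_bc", "sample_bc", (config.sample_bc_length,), whitelist_id="sample")
    seg_umi = Segment("umi", "umi", (config.umi_length,))
    seg_payload = Segment("payload", "payload", (1,))
    schema_rna = BarcodeSchema(
        "RNA", (seg_bc1, seg_l1, seg_bc2, seg_l2, seg_sample, seg_umi, seg_payload)
    )
    schema_gdna = BarcodeSchema("gDNA", (seg_bc1, seg_l1, seg_bc2, seg_l2, seg_payload))

    spacing = 40
    chrom_len = config.n_gdna_targets * (config.amplicon_length + spacing) + spacing
    genome = {"chrS": _random_seq(rng, chrom_len)}
    panel: list[AmpliconTarget] = []
    for i in range(config.n_gdna_targets):
        start = spacing + i * (config.amplicon_length + spacing)
        end = start + config.amplicon_length
        seq = genome["chrS"][start:end]
        panel.append(
            AmpliconTarget(
                name=f"amp{i:02d}", modality="gDNA", chrom="chrS", start=start,
                end=end, strand="+", fwd_primer=seq[:20], rev_primer=seq[-20:],
            )
        )
    transcripts: dict[str, tuple[str, int]] = {}
    for i in range(config.n_rna_targets):
        name = f"gene{i:02d}"
        transcripts[name] = (_random_seq(rng, config.transcript_length), config.primer_offset)
        panel.append(
            AmpliconTarget(
                name=name, modality="RNA", chrom=name, start=0,
                end=config.transcript_length, strand="+",
                fwd_primer=transcripts[name][0][config.primer_offset : config.primer_offset + 20],
                rev_primer="T" * 20,
            )
        )
    references_gdna = build_gdna_reference(panel, genome)
    references_rna = [
        build_rna_reference(t, transcripts[t.name]) for t in panel if t.modality == "RNA"
    ]

    # one SNP per gDNA amplicon, placed where the payload read covers it
    variants: dict[str, VariantKey] = {}
    variant_offsets: dict[str, int] = {}
    variant_amplicon: dict[str, str] = {}
    locus_class: dict[str, str] = {}
    n_het = max(1, math.ceil(config.n_gdna_targets / 3))
    n_ref = max(1, math.ceil(config.n_gdna_targets / 3))
    for i, target in enumerate(t for t in panel if t.modality == "gDNA"):
        offset = int(rng.integers(30, min(90, config.r2_length - 10)))
        ref_base = genome[target.chrom][target.start + offset]
        alt_base = rng.choice([b for b in BASES if b != ref_base])
        key = VariantKey(target.chrom, target.start + offset + 1, ref_base, str(alt_base))
        vid = str(key)
        variants[vid] = key
        variant_offsets[vid] = offset
        variant_amplicon[vid] = target.name
        if i < n_het:
            locus_class[vid] = "het"
        elif i < n_het + n_ref:
            locus_class[vid] = "ref"
        else:
            locus_class[vid] = "segregating"
    return SimulatedAssay(
        whitelists={"bc1": wl_bc1, "bc2": wl_bc2, "sample": wl_sample},
        schema_rna=schema_rna,
        schema_gdna=schema_gdna,
        panel=panel,
        genome=genome,
        transcripts=transcripts,
        references_gdna=references_gdna,
        references_rna=references_rna,
        variants=variants,
        variant_offsets=variant_offsets,
        variant_amplicon=variant_amplicon,
        locus_class=locus_class,
    )


@dataclass
class TruthTables:
    """Ground truth for one simulated run."""

    assay: SimulatedAssay
    droplets: pd.DataFrame  # droplet_id, bc1, bc2, cell_bc, is_doublet, samples
    constituents: pd.DataFrame  # constituent_id, droplet_id, cell_bc, sample_bc
    genotypes: pd.DataFrame  # constituent_id, cell_bc, variant, class, genotype, allele_pool
    rna_counts: pd.DataFrame  # constituent_id, cell_bc, sample_bc, gene, n_molecules


def simulate_cells(config: SimulationConfig) -> TruthTables:
    """Draw the cell roster, genotypes (with dropout/noise events) and true
    RNA molecule counts."""
    assay = build_assay(config)
    rng = np.random.default_rng([config.seed % (2**31), 23])
    wl1, wl2 = assay.whitelists["bc1"].barcodes, assay.whitelists["bc2"].barcodes
    samples = assay.whitelists["sample"].barcodes[: config.n_samples]
    if len(samples) < config.n_samples:
        raise ValueError("sample whitelist smaller than n_samples")

    n_pairs = len(wl1) * len(wl2)
    if config.n_cells > n_pairs:
        raise ValueError("whitelist exhausted: more cells than unique BC pairs")
    pair_idx = rng.choice(n_pairs, size=config.n_cells, replace=False)
    n_doublets = int(rng.binomial(config.n_cells, config.doublet_rate))

    droplets = []
    constituents = []
    cid = 0
    for d, pi in enumerate(pair_idx):
        bc1, bc2 = wl1[pi // len(wl2)], wl2[pi % len(wl2)]
        cell_bc = bc1 + bc2
        is_doublet = d < n_doublets
        if is_doublet:
            # two constituents from distinct samples so the sample barcode
            # can reveal the doublet
            s1, s2 = rng.choice(len(samples), size=2, replace=False)
            members = [samples[s1], samples[s2]]
        else:
            members = [samples[d % len(samples)]]
        droplets.append(
            {"droplet_id": d, "bc1": bc1, "bc2": bc2, "cell_bc": cell_bc,
             "is_doublet": is_doublet, "samples": tuple(sorted(members))}
        )
        for sample in members:
            constituents.append(
                {"constituent_id": cid, "droplet_id": d, "cell_bc": cell_bc,
                 "sample_bc": sample}
            )
            cid += 1
    droplets = pd.DataFrame(droplets)
    constituents = pd.DataFrame(constituents)

    geno_rows = []
    p_alt = config.alt_allele_freq
    hwe = [(1 - p_alt) ** 2, 2 * p_alt * (1 - p_alt), p_alt**2]
    for row in constituents.itertuples():
        for vid, cls in assay.locus_class.items():
            if cls == "het":
                genotype = 1
            elif cls == "ref":
                genotype = 0
            else:
                genotype = int(rng.choice(3, p=hwe))
            pool = {0: ["ref", "ref"], 1: ["ref", "alt"], 2: ["alt", "alt"]}[genotype]
            event = ""
            if genotype == 1 and rng.random() < config.ado_rate:
                dropped = pool.pop(int(rng.integers(0, 2)))
                event = f"ado_dropped_{dropped}"
            elif genotype == 0 and rng.random() < config.noise_rate:
                pool = ["ref", "alt"]
                event = "noise_alt"
            geno_rows.append(
                {"constituent_id": row.constituent_id, "cell_bc": row.cell_bc,
                 "sample_bc": row.sample_bc, "variant": vid, "class": cls,
                 "genotype": genotype, "allele_pool": tuple(pool), "event": event}
            )
    genotypes = pd.DataFrame(geno_rows)

    rna_rows = []
    genes = [t.name for t in assay.panel if t.modality == "RNA"]
    for row in constituents.itertuples():
        n_mols = rng.poisson(config.mean_rna_molecules_per_gene, size=len(genes))
        for gene, n in zip(genes, n_mols):
            rna_rows.append(
                {"constituent_id": row.constituent_id, "cell_bc": row.cell_bc,
                 "sample_bc": row.sample_bc, "gene": gene, "n_molecules": int(n)}
            )
    rna_counts = pd.DataFrame(rna_rows)
    return TruthTables(assay, droplets, constituents, genotypes, rna_counts)


def inject_errors(
    sequence: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, str]]]:
    """Mutate a sequence with per-position independent substitution (uniform
    over the three alternatives), insertion (uniform base, after the
    position) and deletion.  Returns (mutated sequence, event log)."""
    total = sub_rate + ins_rate + del_rate
    if total == 0.0 or not sequence:
        return sequence, []
    u = rng.random(len(sequence))
    hits = np.nonzero(u < total)[0]
    if len(hits) == 0:
        return sequence, []
    events: list[tuple[int, str]] = []
    out = []
    prev = 0
    for pos in hits:
        out.append(sequence[prev:pos])
        x = u[pos]
        base = sequence[pos]
        if x < sub_rate:
            new = BASES[(BASES.index(base) + 1 + int(rng.integers(0, 3))) % 4] \
                if base in BASES else str(rng.choice(list(BASES)))
            out.append(new)
            events.append((int(pos), f"sub:{base}>{new}"))
        elif x < sub_rate + ins_rate:
            ins = BASES[int(rng.integers(0, 4))]
            out.append(base + ins)
            events.append((int(pos), f"ins:{ins}"))
        else:
            events.append((int(pos), f"del:{base}"))
        prev = pos + 1
    out.append(sequence[prev:])
    return "".join(out), events


@dataclass
class SimulatedReads:
    """Emitted read pairs plus per-read provenance."""

    gdna: list[tuple[str, str, str]]  # (read_id, R1, R2)
    rna: list[tuple[str, str, str]]
    provenance: pd.DataFrame


def synthesize_reads(truth: TruthTables, config: SimulationConfig) -> SimulatedReads:
    """Emit barcode/payload read pairs for both libraries.

    RNA barcode reads are BC1 + linker (length drawn from the allowed set) +
    BC2 + linker + sample BC + UMI, padded into the payload; gDNA reads omit
    the sample BC and UMI.  Payload reads are reference prefixes carrying
    the constituent's allele at the variant position.  PCR duplicates share
    a UMI and molecule id.  With probability ``ambient_fraction`` a read is
    re-barcoded to a uniformly drawn other droplet (ambient contamination).
    """
    assay = truth.assay
    rng = np.random.default_rng([config.seed % (2**31), 37])
    l1 = assay.schema_rna.segment("linker1").fixed_sequences
    l2seq = assay.schema_rna.segment("linker2").fixed_sequences[15]
    l1_lengths = sorted(l1)
    droplet_bcs = list(zip(truth.droplets["bc1"], truth.droplets["bc2"]))
    cons_droplet = dict(zip(truth.constituents["constituent_id"], truth.constituents["droplet_id"]))

    ref_by_name = {r.target_name: r.sequence for r in assay.references}
    amp_variant: dict[str, tuple[str, int]] = {}  # amplicon -> (vid, offset)
    for vid, amp in assay.variant_amplicon.items():
        amp_variant[amp] = (vid, assay.variant_offsets[vid])

    pool_by_cons_variant = {
        (r.constituent_id, r.variant): r.allele_pool for r in truth.genotypes.itertuples()
    }

    gdna_reads: list[tuple[str, str, str]] = []
    rna_reads: list[tuple[str, str, str]] = []
    prov: list[dict] = []
    read_no = 0
    molecule_no = 0

    def emit(modality, source_cons, bc1, bc2, sample_bc, umi, target, mol_id, payload_seq):
        nonlocal read_no
        read_no += 1
        rid = f"{'g' if modality == 'gDNA' else 'r'}{read_no:08d}"
        # ambient: molecule re-barcoded to a random other droplet
        is_ambient = rng.random() < config.ambient_fraction
        if is_ambient:
            j = int(rng.integers(0, len(droplet_bcs)))
            bc1, bc2 = droplet_bcs[j]
        linker_len = l1_lengths[int(rng.integers(0, len(l1_lengths)))]
        parts = [bc1, l1[linker_len], bc2, l2seq]
        if modality == "RNA":
            parts += [sample_bc, umi]
        backbone = "".join(parts)
        r1_clean = (backbone + payload_seq)[: config.r1_length]
        r2_clean = payload_seq[: config.r2_length]
        r1, ev1 = inject_errors(r1_clean, config.sub_rate, config.ins_rate, config.del_rate, rng)
        r2, ev2 = inject_errors(r2_clean, config.sub_rate, config.ins_rate, config.del_rate, rng)
        rec = (rid, r1, r2)
        (gdna_reads if modality == "gDNA" else rna_reads).append(rec)
        prov.append(
            {"read_id": rid, "modality": modality, "constituent_id": source_cons,
             "cell_bc": bc1 + bc2, "sample_bc": sample_bc or "", "umi": umi or "",
             "target": target, "molecule_id": mol_id, "is_ambient": is_ambient,
             "n_errors": len(ev1) + len(ev2)}
        )

    for cons in truth.constituents.itertuples():
        # gDNA: reads drawn directly from the allele pool of each amplicon
        for target in (t for t in assay.panel if t.modality == "gDNA"):
            ref = ref_by_name[target.name]
            vid, offset = amp_variant[target.name]
            pool = pool_by_cons_variant[(cons.constituent_id, vid)]
            alt_base = assay.variants[vid].alt
            n_reads = int(rng.poisson(config.mean_gdna_reads_per_amplicon))
            for _ in range(n_reads):
                allele = pool[int(rng.integers(0, len(pool)))]
                seq = ref if allele == "ref" else ref[:offset] + alt_base + ref[offset + 1 :]
                molecule_no += 1
                emit("gDNA", cons.constituent_id, cons.cell_bc[: config.bc_length],
                     cons.cell_bc[config.bc_length :], None, None, target.name,
                     molecule_no, seq)
    rna_ref = {r.target_name: r.sequence for r in assay.references_rna}
    for mol in truth.rna_counts.itertuples():
        ref = rna_ref[mol.gene]
        for _ in range(mol.n_molecules):
            molecule_no += 1
            umi = _random_seq(rng, config.umi_length)
            n_reads = 1 + int(rng.poisson(max(config.mean_reads_per_molecule - 1.0, 0.0)))
            for _ in range(n_reads):
                emit("RNA", mol.constituent_id, mol.cell_bc[: config.bc_length],
                     mol.cell_bc[config.bc_length :], mol.sample_bc, umi, mol.gene,
                     molecule_no, ref)
    return SimulatedReads(gdna=gdna_reads, rna=rna_reads, provenance=pd.DataFrame(prov))


def write_fastq_pair(prefix, reads: Sequence[tuple[str, str, str]]) -> tuple[Path, Path]:
    """Write (read_id, R1, R2) triples as a gzipped FASTQ pair with constant
    'I' qualities."""
    p1, p2 = Path(f"{prefix}_R1.fastq.gz"), Path(f"{prefix}_R2.fastq.gz")
    with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
        for rid, r1, r2 in reads:
            f1.write(f"@{rid}\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}\n{r2}\n+\n{'I' * len(r2)}\n")
    return p1, p2


def expected_counts(
    truth: TruthTables, reads: SimulatedReads
) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str, str], dict[str, int]]]:
    """Truth-side tallies from per-read provenance.

    Returns (gDNA read counts per (cell_bc, target), RNA UMI read-count
    multisets per (cell_bc, sample_bc, gene)).  Cell assignment follows the
    barcode each read carries (ambient reads count toward their recipient
    droplet); the RNA multisets are the input to any UMI-collapse rule.
    """
    gdna: dict[tuple[str, str], int] = {}
    rna: dict[tuple[str, str, str], dict[str, int]] = {}
    for row in reads.provenance.itertuples():
        if row.modality == "gDNA":
            key = (row.cell_bc, row.target)
            gdna[key] = gdna.get(key, 0) + 1
        else:
            group = rna.setdefault((row.cell_bc, row.sample_bc, row.target), {})
            group[row.umi] = group.get(row.umi, 0) + 1
    return gdna, rna


# ---------------------------------------------------------------------------
# Fixture genotype caller


def _base_at_offset(payload: str, reference: str, offset: int) -> str | None:
    """Base of ``payload`` aligned over reference position ``offset`` (None
    when the position is deleted or past the aligned prefix)."""
    res = edlib.align(payload, reference, mode="SHW", task="path")
    qpos = tpos = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            if tpos <= offset < tpos + n:
                return payload[qpos + (offset - tpos)]
            qpos += n
            tpos += n
        elif ch == "I":
            qpos += n
        elif ch == "D":
            if tpos <= offset < tpos + n:
                return None
            tpos += n
    return None


def _genotype_quality(n_ref: int, n_alt: int, error: float = 0.02) -> int:
    """Phred-scaled gap between the best and second-best diploid genotype
    likelihoods under a symmetric allele-error model."""
    logls = [
        n_ref * math.log10(1 - error) + n_alt * math.log10(error),  # hom ref
        (n_ref + n_alt) * math.log10(0.5),  # het
        n_ref * math.log10(error) + n_alt * math.log10(1 - error),  # hom alt
    ]
    ordered = sorted(logls, reverse=True)
    return min(99, int(round(10.0 * (ordered[0] - ordered[1]))))


def call_genotypes_naive(
    gdna_reads: Iterable[tuple[str, str, str]],
    references: Mapping[str, str],
    variants: Mapping[str, VariantKey],
    variant_offsets: Mapping[str, int],
    variant_amplicon: Mapping[str, str],
    min_alt_reads: int = 3,
    min_alt_frac: float = 0.1,
    hom_alt_frac: float = 0.9,
) -> pd.DataFrame:
    """Naive allele-count diploid caller over (cell_bc, target, payload)
    triples.  Emits one row per (cell, variant) with alt evidence of at
    least ``min_alt_reads`` reads and ``min_alt_frac`` fraction; HET below
    ``hom_alt_frac``, ALT at or above it.  Cells without alt evidence are
    left uncalled (wild-type inclusion is downstream work).
    """
    by_amplicon: dict[str, list[str]] = {}
    for vid, amp in variant_amplicon.items():
        by_amplicon.setdefault(amp, []).append(vid)
    counts: dict[tuple[str, str], list[int]] = {}
    for cell_bc, target, payload in gdna_reads:
        for vid in by_amplicon.get(target, ()):
            base = _base_at_offset(payload, references[target], variant_offsets[vid])
            if base is None:
                continue
            acc = counts.setdefault((cell_bc, vid), [0, 0])
            if base == variants[vid].ref:
                acc[0] += 1
            elif base == variants[vid].alt:
                acc[1] += 1
    rows = []
    for (cell_bc, vid), (n_ref, n_alt) in sorted(counts.items()):
        depth = n_ref + n_alt
        if depth == 0 or n_alt < min_alt_reads or n_alt / depth < min_alt_frac:
            continue
        gt = "1/1" if n_alt / depth >= hom_alt_frac else "0/1"
        rows.append(
            {"cell_bc": cell_bc, "variant": vid, "gt": gt, "dp": depth,
             "gq": _genotype_quality(n_ref, n_alt), "ad_ref": n_ref, "ad_alt": n_alt}
        )
    return pd.DataFrame(rows, columns=["cell_bc", "variant", "gt", "dp", "gq", "ad_ref", "ad_alt"])


def write_merged_vcf(
    path,
    calls: pd.DataFrame,
    variants: Mapping[str, VariantKey],
    cells: Sequence[str],
) -> None:
    """Write naive-caller output as a merged VCF with one sample column per
    cell; cells without a call are ./. (uncalled, not wild-type)."""
    by_cell_variant = {
        (r.cell_bc, r.variant): r for r in calls.itertuples()
    } if len(calls) else {}
    chroms = sorted({k.chrom for k in variants.values()})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sdrkit-naive-caller\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cells) + "\n")
        for vid, key in sorted(variants.items(), key=lambda kv: kv[1]):
            fields = [key.chrom, str(key.pos), ".", key.ref, key.alt, ".", "PASS", ".", "GT:DP:GQ:AD"]
            for cell in cells:
                rec = by_cell_variant.get((cell, vid))
                if rec is None:
                    fields.append("./.")
                else:
                    fields.append(f"{rec.gt}:{rec.dp}:{rec.gq}:{rec.ad_ref},{rec.ad_alt}")
            fh.write("\t".join(fields) + "\n")
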