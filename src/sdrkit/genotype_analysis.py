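"""Per-cell genotype matrix construction, filtering and analytics.

A merged multi-sample VCF (one sample column per cell barcode) is turned
into a cells x variants matrix of diploid calls (REF / HET / ALT / missing)
with depth, genotype quality, allele depths and variant allele frequency
(VAF).  Wild-type (homozygous reference) entries are filled in for uncalled
cells with sufficient amplicon read depth; entries are then masked on
depth/quality, low-frequency variants dropped, and the matrix feeds
allelic-dropout (ADO) and noise estimation, per-cell variant burden and
state-wise differential abundance testing.

Fixed pipeline order: ingest -> include_wildtype -> apply_quality_filters ->
remove_low_frequency_variants.  Each stage is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .quantify_qc import CountMatrix

__all__ = [
    "VariantKey",
    "GenotypeMatrix",
    "GenotypeError",
    "REF", "HET", "ALT", "MISSING",
    "ingest_merged_vcf",
    "map_variants_to_amplicons",
    "include_wildtype",
    "apply_quality_filters",
    "remove_low_frequency_variants",
    "estimate_ado",
    "estimate_variant_noise",
    "variant_burden",
    "differential_abundance",
]

MISSING, REF, HET, ALT = -1, 0, 1, 2
CALL_NAMES = {MISSING: "missing", REF: "REF", HET: "HET", ALT: "ALT"}


class GenotypeError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class VariantKey:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise GenotypeError("alleles must be non-empty")
        if self.ref == self.alt:
            raise GenotypeError("ref and alt must differ")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def variant_class(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "substitution"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"


@dataclass
class GenotypeMatrix:
    """Cells x variants grid of genotype calls with per-entry DP/GQ/AD.

    All frames share the same index (cell barcodes) and columns (variant
    keys as strings).  GQ is NaN where the caller provided none (e.g.
    wild-type entries included from amplicon depth alone).
    """

    variants: dict[str, VariantKey]
    calls: pd.DataFrame  # int codes MISSING/REF/HET/ALT
    dp: pd.DataFrame  # float, NaN where no data
    gq: pd.DataFrame
    ad_ref: pd.DataFrame
    ad_alt: pd.DataFrame
    annotations: pd.DataFrame | None = None  # per-variant pass-through text

    @property
    def cells(self) -> list[str]:
        return list(self.calls.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def vaf(self) -> pd.DataFrame:
        """Alt reads / (ref + alt reads); NaN at zero allele-informative depth."""
        denom = self.ad_ref + self.ad_alt
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return self.ad_alt / denom.where(denom > 0)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dict(self.variants), self.calls.copy(), self.dp.copy(), self.gq.copy(),
            self.ad_ref.copy(), self.ad_alt.copy(),
            None if self.annotations is None else self.annotations.copy(),
        )

    def n_nonmissing(self) -> int:
        return int((self.calls.values != MISSING).sum())


def _gt_to_call(alleles: tuple, alt_index: int) -> int:
    if any(a is None for a in alleles) or not alleles:
        return MISSING
    k = sum(1 for a in alleles if a == alt_index)
    return (REF, HET, ALT)[min(k, 2)]


def ingest_merged_vcf(path, cells: Sequence[str]) -> GenotypeMatrix:
    """Read a merged per-cell VCF into a genotype matrix.

    Sample names must be cell barcodes; only samples in ``cells`` are kept.
    Multi-allelic records are split into one variant per alternate allele.
    Cells with no record at a variant are missing (wild-type inclusion is a
    separate, later step).
    """
    import pysam

    cells = list(cells)
    cell_set = set(cells)
    variants: dict[str, VariantKey] = {}
    columns: dict[str, dict[str, tuple]] = {}  # vid -> cell -> (call, dp, gq, adr, ada)
    with pysam.VariantFile(str(path)) as vcf:
        vcf_cells = [s for s in vcf.header.samples if s in cell_set]
        for rec in vcf:
            alts = rec.alts or ()
            for k, alt in enumerate(alts, start=1):
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                vid = str(key)
                variants.setdefault(vid, key)
                col = columns.setdefault(vid, {})
                for cell in vcf_cells:
                    smp = rec.samples[cell]
                    gt = smp.get("GT")
                    if gt is None or all(a is None for a in gt):
                        continue
                    call = _gt_to_call(tuple(gt), k)
                    dp = smp.get("DP")
                    gq = smp.get("GQ")
                    ad = smp.get("AD")
                    adr = ad[0] if ad and ad[0] is not None else np.nan
                    ada = ad[k] if ad and len(ad) > k and ad[k] is not None else np.nan
                    col[cell] = (
                        call,
                        np.nan if dp is None else float(dp),
                        np.nan if gq is None else float(gq),
                        float(adr) if adr == adr else np.nan,
                        float(ada) if ada == ada else np.nan,
                    )
    vids = sorted(variants, key=lambda v: variants[v])
    shape = (len(cells), len(vids))
    calls = pd.DataFrame(np.full(shape, MISSING, dtype=np.int64), index=cells, columns=vids)
    dp = pd.DataFrame(np.full(shape, np.nan), index=cells, columns=vids)
    gq = dp.copy()
    ad_ref = dp.copy()
    ad_alt = dp.copy()
    for vid in vids:
        for cell, (call, d, q, ar, aa) in columns[vid].items():
            calls.at[cell, vid] = call
            dp.at[cell, vid] = d
            gq.at[cell, vid] = q
            ad_ref.at[cell, vid] = ar
            ad_alt.at[cell, vid] = aa
    return GenotypeMatrix({v: variants[v] for v in vids}, calls, dp, gq, ad_ref, ad_alt)


def map_variants_to_amplicons(
    variants: Mapping[str, VariantKey], panel
) -> dict[str, str]:
    """Map each variant to the amplicon whose genomic span contains it.

    VCF positions are 1-based; panel spans are 0-based half-open.
    """
    mapping = {}
    for vid, key in variants.items():
        hit = None
        for target in panel:
            if target.modality != "gDNA" or target.chrom != key.chrom:
                continue
            if target.start <= key.pos - 1 < target.end:
                hit = target.name
                break
        if hit is None:
            raise GenotypeError(f"variant {vid} maps to no gDNA amplicon in the panel")
        mapping[vid] = hit
    return mapping


def include_wildtype(
    matrix: GenotypeMatrix,
    gdna_reads: CountMatrix,
    variant_to_amplicon: Mapping[str, str],
    dp_min: int = 10,
) -> GenotypeMatrix:
    """Fill uncalled (cell, variant) entries with homozygous-reference calls
    when the covering amplicon has read depth >= ``dp_min`` in that cell.

    Existing calls are never overwritten; depth below ``dp_min`` stays
    missing.  Included entries carry the amplicon depth as DP, AD =
    (depth, 0) and no GQ.
    """
    out = matrix.copy()
    depth = pd.DataFrame.sparse.from_spmatrix(
        gdna_reads.m, index=gdna_reads.rows, columns=gdna_reads.cols
    ).sparse.to_dense()
    for vid in out.variant_ids:
        amplicon = variant_to_amplicon.get(vid)
        if amplicon is None:
            raise GenotypeError(f"variant {vid} has no amplicon mapping")
        if amplicon not in depth.columns:
            continue
        col = depth[amplicon].reindex(out.cells).fillna(0)
        fill = (out.calls[vid] == MISSING) & (col >= dp_min)
        out.calls.loc[fill, vid] = REF
        out.dp.loc[fill, vid] = col[fill]
        out.ad_ref.loc[fill, vid] = col[fill]
        out.ad_alt.loc[fill, vid] = 0.0
    return out


def apply_quality_filters(
    matrix: GenotypeMatrix, dp_min: int = 10, gq_min: int = 30
) -> GenotypeMatrix:
    """Mask entries with DP < dp_min or (where GQ is present) GQ < gq_min.

    Boundaries are inclusive on the keep side: DP = dp_min and GQ = gq_min
    are retained.  Missing DP counts as failing.
    """
    out = matrix.copy()
    called = out.calls.values != MISSING
    dp_ok = (out.dp.values >= dp_min)  # NaN compares False -> masked
    gq = out.gq.values
    gq_ok = np.isnan(gq) | (gq >= gq_min)
    mask = called & ~(dp_ok & gq_ok)
    out.calls = out.calls.mask(
        pd.DataFrame(mask, index=out.calls.index, columns=out.calls.columns), MISSING
    )
    return out


def remove_low_frequency_variants(
    matrix: GenotypeMatrix, min_frac: float = 0.0, min_cells: int = 0
) -> GenotypeMatrix:
    """Drop variants with non-reference (HET + ALT) support below a cell
    fraction (among non-missing entries) or an absolute cell count."""
    if not (0.0 <= min_frac <= 1.0):
        raise GenotypeError("min_frac must be within [0, 1]")
    keep = []
    for vid in matrix.variant_ids:
        col = matrix.calls[vid].values
        nonmissing = int((col != MISSING).sum())
        nonref = int(((col == HET) | (col == ALT)).sum())
        frac = nonref / nonmissing if nonmissing else 0.0
        if frac >= min_frac and nonref >= min_cells:
            keep.append(vid)
    out = matrix.copy()
    out.variants = {v: out.variants[v] for v in keep}
    out.calls = out.calls[keep]
    out.dp = out.dp[keep]
    out.gq = out.gq[keep]
    out.ad_ref = out.ad_ref[keep]
    out.ad_alt = out.ad_alt[keep]
    if out.annotations is not None:
        out.annotations = out.annotations.loc[out.annotations.index.isin(keep)]
    return out


def estimate_ado(
    matrix: GenotypeMatrix,
    known_het_variants: Sequence[str],
    detection_min: float = 0.8,
) -> tuple[pd.DataFrame, float]:
    """Estimate allelic dropout at known-heterozygous variants.

    Per variant: het_call_rate = HET calls / non-missing calls, ado = 1 -
    het_call_rate, n_covered = non-missing calls.  The summary ADO is the
    mean over variants detected (non-missing) in more than ``detection_min``
    of cells; variants with zero non-missing calls are excluded with a
    warning.
    """
    unknown = set(known_het_variants) - set(matrix.variant_ids)
    if unknown:
        raise GenotypeError(f"unknown variants: {sorted(unknown)}")
    rows = []
    n_cells = len(matrix.cells)
    for vid in known_het_variants:
        col = matrix.calls[vid].values
        covered = int((col != MISSING).sum())
        if covered == 0:
            warnings.warn(f"variant {vid}: no non-missing calls; excluded from ADO")
            continue
        het_rate = int((col == HET).sum()) / covered
        rows.append(
            {
                "variant": vid,
                "het_call_rate": het_rate,
                "ado": 1.0 - het_rate,
                "n_covered": covered,
                "detection": covered / n_cells if n_cells else 0.0,
            }
        )
    table = pd.DataFrame(rows, columns=["variant", "het_call_rate", "ado", "n_covered", "detection"])
    well_covered = table[table["detection"] > detection_min]
    summary = float(well_covered["ado"].mean()) if len(well_covered) else float("nan")
    return table, summary


def estimate_variant_noise(
    matrix: GenotypeMatrix, expected_ref_variants: Sequence[str]
) -> tuple[pd.DataFrame, float]:
    """Noise rate at loci expected homozygous-reference: non-REF calls /
    non-missing calls, stratified by (reference base, variant class).

    Returns the per-stratum table (with per-variant counts aggregated) and
    the overall rate.  The weighted sum of stratum rates equals the overall
    rate by construction.
    """
    unknown = set(expected_ref_variants) - set(matrix.variant_ids)
    if unknown:
        raise GenotypeError(f"unknown variants: {sorted(unknown)}")
    per_stratum: dict[tuple[str, str], list[int]] = {}
    total_nonref = total_calls = 0
    for vid in expected_ref_variants:
        key = matrix.variants[vid]
        col = matrix.calls[vid].values
        nonmissing = int((col != MISSING).sum())
        nonref = int(((col == HET) | (col == ALT)).sum())
        stratum = (key.ref[0], key.variant_class)
        acc = per_stratum.setdefault(stratum, [0, 0])
        acc[0] += nonref
        acc[1] += nonmissing
        total_nonref += nonref
        total_calls += nonmissing
    rows = [
        {
            "ref_base": base,
            "variant_class": cls,
            "n_nonref": nonref,
            "n_calls": calls,
            "noise_rate": nonref / calls if calls else float("nan"),
        }
        for (base, cls), (nonref, calls) in sorted(per_stratum.items())
    ]
    table = pd.DataFrame(rows, columns=["ref_base", "variant_class", "n_nonref", "n_calls", "noise_rate"])
    overall = total_nonref / total_calls if total_calls else float("nan")
    return table, overall


def variant_burden(
    matrix: GenotypeMatrix, hi: float = 0.2, lo: float = 0.2
) -> pd.DataFrame:
    """Per-cell variant burden (count of HET + ALT calls) with strata:
    top ``hi`` fraction "high", bottom ``lo`` fraction "low", rest "mid".

    Ties resolve by rank under stable cell ordering.  If every cell has the
    same burden, all cells are "mid" (with a warning).
    """
    calls = matrix.calls.values
    burden = ((calls == HET) | (calls == ALT)).sum(axis=1)
    df = pd.DataFrame({"cell": matrix.cells, "burden": burden})
    df["stratum"] = "mid"
    n = len(df)
    if n == 0:
        return df
    if df["burden"].nunique() == 1:
        warnings.warn("all cells have equal variant burden; no high/low strata")
        return df
    order = df.sort_values("burden", kind="stable").index
    n_lo = int(n * lo)
    n_hi = int(n * hi)
    if n_lo:
        df.loc[order[:n_lo], "stratum"] = "low"
    if n_hi:
        df.loc[order[n - n_hi :], "stratum"] = "high"
    return df


def differential_abundance(
    matrix: GenotypeMatrix,
    cell_states: Mapping[str, str],
    states: tuple[str, str],
    allele: str = "any",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test per-variant allele-carrier abundance between two cell states.

    For each variant a 2x2 table (allele carrier / non-carrier x state) over
    non-missing cells is tested with a Pearson chi-squared test (no
    continuity correction); p-values are Benjamini-Hochberg adjusted over
    all tested variants.  ``allele`` selects the carrier definition: "HET",
    "ALT", or "any" (HET or ALT).  delta is the carrier percentage in
    ``states[0]`` minus ``states[1]``, in percentage points.  Variants with
    an empty table margin are skipped and reported with NaN statistics.
    """
    s1, s2 = states
    cells1 = [c for c in matrix.cells if cell_states.get(c) == s1]
    cells2 = [c for c in matrix.cells if cell_states.get(c) == s2]
    if not cells1 or not cells2:
        raise GenotypeError(f"both states must be non-empty: {s1!r}, {s2!r}")
    if allele == "HET":
        carrier_codes = (HET,)
    elif allele == "ALT":
        carrier_codes = (ALT,)
    elif allele == "any":
        carrier_codes = (HET, ALT)
    else:
        raise GenotypeError(f"unknown allele class {allele!r}")
    rows = []
    for vid in matrix.variant_ids:
        col = matrix.calls[vid]
        g1 = col.loc[cells1].values
        g2 = col.loc[cells2].values
        g1 = g1[g1 != MISSING]
        g2 = g2[g2 != MISSING]
        a = int(np.isin(g1, carrier_codes).sum())
        b = len(g1) - a
        c = int(np.isin(g2, carrier_codes).sum())
        d = len(g2) - c
        table = np.array([[a, b], [c, d]], dtype=float)
        row = {"variant": vid, "n_state1": len(g1), "n_state2": len(g2),
               "carriers_state1": a, "carriers_state2": c}
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            row.update({"chi2": np.nan, "p": np.nan, "delta": np.nan, "tested": False})
        else:
            chi2, p, _, _ = chi2_contingency(table, correction=False)
            delta = 100.0 * (a / (a + b) - c / (c + d))
            row.update({"chi2": chi2, "p": p, "delta": delta, "tested": True})
        rows.append(row)
    result = pd.DataFrame(rows)
    result["q"] = np.nan
    tested = result["tested"].fillna(False).astype(bool)
    if tested.any():
        _, q, _, _ = multipletests(result.loc[tested, "p"].values, method="fdr_bh")
        result.loc[tested, "q"] = q
    result["significant"] = result["q"] < alpha
    return result
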