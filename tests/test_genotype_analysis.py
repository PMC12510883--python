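import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2 as chi2_dist

from oracles import bh_adjust_brute, chi2_2x2
from sdrkit.barcode_schema import AmpliconTarget
from sdrkit.genotype_analysis import (
    ALT,
    HET,
    MISSING,
    REF,
    GenotypeError,
    GenotypeMatrix,
    VariantKey,
    apply_quality_filters,
    differential_abundance,
    estimate_ado,
    estimate_variant_noise,
    include_wildtype,
    ingest_merged_vcf,
    map_variants_to_amplicons,
    remove_low_frequency_variants,
    variant_burden,
)
from sdrkit.quantify_qc import CountMatrix

TOY_VCF = """##fileformat=VCFv4.2
##contig=<ID=chrS>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tCELL1\tCELL2
chrS\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ:AD\t0/1:30:99:14,16\t1/1:25:80:0,25
chrS\t200\t.\tC\tT\t.\tPASS\t.\tGT:DP:GQ:AD\t0/0:40:99:40,0\t./.
chrS\t300\t.\tA\tC,T\t.\tPASS\t.\tGT:DP:GQ:AD\t1/2:22:50:2,10,10\t0/1:18:40:9,9,0
"""


@pytest.fixture
def toy_matrix(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(TOY_VCF)
    return ingest_merged_vcf(vcf, ["CELL1", "CELL2"])


class TestIngest:
    def test_calls_map_gt_codes(self, toy_matrix):
        gm = toy_matrix
        assert gm.calls.at["CELL1", "chrS:100:A>G"] == HET
        assert gm.calls.at["CELL2", "chrS:100:A>G"] == ALT
        assert gm.calls.at["CELL1", "chrS:200:C>T"] == REF
        assert gm.calls.at["CELL2", "chrS:200:C>T"] == MISSING

    def test_multiallelic_split_into_two_variants(self, toy_matrix):
        gm = toy_matrix
        assert "chrS:300:A>C" in gm.variant_ids and "chrS:300:A>T" in gm.variant_ids
        # 1/2 carries one copy of each alt
        assert gm.calls.at["CELL1", "chrS:300:A>C"] == HET
        assert gm.calls.at["CELL1", "chrS:300:A>T"] == HET
        assert gm.calls.at["CELL2", "chrS:300:A>C"] == HET
        assert gm.calls.at["CELL2", "chrS:300:A>T"] == REF

    def test_format_fields_copied_and_vaf(self, toy_matrix):
        gm = toy_matrix
        assert gm.dp.at["CELL1", "chrS:100:A>G"] == 30
        assert gm.gq.at["CELL2", "chrS:100:A>G"] == 80
        assert gm.vaf.at["CELL1", "chrS:100:A>G"] == pytest.approx(16 / 30)
        assert np.isnan(gm.vaf.at["CELL2", "chrS:200:C>T"])


def _matrix(calls, dp=None, gq=None):
    cells = [f"C{i}" for i in range(len(calls))]
    vids = [f"chrS:{100+i}:A>G" for i in range(len(calls[0]))]
    variants = {v: VariantKey("chrS", 100 + i, "A", "G") for i, v in enumerate(vids)}
    calls_df = pd.DataFrame(calls, index=cells, columns=vids)
    mk = lambda vals, default: pd.DataFrame(
        vals if vals is not None else np.full(calls_df.shape, default, dtype=float),
        index=cells, columns=vids,
    )
    return GenotypeMatrix(
        variants, calls_df, mk(dp, 50.0), mk(gq, 99.0),
        mk(None, 25.0), mk(None, 25.0),
    )


class TestWildtypeInclusion:
    def _setup(self):
        gm = _matrix([[MISSING], [MISSING], [HET]])
        gdna = CountMatrix.from_counts(
            "gDNA", {("C0", "amp0"): 50, ("C1", "amp0"): 9, ("C2", "amp0"): 40}
        )
        return gm, gdna, {gm.variant_ids[0]: "amp0"}

    def test_deep_uncalled_becomes_ref(self):
        gm, gdna, vmap = self._setup()
        out = include_wildtype(gm, gdna, vmap, dp_min=10)
        assert out.calls.at["C0", gm.variant_ids[0]] == REF
        assert out.dp.at["C0", gm.variant_ids[0]] == 50

    def test_shallow_uncalled_stays_missing(self):
        gm, gdna, vmap = self._setup()
        out = include_wildtype(gm, gdna, vmap, dp_min=10)
        assert out.calls.at["C1", gm.variant_ids[0]] == MISSING

    def test_existing_calls_not_overwritten(self):
        gm, gdna, vmap = self._setup()
        out = include_wildtype(gm, gdna, vmap, dp_min=10)
        assert out.calls.at["C2", gm.variant_ids[0]] == HET

    def test_unmapped_variant_is_config_error(self):
        gm, gdna, _ = self._setup()
        with pytest.raises(GenotypeError):
            include_wildtype(gm, gdna, {}, dp_min=10)

    def test_variant_to_amplicon_uses_coordinates(self):
        panel = [AmpliconTarget("amp0", "gDNA", "chrS", 40, 200, "+", "AA", "TT")]
        vmap = map_variants_to_amplicons(
            {"chrS:100:A>G": VariantKey("chrS", 100, "A", "G")}, panel
        )
        assert vmap == {"chrS:100:A>G": "amp0"}


class TestQualityFilters:
    @pytest.mark.parametrize(
        "dp,gq,expect",
        [(9, 99, MISSING), (50, 29, MISSING), (10, 30, HET), (50, 99, HET)],
    )
    def test_boundaries(self, dp, gq, expect):
        gm = _matrix([[HET]], dp=[[float(dp)]], gq=[[float(gq)]])
        out = apply_quality_filters(gm, dp_min=10, gq_min=30)
        assert out.calls.iat[0, 0] == expect

    def test_missing_gq_passes_gq_filter(self):
        gm = _matrix([[REF]], dp=[[50.0]], gq=[[np.nan]])
        out = apply_quality_filters(gm)
        assert out.calls.iat[0, 0] == REF

    def test_raising_thresholds_never_recovers_entries(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([REF, HET, ALT], size=(30, 5))
        dp = rng.integers(0, 60, size=(30, 5)).astype(float)
        gq = rng.integers(0, 100, size=(30, 5)).astype(float)
        gm = _matrix(calls, dp=dp, gq=gq)
        prev = None
        for dp_min in (0, 5, 10, 20, 40):
            out = apply_quality_filters(gm, dp_min=dp_min, gq_min=30)
            n = out.n_nonmissing()
            if prev is not None:
                assert n <= prev
            prev = n

    def test_idempotent(self):
        gm = _matrix([[HET, REF], [ALT, MISSING]], dp=[[9, 50], [50, 50]])
        once = apply_quality_filters(gm)
        twice = apply_quality_filters(once)
        assert once.calls.equals(twice.calls)


class TestLowFrequencyRemoval:
    def test_sub_threshold_fraction_dropped(self):
        calls = [[HET] if i < 2 else [REF] for i in range(1000)]
        gm = _matrix(calls)
        out = remove_low_frequency_variants(gm, min_frac=0.003)
        assert out.variant_ids == []

    def test_min_cells_rule(self):
        calls = [[HET] if i < 40 else [REF] for i in range(100)]
        gm = _matrix(calls)
        assert remove_low_frequency_variants(gm, min_cells=30).variant_ids == gm.variant_ids
        calls = [[HET] if i < 29 else [REF] for i in range(100)]
        gm = _matrix(calls)
        assert remove_low_frequency_variants(gm, min_cells=30).variant_ids == []

    def test_zero_thresholds_identity(self):
        gm = _matrix([[HET, REF], [REF, REF]])
        out = remove_low_frequency_variants(gm, min_frac=0.0, min_cells=0)
        assert out.calls.equals(gm.calls)


class TestHandCountedFilterTable:
    """A 20-entry hand-written genotype table with exact expected masking
    and variant-dropping counts."""

    def test_exact_masked_and_dropped_counts(self):
        # 10 cells x 2 variants; DP/GQ chosen so that exactly 6 entries fail
        # DP<10 or GQ<30 (hand count below)
        dp = [
            [50, 9],   # v2 fail
            [8, 50],   # v1 fail
            [50, 50],
            [50, 29],  # v2 fail (GQ)
            [9, 9],    # both fail
            [50, 50],
            [10, 30],  # both at boundary: keep
            [50, 50],
            [50, 8],   # v2 fail
            [50, 50],
        ]
        gq = [
            [99, 99], [99, 99], [99, 99], [99, 29], [99, 99],
            [99, 99], [30, 30], [99, 99], [99, 99], [99, 99],
        ]
        calls = [[HET, HET]] * 10
        gm = _matrix(calls, dp=[[float(x) for x in row] for row in dp],
                     gq=[[float(x) for x in row] for row in gq])
        out = apply_quality_filters(gm, dp_min=10, gq_min=30)
        masked = (out.calls.values == MISSING).sum()
        assert masked == 6  # hand count: rows 0,1,3,4(x2),8

        # variant dropping: v1 has 9 HET of 9 non-missing (kept), v2 has
        # 6 HET of 6 (kept); with min_cells=30 both drop
        dropped = remove_low_frequency_variants(out, min_frac=0.003, min_cells=0)
        assert len(dropped.variant_ids) == 2
        dropped = remove_low_frequency_variants(out, min_cells=30)
        assert len(dropped.variant_ids) == 0


class TestAdoAndNoise:
    def test_all_het_gives_zero_ado(self):
        gm = _matrix([[HET]] * 100)
        table, summary = estimate_ado(gm, gm.variant_ids)
        assert table["ado"].iloc[0] == 0.0 and summary == 0.0

    def test_hand_computed_het_rate(self):
        calls = [[HET]] * 90 + [[REF]] * 5 + [[ALT]] * 3 + [[MISSING]] * 2
        gm = _matrix(calls)
        table, _ = estimate_ado(gm, gm.variant_ids)
        assert table["het_call_rate"].iloc[0] == pytest.approx(90 / 98)
        assert table["n_covered"].iloc[0] == 98

    def test_uncovered_variant_excluded_with_warning(self):
        gm = _matrix([[MISSING], [MISSING]])
        with pytest.warns(UserWarning):
            table, summary = estimate_ado(gm, gm.variant_ids)
        assert len(table) == 0 and np.isnan(summary)

    def test_zero_error_noise_is_zero(self):
        gm = _matrix([[REF, REF]] * 50)
        table, overall = estimate_variant_noise(gm, gm.variant_ids)
        assert overall == 0.0
        assert (table["noise_rate"] == 0).all()

    def test_stratified_rates_reconstruct_overall(self):
        rng = np.random.default_rng(8)
        calls = rng.choice([REF, REF, REF, REF, HET, MISSING], size=(200, 4))
        gm = _matrix(calls)
        table, overall = estimate_variant_noise(gm, gm.variant_ids)
        weighted = (table["noise_rate"] * table["n_calls"]).sum() / table["n_calls"].sum()
        assert weighted == pytest.approx(overall)


class TestBurden:
    def test_quantile_strata_on_distinct_burdens(self):
        calls = [[HET] * b + [REF] * (9 - b) for b in range(10)]
        gm = _matrix(calls)
        df = variant_burden(gm, hi=0.2, lo=0.2)
        strata = dict(zip(df["cell"], df["stratum"]))
        assert [strata[f"C{i}"] for i in (0, 1)] == ["low", "low"]
        assert [strata[f"C{i}"] for i in (8, 9)] == ["high", "high"]
        assert all(strata[f"C{i}"] == "mid" for i in range(2, 8))

    def test_equal_burdens_all_mid_with_warning(self):
        gm = _matrix([[HET]] * 5)
        with pytest.warns(UserWarning):
            df = variant_burden(gm)
        assert (df["stratum"] == "mid").all()

    def test_empty_matrix(self):
        gm = _matrix([[HET]])
        gm.calls = gm.calls.iloc[:0]
        df = variant_burden(gm)
        assert len(df) == 0


class TestDifferentialAbundance:
    def _states(self, n1, n2):
        return {f"C{i}": ("DZ" if i < n1 else "LZ") for i in range(n1 + n2)}

    def test_identical_proportions_give_zero_chi2(self):
        calls = [[HET] if i % 2 else [REF] for i in range(40)]
        gm = _matrix(calls)
        states = {f"C{i}": ("DZ" if i < 20 else "LZ") for i in range(40)}
        res = differential_abundance(gm, states, ("DZ", "LZ"))
        assert res["chi2"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_chi2_matches_closed_form(self):
        # 30 carriers / 70 non in DZ; 60 / 40 in LZ
        calls = [[HET]] * 30 + [[REF]] * 70 + [[HET]] * 60 + [[REF]] * 40
        gm = _matrix(calls)
        states = self._states(100, 100)
        res = differential_abundance(gm, states, ("DZ", "LZ"))
        expected = chi2_2x2(30, 70, 60, 40)
        assert res["chi2"].iloc[0] == pytest.approx(expected, abs=1e-9)
        assert res["delta"].iloc[0] == pytest.approx(-30.0)
        assert res["p"].iloc[0] == pytest.approx(chi2_dist.sf(expected, 1))

    def test_bh_adjustment_matches_step_up(self):
        rng = np.random.default_rng(17)
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(int(rng.integers(1, 100)))
            _, q, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(q, bh_adjust_brute(list(p)))

    def test_textbook_bh_example(self):
        assert bh_adjust_brute([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_empty_margin_skipped(self):
        calls = [[REF]] * 10 + [[REF]] * 10  # no carriers anywhere
        gm = _matrix(calls)
        res = differential_abundance(gm, self._states(10, 10), ("DZ", "LZ"))
        assert not res["tested"].iloc[0]
        assert np.isnan(res["chi2"].iloc[0])

    def test_empty_state_errors(self):
        gm = _matrix([[HET]])
        with pytest.raises(GenotypeError):
            differential_abundance(gm, {"C0": "DZ"}, ("DZ", "LZ"))
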