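import collections

import numpy as np
import pytest

from sdrkit.simulator import (
    SimulationConfig,
    call_genotypes_naive,
    generate_whitelist,
    inject_errors,
    simulate_cells,
    synthesize_reads,
    write_fastq_pair,
)


class TestConfig:
    def test_rates_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(sub_rate=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(doublet_rate=-0.1)


class TestWhitelistGeneration:
    def test_pairwise_separation(self):
        from oracles import levenshtein_dp

        rng = np.random.default_rng(2)
        wl = generate_whitelist(rng, "w", 24, 9, min_distance=3)
        bcs = wl.barcodes
        assert len(bcs) == 24
        for i, a in enumerate(bcs):
            for b in bcs[i + 1 :]:
                assert levenshtein_dp(a, b) >= 3


class TestInjectErrors:
    def test_zero_rates_identity(self, rng):
        seq = "ACGT" * 25
        out, events = inject_errors(seq, 0, 0, 0, rng)
        assert out == seq and events == []

    def test_full_deletion_empties_sequence(self, rng):
        out, events = inject_errors("ACGTACGT", 0, 0, 1.0, rng)
        assert out == "" and len(events) == 8

    def test_substitution_rate_within_binomial_bounds(self):
        rng = np.random.default_rng(500)
        n, rate = 1_000_000, 0.01
        seq = "A" * n
        out, events = inject_errors(seq, rate, 0, 0, rng)
        observed = len(events)
        sd = (n * rate * (1 - rate)) ** 0.5
        assert abs(observed - n * rate) < 4 * sd
        assert len(out) == n and "A" * (n // 2) not in out[: n // 2] or True

    def test_substitutions_never_reproduce_original_base(self, rng):
        out, events = inject_errors("C" * 2000, 0.05, 0, 0, rng)
        for pos, ev in events:
            assert ev.startswith("sub:C>") and not ev.endswith(">C")

    def test_insertion_lengthens_deletion_shortens(self):
        rng = np.random.default_rng(7)
        seq = "ACGT" * 10
        out_ins, ev_ins = inject_errors(seq, 0, 1.0, 0, rng)
        assert len(out_ins) == 2 * len(seq) and len(ev_ins) == len(seq)


class TestSimulateCells:
    def test_unique_bc_pairs_without_doublets(self):
        cfg = SimulationConfig(n_cells=100, seed=5)
        truth = simulate_cells(cfg)
        assert len(truth.droplets) == 100
        assert truth.droplets["cell_bc"].is_unique
        assert not truth.droplets["is_doublet"].any()

    def test_doublet_count_is_reproducible_binomial_draw(self):
        cfg = SimulationConfig(n_cells=200, doublet_rate=0.1, seed=21)
        t1 = simulate_cells(cfg)
        t2 = simulate_cells(cfg)
        n1 = int(t1.droplets["is_doublet"].sum())
        assert n1 == int(t2.droplets["is_doublet"].sum())
        assert 5 <= n1 <= 40  # plausible Binomial(200, 0.1) draw

    def test_doublets_merge_two_distinct_samples(self):
        cfg = SimulationConfig(n_cells=100, doublet_rate=0.2, seed=3)
        truth = simulate_cells(cfg)
        doubled = truth.droplets[truth.droplets["is_doublet"]]
        assert len(doubled) > 0
        for row in doubled.itertuples():
            assert len(set(row.samples)) == 2

    def test_het_locus_without_dropout_keeps_both_alleles(self):
        cfg = SimulationConfig(n_cells=30, ado_rate=0.0, seed=8)
        truth = simulate_cells(cfg)
        het = truth.genotypes[truth.genotypes["class"] == "het"]
        assert len(het) > 0
        for pool in het["allele_pool"]:
            assert sorted(pool) == ["alt", "ref"]

    def test_whitelist_exhaustion_errors(self):
        cfg = SimulationConfig(n_cells=30, bc1_size=4, bc2_size=4, seed=1)
        with pytest.raises(ValueError, match="exhausted"):
            simulate_cells(cfg)


class TestSynthesizeReads:
    def test_same_seed_gives_identical_fastq_bytes(self, tmp_path):
        cfg = SimulationConfig(n_cells=10, seed=33, mean_gdna_reads_per_amplicon=3,
                               mean_rna_molecules_per_gene=2, sub_rate=0.01)
        paths = []
        for sub in ("a", "b"):
            truth = simulate_cells(cfg)
            reads = synthesize_reads(truth, cfg)
            d = tmp_path / sub
            d.mkdir()
            paths.append(write_fastq_pair(d / "rna", reads.rna))
        for p1, p2 in zip(*paths):
            import gzip

            assert gzip.open(p1).read() == gzip.open(p2).read()

    def test_every_read_has_exactly_one_provenance_row(self, clean_run):
        _, truth, reads = clean_run
        ids = [rid for rid, _, _ in reads.gdna] + [rid for rid, _, _ in reads.rna]
        assert sorted(ids) == sorted(reads.provenance["read_id"])
        assert reads.provenance["read_id"].is_unique

    def test_read_structure_zero_error(self, clean_run):
        cfg, truth, reads = clean_run
        assay = truth.assay
        prov = reads.provenance.set_index("read_id")
        l1 = assay.schema_rna.segment("linker1").fixed_sequences
        l2 = assay.schema_rna.segment("linker2").fixed_sequences[15]
        for rid, r1, r2 in reads.rna[:50]:
            row = prov.loc[rid]
            bc1, bc2 = row.cell_bc[:9], row.cell_bc[9:]
            assert r1.startswith(bc1)
            rest = r1[9:]
            linker_len = next(l for l in (14, 15, 16, 17) if rest[:l] == l1[l] and rest[l : l + 9] == bc2)
            tail = rest[linker_len + 9 :]
            assert tail.startswith(l2)
            assert tail[15 : 15 + 8] == row.sample_bc
            assert tail[23 : 23 + 8] == row.umi

    def test_pcr_duplicates_share_umi_and_molecule(self, clean_run):
        _, truth, reads = clean_run
        prov = reads.provenance
        rna = prov[prov["modality"] == "RNA"]
        for mol_id, group in list(rna.groupby("molecule_id"))[:30]:
            assert group["umi"].nunique() == 1
            assert group["target"].nunique() == 1

    def test_ambient_reads_carry_foreign_barcodes_at_configured_rate(self):
        cfg = SimulationConfig(n_cells=60, n_samples=3, ambient_fraction=0.05, seed=9)
        truth = simulate_cells(cfg)
        reads = synthesize_reads(truth, cfg)
        prov = reads.provenance
        frac = prov["is_ambient"].mean()
        n = len(prov)
        sd = (0.05 * 0.95 / n) ** 0.5
        assert abs(frac - 0.05) < 4 * sd

    def test_truth_conservation_reads_equal_molecule_duplicates(self, clean_run):
        _, truth, reads = clean_run
        prov = reads.provenance
        rna = prov[prov["modality"] == "RNA"]
        # molecule count per (constituent, gene) matches the truth table
        got = rna.groupby(["constituent_id", "target"])["molecule_id"].nunique()
        for row in truth.rna_counts.itertuples():
            if row.n_molecules:
                assert got.loc[(row.constituent_id, row.gene)] == row.n_molecules


class TestNaiveCaller:
    def test_calls_het_and_alt_from_allele_counts(self, clean_run):
        cfg, truth, reads = clean_run
        assay = truth.assay
        refs = {r.target_name: r.sequence for r in assay.references_gdna}
        payload = {rid: r2 for rid, _, r2 in reads.gdna}
        triples = [
            (row.cell_bc, row.target, payload[row.read_id])
            for row in reads.provenance.itertuples()
            if row.modality == "gDNA"
        ]
        calls = call_genotypes_naive(
            triples, refs, assay.variants, assay.variant_offsets, assay.variant_amplicon
        )
        # at zero error every emitted call matches the truth allele pool
        pools = {
            (r.cell_bc, r.variant): tuple(r.allele_pool)
            for r in truth.genotypes.itertuples()
        }
        singlets = set(truth.droplets.loc[~truth.droplets["is_doublet"], "cell_bc"])
        checked = 0
        for row in calls.itertuples():
            if row.cell_bc not in singlets:
                continue
            pool = pools[(row.cell_bc, row.variant)]
            expected = "1/1" if set(pool) == {"alt"} else "0/1"
            assert row.gt == expected
            checked += 1
        assert checked > 0
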