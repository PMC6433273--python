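"""Fixture integrity and synthetic-data generator contracts."""

import numpy as np
import pytest

from smallrna import syndata
from smallrna.annotate import to_cpm
from smallrna.core import ReferenceRecord
from smallrna.de_paired import paired_log2fc

from conftest import random_dna


class TestCatalogueFixture:
    def test_lysctt_row_parsed_intact(self, table4):
        row = next(
            r for r in table4.rows
            if r.trna_type == "LysCTT" and r.position_code == "5"
        )
        assert row.trf_sequence == "GCTAGCTCAGTCGGTAGAGCA"
        assert len(row.locus_ids) == 9

    def test_bookkeeping_counts(self, table4):
        assert len(table4.rows) == 18
        assert len(table4.locus_ids) == 50
        assert len(table4.amino_acids) == 12
        # two anticodon types appear twice, so 16 distinct types
        assert len(table4.trna_types) == 16
        assert table4.numbered_trf_names == {"tRF-1001", "tRF-3006", "tRF-5005"}

    def test_sequences_are_short_dna(self, table4):
        for row in table4.rows:
            assert set(row.trf_sequence) <= set("ACGT")
            assert 19 <= len(row.trf_sequence) <= 21

    def test_de_tables_match_published_shape(self):
        t6 = syndata.load_de_table(6)
        t24 = syndata.load_de_table(24)
        assert len(t6) == 15 and (t6["direction"] == "up").all()
        assert len(t24) == 13
        down = t24[t24["direction"] == "down"]
        assert list(down["gene"]) == ["hsa-mir-7151"]
        assert (t6["padj"] < 0.05).all() and (t24["padj"] < 0.05).all()


class TestBuildReference:
    def test_pure_function_of_arguments(self, table4):
        a = syndata.build_reference(table4, n_decoys=10, seed=3)
        b = syndata.build_reference(table4, n_decoys=10, seed=3)
        assert a == b
        c = syndata.build_reference(table4, n_decoys=10, seed=4)
        assert a != c

    def test_one_locus_record_per_catalogue_locus(self, table4, reference):
        loci = {r.id for r in reference if r.category == "tRNA_locus"}
        assert loci == table4.locus_ids

    def test_placement_matches_position_code(self, table4, reference):
        by_id = {r.id: r for r in reference}
        for row in table4.rows:
            trf = row.trf_sequence
            for lid in row.locus_ids:
                rec = by_id[lid]
                body = rec.sequence[rec.body_start: rec.body_end]
                if row.position_code == "5":
                    assert body.startswith(trf)
                elif row.position_code == "3":
                    assert body.endswith(trf)
                elif row.position_code == "3down":
                    # trailer begins immediately after the genomic body end
                    assert rec.sequence[rec.body_end: rec.body_end + len(trf)] == trf
                else:
                    idx = body.find(trf)
                    assert idx > 3 and idx + len(trf) < len(body) - 3

    def test_decoys_contain_no_catalogue_sequence(self, table4, reference):
        decoys = [r for r in reference if r.category != "tRNA_locus"]
        assert decoys, "reference should include decoy records"
        for rec in decoys:
            for row in table4.rows:
                assert row.trf_sequence not in rec.sequence

    def test_shared_rows_embed_identical_subsequence(self, table4, reference):
        by_id = {r.id: r for r in reference}
        for row in table4.rows:
            for lid in row.locus_ids:
                assert row.trf_sequence in by_id[lid].sequence

    def test_short_flank_rejected(self, table4):
        with pytest.raises(ValueError, match="flank"):
            syndata.build_reference(table4, flank=10)


class TestSimulateReads:
    def _tiny_reference(self, rng):
        body = random_dna(rng, 80)
        return [
            ReferenceRecord(
                "locus1", "tRNA_locus", random_dna(rng, 30) + body + random_dna(rng, 30),
                body_start=30, body_end=110,
            )
        ], body

    def test_foreground_counts_match_cpm(self, rng, tmp_path):
        ref, body = self._tiny_reference(rng)
        insert = body[:20]
        spec = syndata.ReadSimSpec(
            foreground={insert: 600.0}, total_reads=10_000,
            background_fraction=1 - 600.0 / 1e6, seed=5,
        )
        counts = syndata.simulate_reads(ref, spec, str(tmp_path / "a.fastq"))
        assert counts[insert] == 6  # 600 CPM of 1e4 reads

    def test_zero_background_means_all_foreground(self, rng, tmp_path):
        ref, body = self._tiny_reference(rng)
        spec = syndata.ReadSimSpec(
            foreground={body[:20]: 4e5, body[20:41]: 6e5},
            total_reads=1000, background_fraction=0.0, seed=5,
        )
        path = tmp_path / "b.fastq"
        syndata.simulate_reads(ref, spec, str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 4000
        inserts = {l[: -len(spec.adaptor)] for l in lines[1::4]}
        assert inserts == {body[:20], body[20:41]}

    def test_same_seed_byte_identical(self, rng, tmp_path):
        ref, body = self._tiny_reference(rng)
        spec = syndata.ReadSimSpec(
            foreground={body[:20]: 1e5}, total_reads=2000,
            background_fraction=0.9, seed=11,
        )
        p1, p2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
        syndata.simulate_reads(ref, spec, str(p1))
        syndata.simulate_reads(ref, spec, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_infeasible_allocation_rejected(self, rng, tmp_path):
        ref, body = self._tiny_reference(rng)
        spec = syndata.ReadSimSpec(
            foreground={body[:20]: 100.0}, total_reads=1000,
            background_fraction=0.5, seed=0,  # 100 CPM + 50% != whole library
        )
        with pytest.raises(ValueError, match="infeasible"):
            syndata.simulate_reads(ref, spec, str(tmp_path / "c.fastq"))

    def test_unknown_foreground_insert_rejected(self, rng, tmp_path):
        ref, _ = self._tiny_reference(rng)
        spec = syndata.ReadSimSpec(
            foreground={"A" * 20: 1e6}, total_reads=100, seed=0
        )
        with pytest.raises(ValueError, match="not found"):
            syndata.simulate_reads(ref, spec, str(tmp_path / "d.fastq"))


class TestSimulatePairedCounts:
    def test_study_layout_of_seven_donors(self):
        m = syndata.simulate_paired_counts(
            [syndata.SpikeSpec("s1", 100.0, 1.0)], n_null=5, n_donors=7, seed=0
        )
        assert m.values.shape == (6, 14)
        per_donor = m.meta.groupby("donor")["treatment"].apply(set)
        assert len(per_donor) == 7
        assert all(v == {"LPS", "medium"} for v in per_donor)

    def test_spiked_mean_recovery_without_noise_sources(self):
        # dispersion -> 0 (Poisson) and donor effect off: LPS sample mean
        # approaches baseline * 2**log2fc within 3 standard errors
        spike = syndata.SpikeSpec("s1", 400.0, 1.5)
        m = syndata.simulate_paired_counts(
            [spike], n_null=0, n_donors=200, dispersion=0.0, seed=2, donor_sd_log=0.0
        )
        lps = m.meta.index[m.meta["treatment"] == "LPS"]
        expected = 400.0 * 2**1.5
        observed = m.values.loc["s1", lps]
        se = np.sqrt(expected / len(lps))
        assert abs(observed.mean() - expected) < 3 * se

    def test_condition_swap_negates_log2fc(self):
        spikes = [syndata.SpikeSpec("s1", 300.0, 2.0), syndata.SpikeSpec("s2", 300.0, -1.0)]
        m = syndata.simulate_paired_counts(spikes, n_null=20, n_donors=7, seed=3)
        cpm = to_cpm(m)
        fwd = paired_log2fc(cpm, center=False)
        swapped = cpm.meta.copy()
        swapped["treatment"] = swapped["treatment"].map({"LPS": "medium", "medium": "LPS"})
        cpm_sw = type(cpm)(cpm.values, swapped, "CPM")
        rev = paired_log2fc(cpm_sw, center=False)
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy())

    def test_truth_records_spiked_effects(self):
        m = syndata.simulate_paired_counts(
            [syndata.SpikeSpec("s1", 50.0, 2.5)], n_null=3, n_donors=3, seed=0
        )
        assert m.truth["s1"] == 2.5
        assert (m.truth.drop("s1") == 0).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            syndata.SpikeSpec("bad", -1.0, 0.0)
        with pytest.raises(ValueError, match="donors"):
            syndata.simulate_paired_counts([], n_null=4, n_donors=1, seed=0)
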