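"""Quality scoring, recovery classification, and the derived metrics."""

import math

import pytest

from magbench import (
    BinRecord,
    accuracy,
    classify_recovery,
    coverage,
    detection_limit_summary,
    filter_bins,
    quality_score,
    relative_abundance,
    species_pair_recovery,
)
from magbench.evaluate import read_bin_table, write_bin_table


def _bin(species, completeness=95.0, contamination=0.5, bin_id=None,
         profile="A-p", pipeline="mock", mapped=1000, size=100_000):
    return BinRecord(
        bin_id=bin_id or f"b-{species}-{completeness}",
        profile_id=profile,
        pipeline=pipeline,
        completeness=completeness,
        contamination=contamination,
        assigned_species=species,
        mapped_reads=mapped,
        bin_size_bp=size,
    )


class TestQualityScore:
    @pytest.mark.parametrize(
        "comp,cont,expected",
        [(100, 0, 100.0), (90, 8, 50.0), (96.74, 0.363, 94.925), (50, 20, -50.0)],
    )
    def test_score_arithmetic(self, comp, cont, expected):
        assert quality_score(comp, cont) == pytest.approx(expected)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            quality_score(101, 0)
        with pytest.raises(ValueError):
            quality_score(50, -1)

    def test_score_of_exactly_50_fails_strict_filter(self):
        at_50 = _bin("x", completeness=90, contamination=8)
        assert quality_score(90, 8) == 50.0
        assert filter_bins([at_50]) == []

    def test_strict_threshold_boundary(self):
        bins = [
            _bin("a", 50, 0),      # score 50    -> out
            _bin("b", 50.01, 0),   # score 50.01 -> in
            _bin("c", 49.99, 0),   # score 49.99 -> out
        ]
        assert [b.assigned_species for b in filter_bins(bins)] == ["b"]

    def test_filter_is_monotone_in_threshold(self):
        bins = [_bin(f"s{i}", 50 + i, 0.1 * i) for i in range(10)]
        prev = set(b.bin_id for b in filter_bins(bins, threshold=0))
        for thr in (20, 40, 50, 55, 60):
            cur = set(b.bin_id for b in filter_bins(bins, threshold=thr))
            assert cur <= prev
            prev = cur

    def test_empty_list_passes_through(self):
        assert filter_bins([]) == []


class TestAccuracy:
    @pytest.mark.parametrize("tp,fp,expected", [(3, 1, 75.0), (42, 0, 100.0)])
    def test_arithmetic(self, tp, fp, expected):
        assert accuracy(tp, fp) == expected

    def test_no_calls_is_nan(self):
        assert math.isnan(accuracy(0, 0))

    def test_fp_per_10000_mags_range(self):
        """Published-scale accuracies of 92% and 76% imply 800 and 2400
        false positives per 10,000 recovered MAGs."""
        for acc, expected_fp in [(92.0, 800), (76.0, 2400)]:
            fp_fraction = 1 - acc / 100
            assert round(fp_fraction * 10_000) == expected_fp
            # and back through the accuracy definition
            assert accuracy(10_000 - expected_fp, expected_fp) == pytest.approx(acc)


class TestClassifyRecovery:
    def test_species_level_partition(self):
        truth = {"genus one", "genus two", "genus three"}
        bins = [_bin("Genus one"), _bin("Genus one", 97), _bin("Genus four")]
        t = classify_recovery(bins, truth)
        assert t.tp_species == {"genus one"}
        assert t.fn_species == {"genus two", "genus three"}
        assert t.n_fp_bins == 1
        assert t.fp_species == {"genus four"}
        assert t.tp_species | t.fn_species == truth
        assert not (t.fp_species & truth)

    def test_full_recovery_accuracy_100(self):
        truth = {"a x", "b y"}
        t = classify_recovery([_bin("A x"), _bin("B y")], truth)
        assert t.accuracy() == 100.0
        assert t.n_fn == 0

    def test_no_calls_accuracy_is_nan(self):
        t = classify_recovery([], {"a x"})
        assert math.isnan(t.accuracy())

    def test_unassigned_bins_are_not_fp(self):
        truth = {"a x"}
        t = classify_recovery([_bin("unassigned"), _bin("A x")], truth)
        assert t.n_fp_bins == 0
        assert len(t.unassigned_bins) == 1
        assert t.accuracy() == 100.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            classify_recovery([], set())

    def test_bin_level_fp_switch(self):
        truth = {"a x"}
        bins = [_bin("A x"), _bin("B y"), _bin("B y", 97)]
        t = classify_recovery(bins, truth)
        assert t.accuracy("species") == pytest.approx(50.0)
        assert t.accuracy("bin") == pytest.approx(100 / 3)


class TestPairRecovery:
    def _table(self, tp):
        return classify_recovery([_bin(s) for s in tp],
                                 {"r1 a", "v1 a", "r2 a", "v2 a"} | set(tp))

    def test_all_pairs_recovered(self):
        pairs = [("r1 a", "v1 a"), ("r2 a", "v2 a")]
        t = self._table(["R1 a", "V1 a", "R2 a", "V2 a"])
        assert species_pair_recovery(t, pairs) == 1.0

    def test_no_pair_recovered(self):
        pairs = [("r1 a", "v1 a"), ("r2 a", "v2 a")]
        t = self._table(["R1 a", "R2 a"])  # partners missing
        assert species_pair_recovery(t, pairs) == 0.0

    def test_fractional_recovery(self):
        pairs = [("r1 a", "v1 a"), ("r2 a", "v2 a"), ("r3 a", "v3 a"), ("r4 a", "v4 a")]
        t = self._table(["R1 a", "V1 a", "R2 a"])
        assert species_pair_recovery(t, pairs) == 0.25

    def test_zero_pairs_is_nan(self):
        t = self._table(["R1 a"])
        assert math.isnan(species_pair_recovery(t, []))


class TestCoverageAndAbundance:
    def test_coverage_identity(self):
        assert coverage(125, 8000, 1_000_000) == 1.0
        assert coverage(125, 0, 12345) == 0.0

    def test_coverage_invalid_inputs(self):
        with pytest.raises(ValueError):
            coverage(125, 10, 0)
        with pytest.raises(ValueError):
            coverage(0, 10, 100)

    def test_relative_abundance_bounds(self):
        assert relative_abundance(0, 100) == 0.0
        assert relative_abundance(100, 100) == 1.0
        with pytest.raises(ValueError):
            relative_abundance(101, 100)
        with pytest.raises(ValueError):
            relative_abundance(1, 0)

    def test_identities_against_truth_tagged_library(self, group_a, small_genomes, tmp_path):
        """N taken from read-header truth tags reproduces the designed
        relative abundances and the depth-implied coverage exactly."""
        from magbench import CommunityProfile, build_spec, simulate_library
        from magbench.simreads import parse_header, read_paired_fastq

        prof = CommunityProfile("A", "log_decay", "random", 20_000, seed=2)
        spec = build_spec(prof, group_a)
        lib = simulate_library(spec, small_genomes, seed=6, out_dir=tmp_path)
        n_mapped: dict[str, int] = {}
        for h1, *_ in read_paired_fastq(lib.mate1_path, lib.mate2_path):
            origin, _ = parse_header(h1)
            n_mapped[origin.species_id] = n_mapped.get(origin.species_id, 0) + 2
        R = spec.total_reads
        assert sum(n_mapped.values()) == R
        for a in spec.assignments:
            ra = relative_abundance(n_mapped[a.species_id], R)
            # budgets are largest-remainder-rounded, so within one pair of design
            assert ra == pytest.approx(a.abundance, abs=1.0 / prof.depth)
            g = small_genomes.genome_length(a.species_id)
            expected_cov = 125 * 2 * a.read_pairs / g
            assert coverage(125, n_mapped[a.species_id], g) == pytest.approx(expected_cov)


class TestDetectionLimits:
    def test_planted_low_abundance_species_identified(self):
        truth = {"deep one", "shallow two"}
        bins = [
            _bin("Deep one", mapped=40, size=100_000),      # cov 0.05, ra 0.0004
            _bin("Shallow two", mapped=50_000, size=100_000),
            _bin("Ghost three", mapped=9000, size=100_000),  # FP
        ]
        t = classify_recovery(bins, truth)
        df = detection_limit_summary([t], bins, {"A-p": 100_000})
        row = df.iloc[0]
        assert row["min_tp_abundance_species"] == "deep one"
        assert row["min_tp_abundance"] == pytest.approx(0.0004)
        assert row["min_tp_coverage"] == pytest.approx(0.05)
        assert row["max_fp_abundance_species"] == "ghost three"
        assert row["max_fp_coverage"] == pytest.approx(125 * 9000 / 100_000)

    def test_profile_without_fp_emits_missing(self):
        truth = {"a x"}
        bins = [_bin("A x")]
        t = classify_recovery(bins, truth)
        df = detection_limit_summary([t], bins, {"A-p": 10_000})
        assert math.isnan(df.iloc[0]["max_fp_abundance"])
        assert df.iloc[0]["min_tp_abundance_species"] == "a x"


def test_bin_table_round_trip(tmp_path):
    bins = [_bin("A x"), _bin("B y", 80, 3.5, mapped=5, size=999)]
    path = tmp_path / "bins.tsv"
    write_bin_table(bins, path)
    assert read_bin_table(path) == bins


def test_bin_table_missing_column(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("bin_id\tprofile_id\nx\ty\n")
    with pytest.raises(ValueError, match="missing"):
        read_bin_table(path)
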