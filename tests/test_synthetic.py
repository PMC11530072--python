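"""Synthetic roster/genome generation and the mock binner."""

import numpy as np
import pytest

from magbench import (
    CommunityProfile,
    MockBinnerParams,
    build_spec,
    classify_recovery,
    filter_bins,
    gen_genomes,
    gen_taxonomy,
    mock_binner,
    validate_group,
)


class TestGenTaxonomy:
    def test_three_groups_of_42_all_validate(self, groups):
        assert len(groups) == 3
        assert sum(len(g.members) for g in groups) == 126
        for g in groups:
            report = validate_group(g)
            assert report.passed, [c.detail for c in report.failures()]
            assert len(g.triplets) == 12
            assert len(g.specials) == 3
            assert len(g.fungi) == 3

    def test_domain_census(self, groups):
        for g in groups:
            by_domain = {"bacteria": 0, "archaea": 0, "eukaryote": 0}
            for m in g.members:
                by_domain[m.domain] += 1
            assert by_domain == {"bacteria": 33, "archaea": 6, "eukaryote": 3}

    def test_special_topologies_include_linear_and_multiple(self, groups):
        for g in groups:
            topos = {g[s].topology for s in g.specials}
            assert "linear" in topos and "multiple" in topos

    def test_same_seed_reproduces_roster(self):
        a = gen_taxonomy(2, seed=99)
        b = gen_taxonomy(2, seed=99)
        for ga, gb in zip(a, b):
            assert ga.members == gb.members
            assert ga.triplets == gb.triplets


class TestGenGenomes:
    def test_topology_respected(self, group_a, small_genomes):
        for m in group_a.members:
            reps = small_genomes.replicons[m.species_id]
            if m.topology == "multiple":
                assert len(reps) >= 2
            elif m.topology == "linear":
                assert len(reps) == 1 and not reps[0].circular
            else:
                assert len(reps) == 1 and reps[0].circular

    def test_lengths_within_requested_range(self, group_a, small_genomes):
        for m in group_a.members:
            total = small_genomes.genome_length(m.species_id)
            assert 20_000 <= total <= 60_000

    def test_gc_content_matches_binomial_expectation(self, group_a):
        coll = gen_genomes(group_a, length_range=(200_000, 200_001),
                           gc_range=(0.5, 0.5), seed=77)
        sid = group_a.members[0].species_id
        seq = "".join(r.seq for r in coll.replicons[sid])
        gc = sum(c in "GC" for c in seq) / len(seq)
        se = np.sqrt(0.25 / len(seq))
        assert abs(gc - 0.5) <= 3 * se


def _spec_for(group, depth=42_000, seed=5, kind="equal", rel="ordered"):
    return build_spec(CommunityProfile(group.group_label, kind, rel, depth, seed), group)


class TestMockBinner:
    def test_perfect_detection_no_fp_gives_tp42_accuracy100(self, group_a):
        spec = _spec_for(group_a)
        params = MockBinnerParams(p_detect=1.0, p_fp=0.0)
        bins = mock_binner(spec, group_a, params, seed=1)
        table = classify_recovery(filter_bins(bins), group_a.truth_names)
        assert table.n_tp == 42
        assert table.n_fp_species == 0
        assert table.accuracy() == 100.0

    def test_mapped_reads_conserve_species_budget(self, group_a):
        spec = _spec_for(group_a, kind="exp_decay", rel="random")
        params = MockBinnerParams(p_detect=1.0, p_fp=0.0, bins_per_species_mean=2.0)
        bins = mock_binner(spec, group_a, params, seed=3)
        budgets = spec.budgets()
        by_species: dict[str, int] = {}
        for b in bins:
            sid = b.bin_id.split(":")[1]
            by_species[sid] = by_species.get(sid, 0) + b.mapped_reads
        for sid, total in by_species.items():
            assert total == 2 * budgets[sid]

    def test_coverage_gate_always_drops_floor_species(self, group_a):
        spec = _spec_for(group_a, kind="exp_decay", rel="random", depth=100_000)
        floor_assign = max(spec.assignments, key=lambda a: a.rank)
        g_len = group_a[floor_assign.species_id].genome_length
        floor_cov = 125 * 2 * floor_assign.read_pairs / g_len
        params = MockBinnerParams(p_detect=1.0, p_fp=0.0,
                                  detection_threshold=floor_cov * 1.01)
        for seed in range(5):
            bins = mock_binner(spec, group_a, params, seed=seed)
            table = classify_recovery(filter_bins(bins), group_a.truth_names)
            floor_name = group_a[floor_assign.species_id].normalized_name
            assert floor_name in table.fn_species

    @pytest.mark.parametrize("fp_mode", ["sibling_genus", "sibling_family", "random_label"])
    def test_fp_labels_are_off_roster(self, group_a, fp_mode):
        spec = _spec_for(group_a)
        params = MockBinnerParams(p_detect=0.0, p_fp=1.0, fp_mode=fp_mode)
        bins = mock_binner(spec, group_a, params, seed=4)
        assert len(bins) == 42
        table = classify_recovery(filter_bins(bins), group_a.truth_names)
        assert table.n_tp == 0
        assert table.n_fp_species == len(filter_bins(bins))
        if fp_mode == "sibling_genus":
            roster_genera = {m.genus for m in group_a.members}
            assert all(b.assigned_species.split()[0] in roster_genera for b in bins)

    def test_deterministic_under_seed(self, group_a):
        spec = _spec_for(group_a)
        params = MockBinnerParams(p_detect=0.8, p_fp=0.2)
        assert mock_binner(spec, group_a, params, seed=6) == \
            mock_binner(spec, group_a, params, seed=6)

    def test_parameter_recovery_across_replicates(self, group_a):
        """Evaluated TP fraction and accuracy recover the configured
        detection and FP probabilities within binomial sampling error."""
        spec = _spec_for(group_a)
        p_detect, p_fp = 0.9, 0.1
        params = MockBinnerParams(p_detect=p_detect, p_fp=p_fp)
        n_rep = 60
        tp_fracs, fp_counts = [], []
        for seed in range(n_rep):
            bins = mock_binner(spec, group_a, params, seed=seed)
            t = classify_recovery(filter_bins(bins), group_a.truth_names)
            tp_fracs.append(t.n_tp / 42)
            fp_counts.append(t.n_fp_species)
        mean_tp = float(np.mean(tp_fracs))
        se_tp = np.sqrt(p_detect * (1 - p_detect) / (42 * n_rep))
        assert abs(mean_tp - p_detect) <= 4 * se_tp
        mean_fp = float(np.mean(fp_counts))
        se_fp = np.sqrt(42 * p_fp * (1 - p_fp) / n_rep)
        assert abs(mean_fp - 42 * p_fp) <= 4 * se_fp


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        MockBinnerParams(p_detect=1.5)
    with pytest.raises(ValueError):
        MockBinnerParams(bins_per_species_mean=0.5)
    with pytest.raises(ValueError):
        MockBinnerParams(fp_mode="nonsense")
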