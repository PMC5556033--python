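import numpy as np
import pytest

from pbflex import (
    PBEnsemble,
    SyntheticScenario,
    SystemSet,
    calf1_regions,
    compare_systems,
    distribution_for_neq,
    hotspots,
    make_wt_variant_pair,
    preprocess,
    region_summary,
    sample_system,
)


def constant_ensemble(string, system="S", run="r0", n_frames=10):
    letters = np.tile(np.array(list(string)), (n_frames, 1))
    return PBEnsemble(system, run, letters, np.arange(1, len(string) + 1),
                      100.0 * np.arange(1, n_frames + 1))


class TestCompareSystems:
    def test_self_comparison_is_identically_zero(self, basic_scenario):
        runs = sample_system(basic_scenario, "WT", n_frames=40)
        a = SystemSet("WT", runs)
        profile = compare_systems(a, a)
        np.testing.assert_array_equal(profile.delta_neq, 0.0)
        np.testing.assert_array_equal(profile.delta_pb, 0.0)

    def test_symmetry_in_both_metrics(self, basic_scenario):
        wt_runs, var_runs, _ = make_wt_variant_pair(basic_scenario, n_frames=60)
        ab = compare_systems(SystemSet("WT", wt_runs), SystemSet("VAR", var_runs))
        ba = compare_systems(SystemSet("VAR", var_runs), SystemSet("WT", wt_runs))
        np.testing.assert_allclose(ab.delta_pb, ba.delta_pb)
        np.testing.assert_allclose(ab.delta_neq, ba.delta_neq)

    def test_planted_alteration_has_maximal_delta_pb(self, basic_scenario):
        wt_runs, var_runs, pair = make_wt_variant_pair(basic_scenario, n_frames=500)
        profile = compare_systems(SystemSet("WT", wt_runs), SystemSet("VAR", var_runs))
        edited = pair.edited_positions[0]
        idx = np.flatnonzero(profile.residue_numbers == edited)[0]
        assert np.nanargmax(profile.delta_pb) == idx

    def test_one_hot_swap_extremes(self):
        # d -> m swap at one position: dPB = 2 while dNeq = 0 (equal entropy)
        wt = SystemSet("WT", [constant_ensemble("ddd")])
        var = SystemSet("V", [constant_ensemble("dmd")])
        profile = compare_systems(wt, var)
        assert profile.delta_pb[1] == pytest.approx(2.0)
        assert profile.delta_neq[1] == pytest.approx(0.0)
        assert profile.delta_pb[0] == profile.delta_pb[2] == 0.0

    def test_undefined_positions_propagate(self):
        wt = SystemSet("WT", [constant_ensemble("Zdd")])
        var = SystemSet("V", [constant_ensemble("Zdm")])
        profile = compare_systems(wt, var)
        assert not profile.defined[0]
        assert profile.defined[1]

    def test_numbering_mismatch_fatal(self):
        a = SystemSet("A", [constant_ensemble("dd")])
        other = PBEnsemble("B", "r0", np.array([list("dd")]), [5, 6])
        b = SystemSet("B", [other])
        with pytest.raises(ValueError, match="numbering"):
            compare_systems(a, b)


class TestHotspots:
    def test_single_nonzero_position_ranks_first(self):
        wt = SystemSet("WT", [constant_ensemble("dddd")])
        var = SystemSet("V", [constant_ensemble("ddfd")])
        table = hotspots(compare_systems(wt, var), k=5)
        assert len(table) == 1
        assert table.iloc[0].residue == 3
        assert table.iloc[0]["rank"] == 1

    def test_all_zero_profile_yields_empty_table(self):
        wt = SystemSet("WT", [constant_ensemble("dddd")])
        table = hotspots(compare_systems(wt, wt), k=5)
        assert len(table) == 0

    def test_nonpositive_k_fatal(self):
        wt = SystemSet("WT", [constant_ensemble("dd")])
        with pytest.raises(ValueError):
            hotspots(compare_systems(wt, wt), k=0)

    def test_distal_hotspot_outranks_untouched_mutation_site(self, basic_scenario):
        wt_runs, var_runs, pair = make_wt_variant_pair(basic_scenario, n_frames=500)
        var = SystemSet("VAR", var_runs, mutation_site=5)
        profile = compare_systems(SystemSet("WT", wt_runs), var)
        table = hotspots(profile, k=3)
        assert table.iloc[0].residue == pair.edited_positions[0]
        site_dpb = table.attrs["mutation_site_delta_pb"]
        assert site_dpb < table.iloc[0].delta_pb

    def test_recovery_over_20_seeded_scenarios(self):
        # planted dPB >= 0.5 at a distal position, 10,000 pooled frames:
        # the planted position must rank first in at least 19 of 20 scenarios
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 25
            targets = rng.uniform(1.2, 3.5, n)
            edit_pos = int(rng.integers(3, n - 2))
            base = SyntheticScenario.from_neq_targets(
                targets, support=5, seed=seed, run_plan_ns=(1,), stride_ps=100.0
            )
            # edit guaranteed >= 0.5 away in L1: move to a fresh support
            edit = distribution_for_neq(2.0, support=4, seed=seed + 500)
            while np.sum(np.abs(edit - base.rows[edit_pos])) < 0.5:
                edit = np.roll(edit, 1)
            scn = SyntheticScenario(
                rows=base.rows,
                variant_edits={"VAR": {edit_pos + 1: edit}},
                run_plan_ns=(1,),
                master_seed=seed,
            )
            wt_runs, var_runs, pair = make_wt_variant_pair(scn, n_frames=10_000)
            profile = compare_systems(
                SystemSet("WT", wt_runs), SystemSet("VAR", var_runs)
            )
            table = hotspots(profile, k=1)
            if int(table.iloc[0].residue) == edit_pos + 1:
                hits += 1
        assert hits >= 19


class TestPreprocess:
    def test_discard_arithmetic(self):
        # 100 ns at 100 ps stride = 1000 frames; discarding 5 ns leaves 950
        ens = constant_ensemble("ddddd", n_frames=1000)
        out = preprocess([ens], "WT", discard_ps=5000.0, trim=0)
        assert out.runs[0].n_frames == 950

    def test_trim_masks_termini_to_z(self):
        ens = constant_ensemble("d" * 10, n_frames=5)
        out = preprocess([ens], "WT", discard_ps=0.0, trim=2)
        letters = out.runs[0].letters
        assert np.all(letters[:, :2] == "Z") and np.all(letters[:, -2:] == "Z")
        assert np.all(letters[:, 2:-2] == "d")

    def test_discard_zero_is_identity(self):
        ens = constant_ensemble("ddd", n_frames=7)
        out = preprocess([ens], "WT", discard_ps=0.0, trim=0)
        np.testing.assert_array_equal(out.runs[0].letters, ens.letters)

    def test_overtrim_fatal(self):
        ens = constant_ensemble("ddd", n_frames=3)
        with pytest.raises(ValueError):
            preprocess([ens], "WT", discard_ps=0.0, trim=2)

    def test_mutation_site_must_be_in_range(self):
        ens = constant_ensemble("ddd", n_frames=3)
        with pytest.raises(ValueError, match="mutation site"):
            preprocess([ens], "V", discard_ps=0.0, trim=0, mutation_site=99)


class TestRegions:
    def test_packaged_calf1_annotation(self):
        regions = calf1_regions()
        assert regions.size("loop9") == 11
        assert regions.size("loop2") == 10
        assert regions.size("loop5") == 8
        assert regions.size("loop1") == 9
        # 10 loops + 9 strands tiling 603..743 without gaps
        assert sum(regions.kinds[i] == "loop" for i in range(len(regions.names))) == 10
        assert sum(regions.kinds[i] == "strand" for i in range(len(regions.names))) == 9
        covered = sum(e - s + 1 for s, e in regions.spans)
        assert covered == 141
        assert regions.label_of(621) == "loop2"
        assert regions.label_of(724) == "strand8"
        assert regions.label_of(999) == "unannotated"

    def test_uniform_profile_gives_equal_region_means(self):
        regions = calf1_regions()
        resnums = np.arange(603, 744)
        summary = region_summary(resnums, np.full(141, 2.5), regions, metric="neq")
        np.testing.assert_allclose(summary["mean_neq"], 2.5)

    def test_planted_hotspot_localized_to_loop2(self):
        regions = calf1_regions()
        resnums = np.arange(603, 744)
        values = np.full(141, 0.1)
        values[resnums == 625] = 1.4
        summary = region_summary(resnums, values, regions, metric="delta_pb")
        best = summary.loc[summary["max_delta_pb"].idxmax()]
        assert best.region == "loop2"
        assert best.argmax_residue == 625

    def test_out_of_region_residues_bucketed(self):
        regions = calf1_regions()
        summary = region_summary([602, 603], [1.0, 2.0], regions)
        assert "unannotated" in set(summary.region)
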