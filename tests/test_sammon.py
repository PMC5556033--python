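import numpy as np
import pytest

from pbflex import (
    SammonMapping,
    SimulationSignature,
    SyntheticScenario,
    barycentres,
    distance_matrix,
    distribution_for_neq,
    sammon_map,
    sample_ensemble,
    signature_distance,
)
from pbflex.sammon import _sammon_stress
from pbflex.statistics import N_PB, PB_LETTERS


def onehot_signature(letter, n_pos=5, sim_id="s", system="sys"):
    row = np.zeros(N_PB)
    row[PB_LETTERS.index(letter)] = 1.0
    return SimulationSignature(sim_id, system, np.tile(row, (n_pos, 1)))


class TestSignatureDistance:
    def test_identical_signatures_give_zero(self):
        a = onehot_signature("d")
        assert signature_distance(a, a) == 0.0

    def test_everywhere_disjoint_one_hots_give_one(self):
        assert signature_distance(onehot_signature("d"), onehot_signature("m")) == 1.0

    def test_matches_bruteforce_l1(self):
        rng = np.random.default_rng(12)
        p = rng.dirichlet(np.ones(N_PB), size=8)
        q = rng.dirichlet(np.ones(N_PB), size=8)
        a = SimulationSignature("a", "A", p)
        b = SimulationSignature("b", "B", q)
        expected = np.mean([np.sum(np.abs(pi - qi)) for pi, qi in zip(p, q)]) / 2
        assert signature_distance(a, b) == pytest.approx(expected)

    def test_undefined_positions_skipped(self):
        p = np.tile(np.eye(N_PB)[0], (4, 1))
        q = p.copy()
        p[0] = np.nan
        a = SimulationSignature("a", "A", p)
        b = SimulationSignature("b", "B", q)
        assert signature_distance(a, b) == 0.0

    def test_no_common_positions_fatal(self):
        p = np.full((3, N_PB), np.nan)
        a = SimulationSignature("a", "A", p)
        with pytest.raises(ValueError):
            signature_distance(a, a)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(3)
        sigs = [
            SimulationSignature(str(i), "S", rng.dirichlet(np.ones(N_PB), size=6))
            for i in range(6)
        ]
        D = distance_matrix(sigs)
        n = len(sigs)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestSammonMapping:
    def test_equilateral_triangle_embeds_exactly(self):
        D = np.ones((3, 3)) - np.eye(3)
        est = SammonMapping().fit(D)
        assert est.stress_ < 1e-6

    def test_planted_2d_configuration_recovered(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        est = SammonMapping(random_state=0).fit(D)
        assert est.stress_ < 1e-4
        d = np.sqrt(((est.embedding_[:, None] - est.embedding_[None]) ** 2).sum(-1))
        iu = np.triu_indices(20, 1)
        assert np.max(np.abs(d[iu] - D[iu]) / D[iu]) < 0.01

    def test_single_point_at_origin(self):
        est = SammonMapping().fit(np.zeros((1, 1)))
        np.testing.assert_array_equal(est.embedding_, [[0.0, 0.0]])
        assert est.stress_ == 0.0

    def test_stress_monotone_nonincreasing(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(15, 6))
        D = np.sqrt(((Y[:, None] - Y[None]) ** 2).sum(-1))
        est = SammonMapping(init="random", random_state=5).fit(D)
        history = np.asarray(est.stress_history_)
        assert np.all(np.diff(history) <= 0)
        assert est.stress_ == history[-1]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(10, 5))
        D = np.sqrt(((Y[:, None] - Y[None]) ** 2).sum(-1))
        a = SammonMapping(init="random", random_state=7).fit(D).embedding_
        b = SammonMapping(init="random", random_state=7).fit(D).embedding_
        np.testing.assert_array_equal(a, b)

    def test_asymmetric_matrix_fatal(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            SammonMapping().fit(D)

    def test_coincident_points_jittered_with_warning(self):
        D = np.array([
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
        ])
        with pytest.warns(UserWarning, match="jitter"):
            est = SammonMapping().fit(D)
        assert np.all(np.isfinite(est.embedding_))

    def test_sklearn_param_interface(self):
        est = SammonMapping(max_iter=123)
        assert est.get_params()["max_iter"] == 123
        est.set_params(tol=1e-6)
        assert est.tol == 1e-6

    def test_relabelling_permutes_rows_only(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(8, 3))
        D = np.sqrt(((Y[:, None] - Y[None]) ** 2).sum(-1))
        perm = rng.permutation(8)
        a = SammonMapping().fit(D).embedding_
        b = SammonMapping().fit(D[np.ix_(perm, perm)]).embedding_
        np.testing.assert_allclose(b, a[perm], atol=1e-8)


class TestBarycentres:
    def test_mean_of_two_points(self):
        out = barycentres(np.array([[0.0, 0.0], [2.0, 2.0]]), ["s", "s"])
        np.testing.assert_allclose(out["s"], [1.0, 1.0])

    def test_single_run_system(self):
        out = barycentres(np.array([[3.0, 4.0]]), ["only"])
        np.testing.assert_allclose(out["only"], [3.0, 4.0])

    def test_unknown_label_count_mismatch_fatal(self):
        with pytest.raises(ValueError):
            barycentres(np.zeros((2, 2)), ["a"])

    def test_study_shape_88_points_8_barycentres(self):
        # 8 systems x 11 runs, one point per simulation
        systems = [f"sys{i}" for i in range(8)]
        rng = np.random.default_rng(0)
        labels, sigs = [], []
        for s, system in enumerate(systems):
            base = rng.dirichlet(np.ones(N_PB) * 0.3, size=10)
            for r in range(11):
                jitter = rng.dirichlet(np.ones(N_PB) * 40, size=10)
                probs = 0.9 * base + 0.1 * jitter
                probs /= probs.sum(axis=1, keepdims=True)
                sigs.append(SimulationSignature(f"{system}|run{r}", system, probs))
                labels.append(system)
        D = distance_matrix(sigs)
        emb = sammon_map(D, [s.simulation_id for s in sigs], labels, seed=1)
        assert emb.points.shape == (88, 2)
        bary = emb.barycentres()
        assert len(bary) == 8
        for system in systems:
            mask = np.array([l == system for l in labels])
            np.testing.assert_allclose(
                bary[system], emb.points[mask].mean(axis=0), atol=1e-12
            )

    def test_cluster_recovery_two_separated_systems(self):
        # planted between-system distance >> within-system: every point ends
        # nearer its own barycentre than the other system's
        scn_a = SyntheticScenario.from_neq_targets([1.2] * 12, support=3, seed=21,
                                                   run_plan_ns=(1,) * 5)
        rows_b = np.stack([
            distribution_for_neq(1.2, support=3, seed=77 + i) for i in range(12)
        ])
        # force disjoint supports by rolling half the alphabet
        rows_b = np.roll(rows_b, 8, axis=1)
        scn_b = SyntheticScenario(rows=rows_b, run_plan_ns=(1,) * 5, master_seed=22)
        sigs, labels = [], []
        for scn, label in ((scn_a, "A"), (scn_b, "B")):
            for r in range(5):
                ens = sample_ensemble(scn, label, r, n_frames=300)
                sigs.append(SimulationSignature.from_ensemble(ens))
                labels.append(label)
        emb = sammon_map(distance_matrix(sigs), systems=labels, seed=3)
        bary = emb.barycentres()
        for point, label in zip(emb.points, labels):
            own = np.linalg.norm(point - bary[label])
            other = min(
                np.linalg.norm(point - b) for l, b in bary.items() if l != label
            )
            assert own < other

    def test_stress_definition_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        D = np.abs(rng.normal(size=(5, 5)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        X = rng.normal(size=(5, 2))
        iu = np.triu_indices(5, 1)
        manual = np.sum(
            (D[iu] - np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))[iu]) ** 2 / D[iu]
        ) / np.sum(D[iu])
        assert _sammon_stress(D, X) == pytest.approx(manual)
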