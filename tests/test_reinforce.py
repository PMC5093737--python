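import numpy as np
import pytest

from ssame import (
    GeneNetwork,
    SmallSubnetwork,
    SSAMEParams,
    extract_pattern,
    rank_genes,
    run_ssa_me,
    update_scores,
    write_results,
)
from ssame.io import read_ranked
from ssame.reinforce import GeneScoreState
from tests.conftest import make_matrix


def make_state(net, mat=None):
    return GeneScoreState(net, mat)


def forced_batch(genes, rmes, mes=1.0):
    return [SmallSubnetwork(genes=tuple(genes), seed=genes[0], mes=mes, rmes=rmes)]


class TestUpdateScores:
    def test_basic_arithmetic(self, toy_net):
        state = make_state(toy_net)
        params = SSAMEParams(forgetfulness=0.995, reinforcement=0.005)
        update_scores(state, forced_batch(["A", "B"], rmes=1.0), params)
        assert state.score_of("A") == pytest.approx(0.5 * 0.995 + 0.005)
        assert state.score_of("B") == pytest.approx(0.5025)

    def test_cap_at_one(self, toy_net):
        state = make_state(toy_net)
        state.scores[:] = 1.0
        params = SSAMEParams(forgetfulness=0.5, reinforcement=0.9)
        update_scores(state, forced_batch(["A", "B"], rmes=1.0), params)
        assert state.score_of("A") == 1.0

    def test_absent_gene_decays(self, toy_net):
        state = make_state(toy_net)
        params = SSAMEParams(forgetfulness=0.995, reinforcement=0.005)
        update_scores(state, forced_batch(["A", "B"], rmes=1.0), params)
        assert state.score_of("C") == pytest.approx(0.4975)

    def test_best_is_max_over_subnetworks(self, toy_net):
        state = make_state(toy_net)
        params = SSAMEParams(forgetfulness=0.995, reinforcement=0.005)
        batch = forced_batch(["A", "B"], rmes=0.3) + forced_batch(
            ["A", "C"], rmes=0.8, mes=2.0
        )
        update_scores(state, batch, params)
        assert state.score_of("A") == pytest.approx(0.5 * 0.995 + 0.005 * 0.8)

    def test_missing_rmes_rejected(self, toy_net):
        state = make_state(toy_net)
        sn = SmallSubnetwork(genes=("A", "B"), seed="A", mes=1.0)
        with pytest.raises(ValueError, match="rmes"):
            update_scores(state, [sn], SSAMEParams())

    def test_scores_stay_in_unit_interval_over_grid(self, toy_net):
        rng = np.random.default_rng(0)
        for f in (0.99, 0.995, 0.9995):
            for r in (0.0005, 0.005, 0.01):
                state = make_state(toy_net)
                params = SSAMEParams(forgetfulness=f, reinforcement=r)
                for _ in range(300):
                    batch = forced_batch(
                        ["A", "B"], rmes=float(rng.random())
                    )
                    update_scores(state, batch, params)
                    assert (state.scores >= 0.0).all()
                    assert (state.scores <= 1.0).all()
                    assert (state.max_score >= state.scores - 1e-15).all()

    def test_max_score_non_decreasing(self, toy_net):
        rng = np.random.default_rng(1)
        state = make_state(toy_net)
        params = SSAMEParams()
        prev = state.max_score.copy()
        for _ in range(200):
            update_scores(state, forced_batch(["A", "B"], float(rng.random())), params)
            assert (state.max_score >= prev - 1e-15).all()
            prev = state.max_score.copy()


class TestClosedForms:
    def test_pure_decay_r_zero_limit(self, toy_net):
        # degenerate r -> 0 realized with best = 0 (no subnetworks): after T
        # iterations every score equals 0.5 * f^T up to iterated rounding
        state = make_state(toy_net)
        f = 0.995
        params = SSAMEParams(forgetfulness=f, reinforcement=0.005)
        expected = 0.5
        for _ in range(1000):
            update_scores(state, [], params)
            expected *= f
        assert state.score_of("A") == expected  # identical arithmetic
        assert expected == pytest.approx(0.00334, abs=5e-5)

    @pytest.mark.parametrize(
        "f,r,m",
        [
            (0.995, 0.005, 0.6),
            (0.99, 0.01, 0.8),
            (0.99, 0.0005, 0.4),
            (0.995, 0.005, 1.0),
            (0.9, 0.5, 1.0),  # fixed point above 1: capped
        ],
    )
    def test_constant_best_fixed_point(self, toy_net, f, r, m):
        state = make_state(toy_net)
        params = SSAMEParams(forgetfulness=f, reinforcement=r)
        for _ in range(10_000):
            update_scores(state, forced_batch(["A", "B"], rmes=m), params)
        expected = min(1.0, r * m / (1.0 - f))
        assert state.score_of("A") == pytest.approx(expected, abs=1e-6)

    def test_monotone_brackets(self, toy_net):
        # f=1: non-decreasing; best=0: strictly decreasing toward 0
        state_up = make_state(toy_net)
        params_up = SSAMEParams(forgetfulness=1.0, reinforcement=0.01)
        prev = state_up.score_of("A")
        for _ in range(100):
            update_scores(state_up, forced_batch(["A", "B"], 0.7), params_up)
            assert state_up.score_of("A") >= prev
            prev = state_up.score_of("A")
        state_dn = make_state(toy_net)
        params_dn = SSAMEParams(forgetfulness=0.9, reinforcement=0.01)
        prev = state_dn.score_of("A")
        for _ in range(100):
            update_scores(state_dn, [], params_dn)
            assert state_dn.score_of("A") < prev
            prev = state_dn.score_of("A")
        assert state_dn.score_of("A") < 1e-4


class TestConvergenceIter:
    def _brute_force(self, trajectory):
        """First index from which every score >= 0.99 * final max."""
        thr = 0.99 * max(trajectory)
        cand = None
        for i, s in enumerate(trajectory):
            if s >= thr:
                if cand is None:
                    cand = i
            else:
                cand = None
        return cand if cand is not None else len(trajectory)

    def test_matches_trajectory_definition(self, toy_net):
        rng = np.random.default_rng(17)
        state = make_state(toy_net)
        params = SSAMEParams(forgetfulness=0.97, reinforcement=0.03)
        traj = {g: [0.5] for g in toy_net.nodes}
        for _ in range(400):
            batch = []
            if rng.random() < 0.8:
                batch = forced_batch(["A", "B"], float(rng.random()))
            if rng.random() < 0.5:
                batch += forced_batch(["C", "D"], float(rng.random()), mes=0.5)
            update_scores(state, batch, params)
            for g in toy_net.nodes:
                traj[g].append(state.score_of(g))
        for g in toy_net.nodes:
            expected = self._brute_force(traj[g])
            got = state.convergence_iter_of(g)
            if expected == len(traj[g]):  # never stabilized -> sentinel
                assert got == state.iteration + 1
            else:
                assert got == expected, g


class TestRunSSAME:
    def test_initial_scores_half(self, toy_net, toy_mat):
        state = GeneScoreState(toy_net, toy_mat)
        assert (state.scores == 0.5).all()

    def test_determinism(self, toy_net, toy_mat):
        params = SSAMEParams(iterations=50, rng_seed=5)
        s1, r1 = run_ssa_me(toy_net, toy_mat, params)
        s2, r2 = run_ssa_me(toy_net, toy_mat, params)
        assert np.array_equal(s1.scores, s2.scores)
        assert r1.to_frame().equals(r2.to_frame())

    def test_scores_bounded(self, toy_net, toy_mat):
        params = SSAMEParams(iterations=200, rng_seed=1)
        state, _ = run_ssa_me(toy_net, toy_mat, params)
        assert (state.scores >= 0.0).all() and (state.scores <= 1.0).all()

    def test_work_per_iteration_equals_seed_count(self, toy_net, toy_mat):
        # toy_net is connected, so every seed yields one scored subnetwork
        params = SSAMEParams(iterations=30, rng_seed=2)
        state, _ = run_ssa_me(toy_net, toy_mat, params)
        n_seeds = 4  # A, B, C, D altered
        assert state.mes_evaluations == [n_seeds] * 30

    def test_exclusive_module_outranks_background(self, toy_net, toy_mat):
        params = SSAMEParams(iterations=400, rng_seed=3)
        _, ranked = run_ssa_me(toy_net, toy_mat, params)
        top3 = set(ranked.genes()[:3])
        assert {"A", "B", "C"} <= top3 | {"D"}  # exclusive trio + linker slack
        assert ranked.genes()[-1] in {"E", "F", "G"}  # unaltered genes sink

    def test_matrix_gene_missing_from_network_warns(self, toy_net, caplog):
        mat = make_matrix(
            ["A", "B", "ZZ"], ["s0", "s1"],
            [("A", "s0"), ("B", "s1"), ("ZZ", "s0")],
        )
        params = SSAMEParams(iterations=5, rng_seed=0)
        with caplog.at_level("WARNING", logger="ssame.sampler"):
            state, ranked = run_ssa_me(toy_net, mat, params)
        assert "absent from the network" in caplog.text
        assert "ZZ" not in ranked.genes()

    def test_convergence_stability_soft(self, toy_study):
        # stability contract: every gene that ever reaches a high score is
        # still within 5% of its maximum at the end of the run (no gene that
        # converges high later drifts back down)
        params = SSAMEParams(iterations=3000, rng_seed=4)
        state, _ = run_ssa_me(toy_study.network, toy_study.matrix, params)
        high = state.max_score > 0.9
        assert high.any()
        assert (state.scores[high] >= 0.95 * state.max_score[high]).all()

    def test_early_stop_disabled_on_small_networks(self, toy_net, toy_mat):
        params = SSAMEParams(iterations=700, rng_seed=0)  # k=100 >= 7 genes
        state, _ = run_ssa_me(toy_net, toy_mat, params)
        assert len(state.mes_evaluations) == 700


class TestRankGenes:
    def _state_with(self, net, max_scores, conv):
        state = GeneScoreState(net)
        for g, v in max_scores.items():
            state.max_score[state.index[g]] = v
        for g, v in conv.items():
            state._cand[state.index[g]] = v
        return state

    def test_order_by_max_score(self, toy_net):
        state = self._state_with(toy_net, {"A": 1.0, "B": 0.7}, {})
        ranked = rank_genes(state)
        assert ranked.genes()[:2] == ["A", "B"]
        assert [e.rank for e in ranked.entries] == list(range(1, 8))

    def test_tie_broken_by_convergence_speed(self, toy_net):
        state = self._state_with(
            toy_net, {"A": 1.0, "B": 1.0}, {"A": 4000, "B": 1200}
        )
        ranked = rank_genes(state)
        assert ranked.genes()[:2] == ["B", "A"]

    def test_full_tie_lexicographic(self, toy_net):
        state = GeneScoreState(toy_net)
        ranked = rank_genes(state)
        assert ranked.genes() == sorted(toy_net.nodes)


class TestExtractPattern:
    def _state_with_tops(self, net, mat, gene, subnetworks):
        state = GeneScoreState(net, mat)
        gi = state.index[gene]
        for sn in subnetworks:
            state._push_top(gi, sn)
        return state

    def test_union_of_retained(self, toy_net, toy_mat):
        sns = [
            SmallSubnetwork(genes=("A", "B", "C"), seed="A", mes=3.0),
            SmallSubnetwork(genes=("A", "C", "D"), seed="A", mes=2.0),
        ]
        state = self._state_with_tops(toy_net, toy_mat, "A", sns)
        genes, tiles = extract_pattern("A", state)
        assert set(genes) == {"A", "B", "C", "D"}
        assert list(tiles.index) == genes  # ordered by descending count
        counts = tiles.sum(axis=1).to_list()
        assert counts == sorted(counts, reverse=True)

    def test_identical_subnetworks_collapse(self, toy_net, toy_mat):
        sn = SmallSubnetwork(genes=("A", "B", "C"), seed="A", mes=3.0)
        state = self._state_with_tops(toy_net, toy_mat, "A", [sn] * 5)
        genes, _ = extract_pattern("A", state)
        assert set(genes) == {"A", "B", "C"}
        assert len(state.top_subnetworks("A")) == 1

    def test_no_retained_gives_singleton(self, toy_net, toy_mat):
        state = GeneScoreState(toy_net, toy_mat)
        genes, tiles = extract_pattern("A", state)
        assert genes == ["A"]
        assert tiles.shape == (1, toy_mat.n_samples)

    def test_top_list_bounded_and_sorted(self, toy_net, toy_mat):
        rng = np.random.default_rng(0)
        state = GeneScoreState(toy_net, toy_mat)
        gi = state.index["A"]
        for i in range(500):
            genes = ("A", f"x{i}")
            state._push_top(
                gi, SmallSubnetwork(genes=genes, seed="A", mes=float(rng.random()))
            )
        tops = state.top_subnetworks("A")
        assert len(tops) == 5
        mes_vals = [sn.mes for sn in tops]
        assert mes_vals == sorted(mes_vals, reverse=True)
        assert mes_vals[0] > 0.97  # kept the best of 500 draws

    def test_retention_bound_in_real_run(self, toy_net, toy_mat):
        params = SSAMEParams(iterations=500, rng_seed=8)
        state, ranked = run_ssa_me(toy_net, toy_mat, params)
        for g in toy_net.nodes:
            tops = state.top_subnetworks(g)
            assert len(tops) <= 5
            assert all(g in sn.genes for sn in tops)
            mes_vals = [sn.mes for sn in tops]
            assert mes_vals == sorted(mes_vals, reverse=True)


class TestWriteResults:
    def test_files_and_round_trip(self, tmp_path, toy_net, toy_mat):
        params = SSAMEParams(iterations=100, rng_seed=0)
        state, ranked = run_ssa_me(toy_net, toy_mat, params)
        written = write_results(ranked, state, tmp_path, n_patterns=3)
        ranked_back = read_ranked(written["ranked_genes"])
        assert ranked_back.genes() == ranked.genes()
        assert [e.rank for e in ranked_back] == [e.rank for e in ranked]
        attrs = (tmp_path / "node_attributes.tsv").read_text().splitlines()
        assert attrs[0] == "gene\tscore\tn_samples_altered"
        assert len(attrs) == 1 + toy_net.n_nodes
        assert len(list((tmp_path / "patterns").glob("*.tsv"))) == 3

    def test_empty_ranking_rejected(self, tmp_path, toy_net, toy_mat):
        from ssame.datatypes import RankedGeneList

        state = GeneScoreState(toy_net, toy_mat)
        with pytest.raises(ValueError):
            write_results(RankedGeneList(), state, tmp_path)
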