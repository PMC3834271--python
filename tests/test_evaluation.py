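import numpy as np
import pytest

from kngp.evaluation import (
    auc_from_ranks,
    calibrate_beta,
    find_best_f,
    loocv_ranks,
)
from kngp.inference import propagate
from kngp.network import RootSet, build_transition_matrix, compute_kngp_prior

from .conftest import make_network, random_network


def roc_trapezoid_auc(ranks, L):
    """Independent oracle: explicit rank-threshold sweep + trapezoid rule.

    At threshold t, sensitivity is the fraction of lists whose held-out
    node sits at rank <= t; the false-positive rate is the fraction of
    the L-1 filler positions per list at or above t.
    """
    ranks = np.asarray(ranks, dtype=float)
    m = ranks.size
    tpr = [0.0]
    fpr = [0.0]
    for t in range(1, L + 1):
        hits = np.sum(ranks <= t)
        tpr.append(hits / m)
        fpr.append((t * m - hits) / (m * (L - 1)))
    return float(np.trapezoid(tpr, fpr))


class TestAucFromRanks:
    def test_all_top_ranks_give_perfect_auc(self):
        assert auc_from_ranks([1] * 30, 100) == 1.0

    def test_uniform_ranks_give_half(self):
        assert auc_from_ranks(np.arange(1, 101), 100) == pytest.approx(0.5)

    def test_symmetric_extremes_give_half(self):
        assert auc_from_ranks([1, 100], 100) == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            auc_from_ranks([], 100)

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValueError, match="ranks must lie"):
            auc_from_ranks([0.5], 100)

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_threshold_sweep_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(5, 120))
        ranks = rng.integers(1, L + 1, size=rng.integers(1, 60))
        assert auc_from_ranks(ranks, L) == pytest.approx(
            roc_trapezoid_auc(ranks, L), abs=1e-12
        )


def five_node_net():
    # star around r1/r2 with one weak outlier; node weights favour c1
    return make_network(
        ["r1", "r2", "c1", "c2", "c3"],
        {
            ("r1", "r2"): 0.9,
            ("r1", "c1"): 0.5,
            ("r2", "c1"): 0.6,
            ("r1", "c2"): 0.2,
            ("c2", "c3"): 0.3,
        },
        node_weights={"r1": 1.0, "r2": 0.8, "c1": 0.9, "c2": 0.3, "c3": 0.1},
    )


class TestLoocvRanks:
    def test_matches_brute_force_enumeration_on_toy_network(self):
        """Each fold re-derived by hand: direct linear solve + manual sort."""
        net = five_node_net()
        roots = RootSet(["r1", "r2"])
        f, beta, k, L, seed = 2.0, 0.4, 1, 3, 123
        res = loocv_ranks(net, roots, f=f, beta=beta, k=k, L=L, seed=seed, delta=1e-12)

        q = build_transition_matrix(net).q
        expected = []
        non_root = [i for i, nid in enumerate(net.node_ids) if nid not in {"r1", "r2"}]
        for i, r in enumerate(["r1", "r2"]):
            held = RootSet([m for m in ["r1", "r2"] if m != r])
            pr = compute_kngp_prior(net, held, f).pr
            po = np.linalg.solve(np.eye(5) - (1 - beta) * q, beta * pr)
            rng = np.random.default_rng(np.random.SeedSequence([seed, net.index_of(r), 0]))
            fillers = rng.choice(np.array(non_root), size=L - 1, replace=False)
            scores = sorted([po[net.index_of(r)]] + [po[j] for j in fillers], reverse=True)
            expected.append(scores.index(po[net.index_of(r)]) + 1)
        assert list(res.list_ranks) == expected

    def test_perfectly_separating_network_gives_auc_one(self):
        # roots massively outweigh candidates at f=0 via node knowledge
        rng = np.random.default_rng(21)
        net = random_network(rng, 40)
        nw = net.node_weights.copy()
        nw[:8] += 100.0
        net = net.__class__(net.node_ids, net.link_weights, nw)
        roots = RootSet(net.node_ids[:8])
        res = loocv_ranks(net, roots, f=0.0, beta=0.5, k=3, L=10, seed=5)
        assert np.all(res.list_ranks == 1)
        assert res.auc == 1.0

    def test_identical_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(22)
        net = random_network(rng, 30)
        roots = RootSet(net.node_ids[:5])
        a = loocv_ranks(net, roots, f=3.0, beta=0.3, k=2, L=8, seed=9)
        b = loocv_ranks(net, roots, f=3.0, beta=0.3, k=2, L=8, seed=9)
        assert np.array_equal(a.list_ranks, b.list_ranks)
        assert a.auc == b.auc

    def test_rank_count_and_range(self):
        rng = np.random.default_rng(23)
        net = random_network(rng, 30)
        roots = RootSet(net.node_ids[:6])
        res = loocv_ranks(net, roots, f=1.0, beta=0.3, k=4, L=12, seed=0)
        assert res.list_ranks.shape == (6 * 4,)
        assert np.all((res.list_ranks >= 1) & (res.list_ranks <= 12))

    def test_too_small_candidate_pool_rejected(self):
        net = five_node_net()
        with pytest.raises(ValueError, match="non-root"):
            loocv_ranks(net, RootSet(["r1", "r2"]), f=1.0, L=5, seed=0)

    def test_fillers_never_include_root_members(self):
        # with L-1 == pool size every filler draw is the full non-root pool
        net = five_node_net()
        res = loocv_ranks(net, RootSet(["r1", "r2"]), f=1.0, beta=0.3, k=2, L=4, seed=1)
        assert res.list_ranks.shape == (4,)


class TestFindBestF:
    def test_singleton_grid_returns_that_f(self):
        rng = np.random.default_rng(30)
        net = random_network(rng, 25)
        best, results = find_best_f(net, RootSet(net.node_ids[:5]), F=[42.0], k=1, L=5, seed=3)
        assert best == 42.0
        assert set(results) == {42.0}

    def test_ties_break_to_smallest_f(self):
        # node-weight-separated net: every f ranks the left-out root first
        rng = np.random.default_rng(31)
        net = random_network(rng, 30)
        nw = net.node_weights.copy()
        nw[:5] += 100.0
        net = net.__class__(net.node_ids, net.link_weights, nw)
        roots = RootSet(net.node_ids[:5])
        best, results = find_best_f(net, roots, F=[0.0, 1.0, 2.0], beta=0.6, k=2, L=6, seed=4)
        aucs = {f: r.auc for f, r in results.items()}
        assert aucs[0.0] == aucs[1.0] == 1.0
        assert best == 0.0

    def test_grid_shares_sampling_across_f(self):
        rng = np.random.default_rng(32)
        net = random_network(rng, 25)
        roots = RootSet(net.node_ids[:4])
        _, results = find_best_f(net, roots, F=[1.0], k=2, L=6, seed=7)
        solo = loocv_ranks(net, roots, f=1.0, k=2, L=6, seed=7)
        assert np.array_equal(results[1.0].list_ranks, solo.list_ranks)

    def test_empty_or_negative_grid_rejected(self):
        net = five_node_net()
        roots = RootSet(["r1"])
        with pytest.raises(ValueError, match="non-empty"):
            find_best_f(net, roots, F=[])
        with pytest.raises(ValueError, match="non-negative"):
            find_best_f(net, roots, F=[-1.0])


class TestCalibrateBeta:
    def test_returns_argmax_beta_and_all_results(self):
        rng = np.random.default_rng(33)
        net = random_network(rng, 30)
        roots = RootSet(net.node_ids[:5])
        best, results = calibrate_beta(net, roots, f=5.0, betas=(0.2, 0.8), k=1, L=6, seed=2)
        assert set(results) == {0.2, 0.8}
        assert results[best].auc == max(r.auc for r in results.values())


class TestAucInvariances:
    def test_auc_invariant_to_list_order(self):
        rng = np.random.default_rng(34)
        ranks = rng.integers(1, 51, size=40)
        shuffled = rng.permutation(ranks)
        assert auc_from_ranks(ranks, 50) == auc_from_ranks(shuffled, 50)

    def test_ranks_invariant_to_monotone_posterior_transform(self):
        rng = np.random.default_rng(35)
        net = random_network(rng, 20)
        roots = RootSet(net.node_ids[:3])
        q = build_transition_matrix(net)
        pr = compute_kngp_prior(net, roots, 2.0)
        post = propagate(q, pr, beta=0.4)
        from kngp.inference import PosteriorVector, rank_candidates

        warped = PosteriorVector(
            po=np.exp(3 * post.po), node_ids=post.node_ids,
            iterations_used=post.iterations_used, converged=True,
        )
        cands = net.node_ids[3:]
        assert list(rank_candidates(post, cands)["rank"]) == list(
            rank_candidates(warped, cands)["rank"]
        )
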