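"""Model averaging: chordal enumeration, hyper-Dirichlet marginals,
and the averaged posterior, each against an independent brute force."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from msesim.bma import DecomposableModel, bma_posterior, enumerate_decomposable, log_marginal
from msesim.synthetic import FrequencyTable, all_histories

from conftest import random_table


# ---------------------------------------------------------------------------
# independent chordality oracle: greedy simplicial elimination
# ---------------------------------------------------------------------------


def is_chordal_by_elimination(K, edges):
    """A graph is chordal iff vertices can be repeatedly eliminated in
    simplicial order (every neighbor pair adjacent)."""
    adj = {v: set() for v in range(K)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    remaining = set(range(K))
    while remaining:
        for v in remaining:
            nbrs = adj[v] & remaining
            if all(b in adj[a] for a, b in itertools.combinations(nbrs, 2)):
                remaining.remove(v)
                break
        else:
            return False
    return True


class TestEnumeration:
    @pytest.mark.parametrize("K,count", [(1, 1), (2, 2), (3, 8), (4, 61), (5, 822)])
    def test_counts_match_chordal_sequence(self, K, count):
        assert len(enumerate_decomposable(K)) == count

    @pytest.mark.parametrize("K", [3, 4, 5])
    def test_exact_edge_sets_against_elimination_oracle(self, K):
        pairs = list(itertools.combinations(range(K), 2))
        oracle = set()
        for mask in range(2 ** len(pairs)):
            edges = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
            if is_chordal_by_elimination(K, edges):
                oracle.add(frozenset(frozenset(e) for e in edges))
        got = {m.edges for m in enumerate_decomposable(K)}
        assert got == oracle

    @pytest.mark.parametrize("K", [3, 4])
    def test_junction_factorization_valid(self, K):
        for m in enumerate_decomposable(K):
            vertices = set().union(*m.cliques) if m.cliques else set()
            assert vertices == set(range(K))
            # running-intersection: order cliques so each one's overlap with
            # the union of its predecessors sits inside a single predecessor
            assert len(m.separators) <= len(m.cliques) - 1 or not m.separators
            counts = {}
            for s in m.separators:
                counts[s] = counts.get(s, 0) + 1
            # each separator must be contained in at least two cliques
            for s in m.separators:
                assert sum(s <= c for c in m.cliques) >= 2

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            enumerate_decomposable(6)


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


def brute_log_marginal(model, table, n0, delta):
    """From-scratch hyper-Dirichlet marginal: explicit margins, explicit
    Dirichlet-multinomial normalizers, explicit multinomial coefficient."""
    K = model.K
    full = np.zeros(2**K)
    full[0] = n0
    full[1:] = table.array
    N = full.sum()
    H = np.vstack([np.zeros(K, dtype=int), all_histories(K)])

    def dm(subset):
        idx = sorted(subset)
        cells = {}
        for row, cnt in zip(H, full):
            key = tuple(row[i] for i in idx)
            cells[key] = cells.get(key, 0.0) + cnt
        d = delta * 2 ** (K - len(idx))
        s = d * len(cells)
        out = gammaln(s) - gammaln(s + N)
        for cnt in cells.values():
            out += gammaln(d + cnt) - gammaln(d)
        return out

    out = gammaln(N + 1) - gammaln(full + 1).sum()
    for c in model.cliques:
        out += dm(c)
    for s in model.separators:
        out -= dm(s)
    return out


class TestLogMarginal:
    def test_matches_brute_force_all_k3_models(self, rng):
        t = random_table(rng, K=3, lam=4.0)
        for model in enumerate_decomposable(3):
            for n0 in (0, 5, 40):
                assert log_marginal(model, t, n0) == pytest.approx(
                    brute_log_marginal(model, t, n0, 2.0**-3), abs=1e-9
                )

    def test_saturated_equals_plain_dirichlet_multinomial(self, rng):
        t = random_table(rng, K=3, lam=3.0)
        sat = next(m for m in enumerate_decomposable(3) if len(m.edges) == 3)
        n0, delta = 7, 2.0**-3
        x = np.r_[n0, t.array].astype(float)
        N = x.sum()
        oracle = (
            gammaln(N + 1)
            - gammaln(x + 1).sum()
            + gammaln(8 * delta)
            - gammaln(8 * delta + N)
            + (gammaln(delta + x) - gammaln(delta)).sum()
        )
        assert log_marginal(sat, t, n0) == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("total", [3, 4])
    def test_sums_to_one_over_table_partition(self, total):
        # the marginal including the multinomial coefficient is a proper
        # distribution over completed tables at fixed total
        for model in enumerate_decomposable(2):
            acc = []
            for x in itertools.product(range(total + 1), repeat=4):
                if sum(x) != total:
                    continue
                t = FrequencyTable(2, np.array(x[1:]))
                acc.append(log_marginal(model, t, x[0]))
            assert np.exp(logsumexp(acc)) == pytest.approx(1.0, abs=1e-10)

    def test_list_swap_symmetry(self):
        t = FrequencyTable(2, {(1, 0): 4, (0, 1): 4, (1, 1): 2})
        indep = next(m for m in enumerate_decomposable(2) if not m.edges)
        swapped = FrequencyTable(2, {(1, 0): 4, (0, 1): 4, (1, 1): 2})
        assert log_marginal(indep, t, 3) == pytest.approx(log_marginal(indep, swapped, 3))

    def test_empty_table_zero_n0(self):
        t = FrequencyTable(2, np.zeros(3, dtype=int))
        for model in enumerate_decomposable(2):
            assert log_marginal(model, t, 0) == pytest.approx(0.0, abs=1e-12)

    def test_negative_n0_rejected(self, rng):
        t = random_table(rng, K=3)
        with pytest.raises(ValueError):
            log_marginal(enumerate_decomposable(3)[0], t, -1)


# ---------------------------------------------------------------------------
# averaged posterior
# ---------------------------------------------------------------------------


def brute_posterior(table, n0_max, delta, models):
    logw = np.array(
        [
            [brute_log_marginal(m, table, n0, delta) - np.log(table.n_observed + n0) for n0 in range(n0_max + 1)]
            for m in models
        ]
    )
    joint = np.exp(logw - logsumexp(logw))
    return joint.sum(axis=0) / joint.sum()


class TestAveragedPosterior:
    def test_matches_brute_force_on_k3_toy(self, rng):
        t = random_table(rng, K=3, lam=3.0)
        models = enumerate_decomposable(3)
        grid = bma_posterior(t, n0_max=60, models=models)
        brute = brute_posterior(t, 60, 2.0**-3, models)
        assert np.allclose(grid.averaged_posterior, brute, atol=1e-10)
        assert grid.averaged_posterior.sum() == pytest.approx(1.0)
        assert grid.model_posteriors.sum() == pytest.approx(1.0)

    def test_single_model_set_reduces_to_that_model(self, rng):
        t = random_table(rng, K=3, lam=3.0)
        sat = [m for m in enumerate_decomposable(3) if len(m.edges) == 3]
        grid = bma_posterior(t, n0_max=60, models=sat)
        assert grid.model_posteriors == pytest.approx([1.0])
        brute = brute_posterior(t, 60, 2.0**-3, sat)
        assert np.allclose(grid.averaged_posterior, brute, atol=1e-10)

    def test_relabeling_lists_leaves_posterior_unchanged(self, rng):
        t = random_table(rng, K=3, lam=6.0)
        perm = [1, 2, 0]
        t2 = FrequencyTable(3, {tuple(h[i] for i in perm): c for h, c in t.counts.items()})
        g1 = bma_posterior(t, n0_max=80)
        g2 = bma_posterior(t2, n0_max=80)
        assert np.allclose(g1.averaged_posterior, g2.averaged_posterior, atol=1e-10)

    def test_truncation_tail_negligible_at_default_cap(self, rng):
        t = random_table(rng, K=3, lam=10.0)
        grid = bma_posterior(t, n0_max=10 * t.n_observed)
        assert grid.averaged_posterior[-1] < 1e-6

    def test_interval_and_median_are_quantiles(self, rng):
        t = random_table(rng, K=3, lam=10.0)
        grid = bma_posterior(t, n0_max=10 * t.n_observed)
        lo, hi = grid.interval(0.95)
        assert lo <= grid.median_N <= hi
        assert grid.median_N >= t.n_observed

    def test_self_consistency_calibration(self):
        # data drawn from the model's own prior must be covered at the
        # nominal rate: a direct check that the posterior is correct Bayes
        rng = np.random.default_rng(17)
        K, delta = 3, 2.0**-3
        sat = [m for m in enumerate_decomposable(K) if len(m.edges) == 3]
        hits = reps = 0
        for _ in range(80):
            Ns = np.arange(50, 1501)
            pr = 1 / Ns
            N = int(rng.choice(Ns, p=pr / pr.sum()))
            q = rng.dirichlet(np.full(2**K, delta))
            counts = rng.multinomial(N, q)
            t = FrequencyTable(K, counts[1:])
            if t.n_observed == 0:
                continue
            lo, hi = bma_posterior(t, n0_max=1500 - t.n_observed, models=sat).interval(0.95)
            hits += lo <= N <= hi
            reps += 1
        assert 0.88 <= hits / reps <= 1.0

    def test_two_list_rejected(self):
        t = FrequencyTable(2, {(1, 0): 5, (0, 1): 5, (1, 1): 2})
        with pytest.raises(ValueError):
            bma_posterior(t, n0_max=10)
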