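"""Triplet statistics, KLD estimation, EPR_aff / EPR_WTD / MDAF."""

import numpy as np
import pytest

from wtdepr.chains import JumpChain
from wtdepr.semimarkov import (
    TripletStats,
    bootstrap_errors,
    collect_triplets,
    epr_aff,
    epr_wtd,
    kld_estimate,
    mdaf,
    triplet_probability,
)
from wtdepr.synthetic import closed_form_kld


def brute_force_triplets(states, dwells):
    """Independent enumeration oracle for triplet statistics."""
    counts, samples, pairs = {}, {}, {}
    for idx in range(1, len(states) - 1):
        t = (states[idx - 1], states[idx], states[idx + 1])
        counts[t] = counts.get(t, 0) + 1
        samples.setdefault(t, []).append(dwells[idx])
        pairs[t[:2]] = pairs.get(t[:2], 0) + 1
    total = sum(pairs.values())
    R = {p: c / total for p, c in pairs.items()}
    tau_ij = {
        p: np.mean([dw for t, s in samples.items() if t[:2] == p for dw in s]) for p in pairs
    }
    trans = {t: c / pairs[t[:2]] for t, c in counts.items()}
    tau = sum(R[p] * tau_ij[p] for p in pairs)
    return counts, samples, R, tau_ij, trans, tau


class TestCollectTriplets:
    def test_alternating_chain_by_hand(self):
        states = np.array([1, 2, 1, 2, 1, 2, 1])
        dwells = np.ones(7)
        stats = collect_triplets(JumpChain(states, dwells))
        assert set(stats.counts) == {(1, 2, 1), (2, 1, 2)}
        assert stats.R[(1, 2)] == pytest.approx(0.6)  # 3 of 5 interior pairs
        assert stats.R[(2, 1)] == pytest.approx(0.4)
        assert stats.tau == pytest.approx(1.0)
        assert stats.transition_prob[(1, 2, 1)] == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        states = [1]
        for _ in range(400):
            s = states[-1]
            nxt = [x for x in (s - 1, s + 1) if 1 <= x <= 4]
            states.append(int(rng.choice(nxt)))
        states = np.array(states)
        dwells = rng.exponential(1.0, len(states))
        chain = JumpChain(states, dwells)
        stats = collect_triplets(chain)
        counts, samples, R, tau_ij, trans, tau = brute_force_triplets(states, dwells)
        assert stats.counts == counts
        for t in counts:
            np.testing.assert_allclose(np.sort(stats.dwell_samples[t]), np.sort(samples[t]))
            assert stats.transition_prob[t] == pytest.approx(trans[t], rel=1e-12)
        for p in R:
            assert stats.R[p] == pytest.approx(R[p], rel=1e-12)
            assert stats.tau_ij[p] == pytest.approx(tau_ij[p], rel=1e-12)
        assert stats.tau == pytest.approx(tau, rel=1e-12)

    def test_normalizations(self, lumped_ctmc_chain):
        stats = collect_triplets(lumped_ctmc_chain)
        assert sum(stats.R.values()) == pytest.approx(1.0, rel=1e-12)
        pair_sums = {}
        for (i, j, k), p in stats.transition_prob.items():
            pair_sums[(i, j)] = pair_sums.get((i, j), 0.0) + p
        for s in pair_sums.values():
            assert s == pytest.approx(1.0, rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            collect_triplets(JumpChain(np.array([1, 2]), np.array([0.5, 0.5])))


class TestEPRAff:
    def test_zero_on_linear_chain(self, lumped_ctmc_chain):
        stats = collect_triplets(lumped_ctmc_chain)
        # statistical zero: the lumped ladder has no observable net flux
        assert abs(epr_aff(stats)) < 1e-3

    def test_hand_filled_table(self):
        # two interior triplets with asymmetric transition probabilities
        samples = {
            (1, 2, 3): np.full(3, 1.0),
            (3, 2, 1): np.full(1, 1.0),
            (1, 2, 1): np.full(1, 1.0),
            (3, 2, 3): np.full(1, 1.0),
            (2, 1, 2): np.full(2, 1.0),
            (2, 3, 2): np.full(2, 1.0),
        }
        counts = {t: len(s) for t, s in samples.items()}
        total = sum(counts.values())
        pair_counts = {}
        for (i, j, k), c in counts.items():
            pair_counts[(i, j)] = pair_counts.get((i, j), 0) + c
        R = {p: c / total for p, c in pair_counts.items()}
        trans = {t: counts[t] / pair_counts[t[:2]] for t in counts}
        stats = TripletStats(
            counts=counts,
            dwell_samples=samples,
            R=R,
            tau_ij={p: 1.0 for p in R},
            transition_prob=trans,
            tau=1.0,
        )
        # independent spreadsheet-style evaluation
        expected = sum(
            R[(i, j)] * trans[(i, j, k)] * np.log(trans[(i, j, k)] / trans[(k, j, i)])
            for (i, j, k) in trans
        )
        assert epr_aff(stats) == pytest.approx(expected, rel=1e-12)
        assert expected > 0  # asymmetric table carries net flux

    def test_reversible_symmetric_chain_is_zero(self):
        rng = np.random.default_rng(1)
        states = [1, 2]
        for _ in range(2000):
            s = states[-1]
            nxt = [x for x in (s - 1, s + 1) if 1 <= x <= 3]
            states.append(int(rng.choice(nxt)))
        chain = JumpChain(np.array(states), rng.exponential(1.0, len(states)))
        value = epr_aff(collect_triplets(chain))
        assert abs(value) < 0.05

    def test_missing_reverse_is_unbounded(self):
        # strictly ascending staircase: no reverse passages at all
        chain = JumpChain(np.array([1, 2, 3, 4, 5]), np.ones(5))
        with pytest.warns(UserWarning, match="no observed reverse"):
            assert epr_aff(collect_triplets(chain)) == np.inf


class TestKLDEstimate:
    def test_identical_samples_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(1.0, 2000)
        res = kld_estimate(x, x.copy(), seed=1)
        assert res.value == 0.0  # clipped; raw may be slightly negative

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(2)
        p = rng.exponential(1.0, 8000)
        q = rng.exponential(0.5, 8000)
        exact = closed_form_kld(("exp", 1.0), ("exp", 2.0))
        res = kld_estimate(p, q, n_boot=40, seed=3)
        assert res.value == pytest.approx(exact, abs=2.5 * max(res.stderr, 0.01))

    def test_gamma_closed_form(self):
        rng = np.random.default_rng(4)
        p = rng.gamma(2.0, 1.0, 8000)
        q = rng.gamma(3.0, 1 / 1.5, 8000)
        exact = closed_form_kld(("gamma", 2.0, 1.0), ("gamma", 3.0, 1.5))
        res = kld_estimate(p, q, n_boot=40, seed=5)
        assert res.value == pytest.approx(exact, abs=2.5 * max(res.stderr, 0.01))

    def test_histogram_method_agrees_roughly(self):
        rng = np.random.default_rng(6)
        p = rng.exponential(1.0, 8000)
        q = rng.exponential(0.5, 8000)
        exact = closed_form_kld(("exp", 1.0), ("exp", 2.0))
        res = kld_estimate(p, q, method="hist", seed=7)
        assert res.value == pytest.approx(exact, rel=0.25)

    def test_lattice_samples_handled(self):
        # dwells quantized to a grid: dithering must keep the estimate finite
        rng = np.random.default_rng(8)
        p = np.ceil(rng.exponential(20.0, 3000))
        q = np.ceil(rng.exponential(10.0, 3000))
        res = kld_estimate(p, q, seed=9)
        assert np.isfinite(res.value) and res.value > 0

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            kld_estimate(np.ones(10), np.ones(10))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            kld_estimate(np.zeros(100) + 1.0, np.linspace(-1, 1, 100))


class TestEPRWTD:
    def test_weighted_sum_recovered_on_known_construction(self):
        # construct a chain whose interior dwells follow Exp(1) up, Exp(2) down
        rng = np.random.default_rng(10)
        states = [1, 2]
        for _ in range(30_000):
            s = states[-1]
            nxt = [x for x in (s - 1, s + 1) if 1 <= x <= 3]
            states.append(int(rng.choice(nxt)))
        states = np.array(states)
        dwells = np.ones(len(states))
        for idx in range(1, len(states) - 1):
            if states[idx] == 2:
                rate = 1.0 if (states[idx - 1], states[idx + 1]) == (1, 3) else (
                    2.0 if (states[idx - 1], states[idx + 1]) == (3, 1) else 1.5
                )
                dwells[idx] = rng.exponential(1 / rate)
            else:
                dwells[idx] = rng.exponential(1.0)
        stats = collect_triplets(JumpChain(states, dwells))
        value, per_triplet, excluded, _ = epr_wtd(stats, seed=11)
        d_up = closed_form_kld(("exp", 1.0), ("exp", 2.0))
        d_down = closed_form_kld(("exp", 2.0), ("exp", 1.0))
        expected = (
            triplet_probability(stats, (1, 2, 3)) * d_up
            + triplet_probability(stats, (3, 2, 1)) * d_down
        ) / stats.tau
        assert not excluded
        assert value == pytest.approx(expected, rel=0.25)
        assert per_triplet[(1, 2, 3)] == pytest.approx(d_up, rel=0.25)

    def test_nonnegative_and_zero_for_identical_directions(self):
        rng = np.random.default_rng(12)
        states = [1, 2]
        for _ in range(5000):
            s = states[-1]
            nxt = [x for x in (s - 1, s + 1) if 1 <= x <= 3]
            states.append(int(rng.choice(nxt)))
        chain = JumpChain(np.array(states), rng.exponential(1.0, len(states)))
        value, _, _, _ = epr_wtd(collect_triplets(chain), seed=13)
        assert value >= 0.0
        assert value < 0.01  # reversible construction: statistical zero

    def test_sparse_triplets_excluded_with_reason(self):
        rng = np.random.default_rng(14)
        states = [1, 2]
        for _ in range(20_000):
            s = states[-1]
            nxt = [x for x in (s - 1, s + 1) if 1 <= x <= 4]
            states.append(int(rng.choice(nxt)))
        stats = collect_triplets(JumpChain(np.array(states), rng.exponential(1.0, len(states))))
        pass_through = [t for t in stats.counts if t[0] != t[2]]
        smallest = min(stats.counts[t] for t in pass_through)
        value, per_triplet, excluded, _ = epr_wtd(stats, min_samples=smallest + 1, seed=15)
        assert excluded  # the sparsest direction pair drops below the threshold
        assert all("insufficient" in reason for _, reason in excluded)
        assert value >= 0  # the better-sampled interior pair still contributes

    def test_no_usable_triplets_refused(self):
        chain = JumpChain(np.array([1, 2, 3, 2, 1, 2, 3]), np.ones(7))
        with pytest.raises(ValueError, match="no usable triplet"):
            epr_wtd(collect_triplets(chain))


class TestMDAF:
    def test_reversible_chain_gives_unity(self):
        rng = np.random.default_rng(16)
        states = [1, 2]
        for _ in range(20_000):
            s = states[-1]
            nxt = [x for x in (s - 1, s + 1) if 1 <= x <= 3]
            states.append(int(rng.choice(nxt)))
        stats = collect_triplets(JumpChain(np.array(states), rng.exponential(1.0, len(states))))
        total, per_pair, _, stderr = mdaf(stats, seed=17)
        assert total == pytest.approx(1.0, abs=max(3 * stderr, 0.05))

    def test_engineered_two_to_one_asymmetry(self):
        rng = np.random.default_rng(18)
        states = [1, 2]
        for _ in range(20_000):
            s = states[-1]
            nxt = [x for x in (s - 1, s + 1) if 1 <= x <= 3]
            states.append(int(rng.choice(nxt)))
        states = np.array(states)
        dwells = rng.exponential(1.0, len(states))
        for idx in range(1, len(states) - 1):
            if (states[idx - 1], states[idx], states[idx + 1]) == (3, 2, 1):
                dwells[idx] = rng.exponential(2.0)  # down passages twice as slow
            elif (states[idx - 1], states[idx], states[idx + 1]) == (1, 2, 3):
                dwells[idx] = rng.exponential(1.0)
        total, per_pair, _, stderr = mdaf(collect_triplets(JumpChain(states, dwells)), seed=19)
        assert per_pair[(1, 2, 3)] == pytest.approx(2.0, abs=0.15)

    def test_normalizer_variants(self, lumped_ctmc_chain):
        stats = collect_triplets(lumped_ctmc_chain)
        t_pairs, per_pair, _, _ = mdaf(stats, normalizer="pairs", n_boot=0)
        t_n, _, _, _ = mdaf(stats, normalizer="n_states", n_boot=0)
        assert t_pairs == pytest.approx(sum(per_pair.values()) / len(per_pair), rel=1e-12)
        assert t_n == pytest.approx(sum(per_pair.values()) / 3, rel=1e-12)


class TestBootstrapErrors:
    def test_constant_statistic_has_zero_stderr(self, lumped_ctmc_chain):
        se = bootstrap_errors(lumped_ctmc_chain, lambda c: 1.0, n_boot=20, seed=20)
        assert se == 0.0

    def test_reproducible_given_seed(self, lumped_ctmc_chain):
        est = lambda c: float(c.dwells.mean())  # noqa: E731
        a = bootstrap_errors(lumped_ctmc_chain, est, n_boot=30, seed=21)
        b = bootstrap_errors(lumped_ctmc_chain, est, n_boot=30, seed=21)
        assert a == b

    def test_stderr_scaling_with_length(self, lumped_ctmc_chain):
        est = lambda c: float(c.dwells.mean())  # noqa: E731
        n = len(lumped_ctmc_chain)
        short = lumped_ctmc_chain.slice(0, n // 8)
        se_short = bootstrap_errors(short, est, n_boot=50, seed=22)
        se_long = bootstrap_errors(lumped_ctmc_chain, est, n_boot=50, seed=22)
        assert se_long < se_short
        # ~1/sqrt(L) scaling within a factor of two
        assert se_short / se_long == pytest.approx(np.sqrt(8), rel=0.6)

    def test_refuses_tiny_chains(self):
        chain = JumpChain(np.array([1, 2, 1]), np.ones(3))
        with pytest.raises(ValueError, match="fewer"):
            bootstrap_errors(chain, lambda c: 0.0, n_blocks=50)
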