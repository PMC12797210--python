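"""Unit and property tests for the Gillespie indel primitives."""

import math

import numpy as np
import pytest
from scipy import stats

from evosim.evo_model import (
    DELETION,
    INSERTION,
    ConfigurationError,
    IndelEvent,
    IndelParams,
    LengthDistribution,
    classify_event,
    length_pmf,
    mean_indel_length,
    sample_deletion_event,
    sample_indel_length,
    sample_insertion_position,
    sample_waiting_time,
    sequence_rates,
    simulate_branch_events,
)


class TestLengthDistribution:
    @pytest.mark.parametrize(
        "dist,expected",
        [
            (LengthDistribution("zipf", 1.0, 3), [6 / 11, 3 / 11, 2 / 11]),
            (LengthDistribution("zipf", 2.0, 1), [1.0]),
            (LengthDistribution("geometric", 0.5, 3), [4 / 7, 2 / 7, 1 / 7]),
        ],
    )
    def test_pmf_known_values(self, dist, expected):
        np.testing.assert_allclose(length_pmf(dist), expected, rtol=1e-12)

    @pytest.mark.parametrize(
        "dist",
        [
            LengthDistribution("zipf", a, M)
            for a in (0.5, 1.0, 2.0)
            for M in (1, 7, 50)
        ]
        + [LengthDistribution("geometric", p, M) for p in (0.1, 0.9, 1.0) for M in (1, 20)],
    )
    def test_pmf_normalized_nonnegative(self, dist):
        pmf = length_pmf(dist)
        assert pmf.min() >= 0
        assert abs(pmf.sum() - 1.0) < 1e-12
        assert len(pmf) == dist.max_length

    def test_mean_values(self):
        # benchmark regime: Zipf a=2 "truncated at 50" read as support 1..49
        excl = LengthDistribution("zipf", 2.0, 50, inclusive=False)
        assert round(mean_indel_length(excl), 2) == 2.76
        assert mean_indel_length(LengthDistribution("zipf", 2.0, 1)) == 1.0
        assert mean_indel_length(LengthDistribution("zipf", 1.0, 3)) == pytest.approx(18 / 11)

    def test_inclusive_truncation_mean_differs(self):
        incl = LengthDistribution("zipf", 2.0, 50, inclusive=True)
        assert round(mean_indel_length(incl), 2) == 2.77

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(family="zipf", parameter=-1.0, truncation=10),
            dict(family="zipf", parameter=2.0, truncation=0),
            dict(family="geometric", parameter=0.0, truncation=10),
            dict(family="geometric", parameter=1.5, truncation=10),
            dict(family="uniform", parameter=1.0, truncation=10),
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            LengthDistribution(**kwargs)

    def test_sampling_degenerate_support(self, rng):
        dist = LengthDistribution("geometric", 0.3, 1)
        assert all(sample_indel_length(dist, rng) == 1 for _ in range(20))

    def test_sampling_matches_analytic_mean(self, rng):
        dist = LengthDistribution("zipf", 2.0, 50)
        draws = np.array([sample_indel_length(dist, rng) for _ in range(100_000)])
        mu = mean_indel_length(dist)
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - mu) < 3 * se

    def test_sampling_goodness_of_fit(self, rng):
        dist = LengthDistribution("zipf", 2.0, 10)
        n = 100_000
        draws = np.array([sample_indel_length(dist, rng) for _ in range(n)])
        observed = np.bincount(draws, minlength=11)[1:]
        expected = length_pmf(dist) * n
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=9)


class TestRatesAndClassification:
    def test_sequence_rates_formulas(self, default_params):
        R_ins, R_del, lam = sequence_rates(100, default_params, 1)
        assert R_ins == pytest.approx(101 * 0.03)  # 3.03
        assert R_del == pytest.approx(0.09 * 100)  # 9.0
        assert lam == pytest.approx(R_ins + R_del)
        # candidate deletion length widens the start range
        _, R_del5, _ = sequence_rates(100, default_params, 5)
        assert R_del5 == pytest.approx(0.09 * 104)

    def test_sequence_rates_empty_sequence_has_no_deletions(self, default_params):
        _, R_del, _ = sequence_rates(0, default_params, 5)
        assert R_del == 0.0

    def test_sequence_rates_rejects_bad_inputs(self, default_params):
        with pytest.raises(ValueError):
            sequence_rates(-1, default_params, 1)
        with pytest.raises(ValueError):
            sequence_rates(10, default_params, 0)

    def test_waiting_time_moments_and_scaling(self, rng):
        draws = np.array([sample_waiting_time(2.0, rng) for _ in range(100_000)])
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - 0.5) < 3 * se
        # inverse-transform property: scaling lambda by c scales draws by 1/c
        r1 = np.random.default_rng(11)
        r2 = np.random.default_rng(11)
        a = [sample_waiting_time(1.0, r1) for _ in range(100)]
        b = [sample_waiting_time(4.0, r2) for _ in range(100)]
        np.testing.assert_allclose(np.array(a) / 4.0, b, rtol=1e-12)

    def test_waiting_time_determinism_and_errors(self):
        assert sample_waiting_time(2.0, np.random.default_rng(5)) == sample_waiting_time(
            2.0, np.random.default_rng(5)
        )
        with pytest.raises(ValueError):
            sample_waiting_time(0.0, np.random.default_rng(5))

    def test_classification_edge_cases(self, rng):
        assert all(classify_event(0.0, 1.0, rng) == DELETION for _ in range(50))
        assert all(classify_event(1.0, 0.0, rng) == INSERTION for _ in range(50))
        with pytest.raises(ValueError):
            classify_event(0.0, 0.0, rng)

    def test_classification_probability(self, rng):
        n = 100_000
        hits = sum(classify_event(1.0, 1.0, rng) == INSERTION for _ in range(n))
        assert abs(hits / n - 0.5) < 3 * math.sqrt(0.25 / n)


class TestPositions:
    def test_insertion_position_range(self, rng):
        assert sample_insertion_position(0, rng) == 0
        draws = [sample_insertion_position(7, rng) for _ in range(2000)]
        assert min(draws) == 0 and max(draws) == 7

    def test_insertion_position_uniform(self, rng):
        n, trials = 100, 100_000
        draws = np.array([sample_insertion_position(n, rng) for _ in range(trials)])
        freq = np.bincount(draws, minlength=n + 1) / trials
        p = 1 / (n + 1)
        tol = 3 * math.sqrt(p * (1 - p) / trials)
        assert np.all(np.abs(freq - p) < tol + 1e-12)

    def test_single_char_deletion_uniform_over_positions(self, rng):
        # with S=1 each position is hit with probability exactly 1/n
        n, trials = 20, 200_000
        hits = np.zeros(n + 1)
        for _ in range(trials):
            start, eff = sample_deletion_event(n, 1, rng)
            assert eff == 1
            hits[start] += 1
        freq = hits[1:] / trials
        p = 1 / n
        assert np.all(np.abs(freq - p) < 3 * math.sqrt(p * (1 - p) / trials))

    def test_deletion_clipping_at_edges(self):
        # force the maximal left overhang: raw start 2-S clips to (1, 1)
        class FixedRaw:
            def __init__(self, value):
                self.value = value

            def integers(self, lo, hi):
                assert lo <= self.value < hi
                return self.value

        start, eff = sample_deletion_event(10, 5, FixedRaw(2 - 5))
        assert (start, eff) == (1, 1)
        start, eff = sample_deletion_event(10, 5, FixedRaw(10))
        assert (start, eff) == (10, 1)
        start, eff = sample_deletion_event(10, 5, FixedRaw(4))
        assert (start, eff) == (4, 5)

    def test_deletion_requires_nonempty_sequence(self, rng):
        with pytest.raises(ValueError):
            sample_deletion_event(0, 3, rng)


def _brute_force_branch(n0, branch_length, params, rng):
    """Independent transcription of the Gillespie loop on an explicit
    character list, used as the oracle for the event-stream generator."""
    seq = list(range(n0))
    t = 0.0
    k = 0
    while True:
        n = len(seq)
        S_cand = sample_indel_length(params.deletion_length, rng) if n > 0 else 1
        R_ins = (n + 1) * params.insertion_rate
        R_del = params.deletion_rate * (n + S_cand - 1) if n > 0 else 0.0
        lam = R_ins + R_del
        if lam <= 0:
            break
        t += rng.exponential(1.0 / lam)
        if t > branch_length:
            break
        if rng.random() < R_ins / lam:
            q = int(rng.integers(0, n + 1))
            S = sample_indel_length(params.insertion_length, rng)
            seq[q:q] = [None] * S
        else:
            raw = int(rng.integers(2 - S_cand, n + 1))
            del seq[max(raw, 1) - 1 : raw + S_cand - 1]
        k += 1
    return k, len(seq)


class TestBranchSimulation:
    def test_trivial_streams(self, default_params, rng):
        events, n = simulate_branch_events(50, 0.0, default_params, rng)
        assert events == [] and n == 50
        params0 = IndelParams(0.0, 0.0, LengthDistribution("zipf", 2.0, 50))
        events, n = simulate_branch_events(50, 1.0, params0, rng)
        assert events == [] and n == 50

    def test_stream_is_reproducible(self, default_params):
        a = simulate_branch_events(100, 0.5, default_params, np.random.default_rng(42))
        b = simulate_branch_events(100, 0.5, default_params, np.random.default_rng(42))
        assert a == b

    def test_monotonicity_without_one_event_type(self, zipf_default):
        ins_only = IndelParams(0.05, 0.0, zipf_default)
        del_only = IndelParams(0.0, 0.12, zipf_default)
        for seed in range(30):
            _, n = simulate_branch_events(60, 0.8, ins_only, np.random.default_rng(seed))
            assert n >= 60
            _, n = simulate_branch_events(60, 0.8, del_only, np.random.default_rng(seed))
            assert n <= 60

    def test_event_coordinates_valid_and_lengths_track(self, default_params):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            events, n_final = simulate_branch_events(80, 0.6, default_params, rng)
            n = 80
            for ev in events:
                if ev.kind == INSERTION:
                    assert 0 <= ev.position <= n
                    n += ev.length
                else:
                    assert 1 <= ev.position
                    assert ev.position + ev.length - 1 <= n
                    assert ev.length <= ev.drawn
                    n -= ev.length
            assert n == n_final

    def test_event_counts_match_brute_force_oracle(self, default_params):
        reps = 1000
        ks_pkg, ks_oracle = [], []
        for seed in range(reps):
            events, _ = simulate_branch_events(
                1000, 0.05, default_params, np.random.default_rng(seed)
            )
            ks_pkg.append(len(events))
            k, _ = _brute_force_branch(
                1000, 0.05, default_params, np.random.default_rng(seed)
            )
            ks_oracle.append(k)
        ks_pkg, ks_oracle = np.array(ks_pkg), np.array(ks_oracle)
        se = math.sqrt(ks_pkg.var(ddof=1) / reps + ks_oracle.var(ddof=1) / reps)
        assert abs(ks_pkg.mean() - ks_oracle.mean()) < 3 * max(se, 1e-9)

    def test_final_lengths_match_brute_force_oracle(self, default_params):
        for seed in range(200):
            _, n_pkg = simulate_branch_events(
                200, 0.2, default_params, np.random.default_rng(seed)
            )
            _, n_oracle = _brute_force_branch(
                200, 0.2, default_params, np.random.default_rng(seed)
            )
            assert n_pkg == n_oracle


def test_event_validation():
    with pytest.raises(ValueError):
        IndelEvent("swap", 1, 1, 0.0)
    with pytest.raises(ValueError):
        IndelEvent(INSERTION, 1, 0, 0.0)
    ev = IndelEvent(DELETION, 3, 2, 0.1, drawn=5)
    assert ev.drawn == 5
    assert IndelEvent(INSERTION, 0, 4, 0.0).drawn == 4
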