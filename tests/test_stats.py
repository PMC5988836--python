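import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from erkpulse import (
    PulseFit,
    PulseParams,
    TestResult as GroupTestResult,
    WaveEvent,
    chi2_bh,
    detect_propagation,
    mann_whitney,
    pulse_onsets,
    steel_dwass,
    summarize_population,
)
from erkpulse.stats import bartlett_check


def make_fit(condition, n_pulses, basal=1.0, classification=None):
    pulses = tuple(
        PulseParams(0.1, 20.0 + 20 * i, 2 * np.pi / 20) for i in range(n_pulses)
    )
    if classification is None:
        classification = "pulse+" if n_pulses else "pulse-"
    return PulseFit(
        basal=basal,
        pulses=pulses,
        sse=0.0,
        classification=classification,
        cell_id=f"{condition}_{n_pulses}_{basal}",
        condition=condition,
    )


class TestSummarize:
    def test_all_flat_fits(self):
        fits = [make_fit("control", 0) for _ in range(4)]
        out = summarize_population(fits, 90.0)
        assert out.loc["control", "proportion_pulse_pos"] == 0.0
        assert out.loc["control", "mean_frequency_per_hour"] == 0.0

    def test_proportion_three_of_four(self):
        fits = [make_fit("c", 1), make_fit("c", 2), make_fit("c", 3),
                make_fit("c", 0)]
        out = summarize_population(fits, 90.0)
        assert out.loc["c", "proportion_pulse_pos"] == pytest.approx(0.75)
        assert out.loc["c", "n_cells"] == 4

    def test_counts_sum_to_input_size(self):
        fits = [make_fit("a", 1), make_fit("a", 0), make_fit("b", 2)]
        out = summarize_population(fits, 90.0)
        assert out["n_cells"].sum() == 3


class TestMannWhitney:
    def test_u_identity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=8), rng.normal(size=5)
        u_ab = mann_whitney(a, b).statistic
        u_ba = mann_whitney(b, a).statistic
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))

    def test_separated_samples_exact_p(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0
        assert r.p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        r = mann_whitney([5, 5, 5, 5], [5, 5, 5, 5])
        assert r.p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (3, 5), (4, 4), (5, 5)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2):
        # brute force: U statistic over every assignment of ranks
        rng = np.random.default_rng(n1 * 10 + n2)
        a = rng.normal(size=n1)
        b = rng.normal(size=n2)
        res = mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        ranks = rankdata(pooled)

        def u_of(idx):
            idx = set(idx)
            r1 = sum(ranks[i] for i in idx)
            return r1 - n1 * (n1 + 1) / 2

        u_obs = u_of(range(n1))
        us = [u_of(c) for c in itertools.combinations(range(n1 + n2), n1)]
        mean_u = n1 * n2 / 2
        p_exact = np.mean(
            [abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9 for u in us]
        )
        assert res.p == pytest.approx(p_exact, abs=1e-9)


class TestSteelDwass:
    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            steel_dwass({"a": [1, 2], "b": [3, 4]})

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            steel_dwass({"a": [1, 2], "b": [3, 4], "c": []})

    def test_shifted_group_flagged_others_not(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.normal(size=20),
            "b": rng.normal(size=20),
            "c": rng.normal(5.0, 1.0, size=20),
        }
        res = {r.groups: r.p for r in steel_dwass(groups)}
        assert res[("a", "c")] < 0.05
        assert res[("b", "c")] < 0.05
        assert res[("a", "b")] > 0.05

    def test_null_familywise_error_controlled(self):
        rng = np.random.default_rng(0)
        fwe = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = {c: rng.normal(size=20) for c in "abc"}
            fwe += any(r.p < 0.05 for r in steel_dwass(groups))
        assert fwe / n_sim <= 0.07

    def test_bartlett_reported(self):
        rng = np.random.default_rng(2)
        groups = {c: rng.normal(size=15) for c in "abc"}
        r = bartlett_check(groups)
        assert r.method == "bartlett"
        assert 0 <= r.p <= 1


class TestChi2BH:
    def test_uniform_table_no_association(self):
        (r,) = chi2_bh([np.array([[10, 10], [10, 10]])])
        assert r.statistic == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_bh_step_up_arithmetic(self):
        # tables engineered to have raw p {~0.01-ish ordering} checked via
        # the analytic BH formula applied to whatever raw p's come out
        tables = [
            np.array([[30, 10], [10, 30]]),
            np.array([[25, 15], [15, 25]]),
            np.array([[22, 18], [18, 22]]),
        ]
        results = chi2_bh(tables)
        raw = np.array([r.p for r in results])
        order = np.argsort(raw)
        m = len(raw)
        stepped = raw[order] * m / np.arange(1, m + 1)
        expected = np.minimum.accumulate(stepped[::-1])[::-1]
        adj = np.array([r.adjusted_p for r in results])
        assert np.allclose(adj[order], np.minimum(expected, 1.0))

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        tables = [rng.integers(5, 40, size=(2, 2)) for _ in range(6)]
        for r in chi2_bh(tables):
            assert r.adjusted_p >= r.p - 1e-12

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_bh([np.array([[0, 0], [5, 5]])])


class TestWaveDetection:
    @staticmethod
    def line_onsets(n, hop=2.0, start=10.0, jitter=0.0, rng=None):
        onsets = {}
        for i in range(n):
            t = start + hop * i
            if jitter and rng is not None:
                t += rng.normal(0, jitter)
            onsets[i] = np.array([t])
        positions = {i: (20.0 * i, 0.0) for i in range(n)}
        return onsets, positions

    def test_clean_chain_detected_with_construction_velocity(self):
        onsets, positions = self.line_onsets(5)
        (ev,) = detect_propagation(onsets, positions, max_lag=3.0)
        assert ev.cells == (0, 1, 2, 3, 4)
        assert ev.velocity == pytest.approx(10.0)

    def test_no_coincident_pulses_no_events(self):
        onsets = {0: np.array([10.0]), 1: np.array([50.0]), 2: np.array([20.0])}
        positions = {i: (20.0 * i, 0.0) for i in range(3)}
        assert detect_propagation(onsets, positions, max_lag=3.0) == []

    def test_jittered_velocity_within_ten_percent(self):
        rng = np.random.default_rng(5)
        vels = []
        for _ in range(50):
            onsets, positions = self.line_onsets(5, jitter=0.3, rng=rng)
            evs = detect_propagation(onsets, positions, max_lag=5.0)
            vels.extend(e.velocity for e in evs)
        assert abs(np.median(vels) - 10.0) / 10.0 <= 0.10

    def test_shuffled_onsets_give_ten_times_fewer_events(self):
        rng = np.random.default_rng(5)
        n_true = n_shuf = 0
        for _ in range(50):
            onsets, positions = self.line_onsets(10, jitter=0.3, rng=rng)
            n_true += len(
                detect_propagation(onsets, positions, max_lag=3.0, min_cells=4)
            )
            perm = rng.permutation(10)
            shuffled = {i: onsets[perm[i]] for i in range(10)}
            n_shuf += len(
                detect_propagation(shuffled, positions, max_lag=3.0, min_cells=4)
            )
        assert n_true >= 45
        assert n_shuf * 10 <= n_true

    def test_fewer_than_two_cells_empty(self):
        assert detect_propagation({0: np.array([1.0])}, {0: (0.0, 0.0)}) == []

    def test_wave_event_invariants(self):
        with pytest.raises(ValueError):
            WaveEvent(cells=(1,), onsets=(0.0,), velocity=1.0)
        with pytest.raises(ValueError):
            WaveEvent(cells=(1, 2), onsets=(3.0, 1.0), velocity=1.0)

    def test_pulse_onsets_support_start(self):
        fit = PulseFit(
            basal=1.0,
            pulses=(PulseParams(0.1, 45.0, 2 * np.pi / 20),),
            sse=0.0,
        )
        ons = pulse_onsets([fit])
        assert ons[None][0] == pytest.approx(35.0)


class TestResultInvariants:
    def test_p_range_enforced(self):
        with pytest.raises(ValueError):
            GroupTestResult(method="x", statistic=0.0, p=1.5, groups=("a",))

    def test_adjusted_not_below_raw(self):
        with pytest.raises(ValueError):
            GroupTestResult(
                method="x", statistic=0.0, p=0.5, groups=("a",), adjusted_p=0.1
            )
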