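import numpy as np
import pytest

from runcoord.errors import InsufficientDataError
from runcoord.gait import Cycle, CyclePartition, Phase
from runcoord.signal_io import ChannelKind, ChannelMeta, Recording, SampledSignal, Side
from runcoord.stability import (
    LocalizationWindow,
    PhaseStabilityStats,
    assess_stability,
    integral_stability,
    localization_window,
    phase_stats,
    shortest_energy_window,
    stability_coefficients,
)
from runcoord.synth import SimulationConfig, simulate_session
from runcoord import emg, gait


def brute_force_window(values, fraction=0.9):
    """Exhaustive O(n^2) search: shortest window with >= fraction of total
    energy, earliest on ties."""
    total = values.sum()
    target = fraction * total
    best = None
    for i in range(len(values)):
        acc = 0.0
        for j in range(i, len(values)):
            acc += values[j]
            if acc >= target - 1e-12 * total:
                length = j - i + 1
                if best is None or length < best[0]:
                    best = (length, i, j + 1)
                break
    return best[1], best[2]


class TestShortestEnergyWindow:
    def test_point_mass(self):
        v = np.zeros(50)
        v[17] = 4.0
        assert shortest_energy_window(v) == (17, 18)

    def test_uniform_energy(self):
        for n in (10, 20, 7):
            i, j = shortest_energy_window(np.ones(n), 0.9)
            assert (i, j) == (0, int(np.ceil(0.9 * n)))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = rng.integers(5, 120)
            v = rng.exponential(1.0, n)
            if rng.random() < 0.3:
                v[rng.random(n) < 0.5] = 0.0
            assert shortest_energy_window(v) == brute_force_window(v)


class TestLocalizationWindow:
    def _energy(self, values, rate=100.0):
        return SampledSignal(values, rate)

    def test_window_inside_phase_with_energy_share(self):
        rng = np.random.default_rng(1)
        e = self._energy(rng.exponential(1.0, 300))
        w = localization_window(e, 0.5, 2.5)
        assert 0.5 <= w.start_s < w.end_s <= 2.5
        assert w.energy >= 0.9 * w.phase_energy - 1e-9
        assert w.duration_ratio <= 1.0

    def test_degenerate_silent_phase_flagged(self):
        e = self._energy(np.zeros(300))
        w = localization_window(e, 0.0, 1.0)
        assert w.degenerate
        assert w.energy == 0.0

    def test_fraction_one_takes_nearly_full_phase(self):
        e = self._energy(np.ones(200))
        w = localization_window(e, 0.0, 1.0, fraction=1.0)
        assert w.duration_ratio == pytest.approx(1.0, abs=0.02)


class TestPhaseStats:
    def _windows(self, energies, ratios=None):
        out = []
        for k, en in enumerate(energies):
            r = 0.5 if ratios is None else ratios[k]
            out.append(
                LocalizationWindow(
                    phase=1, cycle=k, start_s=0.0, end_s=r,
                    energy=en, phase_energy=en, phase_duration_s=1.0,
                )
            )
        return out

    def test_constant_energies(self):
        s = phase_stats(self._windows([2.0, 2.0, 2.0, 2.0]))
        assert s.mean_energy == pytest.approx(2.0)
        assert s.sd_energy == pytest.approx(0.0)

    def test_population_sd(self):
        s = phase_stats(self._windows([1.0, 3.0]))
        assert s.mean_energy == pytest.approx(2.0)
        assert s.sd_energy == pytest.approx(1.0)  # population form, not sqrt(2)

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(9)
        energies = rng.exponential(5.0, 20)
        ratios = rng.uniform(0.2, 0.9, 20)
        s = phase_stats(self._windows(energies, ratios))
        n = 20
        mean_e = sum(energies) / n
        mean_r = sum(ratios) / n
        sd_e = np.sqrt(sum((x - mean_e) ** 2 for x in energies) / n)
        sd_r = np.sqrt(sum((x - mean_r) ** 2 for x in ratios) / n)
        assert s.mean_energy == pytest.approx(mean_e)
        assert s.mean_ratio == pytest.approx(mean_r)
        assert s.sd_energy == pytest.approx(sd_e)
        assert s.sd_ratio == pytest.approx(sd_r)

    def test_single_cycle_rejected(self):
        with pytest.raises(InsufficientDataError):
            phase_stats(self._windows([1.0]))


class TestStabilityCoefficients:
    def _stats(self, mean_e, sd_e, mean_r=0.5, sd_r=0.0):
        return PhaseStabilityStats(
            muscle="m", side=Side.LEFT, phase=1, phase_name="stance",
            energies=np.array([mean_e] * 2), duration_ratios=np.array([mean_r] * 2),
            mean_energy=mean_e, mean_ratio=mean_r, sd_energy=sd_e, sd_ratio=sd_r,
        )

    def test_zero_sd_gives_100(self):
        s = stability_coefficients(self._stats(2.0, 0.0))
        assert s.k_energy == pytest.approx(100.0)

    def test_half_relative_sd_gives_50(self):
        s = stability_coefficients(self._stats(2.0, 1.0))
        assert s.k_energy == pytest.approx(50.0)

    def test_sd_above_mean_clamped_to_zero(self):
        s = stability_coefficients(self._stats(1.0, 1.5))
        assert s.k_energy == 0.0

    def test_zero_mean_excluded(self):
        s = stability_coefficients(self._stats(0.0, 0.0))
        assert s.excluded


class TestIntegralStability:
    def _stat(self, k_e, k_dt, muscle="m", phase=1):
        s = PhaseStabilityStats(
            muscle=muscle, side=Side.LEFT, phase=phase, phase_name="p",
            energies=np.ones(2), duration_ratios=np.ones(2),
        )
        s.k_energy, s.k_ratio = k_e, k_dt
        return s

    def test_all_100(self):
        stats = [self._stat(100.0, 100.0, f"m{i}") for i in range(4)]
        assert integral_stability(stats, 2, 2).k_emg_pct == pytest.approx(100.0)

    def test_single_pair(self):
        rep = integral_stability([self._stat(80.0, 60.0)], 1, 1)
        assert rep.k_emg_pct == pytest.approx(70.0)

    def test_matches_flat_average_m7_f2(self):
        rng = np.random.default_rng(4)
        ks = rng.uniform(0, 100, (7, 2, 2))
        stats = [
            self._stat(ks[m, f, 0], ks[m, f, 1], f"m{m}", f) for m in range(7) for f in range(2)
        ]
        expected = np.mean([(ks[m, f, 0] + ks[m, f, 1]) / 2 for m in range(7) for f in range(2)])
        assert integral_stability(stats, 7, 2).k_emg_pct == pytest.approx(expected)

    def test_excluded_phases_dropped_from_average(self):
        good = self._stat(100.0, 100.0)
        bad = self._stat(0.0, 0.0, "silent")
        bad.excluded = True
        rep = integral_stability([good, bad], 2, 1)
        assert rep.k_emg_pct == pytest.approx(100.0)

    def test_all_excluded_raises(self):
        bad = self._stat(0.0, 0.0)
        bad.excluded = True
        with pytest.raises(InsufficientDataError):
            integral_stability([bad], 1, 1)


def _tiled_recording(n_cycles=20, rate=1000.0, cycle_s=1.0):
    """A recording whose EMG repeats one cycle bit-identically."""
    n = int(cycle_s * rate)
    rng = np.random.default_rng(0)
    one = rng.normal(0, 1, n) * np.exp(-0.5 * ((np.arange(n) / rate - 0.2) / 0.05) ** 2)
    samples = np.tile(one, n_cycles)
    rec = Recording(
        {
            ChannelMeta("emg_rf_l", ChannelKind.EMG, Side.LEFT, "rectus_femoris"):
                SampledSignal(samples, rate),
            ChannelMeta("gyro_x_l", ChannelKind.GYRO_X, Side.LEFT, "tibialis_anterior"):
                SampledSignal(np.zeros(int(n_cycles * cycle_s * 148)), 148.0),
        }
    )
    cycles = [
        Cycle(
            k,
            k * cycle_s,
            (k + 1) * cycle_s,
            [
                Phase(1, "stance", k * cycle_s, k * cycle_s + 0.4),
                Phase(2, "swing", k * cycle_s + 0.4, (k + 1) * cycle_s),
            ],
        )
        for k in range(n_cycles)
    ]
    return rec, CyclePartition(side=Side.LEFT, cycles=cycles)


class TestAssessStability:
    def test_bit_identical_cycles_score_exactly_100(self):
        rec, part = _tiled_recording()
        rep = assess_stability(rec, part, n_cycles=20)
        assert rep.k_emg_pct == 100.0
        for s in rep.per_phase:
            if not s.excluded:
                assert s.sd_energy == 0.0 and s.sd_ratio == 0.0

    def test_scale_invariance_of_coefficients(self):
        rec, part = _tiled_recording(n_cycles=5)
        scaled = Recording(
            {
                meta: (
                    SampledSignal(sig.samples * 4.2, sig.rate_hz, sig.t0_s)
                    if meta.kind is ChannelKind.EMG
                    else sig
                )
                for meta, sig in rec
            }
        )
        r1 = assess_stability(rec, part, n_cycles=5)
        r2 = assess_stability(scaled, part, n_cycles=5)
        for a, b in zip(r1.per_phase, r2.per_phase):
            if not a.excluded:
                assert b.k_energy == pytest.approx(a.k_energy, rel=1e-9)
                assert b.k_ratio == pytest.approx(a.k_ratio, rel=1e-9)

    def test_zero_jitter_simulation_scores_high(self, clean_analysis):
        pre, parts, _ = clean_analysis
        rep = assess_stability(pre, parts[Side.LEFT], n_cycles=20)
        assert rep.k_emg_pct >= 97.0
        assert 0.0 <= rep.k_emg_pct <= 100.0

    def test_amplitude_jitter_monotonically_degrades(self):
        ks = []
        for sa in (0.0, 0.1, 0.3):
            cfg = SimulationConfig(duration_s=18.0, sigma_amp=sa, seed=13)
            rec, _ = simulate_session(cfg)
            pre = emg.preprocess_emg(rec)
            part = gait.segment_gait(
                pre.gyro(Side.LEFT, ChannelKind.GYRO_X), n_cycles=20, side=Side.LEFT
            )
            ks.append(assess_stability(pre, part, n_cycles=20).k_emg_pct)
        assert ks[0] > ks[1] > ks[2]

    def test_insufficient_cycles(self):
        rec, part = _tiled_recording(n_cycles=5)
        with pytest.raises(InsufficientDataError):
            assess_stability(rec, part, n_cycles=20)
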