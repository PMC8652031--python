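import math

import numpy as np
import pytest

from timecycle.synth import (
    CYCLIC_SHAPES,
    NONCYCLIC_SHAPES,
    SHAPES,
    SamplingSpec,
    WaveformSpec,
    degrade_missing,
    draw_waveform,
    grid_specs,
    inject_outliers,
    simulate_dataset,
    simulate_grid,
    waveform_value,
)


class TestWaveformValue:
    def test_flat(self):
        w = WaveformSpec("flat", {"baseline": 5.0})
        assert waveform_value(w, 13.7) == 5.0

    def test_sine_quarter_period(self):
        w = WaveformSpec("sine", {"amplitude": 1.0, "period_h": 24.0,
                                  "phase_rad": 0.0, "baseline": 0.0})
        assert waveform_value(w, 6.0) == pytest.approx(1.0)

    def test_damped_envelope_halves(self):
        lam = math.log(2) / 24.0
        w = WaveformSpec("damped", {"amplitude": 2.0, "period_h": 24.0,
                                    "phase_rad": 0.0, "baseline": 0.0,
                                    "envelope_rate": lam})
        # peak of the envelope at t and t+24 differ by a factor of 2
        t = np.array([6.0, 30.0])
        v = waveform_value(w, t)
        assert v[0] / v[1] == pytest.approx(2.0)

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            WaveformSpec("wiggle", {})

    def test_cyclic_flags(self):
        assert len(CYCLIC_SHAPES) == 7
        assert len(NONCYCLIC_SHAPES) == 4
        for shape in CYCLIC_SHAPES:
            assert WaveformSpec(shape, {}).is_cyclic
        for shape in NONCYCLIC_SHAPES:
            assert not WaveformSpec(shape, {}).is_cyclic

    def test_contractile_period_shrinks(self):
        w = WaveformSpec("contractile", {
            "amplitude": 1.0, "period_h": 24.0, "phase_rad": 0.0,
            "baseline": 0.0, "shrink_rate": 0.08})
        t = np.linspace(0, 96, 4000)
        v = waveform_value(w, t)
        zeros = np.nonzero(np.diff(np.sign(v)))[0]
        gaps = np.diff(t[zeros])
        # half-period gaps shrink over time
        assert gaps[-1] < gaps[0]


class TestSimulateDataset:
    def test_counts_and_labels(self, rng):
        spec = SamplingSpec(2.0, 48.0, 1, 0.1)
        es, labels = simulate_dataset(spec, 10, rng)
        assert es.n_genes == 110
        assert labels.is_cyclic.sum() == 70
        assert (~labels.is_cyclic).sum() == 40
        assert es.n_samples == 24

    def test_zero_noise_replicates_identical(self, rng):
        spec = SamplingSpec(4.0, 36.0, 3, 0.0)
        es, _ = simulate_dataset(spec, 3, rng)
        n_t = 9
        for g in range(es.n_genes):
            r1 = es.values[g, :n_t]
            assert np.array_equal(es.values[g, n_t:2 * n_t], r1)
            assert np.array_equal(es.values[g, 2 * n_t:], r1)

    def test_seed_determinism(self):
        spec = SamplingSpec(2.0, 48.0, 2, 0.2)
        es1, l1 = simulate_dataset(spec, 5, np.random.default_rng(99))
        es2, l2 = simulate_dataset(spec, 5, np.random.default_rng(99))
        assert np.array_equal(es1.values, es2.values)
        assert l1.equals(l2)

    def test_noise_marginal_matches_noise_frac(self):
        # with 3 replicates the within-replicate deviations estimate the
        # noise sd; averaged over many genes it should sit within 10% of
        # noise_frac * amplitude
        spec = SamplingSpec(2.0, 48.0, 3, 0.3)
        es, labels = simulate_dataset(spec, 100, np.random.default_rng(5))
        n_t = 24
        ratios = []
        for g in range(es.n_genes):
            reps = es.values[g].reshape(3, n_t)
            resid = reps - reps.mean(axis=0)
            sd_est = resid.std(ddof=0) * np.sqrt(3.0 / 2.0)
            ratios.append(sd_est / labels.amplitude.iloc[g])
        assert np.mean(ratios) == pytest.approx(0.3, rel=0.10)


class TestGrid:
    def test_144_distinct_specs(self):
        specs = grid_specs()
        assert len(specs) == 144
        assert len(set(specs)) == 144

    def test_36_have_48h_length(self):
        assert sum(s.length_h == 48.0 for s in grid_specs()) == 36

    def test_lazy_realization_matches_specs(self):
        it = simulate_grid(n_per_shape=1, seed=0)
        spec, es, labels = next(it)
        assert spec == grid_specs()[0]
        assert es.n_genes == 11
        assert labels.is_cyclic.sum() == 7


class TestDegradeMissing:
    def test_zero_fraction_identity(self, rng):
        es, _ = simulate_dataset(SamplingSpec(2.0, 48.0, 1, 0.1), 2, rng)
        out = degrade_missing(es, 0.0, rng)
        assert np.array_equal(out.values, es.values)

    def test_half_missing_on_24_points(self, rng):
        es, _ = simulate_dataset(SamplingSpec(2.0, 48.0, 1, 0.1), 5, rng)
        out = degrade_missing(es, 0.5, rng)
        assert np.all(np.isnan(out.values).sum(axis=1) == 12)

    def test_cap_leaves_two_observed(self, rng):
        es, _ = simulate_dataset(SamplingSpec(2.0, 48.0, 1, 0.1), 5, rng)
        out = degrade_missing(es, 0.999, rng)
        assert np.all(np.isnan(out.values).sum(axis=1) == 22)


class TestInjectOutliers:
    def test_zero_rate_identity(self, rng):
        es, _ = simulate_dataset(SamplingSpec(2.0, 48.0, 1, 0.1), 2, rng)
        out = inject_outliers(es, 0.0, rng)
        assert np.array_equal(out.values, es.values)

    def test_injected_values_in_band(self, rng):
        es, _ = simulate_dataset(SamplingSpec(2.0, 48.0, 1, 0.2), 30, rng)
        out = inject_outliers(es, 0.05, rng)
        changed = out.values != es.values
        assert changed.any()
        for g in range(es.n_genes):
            idx = np.nonzero(changed[g])[0]
            if len(idx) == 0:
                continue
            mu = es.values[g].mean()
            sigma = es.values[g].std(ddof=1)
            z = np.abs(out.values[g, idx] - mu) / sigma
            assert np.all(z >= 3.0 - 1e-12)
            assert np.all(z <= 4.0 + 1e-12)

    def test_injection_count_near_binomial_expectation(self, rng):
        es, _ = simulate_dataset(SamplingSpec(2.0, 48.0, 1, 0.2), 100, rng)
        out = inject_outliers(es, 0.01, rng)
        n_changed = int((out.values != es.values).sum())
        n_cells = es.values.size
        expect = 0.01 * n_cells
        sd = np.sqrt(n_cells * 0.01 * 0.99)
        assert abs(n_changed - expect) < 5 * sd


class TestDrawWaveform:
    @pytest.mark.parametrize("shape", SHAPES)
    def test_draws_are_finite_on_grid(self, shape, rng):
        t = np.arange(0.0, 96.0, 1.0)
        for _ in range(20):
            w = draw_waveform(shape, rng)
            v = waveform_value(w, t)
            assert np.all(np.isfinite(v))
            assert 1.0 <= w.parameters["amplitude"] <= 4.0
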