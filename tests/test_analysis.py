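"""QC, slope estimation, variability statistics and stoichiometry mapping."""

import numpy as np
import pytest

import tmsdrop as td
from tmsdrop.errors import EmptyResultError, FitError, InputError
from tmsdrop.synthetic_traces import DEFAULT_BACKGROUND

CLEAN = td.RateParameters(td.K_CLEAN, "clean")
POOL = td.RateParameters(td.K_POOL, "pool")


def _labeled_artifact_set(acq, n=2000, seed=2):
    cfg = td.EmulsionConfig(n_droplets=n, radius_cv=0.03)
    em = td.generate_emulsion(cfg, seed=seed)
    traces = td.simulate_trace_set(em, CLEAN, acq, td.NoiseModel(), seed=seed)
    spec = td.ArtifactSpec(
        frac_negative_slope=0.1, frac_jump=0.05, frac_out_of_focus=0.05
    )
    return td.inject_artifacts(traces, spec, seed=seed + 1)


class TestQCFilter:
    def test_clean_set_fully_kept(self, noiseless_traces):
        report = td.qc_filter(noiseless_traces)
        assert report.n_kept == len(noiseless_traces)
        assert not report.discarded

    def test_sensitivity_and_specificity_on_labeled_artifacts(self, acq):
        traces = _labeled_artifact_set(acq)
        report = td.qc_filter(traces)
        truth = {tr.droplet_id: tr.truth.artifact for tr in traces}
        negatives = [i for i, a in truth.items() if a == "negative_slope"]
        clean = [i for i, a in truth.items() if a == "none"]
        hit = sum(1 for i in negatives if report.discarded.get(i) == "negative_slope")
        assert hit / len(negatives) >= 0.95
        false_pos = sum(1 for i in clean if i in report.discarded)
        assert false_pos / len(clean) <= 0.02

    def test_step_trace_flagged_as_jump(self):
        times = np.arange(4.0, 120.0, 2.0)
        red = np.full(times.size, 100.0)
        red[times >= 30.0] *= 1.5  # 50% step inside the slope window
        tr = td.DropletTrace("step", times, np.full(times.size, 100.0), red)
        ok = td.DropletTrace(
            "ok", times, np.full(times.size, 100.0),
            100.0 + 0.5 * (times - times[0]),
        )
        report = td.qc_filter([tr, ok])
        assert report.discarded["step"] == "intensity_jump"

    def test_all_discarded_raises(self):
        times = np.arange(4.0, 120.0, 2.0)
        falling = td.DropletTrace(
            "f", times, np.full(times.size, 100.0), 200.0 - times
        )
        with pytest.raises(EmptyResultError):
            td.qc_filter([falling])

    def test_deterministic(self, acq):
        traces = _labeled_artifact_set(acq, n=300)
        assert td.qc_filter(traces) == td.qc_filter(traces)


class TestReferenceNormalize:
    def test_constant_green_identity(self):
        times = np.arange(0.0, 20.0, 2.0)
        red = np.linspace(10, 50, times.size)
        tr = td.DropletTrace("a", times, np.full(times.size, 80.0), red)
        assert np.allclose(td.reference_normalize(tr), red)

    def test_common_wobble_reduces_variance(self):
        rng = np.random.default_rng(4)
        times = np.arange(0.0, 400.0, 2.0)
        wobble = rng.normal(1.0, 0.05, times.size)
        red = 100.0 * wobble
        green = 90.0 * wobble
        tr = td.DropletTrace("w", times, green, red)
        assert np.var(td.reference_normalize(tr)) < np.var(red)

    def test_nonpositive_green_rejected(self):
        times = np.arange(0.0, 10.0, 2.0)
        green = np.full(times.size, 50.0)
        green[2] = 0.0
        tr = td.DropletTrace("z", times, green, np.full(times.size, 10.0))
        with pytest.raises(InputError):
            td.reference_normalize(tr)


class TestEstimateSlopes:
    def test_noiseless_equals_model_window_slope(self, noiseless_traces, acq):
        w = td.SlopeWindow(10.0, 50.0)
        slopes = td.estimate_slopes(noiseless_traces, w)
        tr = noiseless_traces[0]
        i1 = int(np.argmin(np.abs(tr.times - 10.0)))
        i2 = int(np.argmin(np.abs(tr.times - 50.0)))
        expected = td.window_slope(float(tr.red[i1]), float(tr.red[i2]), w)
        assert slopes.raw[0] == expected

    def test_identical_traces_normalize_to_one(self, noiseless_traces):
        slopes = td.estimate_slopes(noiseless_traces, td.SlopeWindow(10, 50))
        assert np.allclose(slopes.normalized, 1.0)
        assert np.mean(slopes.normalized) == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_population_cv_below_one_percent(self, acq):
        cfg = td.EmulsionConfig(n_droplets=2000, radius_cv=0.03)
        em = td.generate_emulsion(cfg, seed=3)
        traces = td.simulate_trace_set(em, CLEAN, acq, td.NoiseModel(0.0, 0.0))
        slopes = td.estimate_slopes(traces, td.SlopeWindow(10, 50))
        assert td.variability_stats(slopes).cv < 0.01

    def test_regression_mode_agrees_on_noiseless_linear_segment(self, noiseless_traces):
        w = td.SlopeWindow(10.0, 50.0)
        two = td.estimate_slopes(noiseless_traces, w, mode="two_point")
        reg = td.estimate_slopes(noiseless_traces, w, mode="regression")
        assert np.allclose(two.raw, reg.raw, rtol=0.05)

    def test_window_outside_data_rejected(self, noiseless_traces):
        with pytest.raises(InputError):
            td.estimate_slopes(noiseless_traces, td.SlopeWindow(10.0, 1e5))


class TestVariabilityStats:
    def test_hand_computed_example(self):
        stats = td.variability_stats(td.SlopeSet.from_raw([0.8, 0.9, 1.1, 1.2]))
        assert stats.cv == pytest.approx(0.18257, abs=1e-4)
        assert stats.iqr == pytest.approx(0.25)
        assert stats.mad == pytest.approx(0.15)

    def test_constant_slopes_zero_dispersion(self):
        stats = td.variability_stats(td.SlopeSet.from_raw([2.0] * 10))
        assert stats.cv == stats.iqr == stats.mad == 0.0

    def test_gaussian_cv_recovery(self):
        rng = np.random.default_rng(8)
        slopes = td.SlopeSet.from_raw(rng.normal(1.0, 0.247, 2000))
        assert td.variability_stats(slopes).cv == pytest.approx(0.247, abs=0.01)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(1.0, 0.2, 100)
        a = td.variability_stats(td.SlopeSet.from_raw(vals))
        b = td.variability_stats(td.SlopeSet.from_raw(rng.permutation(vals)))
        assert (a.cv, a.iqr, a.mad) == pytest.approx((b.cv, b.iqr, b.mad))

    def test_too_few_rejected(self):
        with pytest.raises(InputError):
            td.variability_stats(td.SlopeSet.from_raw([1.0, 1.1]))


class TestCentralPeakFit:
    def test_pure_gaussian_recovery(self):
        rng = np.random.default_rng(12)
        slopes = td.SlopeSet.from_raw(rng.normal(1.0, 0.1, 2000))
        peak = td.central_peak_fit(slopes)
        assert peak.cv == pytest.approx(0.10, abs=0.01)

    def test_outliers_inflate_plain_cv_but_not_peak_cv(self):
        rng = np.random.default_rng(13)
        vals = np.concatenate([rng.normal(1.0, 0.1, 1900), np.full(100, 1.8)])
        slopes = td.SlopeSet.from_raw(vals)
        peak = td.central_peak_fit(slopes)
        plain = td.variability_stats(slopes)
        assert peak.cv == pytest.approx(0.10, abs=0.015)
        assert plain.cv >= 0.15

    def test_empty_after_cut_raises(self):
        rng = np.random.default_rng(14)
        slopes = td.SlopeSet.from_raw(rng.normal(1.0, 0.01, 100))
        with pytest.raises(FitError):
            td.central_peak_fit(slopes, cut=0.5)


class TestConcentrationEstimation:
    def test_anchor_interpolation_example(self):
        intensities = [0.0] * 10 + [600.0] * 10 + [300.0]
        cmap = td.estimate_invader_concentrations(intensities, 500e-9)
        assert cmap.conc[-1] == pytest.approx(250e-9)
        assert cmap.conc[0] == 0.0

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(InputError):
            td.estimate_invader_concentrations([5.0] * 30, 500e-9)

    def test_sweep_recovery_within_one_percent(self, acq):
        cfg = td.EmulsionConfig(
            n_droplets=500, radius_cv=0.0, mixing_mode="sinusoidal"
        )
        prog = td.PressureProgram(period=1.0, droplet_interval=0.0123)
        em = td.generate_emulsion(cfg, prog, seed=4)
        traces = td.simulate_trace_set(em, POOL, acq, td.NoiseModel(0.0, 0.0))
        cmap = td.estimate_invader_concentrations(traces, 500e-9)
        true_conc = np.array([d.conc_invader for d in em])
        assert np.max(np.abs(cmap.conc - true_conc)) < 0.01 * 500e-9


class TestRateFit:
    @pytest.mark.parametrize("k", [td.K_CLEAN, td.K_POOL])
    def test_noiseless_round_trip(self, k):
        times = np.arange(0.0, 2700.0, 2.0)
        f = td.to_fluorescence(
            td.closed_form_conversion(k, 250e-9, 200e-9, times), 200e-9
        )
        fit = td.fit_rate_constant(times, f, 250e-9, 200e-9, 200e-9)
        assert fit.k_hat == pytest.approx(k, rel=1e-6)

    def test_one_percent_noise_two_percent_accuracy(self):
        rng = np.random.default_rng(15)
        times = np.arange(0.0, 600.0, 2.0)
        f = td.to_fluorescence(
            td.closed_form_conversion(td.K_CLEAN, 250e-9, 200e-9, times), 200e-9
        )
        noisy = f + rng.normal(0.0, 0.01 * f.max(), f.size)
        fit = td.fit_rate_constant(times, noisy, 250e-9, 200e-9, 200e-9)
        assert fit.k_hat == pytest.approx(td.K_CLEAN, rel=0.02)

    def test_flat_trace_rejected(self):
        times = np.arange(0.0, 100.0, 2.0)
        with pytest.raises(FitError):
            td.fit_rate_constant(
                times, np.full(times.size, 3.0), 250e-9, 200e-9, 200e-9
            )


class TestCvDecomposition:
    def test_linear_sum(self):
        assert td.cv_decomposition(0.05, 0.03, 0.02) == pytest.approx(0.10)
        assert td.cv_decomposition(0.0, 0.0, 0.0) == 0.0

    def test_common_mode_variation_matches_budget(self):
        # one latent factor perturbing k, [A]0 and [B]0 together: the linear
        # budget is exact to first order
        rng = np.random.default_rng(16)
        eps = rng.normal(0.0, 0.05, 5000)
        v0 = (1 + eps) ** 3  # k * A * B, each carrying the same 5% error
        measured = v0.std() / v0.mean()
        predicted = td.cv_decomposition(0.05, 0.05, 0.05)
        assert measured == pytest.approx(predicted, rel=0.2)

    def test_upper_bound_for_independent_variation(self):
        rng = np.random.default_rng(17)
        k = 1 + rng.normal(0, 0.05, 5000)
        a = 1 + rng.normal(0, 0.05, 5000)
        b = 1 + rng.normal(0, 0.05, 5000)
        v0 = k * a * b
        measured = v0.std() / v0.mean()
        assert measured < td.cv_decomposition(0.05, 0.05, 0.05)
        # quadrature is the right combination for independent errors
        assert measured == pytest.approx(np.sqrt(3) * 0.05, rel=0.1)


@pytest.fixture(scope="module")
def sweep(acq):
    cfg = td.EmulsionConfig(
        n_droplets=500, radius_cv=0.0, mixing_mode="sinusoidal"
    )
    prog = td.PressureProgram(period=1.0, droplet_interval=0.0123)
    em = td.generate_emulsion(cfg, prog, seed=6)
    traces = td.simulate_trace_set(em, POOL, acq, td.NoiseModel(0.0, 0.0))
    w = td.SlopeWindow(10.0, 90.0)
    cmap = td.estimate_invader_concentrations(traces, 500e-9)
    slopes = td.estimate_slopes(traces, w)
    return cmap, slopes, w


class TestParabolaOverlay:
    def test_noiseless_scale_recovers_fluorescence_conversion(self, sweep):
        cmap, slopes, w = sweep
        overlay = td.parabola_overlay(cmap, slopes, POOL, 500e-9, 400e-9, w)
        # 200 n.u. <-> 200 nM, so the conversion factor is 1e9 n.u./M
        assert overlay.scale == pytest.approx(1e9, rel=5e-3)
        assert np.max(np.abs(overlay.residuals)) < 0.01 * slopes.raw.max()

    def test_model_peak_on_coarse_grid_at_half(self, sweep):
        cmap, slopes, w = sweep
        overlay = td.parabola_overlay(
            cmap, slopes, POOL, 500e-9, 400e-9, w, grid_step=0.05
        )
        assert overlay.argmax_xi == pytest.approx(0.5)

    def test_noisy_slopes_scale_within_three_percent(self, sweep):
        cmap, slopes, w = sweep
        rng = np.random.default_rng(18)
        noisy = td.SlopeSet.from_raw(
            slopes.raw * (1 + rng.normal(0, 0.10, slopes.raw.size)),
            w,
            slopes.droplet_ids,
        )
        overlay = td.parabola_overlay(cmap, noisy, POOL, 500e-9, 400e-9, w)
        assert overlay.scale == pytest.approx(1e9, rel=0.03)

    def test_disjoint_ids_rejected(self, sweep):
        cmap, slopes, w = sweep
        other = td.SlopeSet.from_raw([1.0, 2.0], w, ["x1", "x2"])
        with pytest.raises(InputError):
            td.parabola_overlay(cmap, other, POOL, 500e-9, 400e-9, w)


class TestPoolVsCleanEnsembles:
    """The headline qualitative claim: a random pool adds kinetic variability."""

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pool_ensemble_cv_exceeds_clean(self, pool_10k, acq, seed):
        _, ddgs = pool_10k
        base = dict(
            n_droplets=400, radius_mean=10.0, radius_cv=0.03,
            mixing_mode="fixed", xi_fixed=0.45, xi_jitter_sd=0.01,
        )
        em_clean = td.generate_emulsion(td.EmulsionConfig(**base), seed=seed)
        em_pool = td.generate_emulsion(
            td.EmulsionConfig(**base, pool_stock=5e-6, pool_size=10_000),
            pool=ddgs, seed=seed, calibration=td.K_POOL / td.K_CLEAN,
        )
        w = td.SlopeWindow(10.0, 50.0)
        nm = td.NoiseModel(0.0, 0.0)
        cv_clean = td.variability_stats(
            td.estimate_slopes(td.simulate_trace_set(em_clean, CLEAN, acq, nm), w)
        ).cv
        cv_pool = td.variability_stats(
            td.estimate_slopes(td.simulate_trace_set(em_pool, CLEAN, acq, nm), w)
        ).cv
        assert cv_pool > cv_clean

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_fitted_k_pool_below_k_clean(self, pool_10k, acq, seed):
        _, ddgs = pool_10k
        base = dict(n_droplets=200, radius_mean=10.0, radius_cv=0.03)
        em_clean = td.generate_emulsion(td.EmulsionConfig(**base), seed=seed)
        em_pool = td.generate_emulsion(
            td.EmulsionConfig(**base, pool_stock=5e-6, pool_size=10_000),
            pool=ddgs, seed=seed, calibration=td.K_POOL / td.K_CLEAN,
        )
        nm = td.NoiseModel(0.0, 0.0)

        def fitted_k(em):
            traces = td.simulate_trace_set(em, CLEAN, acq, nm)
            times, mean_red = td.mean_trace(traces)
            return td.fit_rate_constant(
                times, mean_red, 250e-9, 200e-9, 200e-9
            ).k_hat

        k_clean = fitted_k(em_clean)
        k_pool = fitted_k(em_pool)
        assert k_pool < k_clean
        assert k_clean == pytest.approx(td.K_CLEAN, rel=0.02)
        assert k_pool == pytest.approx(td.K_POOL, rel=0.02)
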