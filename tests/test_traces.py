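"""WLC conversion, staircase HMM, PFV, crossing times, mixture MLE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from pausekit.traces import (BiexpFit, StepPath, WLCParams, _biexp_nll,
                             contour_length_from_extension,
                             crossing_times, extension_from_contour,
                             fit_biexponential, fit_staircase,
                             locate_pause_sites, pause_catalog,
                             pause_free_velocity, wlc_extension_factor)

RATE = 1333.0


class TestWLC:
    def test_zero_extension_is_zero_contour(self):
        assert contour_length_from_extension(0.0, 10.0) == 0.0

    @pytest.mark.parametrize("force", [5.0, 10.0, 15.0])
    def test_round_trip_identity(self, force):
        bp = 3034.0
        x = extension_from_contour(bp, force)
        back = contour_length_from_extension(x, force)
        assert back == pytest.approx(bp, rel=1e-9)

    def test_high_force_limit(self):
        """As F grows the entropic term vanishes: x/L -> 1 + F/K."""
        wlc = WLCParams()
        f = 1e5
        assert wlc_extension_factor(f, wlc) == pytest.approx(
            1.0 + f / wlc.stretch_modulus_pn, rel=1e-3)

    def test_low_force_rejected(self):
        with pytest.raises(ValueError):
            wlc_extension_factor(0.05, WLCParams())

    @given(force=st.floats(0.5, 60.0), bp=st.floats(10.0, 5000.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_consistency_property(self, force, bp):
        x = extension_from_contour(bp, force)
        assert contour_length_from_extension(x, force) == pytest.approx(
            bp, rel=1e-9)


class TestStaircase:
    def test_noiseless_exact_recovery(self):
        dwells = [200, 150, 400, 90, 300]
        truth = np.repeat(np.arange(5, dtype=float), dwells)
        sp = fit_staircase(truth, RATE, noise_sd=0.2)
        assert list(sp.position_bp) == [0, 1, 2, 3, 4]
        starts = np.round(sp.t_start * RATE).astype(int)
        assert list(starts) == [0, 200, 350, 750, 840]

    def test_moderate_noise_recovery_study(self):
        """1 bp-equivalent noise, 10-sample decimation: >=95% of interior
        step times of >=60 ms dwells land within 2 analysis samples."""
        rng = np.random.default_rng(5)
        hits, total = 0, 0
        for _ in range(8):
            dwell_samples = rng.integers(80, 1400, size=30)
            truth = np.repeat(np.arange(30, dtype=float), dwell_samples)
            noisy = truth + rng.normal(0, 1.0, size=truth.size)
            sp = fit_staircase(noisy, RATE, decimate=10)
            if len(sp.t_start) != 30:
                continue
            true_t = np.cumsum(dwell_samples)[:-1] / RATE
            ok = (dwell_samples[:-1] > 66) & (dwell_samples[1:] > 66)
            err = np.abs(sp.t_start[1:] - true_t)[ok]
            hits += int((err <= 2 * 10 / RATE).sum())
            total += int(ok.sum())
        assert total > 100
        assert hits / total >= 0.95

    def test_instrument_noise_recovery_study(self):
        """At 1 nm (~2.9 bp) acquisition noise with 20-sample decimation,
        >=90% of step times are recovered within 75 ms."""
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(8):
            dwell_samples = rng.integers(80, 1400, size=30)
            truth = np.repeat(np.arange(30, dtype=float), dwell_samples)
            noisy = truth + rng.normal(0, 2.94, size=truth.size)
            sp = fit_staircase(noisy, RATE, decimate=20)
            if len(sp.t_start) != 30:
                continue
            true_t = np.cumsum(dwell_samples)[:-1] / RATE
            ok = (dwell_samples[:-1] > 66) & (dwell_samples[1:] > 66)
            errs.extend(np.abs(sp.t_start[1:] - true_t)[ok].tolist())
        assert len(errs) > 100
        assert np.mean(np.asarray(errs) <= 0.075) >= 0.90

    def test_decreasing_signal_rejected(self):
        y = np.linspace(30.0, 0.0, 2000)
        with pytest.raises(ValueError, match="decreas"):
            fit_staircase(y, RATE)

    def test_path_contract_unit_steps(self):
        with pytest.raises(ValueError):
            StepPath(position_bp=np.array([0, 2]),
                     t_start=np.array([0.0, 1.0]),
                     t_end=np.array([1.0, 2.0]))


class TestPauseCatalog:
    def test_all_short_dwells_no_pauses(self, step_path_factory):
        sp = step_path_factory(np.arange(20), np.full(20, 0.2))
        pauses, density = pause_catalog(sp)
        assert pauses == [] and density == 0.0

    def test_threshold_infinity_no_pauses(self, step_path_factory):
        sp = step_path_factory(np.arange(20), np.full(20, 10.0))
        pauses, _ = pause_catalog(sp, min_dwell_s=np.inf)
        assert pauses == []

    def test_single_interior_pause_detected(self, step_path_factory):
        dwells = np.full(20, 0.2)
        dwells[10] = 3.0
        sp = step_path_factory(np.arange(20), dwells)
        pauses, density = pause_catalog(sp)
        assert len(pauses) == 1
        assert pauses[0]["position_bp"] == 10
        assert density == pytest.approx(1 / 19)

    def test_pause_incidence_matches_generator(self, step_path_factory):
        """Over many simulated molecules the mean number of >0.5 s pauses
        per trace matches the configured efficiency within binomial error.
        Elongation is fast (20 bp/s) so ordinary dwells stay far below the
        0.5 s classification threshold."""
        from pausekit.synthetic import (PauseSiteParams, TemplateSpec,
                                        simulate_trajectories)
        kn, e = 20.0, 0.427
        template = TemplateSpec(
            length=40, kn=kn,
            pause_sites={34: PauseSiteParams(kp=kn * e / (1 - e),
                                             k_escape=1 / 126.0)})
        n = 300
        paths = simulate_trajectories(template, n, 1e6, seed=9)
        count = 0
        for p in paths:
            sp_pos, sp_t = [], []
            for pos, t, state in p.events:
                if state == "elongating" and (not sp_pos
                                              or pos != sp_pos[-1]):
                    sp_pos.append(pos)
                    sp_t.append(t)
            starts = np.asarray(sp_t)
            sp = StepPath(position_bp=np.asarray(sp_pos), t_start=starts,
                          t_end=np.append(starts[1:], p.end_time))
            pauses, _ = pause_catalog(sp)
            count += len(pauses)
        e = 0.427
        # long escape (126 s) makes nearly every pause exceed 0.5 s
        se = np.sqrt(e * (1 - e) / n) + e / np.sqrt(n)
        assert count / n == pytest.approx(e, abs=3 * se + 0.03)


class TestPFV:
    def test_constant_velocity_noiseless(self, step_path_factory):
        v = 3.0
        y = v * np.arange(int(10 * RATE)) / RATE
        sp = fit_staircase(y, RATE)
        res = pause_free_velocity(y, RATE, step_path=sp)
        assert not res.undefined
        assert res.pfv_bp_s == pytest.approx(v, abs=0.25)

    def test_recovery_with_pauses_and_noise(self):
        """Velocity of 5 bp/s with interleaved 2 s pauses and 0.5 bp noise
        is recovered within 10%."""
        rng = np.random.default_rng(11)
        v = 5.0
        parts, x = [], 0.0
        for k in range(5):
            n = int(4 * RATE)
            parts.append(x + v * np.arange(n) / RATE)
            x = parts[-1][-1]
            if k < 4:
                parts.append(np.full(int(2 * RATE), x))
        y = np.concatenate(parts) + rng.normal(0, 0.5, sum(len(p) for p in parts))
        sp = fit_staircase(y, RATE, decimate=5)
        res = pause_free_velocity(y, RATE, step_path=sp)
        assert not res.undefined
        assert res.pfv_bp_s == pytest.approx(v, rel=0.10)

    def test_added_dwell_mass_changes_zero_weight_not_mean(self):
        rng = np.random.default_rng(13)
        v = 5.0
        n = int(6 * RATE)
        ramp = v * np.arange(n) / RATE
        pause = np.full(int(3 * RATE), ramp[-1])
        y1 = np.concatenate([ramp, pause, ramp[-1] + ramp[:n // 2]])
        y2 = np.concatenate([ramp, pause, pause, ramp[-1] + ramp[:n // 2]])
        noise1 = rng.normal(0, 0.3, y1.size)
        noise2 = rng.normal(0, 0.3, y2.size)
        # bypass the pause mask so the zero component absorbs the dwells
        r1 = pause_free_velocity(y1 + noise1, RATE,
                                 step_path=fit_staircase(y1 + noise1, RATE,
                                                         decimate=5),
                                 min_dwell_s=np.inf)
        r2 = pause_free_velocity(y2 + noise2, RATE,
                                 step_path=fit_staircase(y2 + noise2, RATE,
                                                         decimate=5),
                                 min_dwell_s=np.inf)
        assert r2.zero_weight > r1.zero_weight
        assert r2.pfv_bp_s == pytest.approx(r1.pfv_bp_s, rel=0.10)


class TestPauseSitesAndCrossing:
    def test_configured_locus_detected(self, step_path_factory):
        paths = []
        for _ in range(10):
            dwells = np.full(60, 0.2)
            dwells[34] = 6.0
            paths.append(step_path_factory(np.arange(60), dwells))
        sites = locate_pause_sites(paths)
        assert 34 in sites

    def test_hp_locus_at_90(self, step_path_factory):
        paths = []
        for _ in range(10):
            dwells = np.full(120, 0.3)
            dwells[90] = 20.0
            paths.append(step_path_factory(np.arange(120), dwells))
        assert list(locate_pause_sites(paths)) == [90]

    def test_flat_occupancy_no_peaks(self, step_path_factory):
        paths = [step_path_factory(np.arange(50), np.full(50, 0.4))
                 for _ in range(5)]
        assert len(locate_pause_sites(paths)) == 0

    def test_crossing_constant_velocity(self, step_path_factory):
        v = 2.0
        sp = step_path_factory(np.arange(60), np.full(60, 1 / v))
        d, censored = crossing_times([sp], 34, 2.5)
        assert censored == 0
        assert d[0] == pytest.approx(5.0 / v)

    def test_crossing_additivity_with_pause(self, step_path_factory):
        v, extra = 2.0, 7.0
        dwells = np.full(60, 1 / v)
        dwells[34] += extra
        sp = step_path_factory(np.arange(60), dwells)
        d, _ = crossing_times([sp], 34, 2.5)
        assert d[0] == pytest.approx(5.0 / v + extra)

    def test_censoring_counted(self, step_path_factory):
        short = step_path_factory(np.arange(30), np.full(30, 0.5))
        full = step_path_factory(np.arange(60), np.full(60, 0.5))
        d, censored = crossing_times([short, full], 34, 2.5)
        assert censored == 1 and d.size == 1

    def test_center_outside_raises(self, step_path_factory):
        sp = step_path_factory(np.arange(30), np.full(30, 0.5))
        with pytest.raises(ValueError):
            crossing_times([sp], 500, 2.5)


class TestBiexponential:
    @staticmethod
    def draw_mixture(n, e, k1, k2, seed):
        rng = np.random.default_rng(seed)
        z = rng.random(n)
        return np.where(z < e, rng.exponential(1 / k2, n),
                        rng.exponential(1 / k1, n))

    def test_recovers_reference_scale_mixture(self):
        t = self.draw_mixture(300, 0.427, 2.0, 1 / 126.0, seed=17)
        fit = fit_biexponential(t, seed=1)
        assert not fit.degenerate
        assert fit.efficiency == pytest.approx(0.427, abs=0.05)
        assert fit.k1 > fit.k2
        assert fit.tau == pytest.approx(1 / fit.k2)

    def test_single_exponential_flagged(self):
        rng = np.random.default_rng(19)
        fit = fit_biexponential(rng.exponential(1.0, 300), seed=1)
        assert fit.degenerate

    def test_likelihood_beats_grid_scan(self):
        """The optimiser's log-likelihood is at least as good as a 50x50
        (k1, k2) grid scan at several mixture weights (grid oracle)."""
        t = self.draw_mixture(200, 0.4, 2.0, 0.02, seed=23)
        fit = fit_biexponential(t, seed=1)
        best = np.inf
        for k1 in np.geomspace(0.2, 20, 50):
            for k2 in np.geomspace(1e-3, 0.19, 50):
                for a in (0.2, 0.4, 0.6):
                    nll = _biexp_nll(
                        np.array([logit(a), np.log(k1), logit(k2 / k1)]), t)
                    best = min(best, nll)
        assert -fit.loglik <= best + 1e-6

    def test_bootstrap_ci_covers_point(self):
        t = self.draw_mixture(200, 0.4, 2.0, 0.02, seed=29)
        fit = fit_biexponential(t, seed=1, bootstrap=30)
        lo, hi = fit.ci["efficiency"]
        assert lo <= fit.efficiency <= hi

    def test_positive_durations_required(self):
        with pytest.raises(ValueError):
            fit_biexponential(np.array([1.0, -2.0, 3.0, 4.0, 5.0, 6.0]))


def test_biexpfit_invariants():
    fit = BiexpFit(a1=0.6, a2=0.4, k1=2.0, k2=0.01, loglik=0.0)
    assert fit.efficiency == pytest.approx(0.4)
    assert fit.tau == pytest.approx(100.0)
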