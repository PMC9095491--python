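"""Synthetic-data generator: plasma input, tissue simulation, noise, SCR,
cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from fearpet import (CohortConfig, FrameSchedule, InputModel, NoiseModel,
                     ReleaseSchedule, TissueParams, DEFAULT_KINETICS,
                     add_noise, generate_cohort, generate_scr_series,
                     plasma_input, simulate_tissue_tac, frame_average,
                     k3_timecourse)
from fearpet.scr import process_scr_table


class TestFrameSchedule:
    def test_default_is_18_five_minute_frames(self, frames):
        assert frames.n_frames == 18
        assert frames.total_span == (0.0, 90.0)
        np.testing.assert_allclose(frames.durations, 5.0)

    @pytest.mark.parametrize("starts,ends", [
        ([0, 5], [5, 4]),          # end before start
        ([0, 4], [5, 9]),          # overlap
        ([5, 0], [10, 5]),         # not increasing
    ])
    def test_invalid_schedules_rejected(self, starts, ends):
        with pytest.raises(ValueError):
            FrameSchedule(np.array(starts, float), np.array(ends, float))

    def test_frame_average_conserves_mass(self, frames):
        t = frames.fine_grid(0.05)
        curve = np.sin(t / 7.0) ** 2 + 1.0
        avg = frame_average(curve, t, frames)
        for i in range(frames.n_frames):
            m = (t >= frames.starts[i] - 1e-12) & (t <= frames.ends[i] + 1e-12)
            expect = np.trapezoid(curve[m], t[m]) / 5.0
            assert abs(avg[i] - expect) < 1e-10 * abs(expect)


class TestPlasmaInput:
    def test_bolus_only_decays_after_peak(self, input_model):
        t = np.linspace(0, 90, 1801)
        bolus = input_model.bolus_component(t)
        peak = np.argmax(bolus)
        assert np.all(np.diff(bolus[peak:]) <= 1e-12)

    def test_infusion_only_nondecreasing_to_plateau(self, input_model):
        t = np.linspace(0, 90, 1801)
        inf = input_model.infusion_component(t)
        assert np.all(np.diff(inf) >= -1e-12)

    def test_combined_area_equals_component_areas(self, input_model):
        total, _ = quad(lambda s: float(input_model(np.array([s]))[0]),
                        0, 90, limit=200)
        b, _ = quad(lambda s: float(input_model.bolus_component(
            np.array([s]))[0]), 0, 90, limit=200)
        i, _ = quad(lambda s: float(input_model.infusion_component(
            np.array([s]))[0]), 0, 90, limit=200)
        assert abs(total - (b + i)) < 1e-3 * total

    def test_nonnegative_and_frame_sampling(self, frames, input_model):
        curve = plasma_input(frames.fine_grid(0.05), input_model)
        assert np.all(curve >= 0)
        framed = plasma_input(frames, input_model)
        assert framed.shape == (18,)

    def test_nonpositive_kbol_rejected(self):
        with pytest.raises(ValueError):
            InputModel(kbol=0.0)


def _biexp_2tcm_oracle(input_model, tissue, t):
    """Closed-form 2TCM solution for constant k3 (analytic convolution).

    The plasma curve within the infusion window is a constant plus a sum of
    exponentials; convolving each term with the bi-exponential tissue
    impulse response has a closed form.
    """
    k2, k3, k4 = tissue.k2, tissue.k3_base, tissue.k4
    s = k2 + k3 + k4
    disc = np.sqrt(s * s - 4.0 * k2 * k4)
    th1, th2 = (s + disc) / 2.0, (s - disc) / 2.0
    a1 = tissue.K1 * (th1 - k3 - k4) / (th1 - th2)
    a2 = tissue.K1 * (k3 + k4 - th2) / (th1 - th2)
    # plasma terms: constant c0 plus exponentials ci*exp(-li t)
    r = input_model.infusion_rate
    terms = [(r * sum(a / lam for a, lam in zip(input_model.amplitudes,
                                                input_model.rates)), 0.0)]
    for a, lam in zip(input_model.amplitudes, input_model.rates):
        terms.append((r * a * (input_model.kbol - 1.0 / lam), lam))

    out = np.zeros_like(t)
    for amp, th in ((a1, th1), (a2, th2)):
        for c, lam in terms:
            if lam == 0.0:
                out += amp * c * (1.0 - np.exp(-th * t)) / th
            elif abs(th - lam) < 1e-9:      # confluent rates: t exp(-th t)
                out += amp * c * t * np.exp(-th * t)
            else:
                out += amp * c * (np.exp(-lam * t) - np.exp(-th * t)) \
                    / (th - lam)
    return out


class TestTissueSimulator:
    def test_k1_zero_gives_zero_tac(self, frames, input_model):
        tac = simulate_tissue_tac(
            input_model, TissueParams(K1=0.0, k2=0.3, k4=0.17, BP_base=0.3),
            None, frames)
        np.testing.assert_array_equal(tac, 0.0)

    def test_zero_drop_matches_no_schedule_bitwise(self, frames, input_model):
        tissue = TissueParams(BP_base=0.3, **DEFAULT_KINETICS)
        a = simulate_tissue_tac(input_model, tissue, None, frames)
        b = simulate_tissue_tac(
            input_model, tissue,
            ReleaseSchedule(mode="linear_ramp", drop_fraction=0.0), frames)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bp", [0.0, 0.3, 2.6])
    def test_constant_k3_matches_analytic_solution(self, frames, input_model,
                                                   bp):
        """RK4 integration vs the closed-form bi-exponential 2TCM solution."""
        tissue = TissueParams(BP_base=bp, **DEFAULT_KINETICS)
        _, (t, fine) = simulate_tissue_tac(input_model, tissue, None, frames,
                                           return_fine=True)
        oracle = _biexp_2tcm_oracle(input_model, tissue, t)
        scale = oracle.max()
        mask = oracle > 0.01 * scale
        rel = np.abs(fine[mask] - oracle[mask]) / oracle[mask]
        assert rel.max() < 1e-3

    def test_nonnegative_fine_solution(self, frames, input_model):
        tissue = TissueParams(BP_base=2.6, **DEFAULT_KINETICS)
        _, (_, fine) = simulate_tissue_tac(
            input_model, tissue,
            ReleaseSchedule(mode="linear_ramp", drop_fraction=0.3),
            frames, return_fine=True)
        assert fine.min() >= 0.0

    def test_gamma_variate_mode_transient(self, frames, input_model):
        rel = ReleaseSchedule(mode="gamma_variate", drop_fraction=0.2,
                              gamma_shape=2.0, gamma_scale=6.0)
        t = np.linspace(0, 90, 901)
        scale = rel.k3_scale(t)
        assert scale.min() == pytest.approx(0.8, abs=1e-6)
        assert np.argmin(scale) == np.searchsorted(t, 62.0)  # peak at t_on+12
        assert scale[-1] > scale.min()  # partial recovery afterwards

    def test_linear_ramp_asymptotic_bp(self):
        """After t_off the implied binding potential is exactly BP*(1-d)."""
        tissue = TissueParams(BP_base=0.3, **DEFAULT_KINETICS)
        rel = ReleaseSchedule(mode="linear_ramp", drop_fraction=0.15)
        k3 = k3_timecourse(tissue, rel, np.array([75.0, 90.0]))
        np.testing.assert_allclose(k3 / tissue.k4,
                                   0.3 * 0.85 * np.ones(2), rtol=1e-12)


class TestNoise:
    def test_alpha_zero_identity(self, frames, region_tacs):
        tac = region_tacs["amygdala"]
        out = add_noise(tac, frames, NoiseModel(alpha=0.0))
        np.testing.assert_array_equal(out, tac)

    def test_seed_reproducibility(self, frames, region_tacs):
        tac = region_tacs["amygdala"]
        nm = NoiseModel(alpha=0.2, seed=42)
        np.testing.assert_array_equal(add_noise(tac, frames, nm),
                                      add_noise(tac, frames, nm))

    def test_empirical_sd_matches_model(self, frames, region_tacs):
        """Per-frame SD over replicates approaches alpha*sqrt(C/dt)."""
        tac = region_tacs["amygdala"]
        nm = NoiseModel(alpha=0.25)
        rng = np.random.default_rng(7)
        reps = np.stack([add_noise(tac, frames, nm, rng)
                         for _ in range(2000)])
        sd_emp = reps.std(axis=0)
        sd_model = 0.25 * np.sqrt(tac / frames.durations)
        np.testing.assert_allclose(sd_emp, sd_model, rtol=0.05)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(alpha=-0.1)


class TestSCRGenerator:
    def test_default_design_counts(self):
        df = generate_scr_series(seed=0)
        assert len(df) == 40
        assert (df["cs_type"] == "+").sum() == 20
        assert (df["cs_type"] == "-").sum() == 20
        assert df["reinforced"].sum() == 16
        assert (df.loc[df["cs_type"] == "-", "reinforced"] == 0).all()

    def test_overfull_reinforcement_rejected(self):
        with pytest.raises(ValueError):
            generate_scr_series(n_csp=10, n_reinforced=11, seed=0)

    def test_null_effect_gives_zero_mean_delta(self):
        rng = np.random.default_rng(1)
        deltas = []
        for _ in range(1000):
            df = generate_scr_series(effect_size=0.0, seed=rng)
            deltas.append(process_scr_table(df)[1].delta)
        deltas = np.array(deltas)
        se = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs(deltas.mean()) < 2.0 * se + 1e-12

    def test_first_trial_difference_is_null(self):
        """CS+/CS- difference on the first presentation has zero mean even
        with a positive learning effect (learning needs one pairing)."""
        rng = np.random.default_rng(2)
        first_diffs = []
        for _ in range(800):
            df = generate_scr_series(effect_size=0.5, noise_sd=0.05, seed=rng)
            f_p = df[df["cs_type"] == "+"].iloc[0]["amplitude_uS"]
            f_m = df[df["cs_type"] == "-"].iloc[0]["amplitude_uS"]
            first_diffs.append(np.sqrt(f_p) - np.sqrt(f_m))
        first_diffs = np.array(first_diffs)
        se = first_diffs.std(ddof=1) / np.sqrt(first_diffs.size)
        assert abs(first_diffs.mean()) < 3.0 * se

    def test_habituation_declines_across_trials(self):
        df = generate_scr_series(effect_size=0.0, noise_sd=0.0, seed=3)
        csm = df[df["cs_type"] == "-"]["amplitude_uS"].to_numpy()
        assert np.all(np.diff(csm) < 0)


class TestCohortGenerator:
    def test_n_subjects(self):
        bundles = generate_cohort(CohortConfig(n_subjects=18, seed=0))
        assert len(bundles) == 18
        b = bundles[0]
        assert set(b.tacs) == {"striatum", "amygdala", "frontal", "reference"}
        assert b.scr.shape[0] == 40

    def test_zero_coupling_decorrelates(self):
        cfg = CohortConfig(n_subjects=600, loading_release=0.0,
                           loading_scr=0.0, loading_bold=0.0, seed=1,
                           noise=NoiseModel(alpha=0.0))
        bundles = generate_cohort(cfg)
        rel = np.array([b.truth["release_amygdala"] for b in bundles])
        scr = np.array([b.truth["scr_delta"] for b in bundles])
        r = np.corrcoef(rel, scr)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(bundles))

    def test_large_n_truth_structure_recovered(self):
        """Ground-truth correlations approach the configured loading
        products in the large-n limit."""
        cfg = CohortConfig(n_subjects=2000, seed=2,
                           noise=NoiseModel(alpha=0.0))
        bundles = generate_cohort(cfg)
        rel = np.array([b.truth["release_amygdala"] for b in bundles])
        scr = np.array([b.truth["scr_delta"] for b in bundles])
        expected = cfg.loading_release * cfg.loading_scr
        assert np.corrcoef(rel, scr)[0, 1] == pytest.approx(expected,
                                                            abs=0.02)
        assert rel.mean() == pytest.approx(cfg.release_mean,
                                           abs=3 * cfg.release_sd / np.sqrt(2000))
        assert rel.std() == pytest.approx(cfg.release_sd, rel=0.05)

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=2)
        with pytest.raises(ValueError):
            CohortConfig(release_sd=-1.0)
        with pytest.raises(ValueError):
            CohortConfig(loading_release=1.2)
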