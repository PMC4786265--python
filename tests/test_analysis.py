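"""Reaction coordinates, free-energy profiles, Cv, T_F and COM PCA."""

import numpy as np
import pytest

from gosbm.analysis import (
    AnalysisError,
    compute_com_pca,
    compute_q,
    contact_formation_map,
    estimate_tf_from_profiles,
    free_energy_profile,
    specific_heat,
)
from gosbm.contacts import ContactList


def _contacts(entries):
    return ContactList(entries=entries)


def _frames_from(xyzs):
    return np.asarray(xyzs, dtype=float)


@pytest.fixture()
def square_contacts():
    # 4 beads on a line, native distances chosen freely
    return _contacts([(0, 1, 0.4), (0, 2, 0.5), (1, 3, 0.5), (2, 3, 0.4)])


class TestComputeQ:
    def test_native_frame_is_one(self, ci2_cg):
        q = compute_q(ci2_cg["structure"].coords()[None], ci2_cg["contacts"], 1.5)
        assert q.values.tolist() == [1.0]

    def test_fully_extended_frame_is_zero(self, square_contacts):
        frame = np.zeros((1, 4, 3))
        frame[0, :, 0] = np.arange(4) * 10.0
        q = compute_q(frame, square_contacts, 1.5)
        assert q.values.tolist() == [0.0]

    def test_partial_formation_counts(self, square_contacts):
        # place beads so exactly 3 of 4 native pairs are within threshold
        frame = np.zeros((1, 4, 3))
        frame[0, 1, 0] = 0.4
        frame[0, 2, 0] = 0.5
        frame[0, 3, 0] = 5.0  # breaks (1,3) and (2,3)... keeps (0,1), (0,2)
        frame[0, 3, 1] = 0.0
        q = compute_q(frame, square_contacts, 1.5)
        assert q.values[0] == pytest.approx(0.5)
        frame[0, 3, 0] = 0.9  # (1,3): 0.5 <= 0.75 ok; (2,3): 0.4 <= 0.6 ok
        q = compute_q(frame, square_contacts, 1.5)
        assert q.values[0] == pytest.approx(1.0)
        frame[0, 3, 0] = 1.3  # (1,3): 0.9 > 0.75 broken; (2,3): 0.8 > 0.6 broken
        q = compute_q(frame, square_contacts, 1.5)
        assert q.values[0] == pytest.approx(0.5)

    def test_rigid_motion_invariance(self, ci2_cg, rng):
        native = ci2_cg["structure"].coords()
        theta = 1.1
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        perturbed = native + 0.05 * rng.standard_normal(native.shape)
        moved = perturbed @ rot.T + np.array([3.0, -2.0, 1.0])
        q1 = compute_q(perturbed[None], ci2_cg["contacts"])
        q2 = compute_q(moved[None], ci2_cg["contacts"])
        assert q1.values[0] == pytest.approx(q2.values[0], abs=1e-12)

    def test_empty_contacts_rejected(self):
        with pytest.raises(AnalysisError, match="empty contact list"):
            compute_q(np.zeros((1, 2, 3)), ContactList())


class TestFreeEnergyProfile:
    def test_uniform_series_is_flat(self, rng):
        q = rng.uniform(0, 1, size=200_000)
        prof = free_energy_profile(q, n_bins=20)
        assert prof.values.max() < 0.15  # binning noise only

    def test_bimodal_mixture_recovers_component_means(self, rng):
        a = np.clip(rng.normal(0.25, 0.05, 50_000), 0, 1)
        b = np.clip(rng.normal(0.75, 0.05, 50_000), 0, 1)
        prof = free_energy_profile(np.concatenate([a, b]), n_bins=40)
        assert prof.is_bimodal()
        mins = sorted(prof.bin_centers[i] for i in prof.minima()
                      if prof.values[i] < 1.0)
        assert mins[0] == pytest.approx(0.25, abs=0.025)  # within one bin
        assert mins[-1] == pytest.approx(0.75, abs=0.025)

    def test_scaling_invariance_of_probabilities(self, rng):
        q = rng.uniform(0, 1, 5000)
        p1 = free_energy_profile(q, n_bins=10)
        p2 = free_energy_profile(np.concatenate([q, q]), n_bins=10)  # P -> 2P
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-12)

    def test_short_series_rejected(self):
        with pytest.raises(AnalysisError):
            free_energy_profile(np.array([0.5]), n_bins=10)


class TestSpecificHeat:
    def test_harmonic_oscillator_cv_is_one(self, rng):
        """E = p^2/2 + x^2/2 at k_B = 1: Cv = 1 per oscillator."""
        series = {}
        for t in (0.8, 1.0, 1.2):
            x = rng.normal(0, np.sqrt(t), 400_000)
            p = rng.normal(0, np.sqrt(t), 400_000)
            series[t] = 0.5 * (x**2 + p**2)
        curve = specific_heat(series)
        np.testing.assert_allclose(curve.cv, 1.0, rtol=0.05)

    def test_constant_energy_series_gives_zero(self):
        series = {t: np.full(100, 7.0) for t in (0.5, 1.0, 1.5)}
        curve = specific_heat(series)
        assert np.all(curve.cv == 0.0)

    def test_two_state_model_peak_recovered(self, rng):
        """Two-level system with degeneracy g and gap dE peaks near the
        analytic Schottky maximum; the sampled peak lands within the grid
        spacing of the analytic curve's maximum."""
        g, de = 50.0, 2.0
        temps = np.round(np.arange(0.3, 1.51, 0.06), 10)

        def p_excited(t):
            w = g * np.exp(-de / t)
            return w / (1.0 + w)

        series = {}
        for t in temps:
            e = de * (rng.uniform(size=200_000) < p_excited(t))
            series[float(t)] = e
        curve = specific_heat(series)
        analytic_cv = []
        for t in temps:
            p = p_excited(t)
            analytic_cv.append(de**2 * p * (1 - p) / t**2)
        t_true = temps[int(np.argmax(analytic_cv))]
        assert abs(curve.t_f - t_true) <= 0.06

    def test_equal_area_normalization(self, rng):
        series = {t: rng.normal(0, 1 + t, 10_000) for t in (0.5, 1.0, 1.5)}
        curve = specific_heat(series, equal_area=True)
        assert np.trapezoid(curve.cv, curve.temperatures) == pytest.approx(1.0)

    def test_single_frame_series_rejected(self):
        with pytest.raises(AnalysisError):
            specific_heat({0.5: np.ones(1), 1.0: np.ones(1), 1.5: np.ones(1)})


class TestContactFormationMap:
    def test_native_only_trajectory_all_ones(self, ci2_cg):
        frames = np.repeat(ci2_cg["structure"].coords()[None], 5, axis=0)
        q = compute_q(frames, ci2_cg["contacts"])
        probs = contact_formation_map(frames, ci2_cg["contacts"], q, (0.0, 1.0))
        np.testing.assert_array_equal(probs, 1.0)

    def test_difference_with_itself_is_zero(self, ci2_cg):
        frames = np.repeat(ci2_cg["structure"].coords()[None], 3, axis=0)
        q = compute_q(frames, ci2_cg["contacts"])
        probs = contact_formation_map(frames, ci2_cg["contacts"], q, (0.0, 1.0))
        np.testing.assert_array_equal(probs - probs, 0.0)

    def test_counting_oracle_on_handcrafted_frames(self, square_contacts):
        # frame 0: all formed; frame 1: only (0,1) formed
        f0 = np.zeros((4, 3))
        f0[1, 0], f0[2, 0], f0[3, 0] = 0.4, 0.5, 0.9
        f1 = np.zeros((4, 3))
        f1[1, 0], f1[2, 0], f1[3, 0] = 0.4, 5.0, 9.0
        frames = np.stack([f0, f1])
        q = compute_q(frames, square_contacts)
        probs = contact_formation_map(frames, square_contacts, q, (0.0, 1.0))
        np.testing.assert_allclose(probs, [1.0, 0.5, 0.5, 0.5])

    def test_empty_window_rejected(self, ci2_cg):
        frames = np.repeat(ci2_cg["structure"].coords()[None], 3, axis=0)
        q = compute_q(frames, ci2_cg["contacts"])
        with pytest.raises(AnalysisError, match="no frames"):
            contact_formation_map(frames, ci2_cg["contacts"], q, (0.0, 0.2))


class TestComPca:
    def test_rigid_translation_loads_one_mode(self, rng):
        base = rng.standard_normal((30, 3))
        shifts = np.linspace(0, 1, 50)
        frames = base[None] + np.array([[s, 0, 0] for s in shifts])[:, None, :]
        assign = np.arange(30) // 10  # 3 domains
        evals, _ = compute_com_pca(frames, assign)
        assert evals[0] / evals.sum() > 0.999

    def test_eigenvalue_sum_equals_total_com_variance(self, rng):
        frames = rng.standard_normal((200, 12, 3))
        assign = np.arange(12) // 3
        evals, _ = compute_com_pca(frames, assign)
        coms = np.stack(
            [frames[:, assign == d].mean(axis=1) for d in range(4)], axis=1
        ).reshape(200, -1)
        coms -= coms.mean(0)
        total_var = (coms**2).sum() / 199
        assert evals.sum() == pytest.approx(total_var)

    def test_isotropic_noise_spectrum_concentrates_with_frames(self, rng):
        assign = np.arange(20) // 5
        spreads = []
        for n_frames in (100, 10_000):
            frames = 0.1 * rng.standard_normal((n_frames, 20, 3))
            evals, _ = compute_com_pca(frames, assign)
            spreads.append(evals.max() / evals.min())
        assert spreads[1] < spreads[0]  # Marchenko-Pastur-like concentration

    def test_too_few_frames_rejected(self):
        with pytest.raises(AnalysisError):
            compute_com_pca(np.zeros((1, 4, 3)), [0, 0, 1, 1])


class TestEstimateTf:
    def test_logistic_populations_recover_midpoint(self, rng):
        """Synthetic two-state Q ensembles with p_fold(T) logistic around
        T_m = 1.1 recover the midpoint."""
        t_m, width = 1.1, 0.08
        series = {}
        for t in np.round(np.arange(0.9, 1.31, 0.05), 10):
            p_fold = 1.0 / (1.0 + np.exp((t - t_m) / width))
            folded = rng.uniform(size=20_000) < p_fold
            q = np.where(
                folded,
                np.clip(rng.normal(0.85, 0.05, 20_000), 0, 1),
                np.clip(rng.normal(0.15, 0.05, 20_000), 0, 1),
            )
            series[float(t)] = q
        tf = estimate_tf_from_profiles(series)
        assert tf == pytest.approx(t_m, abs=0.03)

    def test_symmetric_single_temperature_bracket(self, rng):
        q_mixed = np.concatenate([
            np.clip(rng.normal(0.2, 0.04, 10_000), 0, 1),
            np.clip(rng.normal(0.8, 0.04, 10_000), 0, 1),
        ])
        series = {
            1.0: np.clip(rng.normal(0.8, 0.04, 10_000), 0, 1),
            1.1: q_mixed,
            1.2: np.clip(rng.normal(0.2, 0.04, 10_000), 0, 1),
        }
        tf = estimate_tf_from_profiles(series)
        assert tf == pytest.approx(1.1, abs=0.051)

    def test_single_basin_data_is_an_error(self, rng):
        series = {
            t: np.clip(rng.normal(0.8, 0.04, 5_000), 0, 1)
            for t in (1.0, 1.1, 1.2)
        }
        with pytest.raises(AnalysisError):
            estimate_tf_from_profiles(series)

    def test_cv_peak_and_population_balance_agree(self, rng):
        """On a synthetic two-state ensemble the two T_F estimators agree
        within their joint uncertainty."""
        t_m, width, de = 1.1, 0.05, 40.0
        temps = np.round(np.arange(0.95, 1.26, 0.05), 10)
        q_series, e_series = {}, {}
        for t in temps:
            p_fold = 1.0 / (1.0 + np.exp((t - t_m) / width))
            folded = rng.uniform(size=50_000) < p_fold
            q_series[float(t)] = np.where(folded, 0.85, 0.15)
            e_series[float(t)] = np.where(folded, -de, 0.0) + rng.normal(
                0, 1.0, 50_000
            )
        tf_pop = estimate_tf_from_profiles(q_series)
        tf_cv = specific_heat(e_series).t_f
        assert abs(tf_pop - tf_cv) < 0.06
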