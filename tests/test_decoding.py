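"""CCA/BCCA recognition, reference construction, and Welch PSD."""

import numpy as np
import pytest
from scipy import stats

from dfssmvep import (
    EEGTrial,
    SimulationConfig,
    bcca_classify,
    bcca_reference_triplet,
    cca_classify,
    first_canonical_correlation,
    harmonic_references,
    select_harmonics,
    simulate_trial,
    welch_psd,
)
from conftest import make_tone_trial

FS = 500.0


class TestHarmonicReferences:
    def test_shape_and_row_frequencies(self):
        refs = harmonic_references(6, 2, FS, 1750)
        assert refs.rows.shape == (4, 1750)
        assert refs.row_frequencies == (6, 6, 12, 12)

    def test_row_energy_is_half_m_for_integer_cycles(self):
        refs = harmonic_references(5, 2, FS, 1000)  # 5 and 10 Hz, 2 s
        energies = np.sum(refs.rows ** 2, axis=1)
        np.testing.assert_allclose(energies, 500.0, rtol=0.01)

    def test_cos_sin_orthogonal_over_full_periods(self):
        refs = harmonic_references(7, 1, FS, 500)
        assert abs(refs.rows[0] @ refs.rows[1]) < 1e-9 * 500

    def test_rejects_aliased_harmonics(self):
        with pytest.raises(ValueError, match="alias"):
            harmonic_references(100, 3, FS, 1000)


class TestFirstCanonicalCorrelation:
    def test_self_correlation_is_one(self, rng):
        X = rng.standard_normal((4, 300))
        rho, _, _ = first_canonical_correlation(X, X)
        assert rho == pytest.approx(1.0, abs=1e-8)

    def test_disjoint_fourier_frequencies_are_uncorrelated(self):
        X = harmonic_references(7, 1, FS, 1000).rows  # 7 Hz sin/cos pair
        Y = harmonic_references(11, 1, FS, 1000).rows
        rho, _, _ = first_canonical_correlation(X, Y)
        assert rho < 0.05

    def test_projections_achieve_rho(self, rng):
        X = rng.standard_normal((3, 400))
        Y = rng.standard_normal((4, 400))
        rho, wx, wy = first_canonical_correlation(X, Y)
        a, b = wx @ X, wy @ Y
        assert abs(np.corrcoef(a, b)[0, 1]) == pytest.approx(rho, abs=1e-9)

    def test_invariant_under_channel_mixing(self, rng):
        X = rng.standard_normal((6, 500))
        Y = harmonic_references(7, 2, FS, 500).rows
        rho0, _, _ = first_canonical_correlation(X, Y)
        for s in range(5):
            r = np.random.default_rng(s)
            q1 = stats.ortho_group.rvs(6, random_state=r)
            q2 = stats.ortho_group.rvs(6, random_state=r)
            mix = q1 @ np.diag(r.uniform(0.5, 2.0, 6)) @ q2
            rho, _, _ = first_canonical_correlation(mix @ X, Y)
            assert abs(rho - rho0) < 1e-9

    def test_matches_brute_force_grid_oracle(self, rng):
        """Exhaustive unit-vector search on 2x2 toys agrees to 1e-3."""
        angles = np.linspace(0, np.pi, 3000, endpoint=False)
        W = np.c_[np.cos(angles), np.sin(angles)]

        def oracle(X, Y):
            A = W @ (X - X.mean(1, keepdims=True))
            B = W @ (Y - Y.mean(1, keepdims=True))
            A -= A.mean(1, keepdims=True)
            B -= B.mean(1, keepdims=True)
            num = A @ B.T
            den = np.sqrt((A * A).sum(1))[:, None] * np.sqrt((B * B).sum(1))
            return np.max(np.abs(num / den))

        for _ in range(10):
            X = rng.standard_normal((2, 60))
            Y = rng.standard_normal((2, 60))
            rho, _, _ = first_canonical_correlation(X, Y)
            assert rho == pytest.approx(oracle(X, Y), abs=1e-3)

    def test_constant_rows_do_not_crash(self, rng):
        X = np.vstack([np.ones(400), rng.standard_normal(400)])
        Y = harmonic_references(6, 1, FS, 400).rows
        rho, _, _ = first_canonical_correlation(X, Y)
        assert 0.0 <= rho <= 1.0

    def test_rejects_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="samples"):
            first_canonical_correlation(rng.standard_normal((4, 8)),
                                        rng.standard_normal((4, 8)))


class TestCCAClassify:
    def test_recovers_tone_with_harmonic(self):
        trial = make_tone_trial([(8, 1.0), (16, 0.5)])
        result = cca_classify(trial, [5, 6, 7, 8, 9], nh=2)
        assert result.predicted == 3
        assert result.scores[3] > 0.99

    def test_white_noise_still_returns_argmax(self, rng):
        trial = EEGTrial(data=rng.standard_normal((6, 1750)), fs=FS,
                         channel_labels=[f"c{i}" for i in range(6)])
        result = cca_classify(trial, [5, 6, 7, 8, 9], nh=2)
        assert result.predicted == int(np.argmax(result.scores))
        assert np.ptp(result.scores) < 0.2

    def test_prediction_invariant_under_mixing(self, rng):
        trial = make_tone_trial([(8, 1.0)], noise=0.3, rng=rng)
        mix = stats.ortho_group.rvs(6, random_state=rng) + 0.1 * np.eye(6)
        mixed = trial.replace(data=mix @ trial.data)
        r1 = cca_classify(trial, [5, 6, 7, 8, 9])
        r2 = cca_classify(mixed, [5, 6, 7, 8, 9])
        assert r1.predicted == r2.predicted


class TestBCCAReferenceTriplet:
    def test_combined_set_structure(self):
        y1, y2, yc = bcca_reference_triplet((6, 9.5), 2, FS, 1750)
        assert y1.rows.shape == (4, 1750)
        assert yc.rows.shape == (10, 1750)
        assert 15.5 in yc.row_frequencies
        assert yc.kind == "combined"

    def test_nh_one_frequencies(self):
        _, _, yc = bcca_reference_triplet((5, 8.5), 1, FS, 1750)
        assert sorted(set(yc.row_frequencies)) == [5, 8.5, 13.5]

    def test_degenerate_pair_deduplicated_full_rank(self):
        _, _, yc = bcca_reference_triplet((6, 6), 2, FS, 1750)
        assert yc.rows.shape[0] == np.linalg.matrix_rank(yc.rows)

    def test_rejects_aliasing_sum_frequency(self):
        with pytest.raises(ValueError, match="alias"):
            bcca_reference_triplet((130, 140), 1, FS, 1000)


class TestBCCAClassify:
    def test_noiseless_pair_all_three_correlations_high(self, plan):
        trial = make_tone_trial([(6, 1.0), (9.5, 1.0)])
        result = bcca_classify(trial, plan, nh=2)
        assert result.predicted == 4  # the (6, 9.5) target
        feat = result.features[4]
        assert min(feat.rho1, feat.rho2, feat.rhoc) > 0.99
        assert feat.rho_a == pytest.approx((feat.rho1 + feat.rho2 + feat.rhoc) / 3)

    def test_imbalanced_pair_still_recognised(self, plan, rng):
        """Strong 6 Hz with a 4:1-attenuated 9.5 Hz component: the bifold
        score finds the pair even where single-frequency CCA at 9.5 Hz
        picks the wrong target."""
        trial = make_tone_trial([(6, 1.0), (9.5, 0.25)], noise=1.0, rng=rng)
        bcca = bcca_classify(trial, plan, nh=2)
        assert bcca.predicted == 4
        cca = cca_classify(trial, plan.secondary_frequencies, nh=2)
        # secondary-frequency CCA has lost most of its evidence
        assert bcca.scores[4] > cca.scores[4]

    def test_non_plan_frequencies_score_low_but_argmax_holds(self, plan):
        # 3.3 and 21.7 Hz sit well away from every plan fundamental,
        # harmonic (10-19 Hz) and sum frequency (13.5-15.5 Hz)
        trial = make_tone_trial([(3.3, 1.0), (21.7, 1.0)])
        result = bcca_classify(trial, plan, nh=2)
        assert result.predicted == int(np.argmax(result.scores))
        assert np.max(result.scores) < 0.5

    def test_scores_in_unit_interval(self, plan, high_snr_config, rng):
        trial = simulate_trial(high_snr_config, plan.pairs[2], rng)
        result = bcca_classify(trial, plan, nh=2)
        assert np.all(result.scores >= 0) and np.all(result.scores <= 1)


def test_time_origin_invariance(plan):
    """Shifting the reference time axis by a constant leaves rho unchanged:
    the sin/cos pair spans the same subspace."""
    trial = make_tone_trial([(6, 1.0), (9.5, 0.7)])
    m, fs = trial.n_samples, trial.fs
    base = harmonic_references(6, 2, fs, m).rows
    rho0, _, _ = first_canonical_correlation(trial.data, base)
    for shift in (0.123, 1.0, 7.7):
        t = np.arange(1, m + 1) / fs + shift
        rows = []
        for h in (1, 2):
            rows += [np.cos(2 * np.pi * 6 * h * t), np.sin(2 * np.pi * 6 * h * t)]
        rho, _, _ = first_canonical_correlation(trial.data, np.vstack(rows))
        assert abs(rho - rho0) < 1e-9


class TestWelchPSD:
    def test_single_tone_peaks_at_its_frequency(self):
        t = np.arange(1750) / FS
        est = welch_psd(np.sin(2 * np.pi * 7 * t), FS, segment_length=500)
        assert est.frequencies[np.argmax(est.power)] == pytest.approx(7.0)
        assert est.df == pytest.approx(1.0)

    def test_dual_frequency_trial_shows_both_peaks(self, plan, high_snr_config):
        rng = np.random.default_rng(3)
        trial = simulate_trial(high_snr_config, (8.0, 6.5), rng)
        est = welch_psd(trial.data[-1], FS, segment_length=1000)
        sub = est.frequencies < 20
        f, p = est.frequencies[sub], est.power[sub]
        local = np.r_[False, (p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:]), False]
        top2 = f[local][np.argsort(p[local])][-2:]
        assert set(np.round(top2 * 2) / 2) == {8.0, 6.5}

    def test_longer_segments_finer_grid_larger_variance(self):
        """Fewer averaged segments -> noisier per-bin estimates."""
        per_l = {}
        for L in (200, 1000):
            vals = []
            for seed in range(100):
                x = np.random.default_rng(seed).standard_normal(4000)
                est = welch_psd(x, FS, segment_length=L)
                band = (est.frequencies > 50) & (est.frequencies < 200)
                vals.append(est.power[band])
            stacked = np.vstack([v[: min(map(len, vals))] for v in vals])
            per_l[L] = np.mean(np.var(stacked, axis=0))
        est_fine = welch_psd(np.zeros(4000), FS, segment_length=1000)
        est_coarse = welch_psd(np.zeros(4000), FS, segment_length=200)
        assert est_fine.df < est_coarse.df
        assert per_l[1000] > per_l[200]

    def test_rejects_segment_longer_than_signal(self):
        with pytest.raises(ValueError, match="exceeds"):
            welch_psd(np.zeros(100), FS, segment_length=500)


class TestSelectHarmonics:
    def _psd_of(self, freqs_amps, rng):
        t = np.arange(5000) / FS
        x = 0.05 * rng.standard_normal(t.size)
        for f, a in freqs_amps:
            x += a * np.sin(2 * np.pi * f * t)
        return welch_psd(x, FS, segment_length=1000)

    def test_tone_plus_second_harmonic(self, rng):
        psd = self._psd_of([(6, 1.0), (12, 0.4)], rng)
        assert select_harmonics(psd, 6, 3) == 2

    def test_pure_tone_gives_one(self, rng):
        psd = self._psd_of([(6, 1.0)], rng)
        assert select_harmonics(psd, 6, 3) == 1

    def test_clamped_by_max_nh(self, rng):
        psd = self._psd_of([(6, 1.0), (12, 0.5), (18, 0.3)], rng)
        assert select_harmonics(psd, 6, 2) == 2
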