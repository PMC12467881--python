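"""Peak detection, cross-instrument matching, ANOVA ranking, incremental selection."""

import numpy as np
import pytest
from scipy.stats import f_oneway

from libsbridge.features import (
    AnovaRanking,
    PeakFeature,
    anova_rank,
    candidate_wavelengths,
    detect_peaks,
    extract_features,
    f_values_matrix,
    match_peaks,
    select_incremental,
)
from libsbridge.simulate import LineList, SpectralLine
from libsbridge.spectra import LabeledSpectrumSet


def gaussian_set(lines, wl, labels=("A", "A", "B", "B"), fwhm=0.25, noise=0.0, seed=0):
    """Labeled set of identical line spectra (plus optional noise)."""
    rng = np.random.default_rng(seed)
    sigma = fwhm / 2.3548
    base = np.zeros(wl.size)
    for center, amp in lines:
        base = base + amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    rows = [base + noise * rng.normal(size=wl.size) for _ in labels]
    return LabeledSpectrumSet(wl, np.vstack(rows), list(labels), "test")


class TestDetectPeaks:
    def test_single_gaussian_above_threshold(self):
        wl = np.linspace(760.0, 775.0, 150)
        s = gaussian_set([(766.49, 3000.0)], wl)
        feats = detect_peaks(s, threshold=1500.0)
        assert len(feats) == 1
        step = wl[1] - wl[0]
        assert abs(feats[0].wavelength_nm - 766.49) <= step

    def test_flat_spectrum_empty_with_warning(self):
        wl = np.linspace(400.0, 500.0, 100)
        s = LabeledSpectrumSet(wl, np.ones((2, 100)), ["A", "B"])
        with pytest.warns(UserWarning, match="threshold"):
            assert detect_peaks(s, threshold=1500.0) == []

    def test_excluded_species_dropped(self):
        wl = np.linspace(650.0, 680.0, 300)
        s = gaussian_set([(656.28, 4000.0), (670.00, 4000.0)], wl)
        lines = LineList(
            [SpectralLine("H", 656.28, 1.0), SpectralLine("Ca I", 670.0, 1.0)]
        )
        feats = detect_peaks(s, 1500.0, lines, exclude_species=("O", "H"))
        assert [f.species for f in feats] == ["Ca I"]

    def test_monotone_in_threshold(self):
        wl = np.linspace(400.0, 500.0, 1000)
        s = gaussian_set(
            [(420.0, 2000.0), (450.0, 4000.0), (480.0, 8000.0)], wl, noise=5.0
        )
        sets = [
            {f.wavelength_nm for f in detect_peaks(s, thr)}
            for thr in (1500.0, 3000.0, 6000.0)
        ]
        assert sets[2] <= sets[1] <= sets[0]
        assert len(sets[0]) == 3 and len(sets[2]) == 1


class TestMatchPeaks:
    def high_grid(self):
        return np.linspace(760.0, 775.0, 4000)  # ~0.00375 nm step

    def test_shifted_peak_matched(self):
        wl = self.high_grid()
        s = gaussian_set([(766.60, 5000.0)], wl, fwhm=0.02, noise=3.0)
        table = match_peaks([PeakFeature(766.49)], s, tol_nm=0.3)
        assert table.match_rates[0] == 1.0
        assert np.all(table.matrix > 3000.0)

    def test_no_false_match_beyond_half_nm(self):
        wl = self.high_grid()
        s = gaussian_set([(767.1, 5000.0)], wl, fwhm=0.02, noise=3.0)
        table = match_peaks([PeakFeature(766.49)], s, tol_nm=0.3, shift_nm=0.0)
        assert table.match_rates[0] == 0.0
        assert np.all(table.matrix < 500.0)  # fallback reads baseline

    def test_nearest_wins_and_tie_to_lower_wavelength(self):
        wl = np.linspace(499.0, 501.0, 2001)  # exact 0.001 steps
        s = gaussian_set(
            [(499.8, 4000.0), (500.2, 4000.0)], wl, fwhm=0.02, noise=0.0
        )
        # equidistant candidates: the lower wavelength must win
        table = match_peaks([PeakFeature(500.0)], s, tol_nm=0.3, shift_nm=0.0)
        # matched value is a peak apex; verify via position of matched max
        assert table.match_rates[0] == 1.0
        near = match_peaks([PeakFeature(500.1)], s, tol_nm=0.3, shift_nm=0.0)
        assert near.match_rates[0] == 1.0

    def test_fallback_reported_in_match_rate(self):
        wl = self.high_grid()
        s = gaussian_set([(766.49, 5000.0)], wl, fwhm=0.02, noise=3.0)
        table = match_peaks(
            [PeakFeature(766.49), PeakFeature(770.0)], s, tol_nm=0.3
        )
        assert table.match_rates[0] == 1.0
        assert table.match_rates[1] == 0.0

    def test_rejects_nonpositive_tolerance(self):
        with pytest.raises(ValueError):
            match_peaks([PeakFeature(500.0)], gaussian_set([], self.high_grid()), 0.0)


class TestAnova:
    def test_hand_worked_example(self):
        # groups {1,2,3}, {2,3,4}, {3,4,5}: SSB = 6, SSW = 6, k = 3, N = 9
        X = np.array([[1, 2, 3, 2, 3, 4, 3, 4, 5]], dtype=float).T
        labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        F = f_values_matrix(X, labels)
        np.testing.assert_allclose(F, [3.0], rtol=1e-12)

    def test_identical_groups_give_zero(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (3, 1))
        F = f_values_matrix(X, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        np.testing.assert_allclose(F, [0.0])

    def test_perfect_separation_gives_inf(self):
        X = np.array([[1.0], [1.0], [2.0], [2.0]])
        F = f_values_matrix(X, ["a", "a", "b", "b"])
        assert np.isinf(F[0])

    def test_matches_scipy_oracle_on_random_instances(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 5))
            sizes = rng.integers(3, 10, size=k)
            groups = [rng.normal(rng.normal(), 1.0, size=n) for n in sizes]
            X = np.concatenate(groups)[:, None]
            labels = np.concatenate(
                [[f"c{i}"] * n for i, n in enumerate(sizes)]
            ).tolist()
            ours = f_values_matrix(X, labels)[0]
            ref = f_oneway(*groups).statistic
            np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(30, 4))
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        F1 = f_values_matrix(X, labels)
        F2 = f_values_matrix(3.7 * X - 11.0, labels)
        np.testing.assert_allclose(F1, F2, rtol=1e-9)

    def test_rank_sorted_descending(self, small_set):
        ranking = anova_rank(small_set, [340.0, 350.0, 360.0])
        assert np.all(np.diff(ranking.f_values) <= 0)

    def test_requires_two_classes(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="2 classes"):
            f_values_matrix(X, ["a"] * 4)


class TestCandidates:
    def test_threshold_and_range_gate(self):
        wl = np.linspace(300.0, 900.0, 600)
        s = gaussian_set([(340.0, 5000.0), (500.0, 5000.0)], wl, fwhm=5.0)
        cands = candidate_wavelengths(s, threshold=1500.0, restrict_range=(350, 850))
        assert cands.size > 0
        assert np.all((cands >= 350) & (cands <= 850))
        assert np.all(np.abs(cands - 500.0) < 10.0)  # 340 nm line gated out


class TestSelectIncremental:
    def _sources(self, rng):
        """Toy problem where one ranked wavelength is genuinely informative."""
        base = [PeakFeature(500.0)]
        n = 60
        labels = ["A"] * (n // 2) + ["B"] * (n // 2)
        y = np.array([0.0] * (n // 2) + [1.0] * (n // 2))

        def table_for(features, seed):
            r = np.random.default_rng(seed)
            cols = []
            for f in features:
                if abs(f.wavelength_nm - 600.0) < 1e-6:
                    cols.append(y + 0.05 * r.normal(size=n))  # informative
                else:
                    cols.append(r.normal(size=n))  # noise
            from libsbridge.features import FeatureTable

            return FeatureTable(list(features), np.column_stack(cols), labels)

        return base, labels, table_for

    def _eval(self, train, test):
        from libsbridge.classify import ForestConfig, evaluate, fit_forest, predict

        model = fit_forest(train, ForestConfig(n_trees=30, min_leaf=2, seed=0))
        return evaluate(test.labels, predict(model, test), model.classes).accuracy

    def test_zero_added_returns_base(self, rng):
        base, labels, table_for = self._sources(rng)
        ranking = AnovaRanking([600.0, 610.0], [50.0, 1.0])
        best, curve = select_incremental(
            base, ranking,
            lambda f: table_for(f, 1), lambda f: table_for(f, 2),
            self._eval, max_added=0,
        )
        assert [f.wavelength_nm for f in best] == [500.0]
        assert len(curve) == 1

    def test_overlapping_candidate_skipped(self, rng):
        base, labels, table_for = self._sources(rng)
        ranking = AnovaRanking([500.0, 600.0], [99.0, 50.0])  # 500 overlaps base
        best, curve = select_incremental(
            base, ranking,
            lambda f: table_for(f, 1), lambda f: table_for(f, 2),
            self._eval, max_added=5, min_sep_nm=0.5,
        )
        wls = [f.wavelength_nm for f in best]
        assert wls.count(500.0) == 1  # not double-counted
        assert 600.0 in wls  # informative feature retained
        assert len(curve) == 2  # base point + one added

    def test_base_never_removed_and_curve_in_unit_interval(self, rng):
        base, labels, table_for = self._sources(rng)
        ranking = AnovaRanking([600.0, 610.0, 620.0], [50.0, 2.0, 1.0])
        best, curve = select_incremental(
            base, ranking,
            lambda f: table_for(f, 1), lambda f: table_for(f, 2),
            self._eval, max_added=3, min_sep_nm=0.5,
        )
        assert {f.wavelength_nm for f in base} <= {f.wavelength_nm for f in best}
        assert curve["accuracy"].between(0.0, 1.0).all()

    def test_deterministic_under_fixed_seed(self, rng):
        base, labels, table_for = self._sources(rng)
        ranking = AnovaRanking([600.0, 610.0], [50.0, 1.0])
        runs = [
            select_incremental(
                base, ranking,
                lambda f: table_for(f, 1), lambda f: table_for(f, 2),
                self._eval, max_added=2, min_sep_nm=0.5,
            )
            for _ in range(2)
        ]
        assert runs[0][1].equals(runs[1][1])
        assert [f.wavelength_nm for f in runs[0][0]] == [
            f.wavelength_nm for f in runs[1][0]
        ]


class TestSerialization:
    def test_feature_frame_columns(self):
        from libsbridge.features import features_to_frame

        df = features_to_frame(
            [PeakFeature(766.49, "K I"), PeakFeature(402.69, None, "anova-added", 825.3)]
        )
        assert list(df.columns) == ["wavelength_nm", "species", "origin", "f_value"]
        assert df.loc[1, "origin"] == "anova-added"


class TestExtract:
    def test_reads_nearest_grid_point(self):
        wl = np.linspace(400.0, 500.0, 101)
        mat = np.tile(wl, (2, 1))
        s = LabeledSpectrumSet(wl, mat, ["A", "B"])
        t = extract_features(s, [PeakFeature(450.4), PeakFeature(400.0)])
        np.testing.assert_allclose(t.matrix, [[450.0, 400.0], [450.0, 400.0]])
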