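"""Label-free quantification: alignment, matching, EPV weighting, ridges."""

import numpy as np
import pytest

import csbn
from csbn.quantify import (
    PeptideMatrix,
    QuantifyConfig,
    align_elution_times,
    build_peptide_matrix,
    build_reference_ridge,
    compute_epv,
    detectability_threshold,
    estimate_abundance,
    match_features,
    normalize_runs,
    quantify_evidence,
    reliability_score,
)
from csbn.synthetic import render_peptide_observations

from conftest import gaussian_mixture_profiles, sliding_average


def _ev(pep, run, time, intensity=1.0, prot="P", mz=500.0):
    return csbn.PeptideEvidence(pep, prot, run, mz, time, intensity, True)


class TestElutionAlignment:
    def _runs(self, n=100, n_runs=6, bad_run=6, offset=0.0, slope=1.0, seed=0):
        """n_runs runs sharing n peptides; one run carries a known distortion."""
        rng = np.random.default_rng(seed)
        times = rng.uniform(10, 120, n)
        ev = []
        for i, t in enumerate(times):
            for run in range(1, n_runs + 1):
                obs = offset + slope * t if run == bad_run else t
                ev.append(_ev(f"p{i}", run, obs))
        return ev, times

    def test_identical_runs_zero_correction(self):
        ev, _ = self._runs()
        out = align_elution_times(ev)
        for a, b in zip(ev, out):
            assert b.elution_time == pytest.approx(a.elution_time, abs=1e-9)

    def test_constant_offset_removed(self):
        ev, times = self._runs(offset=0.5)
        out = align_elution_times(ev)
        res = [
            abs(o.elution_time - times[int(o.peptide_id[1:])])
            for o in out
            if o.run_index == 6
        ]
        assert float(np.median(res)) < 0.05

    def test_linear_drift_removed(self):
        ev, times = self._runs(slope=1.02)
        out = align_elution_times(ev)
        res = [
            abs(o.elution_time - times[int(o.peptide_id[1:])])
            for o in out
            if o.run_index == 6
        ]
        assert float(np.median(res)) < 0.1

    def test_too_few_shared_peptides_left_uncorrected(self, caplog):
        ev, _ = self._runs(n=10, offset=0.7)
        with caplog.at_level("WARNING"):
            out = align_elution_times(ev, min_shared=20)
        assert any("uncorrected" in m for m in caplog.messages)
        for a, b in zip(ev, out):
            assert b.elution_time == a.elution_time


class TestFeatureMatching:
    def test_within_tolerance_matched(self):
        # 1.6 ppm and 0.5 min off: inside the +/-2 ppm, +/-1 min gates
        idx = match_features([500.0008], [10.5], [500.0000], [10.0])
        assert idx[0] == 0

    def test_three_ppm_unmatched_at_default(self):
        idx = match_features([500.0015], [10.0], [500.0000], [10.0])
        assert idx[0] == -1

    def test_nearest_ppm_wins(self):
        # candidates at 1.0 and 1.5 ppm, both within the time gate
        idx = match_features(
            [500.0], [10.0], [500.0 * (1 - 1.0e-6), 500.0 * (1 + 1.5e-6)], [10.9, 10.1]
        )
        assert idx[0] == 0

    def test_ppm_tie_broken_by_time(self):
        idx = match_features(
            [500.0], [10.0], [500.0 * (1 - 1.2e-6), 500.0 * (1 + 1.2e-6)], [10.9, 10.1]
        )
        assert idx[0] == 1

    def test_exhaustive_oracle(self, rng):
        """Vectorized matcher agrees with a brute-force nearest-match search."""
        f_mz = rng.uniform(400, 1200, 150)
        f_t = rng.uniform(10, 120, 150)
        i_mz = rng.uniform(400, 1200, 150) * (1 + rng.normal(0, 2e-6, 150))
        i_t = rng.uniform(10, 120, 150)
        got = match_features(f_mz, f_t, i_mz, i_t, tol_ppm=2.0, tol_min=1.0)
        for k in range(f_mz.size):
            best, key = -1, (np.inf, np.inf)
            for j in range(i_mz.size):
                ppm = abs(f_mz[k] - i_mz[j]) / i_mz[j] * 1e6
                dt = abs(f_t[k] - i_t[j])
                if ppm <= 2.0 and dt <= 1.0 and (ppm, dt) < key:
                    best, key = j, (ppm, dt)
            assert got[k] == best


class TestRunNormalization:
    def _matrix(self, rng, n_pep=30, n_run=50):
        ridge = 10.0 ** rng.uniform(3, 6, n_pep)
        data = np.tile(ridge[:, None], (1, n_run)).astype(float)
        import pandas as pd
        return pd.DataFrame(data, columns=range(1, n_run + 1))

    def test_identical_runs_unit_factors(self, rng):
        factors = normalize_runs(self._matrix(rng))
        assert np.allclose(factors.to_numpy(), 1.0)

    def test_doubled_run_recovered(self, rng):
        df = self._matrix(rng)
        df[25] = df[25] * 2.0
        factors = normalize_runs(df)
        assert factors[25] == pytest.approx(2.0, rel=0.01)
        assert factors[10] == pytest.approx(1.0, rel=0.01)

    def test_window_truncated_at_gel_start(self, rng):
        # doubling runs 22.. leaves run 1's window (slices 1..21) untouched
        df = self._matrix(rng)
        for c in range(22, 51):
            df[c] = df[c] * 2.0
        factors = normalize_runs(df)
        assert factors[1] == pytest.approx(1.0, rel=0.01)

    def test_sparse_window_warns_and_keeps_unit(self, rng, caplog):
        import pandas as pd
        df = pd.DataFrame(np.full((3, 5), 100.0), columns=range(1, 6))
        with caplog.at_level("WARNING"):
            factors = normalize_runs(df, min_peptides=5)
        assert np.allclose(factors.to_numpy(), 1.0)
        assert any("factor 1.0" in m for m in caplog.messages)


def rank1_matrix(ridge, abundance):
    intensity = np.outer(ridge, abundance)
    return PeptideMatrix(
        "P", [f"p{i}" for i in range(len(ridge))],
        list(range(1, len(abundance) + 1)), intensity.astype(float),
    )


class TestEPV:
    def test_rank1_matrix_is_self_consistent(self):
        m = rank1_matrix([1.0, 0.5, 0.2, 0.05], [1, 2, 5, 20, 60, 100, 40, 4])
        compute_epv(m)
        np.testing.assert_allclose(m.epv, m.intensity, rtol=1e-9)
        np.testing.assert_allclose(m.weight, 1.0, atol=1e-9)

    def test_outlier_cell_detected(self):
        m = rank1_matrix([1.0, 0.4, 0.1], [10.0, 20.0, 40.0])
        expected = m.intensity[1, 1]
        m.intensity[1, 1] *= 10.0
        compute_epv(m)
        # the EPV stays near the consistent rank-1 value ...
        assert m.epv[1, 1] == pytest.approx(expected, rel=0.2)
        # ... so the corrupted cell carries the largest deviation / lowest weight
        assert np.argmin(m.weight) == np.ravel_multi_index((1, 1), m.weight.shape)

    def test_neighbour_interpolation_fallback(self):
        # row-only predictions disabled beyond slice 4 leave the last cell of
        # peptide A unpredictable; its EPV comes from the neighbouring slices
        intensity = np.array(
            [[10.0, 20.0, 40.0, 80.0, 160.0], [5.0, 10.0, 20.0, 40.0, np.nan]]
        )
        m = PeptideMatrix("P", ["a", "b"], [1, 2, 3, 4, 5], intensity.copy())
        cfg = QuantifyConfig(epv_col_window=0, epv_min_predictions=1)
        compute_epv(m, cfg)
        # cell (0, 4): no row partner observed at slice 5 -> interpolated from
        # the validated EPVs of slices 3..4 (log-linear extension)
        assert np.isfinite(m.epv[0, 4])
        assert m.weight[0, 4] > 0

    def test_single_peptide_epv_undefined(self):
        m = PeptideMatrix("P", ["a"], [1, 2, 3], np.array([[1.0, 2.0, 3.0]]))
        compute_epv(m)
        assert m.epv_undefined
        np.testing.assert_allclose(m.weight[np.isfinite(m.intensity)], 1.0)


class TestDetectabilityThreshold:
    def test_linear_interpolation_percentile(self):
        times = np.full(100, 50.0)
        intensities = np.arange(1.0, 101.0)
        thr, defined = detectability_threshold(times, intensities, 50.0)
        assert defined and thr == pytest.approx(3.97)

    def test_constant_intensities(self):
        thr, defined = detectability_threshold(
            np.full(20, 50.0), np.full(20, 7.5), 50.0
        )
        assert defined and thr == 7.5

    def test_below_minimum_peptides_undefined(self):
        thr, defined = detectability_threshold(
            np.full(5, 50.0), np.arange(5.0) + 1, 50.0
        )
        assert not defined and np.isnan(thr)

    def test_window_selects_coeluters_only(self):
        times = np.concatenate([np.full(50, 50.0), np.full(50, 80.0)])
        intensities = np.concatenate([np.arange(1.0, 51.0), np.full(50, 1e9)])
        thr, defined = detectability_threshold(times, intensities, 50.0)
        assert defined and thr < 51.0


class TestReferenceRidge:
    def test_single_run_proportional(self):
        m = rank1_matrix([1.0, 0.5, 0.25], [42.0])
        compute_epv(m)
        ridge = build_reference_ridge(m)
        np.testing.assert_allclose(ridge.ridge, [1.0, 0.5, 0.25])

    def test_anchor_invariance_for_proportional_runs(self):
        m1 = rank1_matrix([1.0, 0.5, 0.25], [10.0, 30.0])
        m2 = rank1_matrix([1.0, 0.5, 0.25], [30.0, 10.0])  # anchor swaps
        r1 = build_reference_ridge(compute_epv(m1))
        r2 = build_reference_ridge(compute_epv(m2))
        np.testing.assert_allclose(r1.ridge, r2.ridge, rtol=1e-9)

    def test_noisy_rank1_recovery_within_5_percent(self):
        rng = np.random.default_rng(4)
        eff = np.array([1.0, 0.6, 0.3, 0.15, 0.05])
        abundance = np.array([20.0, 50.0, 100.0, 80.0, 40.0, 10.0])
        m = rank1_matrix(eff, abundance)
        m.intensity *= np.exp(rng.normal(0, 0.05, m.intensity.shape))
        ridge = build_reference_ridge(compute_epv(m))
        np.testing.assert_allclose(ridge.ridge, eff / eff.max(), rtol=0.05)

    def test_no_consistent_evidence_raises(self):
        m = PeptideMatrix("P", ["a"], [1], np.array([[np.nan]]))
        m.weight = np.array([[np.nan]])
        m.epv = np.array([[np.nan]])
        with pytest.raises(ValueError, match="no consistent evidence"):
            build_reference_ridge(m)


class TestAbundanceEstimation:
    def test_exact_scale_recovered(self):
        m = rank1_matrix([1.0, 0.5, 0.2], np.full(7, 3.5))
        compute_epv(m)
        ridge = build_reference_ridge(m)
        est = estimate_abundance(m, ridge, 4)
        assert est.abundance == pytest.approx(3.5, rel=1e-12)
        assert est.n_peptides_used == 3

    def test_missing_cells_ignored(self):
        m = rank1_matrix([1.0, 0.5, 0.2], np.full(5, 7.0))
        m.intensity[:, 1] = np.nan
        m.intensity[:, 3] = np.nan
        compute_epv(m)
        ridge = build_reference_ridge(m)
        est = estimate_abundance(m, ridge, 3)
        assert est.abundance == pytest.approx(7.0, rel=1e-9)

    def test_all_below_threshold_zero_with_zero_reliability(self):
        m = rank1_matrix([1.0, 0.5], np.full(5, 2.0))
        compute_epv(m)
        ridge = build_reference_ridge(m)
        m.detect_threshold = np.full_like(m.intensity, 1e9)
        est = estimate_abundance(m, ridge, 3)
        assert est.abundance == 0.0 and est.reliability == 0.0

    def test_weighted_lsq_oracle_equivalence(self, rng):
        """On a complete matrix the estimate equals the direct weighted solve."""
        eff = 10.0 ** rng.uniform(-1.5, 0, 6)
        abundance = 10.0 ** rng.uniform(1, 3, 9)
        m = rank1_matrix(eff, abundance)
        m.intensity *= np.exp(rng.normal(0, 0.2, m.intensity.shape))
        compute_epv(m)
        ridge = build_reference_ridge(m)
        for s in range(1, 10):
            est = estimate_abundance(m, ridge, s)
            cols = [j for j in range(9) if abs(j - (s - 1)) <= 2]
            r_map = dict(zip(ridge.peptide_ids, ridge.ridge))
            x = np.array([r_map[p] for p in m.peptide_ids for _ in cols])
            y = np.array([m.intensity[i, j] for i in range(6) for j in cols])
            w = np.array([m.weight[i, j] for i in range(6) for j in cols])
            direct = float(
                np.linalg.lstsq(
                    (np.sqrt(w) * x)[:, None], np.sqrt(w) * y, rcond=None
                )[0][0]
            )
            assert est.abundance == pytest.approx(direct, rel=1e-8)


class TestReliabilityScore:
    def test_range_endpoints(self):
        assert reliability_score(0, 0.0) == 0.0
        assert reliability_score(1000, 0.0) == pytest.approx(1.0, abs=1e-6)

    def test_monotonicity(self):
        assert reliability_score(6, 0.5) > reliability_score(2, 0.5)
        assert reliability_score(4, 0.1) > reliability_score(4, 2.0)

    def test_bounded(self, rng):
        for _ in range(50):
            s = reliability_score(int(rng.integers(0, 50)), float(rng.uniform(0, 10)))
            assert 0.0 <= s <= 1.0


class TestPipelineProperties:
    def test_scale_equivariance(self):
        truth = gaussian_mixture_profiles(11, 4, n_slices=32)
        ev = render_peptide_observations(truth, 4, seed=12, noise_sigma=0.1)
        scaled = [
            csbn.PeptideEvidence(
                e.peptide_id, e.protein_id, e.run_index, e.mz, e.elution_time,
                e.intensity * (3.0 if e.protein_id == "P001" else 1.0), e.is_specific,
            )
            for e in ev
        ]
        base, _ = quantify_evidence(ev, n_slices=32)
        out, _ = quantify_evidence(scaled, n_slices=32)
        np.testing.assert_allclose(
            out.profile("P001"), 3.0 * base.profile("P001"), rtol=1e-9
        )
        np.testing.assert_allclose(
            out.reliability[out._index["P001"]],
            base.reliability[base._index["P001"]],
            atol=1e-9,
        )

    def test_run_permutation_invariance(self, rng):
        truth = gaussian_mixture_profiles(13, 3, n_slices=32)
        ev = render_peptide_observations(truth, 4, seed=14, noise_sigma=0.1)
        shuffled = list(ev)
        rng.shuffle(shuffled)
        a, _ = quantify_evidence(ev, n_slices=32)
        b, _ = quantify_evidence(shuffled, n_slices=32)
        assert a.protein_ids == b.protein_ids
        np.testing.assert_allclose(a.abundance, b.abundance, rtol=1e-12)

    def test_missingness_robustness(self):
        """An inconsistent (down-weighted) peptide row moves the estimate less
        than removing the highest-weight row does."""
        eff = np.array([1.0, 0.8, 0.6, 0.4, 0.2])
        m = rank1_matrix(eff, np.full(9, 50.0))
        # corrupt one row with alternating 2x / 0.5x swings (low consistency)
        m.intensity[2, ::2] *= 2.0
        m.intensity[2, 1::2] *= 0.5
        compute_epv(m)
        ridge = build_reference_ridge(m)
        full = estimate_abundance(m, ridge, 5).abundance
        weights = np.nansum(m.weight, axis=1)

        def without(row):
            keep = [i for i in range(5) if i != row]
            sub = PeptideMatrix(
                "P", [m.peptide_ids[i] for i in keep], m.runs, m.intensity[keep].copy()
            )
            compute_epv(sub)
            r = build_reference_ridge(sub)
            # rescale: ridge normalization changes when the max row is dropped
            r_map = dict(zip(r.ridge, r.ridge))
            est = estimate_abundance(sub, r, 5)
            scale = max(eff[keep]) / eff.max()
            return est.abundance * scale

        corrupted_change = abs(without(2) - full)
        top_change = abs(without(int(np.argmax(weights))) - full)
        assert corrupted_change <= top_change + 1e-9

    def test_end_to_end_recovery(self):
        """Rank-1 evidence with lognormal noise: the quantified profile tracks
        the window-integrated truth at r > 0.98 for every protein."""
        truth = gaussian_mixture_profiles(0, 50, n_slices=64)
        ev = render_peptide_observations(truth, 6, seed=200, noise_sigma=0.2)
        est, details = quantify_evidence(ev, n_slices=64)
        assert est.n_proteins == 50
        for pid in est.protein_ids:
            target = sliding_average(truth.profile(pid))
            r = np.corrcoef(target, est.profile(pid))[0, 1]
            assert r > 0.98, pid
        assert set(details.columns) == {
            "protein_id", "slice", "n_peptides", "deviation", "reliability"
        }
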