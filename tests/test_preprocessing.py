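"""Preprocessing chain: each stage's contract plus end-to-end recovery."""

import numpy as np
import pytest

from breathdisc.io import ChromatogramRun, ConfigurationError, StageError, ValidationError
from breathdisc import preprocessing as prep
from conftest import single_peak_run


def _run_from(intensities, stage, sample_id="t"):
    n, k = np.atleast_2d(intensities).shape
    return ChromatogramRun(sample_id, np.arange(n) + 1.0, np.arange(40, 40 + k),
                          np.atleast_2d(intensities), stage=stage)


class TestLogTransform:
    def test_closed_form_values(self):
        m = np.array([[0.0, np.e - 1.0]])
        out = prep.log_transform(_run_from(np.vstack([m, m]), "raw"))
        np.testing.assert_allclose(out.intensities[0], [0.0, 1.0], atol=1e-12)
        assert out.stage == "logged"

    def test_stage_order_enforced(self):
        run = _run_from(np.zeros((10, 2)), "logged")
        with pytest.raises(StageError):
            prep.log_transform(run)

    def test_stabilizes_multiplicative_noise(self):
        # SD of ln(1+x) varies far less across a 100x intensity range than x
        rng = np.random.default_rng(0)
        levels = np.array([1e2, 1e3, 1e4])
        raw_sd, log_sd = [], []
        for mu in levels:
            x = mu * (1 + 0.1 * rng.standard_normal(4000)).clip(0)
            raw_sd.append(x.std())
            log_sd.append(np.log1p(x).std())
        assert max(raw_sd) / min(raw_sd) > 30
        assert max(log_sd) / min(log_sd) < 3


class TestWaveletDenoise:
    def test_zero_trace_maps_to_zero(self):
        out = prep.wavelet_denoise(_run_from(np.zeros((256, 3)), "logged"))
        assert np.all(out.intensities == 0)

    def test_constant_trace_preserved(self):
        out = prep.wavelet_denoise(_run_from(np.full((256, 2), 7.0), "logged"))
        np.testing.assert_allclose(out.intensities, 7.0, rtol=1e-10)

    def test_denoising_beats_doing_nothing_on_noisy_gaussian(self):
        scans = np.arange(512, dtype=float)
        clean = 5.0 * np.exp(-0.5 * ((scans - 256) / 8.0) ** 2)
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.standard_normal(512)  # SNR ~ 5
            run = _run_from(noisy[:, None], "logged")
            den = prep.wavelet_denoise(run).intensities[:, 0]
            if np.sqrt(np.mean((den - clean) ** 2)) < np.sqrt(np.mean((noisy - clean) ** 2)):
                wins += 1
        assert wins >= 95

    def test_short_trace_rejected(self):
        with pytest.raises(ValidationError, match="filter support"):
            prep.wavelet_denoise(_run_from(np.zeros((4, 1)), "logged"))


class TestBaseline:
    def test_linear_ramp_removed(self):
        ramp = np.linspace(1.0, 6.0, 600)[:, None]
        out, z = prep.baseline_correct(_run_from(ramp, "denoised"))
        assert np.abs(out.intensities).max() < 1e-3 * 5.0

    def test_peak_on_offset_recovered(self):
        scans = np.arange(800, dtype=float)
        h, c = 4.0, 2.0
        trace = c + h * np.exp(-0.5 * ((scans - 400) / 5.0) ** 2)
        out, _ = prep.baseline_correct(_run_from(trace[:, None], "denoised"))
        apex_raw = np.expm1(out.intensities[400, 0])
        want = np.expm1(c + h) - np.expm1(c)  # additive offset on the raw scale
        assert apex_raw == pytest.approx(want, rel=0.05)

    def test_output_non_negative(self):
        rng = np.random.default_rng(1)
        trace = np.abs(rng.standard_normal((500, 3)))
        out, _ = prep.baseline_correct(_run_from(trace, "denoised"))
        assert np.all(out.intensities >= 0)

    @pytest.mark.parametrize("kw", [{"lam": -1.0}, {"p": 0.0}, {"p": 1.5}])
    def test_bad_hyperparameters_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            prep.baseline_correct(_run_from(np.zeros((100, 1)), "denoised"), **kw)


def _peaky_cohort(n_runs=6, n=800, seed=0, translate=None):
    """Cohort of multi-peak runs with per-run amplitudes; optional translation."""
    rng = np.random.default_rng(seed)
    scans = np.arange(n, dtype=float)
    apexes = np.arange(80, n - 80, 90)
    runs = []
    for i in range(n_runs):
        tr = np.zeros(n)
        for a in apexes:
            amp = rng.uniform(3.0, 8.0)
            tr += amp * np.exp(-0.5 * ((scans - a) / 4.0) ** 2)
        if translate is not None and i == 0:
            tr = np.roll(tr, translate)
            tr[:max(translate, 0)] = 0.0
        runs.append(_run_from(np.column_stack([tr, 0.5 * tr]), "baseline_corrected",
                              sample_id=f"r{i}"))
    return runs, apexes


class TestAlign:
    def test_identical_runs_unchanged(self):
        run = single_peak_run(stage="baseline_corrected")
        cohort = [ChromatogramRun(f"r{i}", run.scan_times, run.mz_axis,
                                  run.intensities.copy(), "baseline_corrected")
                  for i in range(4)]
        out = prep.align_runs(cohort)
        for o, r in zip(out, cohort):
            assert np.all(o.segment_shifts == 0)
            np.testing.assert_allclose(o.intensities, r.intensities, rtol=1e-12)

    def test_planted_translation_recovered(self):
        runs, apexes = _peaky_cohort(translate=5, seed=3)
        out = prep.align_runs(runs)
        tic = out[0].tic()
        for a in apexes:
            err = int(np.argmax(tic[a - 10 : a + 11])) - 10
            assert abs(err) <= 1

    def test_shift_beyond_cap_is_capped_with_warning(self, caplog):
        runs, _ = _peaky_cohort(translate=40, seed=4)
        with caplog.at_level("WARNING", logger="breathdisc"):
            out = prep.align_runs(runs, max_shift=25)
        assert np.abs(out[0].segment_shifts).max() <= 25
        assert any("cap" in r.message for r in caplog.records)

    def test_total_ion_count_approximately_conserved(self):
        runs, _ = _peaky_cohort(translate=5, seed=5)
        out = prep.align_runs(runs)
        before = runs[0].intensities.sum()
        after = out[0].intensities.sum()
        assert abs(after - before) / before < 0.005

    def test_segment_shorter_than_twice_cap_rejected(self):
        runs, _ = _peaky_cohort()
        with pytest.raises(ConfigurationError):
            prep.align_runs(runs, segment_len=30, max_shift=25)


class TestPqn:
    def _cohort(self):
        base = single_peak_run(stage="raw").intensities
        runs = []
        for i, scale in enumerate([1.0, 1.0, 1.0, 3.0]):
            runs.append(_run_from(np.log1p(scale * base), "aligned", sample_id=f"r{i}"))
        return runs

    def test_exact_dilution_recovered_and_removed(self):
        runs = self._cohort()
        out, q = prep.pqn_normalize(runs)
        assert q[3] == pytest.approx(3.0, rel=1e-9)
        np.testing.assert_allclose(out[3].intensities, runs[0].intensities, rtol=1e-9)

    def test_identity_run_unchanged(self):
        runs = self._cohort()
        out, q = prep.pqn_normalize(runs)
        assert q[0] == pytest.approx(1.0, rel=1e-9)
        np.testing.assert_allclose(out[0].intensities, runs[0].intensities, rtol=1e-9)

    def test_idempotent(self):
        runs = self._cohort()
        out, _ = prep.pqn_normalize(runs)
        again = [r.with_intensities(r.intensities, "aligned") for r in out]
        out2, q2 = prep.pqn_normalize(again)
        np.testing.assert_allclose(q2, 1.0, atol=1e-6)
        for a, b in zip(out, out2):
            np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-6)

    def test_all_zero_reference_rejected(self):
        runs = [_run_from(np.zeros((100, 2)), "aligned", sample_id=f"r{i}")
                for i in range(3)]
        with pytest.raises(ValidationError):
            prep.pqn_normalize(runs)


class TestPeakPicking:
    def test_flat_cohort_has_no_peaks(self):
        runs = [_run_from(np.zeros((300, 2)), "normalized", sample_id=f"r{i}")
                for i in range(3)]
        feats, areas = prep.pick_peaks(runs)
        assert feats == []
        assert areas.shape == (3, 0)

    def test_single_gaussian_area_matches_closed_form(self):
        h, sigma = 100.0, 2.0
        scans = np.arange(400, dtype=float)
        tr = h * np.exp(-0.5 * ((scans - 200) / sigma) ** 2)
        runs = [_run_from(np.log1p(tr[:, None]), "normalized", sample_id=f"r{i}")
                for i in range(2)]
        feats, areas = prep.pick_peaks(runs)
        assert len(feats) == 1
        assert abs(feats[0].apex_scan - 200) <= 1
        assert areas[0, 0] == pytest.approx(h * sigma * np.sqrt(2 * np.pi), rel=0.05)

    def test_resolved_pair_yields_two_peaks(self):
        scans = np.arange(400, dtype=float)
        tr = (50 * np.exp(-0.5 * ((scans - 150) / 3.0) ** 2)
              + 80 * np.exp(-0.5 * ((scans - 250) / 3.0) ** 2))
        runs = [_run_from(np.log1p(tr[:, None]), "normalized", sample_id="r0")]
        feats, _ = prep.pick_peaks(runs)
        assert len(feats) == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            prep.pick_peaks([])


class TestMergePeaks:
    def _feat(self, pid, apex, spec):
        return prep.PeakFeature(pid, apex, apex - 5, apex + 5,
                                np.asarray(spec) / np.sum(spec), [pid])

    def test_identical_spectra_close_apexes_merge_with_summed_area(self):
        s = [0.5, 0.3, 0.2, 0.0]
        feats = [self._feat("a", 100, s), self._feat("b", 105, s)]
        areas = np.array([[2.0, 3.0], [4.0, 1.0]])
        merged, marea = prep.merge_peaks(feats, areas)
        assert len(merged) == 1
        np.testing.assert_allclose(marea[:, 0], [5.0, 5.0])
        assert merged[0].member_peaks == ["a", "b"]

    def test_uncorrelated_spectra_not_merged(self):
        feats = [self._feat("a", 100, [0.9, 0.1, 0.0, 0.0]),
                 self._feat("b", 105, [0.0, 0.05, 0.15, 0.8])]
        merged, _ = prep.merge_peaks(feats, np.ones((1, 2)))
        assert len(merged) == 2

    def test_distant_apexes_not_merged_despite_identical_spectra(self):
        s = [0.5, 0.5, 0.0, 0.0]
        feats = [self._feat("a", 100, s), self._feat("b", 200, s)]
        merged, _ = prep.merge_peaks(feats, np.ones((1, 2)), rt_window=15)
        assert len(merged) == 2


class TestBuildFeatureMatrix:
    def test_noiseless_cohort_recovers_planted_compound_count(self, tiny_cohort):
        cfg, runs, clinical, truth = tiny_cohort
        fm = prep.build_feature_matrix(runs, clinical)
        assert fm.n_peaks == cfg.n_compounds
        assert fm.n_samples == len(runs)
        assert set(fm.groups) == {"control", "IPF-like", "CTD-like"}

    def test_deterministic(self, tiny_cohort):
        cfg, runs, clinical, _ = tiny_cohort
        fm1 = prep.build_feature_matrix(runs, clinical)
        fm2 = prep.build_feature_matrix(runs, clinical)
        np.testing.assert_array_equal(fm1.areas, fm2.areas)

    def test_missing_clinical_id_named_in_error(self, tiny_cohort):
        cfg, runs, clinical, _ = tiny_cohort
        broken = clinical[clinical["sample_id"] != "S003"]
        with pytest.raises(ValidationError, match="S003"):
            prep.build_feature_matrix(runs, broken)
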