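"""Chromatogram conditioning: from raw scan x m/z matrices to a peak table.

The chain runs in a fixed order, each stage consuming the previous stage's
output (enforced via the run's ``stage`` tag):

1.  ``log_transform`` — ln(1+x), converting the instrument's multiplicative
    (heteroscedastic) intensity noise into approximately additive noise.
2.  ``wavelet_denoise`` — per-channel Daubechies decomposition (two detail
    levels by default), soft-thresholding the detail coefficients with the
    universal threshold sigma*sqrt(2 ln n).
3.  ``baseline_correct`` — asymmetric least squares: a second-difference
    penalized smoother whose weights are asymmetric (points above the fit
    get weight p << 1), so it hugs the baseline under the peaks.
4.  ``align_runs`` — piecewise-constant-shift retention-time alignment of
    each run's TIC against the cohort median TIC, shifts interpolated
    between segment centers.
5.  ``pqn_normalize`` — probabilistic quotient normalization: divide each
    run by the median ratio of its TIC to the cohort reference, removing
    per-sample dilution.
6.  ``pick_peaks`` / ``merge_peaks`` — prominence-based peak picking on the
    cohort-mean TIC (one shared peak set, so the output matrix is
    rectangular), trapezoidal areas per sample, then merging of peaks whose
    consensus mass spectra correlate strongly within a retention window
    (split peaks of one compound).

Each stage is also available as a sklearn-style transformer
(``fit``/``transform`` over a list of runs) so chains can be composed and
parameterized the sklearn way; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.linalg import solveh_banded
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin

from .io import (
    ChromatogramRun,
    ConfigurationError,
    FeatureMatrix,
    ValidationError,
    require_stage,
)

logger = logging.getLogger("breathdisc")


@dataclass
class PeakFeature:
    """One picked (possibly merged) chromatographic peak."""

    peak_id: str
    apex_scan: int
    left_bound: int   # half-open [left, right)
    right_bound: int
    consensus_spectrum: np.ndarray  # unit-sum over the m/z axis
    member_peaks: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.left_bound <= self.apex_scan < self.right_bound):
            raise ValidationError(
                f"peak {self.peak_id}: apex {self.apex_scan} outside "
                f"[{self.left_bound}, {self.right_bound})"
            )
        s = float(self.consensus_spectrum.sum())
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(f"peak {self.peak_id}: spectrum sums to {s}, not 1")


# ---------------------------------------------------------------------------
# stage 1: log transform


def log_transform(run: ChromatogramRun) -> ChromatogramRun:
    """ln(1+x); heteroscedastic multiplicative noise becomes ~homoscedastic."""
    require_stage(run, "raw")
    if (run.intensities < 0).any():
        raise ValidationError(f"run {run.sample_id}: negative intensities")
    return run.with_intensities(np.log1p(run.intensities), "logged")


# ---------------------------------------------------------------------------
# stage 2: wavelet denoising


def wavelet_denoise(run: ChromatogramRun, wavelet: str = "db4", levels: int = 2) -> ChromatogramRun:
    """Per-channel Daubechies denoising with universal soft threshold.

    sigma is estimated per channel from the median absolute deviation of the
    finest detail coefficients (MAD / 0.6745).
    """
    require_stage(run, "logged")
    if levels < 1:
        raise ConfigurationError("levels: must be >= 1")
    w = pywt.Wavelet(wavelet)
    n = run.n_scans
    if n < w.dec_len:
        raise ValidationError(
            f"trace length {n} shorter than {wavelet} filter support {w.dec_len}"
        )
    coeffs = pywt.wavedec(run.intensities, w, level=levels, axis=0)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest, axis=0)), axis=0) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(n))
    # soft threshold with a per-channel value (pywt.threshold wants a scalar)
    out = [coeffs[0]] + [
        np.sign(c) * np.maximum(np.abs(c) - thresh, 0.0) for c in coeffs[1:]
    ]
    rec = pywt.waverec(out, w, axis=0)[:n]
    return run.with_intensities(np.clip(rec, 0.0, None), "denoised")


# ---------------------------------------------------------------------------
# stage 3: asymmetric least squares baseline


def _als_banded(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    """Asymmetric least squares baseline for one or more columns of y.

    Minimizes sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2 with w_i = p where
    y_i > z_i else 1-p; solved with a symmetric pentadiagonal (banded) solver.
    """
    y = np.atleast_2d(y.T).T  # (n, k)
    n, k = y.shape
    # explicit pentadiagonal stencil of D2'D2, D2 the (n-2) x n second difference
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.full(n - 2, 1.0)
    z = np.zeros_like(y)
    for j in range(k):
        w = np.ones(n)
        yj = y[:, j]
        for _ in range(n_iter):
            ab = np.zeros((3, n))
            ab[0, 2:] = lam * off2
            ab[1, 1:] = lam * off1
            ab[2, :] = lam * main + w
            zj = solveh_banded(ab, w * yj, lower=False)
            w_new = np.where(yj > zj, p, 1.0 - p)
            if np.array_equal(w_new, w):
                break
            w = w_new
        z[:, j] = zj
    return z


def baseline_correct(
    run: ChromatogramRun, lam: float = 1e5, p: float = 0.001, n_iter: int = 10
):
    """Subtract an asymmetric-least-squares baseline per channel.

    The baseline is *estimated* on the variance-stabilized (log) trace, where
    the asymmetric smoother is robust, but *subtracted* on the raw intensity
    scale: drift adds to ion counts, and subtracting its log would divide the
    peaks instead. Returns ``(corrected_run, baseline_matrix)`` with the
    baseline in raw intensity units; corrected intensities are clipped at 0.

    Channels whose valley floor (25th intensity percentile) sits below 1% of
    the channel's maximum are left untouched: their baseline is
    indistinguishable from zero — drift lifts the valleys, whereas
    multiplicative noise leaves true zeros at zero — and subtracting the
    fitted ripple there would only distort the peaks.
    """
    require_stage(run, "denoised")
    if lam <= 0:
        raise ConfigurationError("lam: must be positive")
    if not 0 < p < 1:
        raise ConfigurationError("p: must be in (0, 1)")
    z = _als_banded(run.intensities, lam, p, n_iter)
    valley = np.percentile(run.intensities, 25, axis=0)
    negligible = valley < 0.01 * run.intensities.max(axis=0)
    z[:, negligible] = 0.0
    baseline = np.expm1(np.clip(z, 0.0, None))
    corrected = np.log1p(np.clip(np.expm1(run.intensities) - baseline, 0.0, None))
    return run.with_intensities(corrected, "baseline_corrected"), baseline


# ---------------------------------------------------------------------------
# stage 4: retention-time alignment


def align_runs(cohort, segment_len: int = 100, max_shift: int = 25, min_gain: float = 0.03):
    """Align each run's retention axis to the cohort-median TIC.

    The TIC is split into segments; per segment the integer shift in
    [-max_shift, max_shift] maximizing Pearson correlation with the reference
    is found, shifts are linearly interpolated between segment centers, and
    every channel is resampled accordingly. Shifts are capped at max_shift
    (planted shifts beyond the cap are only partially recovered; a warning is
    logged).
    """
    if segment_len < 2 * max_shift:
        raise ConfigurationError("segment_len: must be >= 2 * max_shift")
    for run in cohort:
        require_stage(run, "baseline_corrected")
    n = cohort[0].n_scans
    tics = np.stack([r.tic() for r in cohort])
    ref = np.median(tics, axis=0)

    starts = np.arange(0, n, segment_len)
    centers = np.minimum(starts + segment_len // 2, n - 1)

    aligned = []
    for run, tic in zip(cohort, tics):
        seg_shifts = np.zeros(starts.size)
        confident = np.zeros(starts.size, dtype=bool)
        saturated = False
        for si, a in enumerate(starts):
            b = min(a + segment_len, n)
            ref_seg = ref[a:b]
            if ref_seg.std() == 0:
                continue
            best_corr, best_s, corr0 = -np.inf, 0, -np.inf
            # small |shift| preferred on ties (identical runs must map to 0);
            # at the run boundaries the windows are cropped to their overlap
            for s in sorted(range(-max_shift, max_shift + 1), key=lambda v: (abs(v), v)):
                lo, hi = max(a + s, 0), min(b + s, n)
                if hi - lo < (b - a) // 2:
                    continue
                seg = tic[lo:hi]
                rseg = ref[lo - s : hi - s]
                if seg.std() == 0 or rseg.std() == 0:
                    continue
                corr = np.corrcoef(seg, rseg)[0, 1]
                if s == 0:
                    corr0 = corr
                if corr > best_corr + 1e-9:
                    best_corr, best_s = corr, s
            # a shift must buy a real correlation gain over staying put and
            # land on a decent match; amplitude differences alone produce
            # spurious optima, and flat segments correlate with anything
            applied = best_s
            if best_s != 0 and (best_corr <= corr0 + min_gain or best_corr < 0.5):
                applied = 0
            if abs(best_s) >= max_shift:
                saturated = True
            seg_shifts[si] = applied
            # only segments whose optimum survived the gates pin the warp; a
            # rejected candidate means "ambiguous", and such segments inherit
            # their shift by interpolation from confident neighbours
            confident[si] = best_corr >= 0.5 and applied == best_s
        if saturated or np.any(np.abs(seg_shifts) >= max_shift):
            logger.warning(
                "run %s: alignment shift hit the cap +/-%d; larger "
                "misalignments cannot be recovered", run.sample_id, max_shift
            )
        if confident.any():
            # 3-point median filter over the confident sequence: a lone
            # outlier between agreeing neighbours is an estimation artifact
            cs = seg_shifts[confident]
            if cs.size >= 3:
                padded = np.r_[cs[0], cs, cs[-1]]
                cs = np.median(
                    np.column_stack([padded[:-2], padded[1:-1], padded[2:]]), axis=1
                )
            shift_at = np.interp(np.arange(n), centers[confident], cs)
            seg_shifts[confident] = cs
        else:
            shift_at = np.zeros(n)
        src = np.clip(np.arange(n) + shift_at, 0, n - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n - 1)
        frac = (src - lo)[:, None]
        new_int = (1 - frac) * run.intensities[lo] + frac * run.intensities[hi]
        out = run.with_intensities(new_int, "aligned")
        out.segment_shifts = seg_shifts
        aligned.append(out)
    return aligned


# ---------------------------------------------------------------------------
# stage 5: probabilistic quotient normalization


def pqn_normalize(cohort):
    """Divide each run by the median quotient to the cohort reference TIC.

    Dilution acts multiplicatively on raw intensities, so quotients are
    computed and applied on the back-transformed (expm1) intensity scale:
    reference = median raw TIC over runs; quotients taken over scans where
    the reference exceeds both its 25th percentile and 1% of its maximum
    (avoids near-zero divisions and keeps baseline-residual valley scans,
    whose ratios carry no dilution information, out of the median);
    each run's raw intensities are divided by its median quotient and the
    result re-logged. Returns ``(cohort, median_quotients)`` — the quotients
    estimate each sample's dilution factor.
    """
    for run in cohort:
        require_stage(run, "aligned")
    raw = [np.expm1(r.intensities) for r in cohort]
    tics = np.stack([x.sum(axis=1) for x in raw])
    ref = np.median(tics, axis=0)
    if not np.any(ref > 0):
        raise ValidationError("all-zero reference TIC; cannot normalize")
    mask = ref > max(np.percentile(ref, 25), 0.01 * ref.max())
    quotients = np.array([np.median(t[mask] / ref[mask]) for t in tics])
    if np.any(quotients <= 0):
        raise ValidationError("non-positive median quotient; degenerate run")
    out = [
        r.with_intensities(np.log1p(x / q), "normalized")
        for r, x, q in zip(cohort, raw, quotients)
    ]
    return out, quotients


# ---------------------------------------------------------------------------
# stage 6: peak picking and merging


def pick_peaks(cohort, k: float = 5.0, min_width: int = 2):
    """Pick peaks on the cohort-mean TIC; integrate every sample over the
    shared bounds.

    Candidates are local maxima with prominence >= k * sigma, sigma the
    MAD/0.6745 of the first-differenced mean TIC; bounds sit at the flanking
    minima. Returns ``(features, areas)`` with areas (n_samples, n_peaks)
    trapezoidal integrals of each sample's TIC.

    Picking and integration run on the back-transformed (expm1) intensity
    scale: peak areas are reported in the instrument's intensity units, the
    log scale having served its purpose during denoising/baseline removal.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    for run in cohort:
        require_stage(run, "normalized")
    raw = [np.expm1(r.intensities) for r in cohort]
    mean_mat = np.mean(raw, axis=0)
    mean_tic = mean_mat.sum(axis=1)
    d = np.diff(mean_tic)
    sigma = np.median(np.abs(d - np.median(d))) / 0.6745
    prominence = max(k * sigma, 1e-12)
    apexes, props = find_peaks(mean_tic, prominence=prominence)
    if apexes.size == 0:
        return [], np.zeros((len(cohort), 0))

    n = mean_tic.size
    bounds = []
    for i, apex in enumerate(apexes):
        left_lim = apexes[i - 1] if i > 0 else 0
        right_lim = apexes[i + 1] if i + 1 < apexes.size else n - 1
        left = left_lim + int(np.argmin(mean_tic[left_lim:apex + 1])) if apex > left_lim else apex
        right = apex + int(np.argmin(mean_tic[apex:right_lim + 1])) if right_lim > apex else apex + 1
        right = max(right, apex + 1)
        bounds.append((left, right))

    features = []
    for i, (apex, (left, right)) in enumerate(zip(apexes, bounds)):
        sl = slice(max(apex - 1, 0), min(apex + 2, n))
        spec = (mean_mat[sl] * mean_tic[sl, None]).sum(axis=0)
        total = spec.sum()
        spec = spec / total if total > 0 else np.full(mean_mat.shape[1], 1.0 / mean_mat.shape[1])
        features.append(
            PeakFeature(
                peak_id=f"peak_{i:04d}", apex_scan=int(apex),
                left_bound=int(left), right_bound=int(right),
                consensus_spectrum=spec, member_peaks=[f"peak_{i:04d}"],
            )
        )
    areas = np.zeros((len(cohort), len(features)))
    for si, x in enumerate(raw):
        tic = x.sum(axis=1)
        for fi, f in enumerate(features):
            areas[si, fi] = np.trapezoid(tic[f.left_bound : f.right_bound])
    return features, areas


def merge_peaks(features, areas, corr_threshold: float = 0.95, rt_window: int = 15):
    """Merge peaks of the same compound by mass-spectral correlation.

    Eligible pairs (Pearson correlation of consensus spectra >= threshold and
    apexes within rt_window scans) merge greedily in descending correlation
    order, ties broken by the earlier apex; merged area = sum of member
    areas, merged spectrum = area-weighted mean.
    """
    m = len(features)
    if m <= 1:
        return list(features), np.asarray(areas)
    spectra = np.stack([f.consensus_spectrum for f in features])
    apex = np.array([f.apex_scan for f in features])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(spectra)
    corr = np.nan_to_num(corr, nan=-1.0)
    pairs = [
        (corr[i, j], min(apex[i], apex[j]), i, j)
        for i in range(m)
        for j in range(i + 1, m)
        if corr[i, j] >= corr_threshold and abs(int(apex[i]) - int(apex[j])) <= rt_window
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))

    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for _, _, i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    clusters = {}
    for i in range(m):
        clusters.setdefault(find(i), []).append(i)

    areas = np.asarray(areas)
    merged_feats, merged_cols = [], []
    for new_id, (root, members) in enumerate(sorted(clusters.items())):
        members = sorted(members)
        col = areas[:, members].sum(axis=1)
        w = areas[:, members].sum(axis=0)
        w = w / w.sum() if w.sum() > 0 else np.full(len(members), 1.0 / len(members))
        spec = (spectra[members] * w[:, None]).sum(axis=0)
        spec = spec / spec.sum()
        lead = members[int(np.argmax(w))]
        merged_feats.append(
            PeakFeature(
                peak_id=f"feature_{new_id:04d}",
                apex_scan=features[lead].apex_scan,
                left_bound=min(features[i].left_bound for i in members),
                right_bound=max(features[i].right_bound for i in members),
                consensus_spectrum=spec,
                member_peaks=[features[i].peak_id for i in members],
            )
        )
        merged_cols.append(col)
    return merged_feats, np.column_stack(merged_cols)


# ---------------------------------------------------------------------------
# sklearn-style transformers


class _CohortTransform(BaseEstimator, TransformerMixin):
    def fit(self, X, y=None):  # stateless by default
        return self

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X, y).transform(X)


class LogTransform(_CohortTransform):
    """ln(1+x) on every run of the cohort."""

    def transform(self, X):
        return [log_transform(r) for r in X]


class WaveletDenoiser(_CohortTransform):
    def __init__(self, wavelet: str = "db4", levels: int = 2):
        self.wavelet = wavelet
        self.levels = levels

    def transform(self, X):
        return [wavelet_denoise(r, self.wavelet, self.levels) for r in X]


class BaselineCorrector(_CohortTransform):
    def __init__(self, lam: float = 1e5, p: float = 0.001, n_iter: int = 10):
        self.lam = lam
        self.p = p
        self.n_iter = n_iter

    def transform(self, X):
        out, baselines = [], []
        for r in X:
            corrected, baseline = baseline_correct(r, self.lam, self.p, self.n_iter)
            out.append(corrected)
            baselines.append(baseline)
        self.baselines_ = baselines
        return out


class CohortAligner(_CohortTransform):
    def __init__(self, segment_len: int = 100, max_shift: int = 25, min_gain: float = 0.03):
        self.segment_len = segment_len
        self.max_shift = max_shift
        self.min_gain = min_gain

    def transform(self, X):
        return align_runs(X, self.segment_len, self.max_shift, self.min_gain)


class PqnNormalizer(_CohortTransform):
    def transform(self, X):
        out, quotients = pqn_normalize(X)
        self.quotients_ = quotients
        return out


class PeakTableBuilder(_CohortTransform):
    """pick_peaks + merge_peaks -> FeatureMatrix (groups attached later)."""

    def __init__(self, k: float = 5.0, corr_threshold: float = 0.95, rt_window: int = 15):
        self.k = k
        self.corr_threshold = corr_threshold
        self.rt_window = rt_window

    def transform(self, X):
        feats, areas = pick_peaks(X, k=self.k)
        feats, areas = merge_peaks(feats, areas, self.corr_threshold, self.rt_window)
        self.features_ = feats
        return FeatureMatrix(
            sample_ids=[r.sample_id for r in X],
            peak_ids=[f.peak_id for f in feats],
            areas=areas,
            groups=["unknown"] * len(X),
            features=feats,
        )


def build_feature_matrix(cohort, clinical, params: dict | None = None) -> FeatureMatrix:
    """Full chain on raw runs: log -> denoise -> baseline -> align -> PQN ->
    pick -> merge, then attach group labels from the clinical table."""
    params = params or {}
    pqn = PqnNormalizer()
    chain = [
        LogTransform(),
        WaveletDenoiser(**params.get("wavelet", {})),
        BaselineCorrector(**params.get("baseline", {})),
        CohortAligner(**params.get("align", {})),
        pqn,
    ]
    X = cohort
    for step in chain:
        X = step.fit_transform(X)
        logger.info("stage %s done (%d runs)", X[0].stage, len(X))
    builder = PeakTableBuilder(**params.get("peaks", {}))
    fm = builder.fit_transform(X)
    fm.pqn_quotients = pqn.quotients_
    logger.info("picked %d merged features", fm.n_peaks)

    idx = {str(s): g for s, g in zip(clinical["sample_id"], clinical["group"])}
    missing = [s for s in fm.sample_ids if s not in idx]
    if missing:
        raise ValidationError(f"clinical table missing sample id(s): {missing}")
    fm.groups = [idx[s] for s in fm.sample_ids]
    return fm
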