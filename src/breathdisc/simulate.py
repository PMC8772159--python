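"""Synthetic GC-tof-MS breath cohorts with full ground truth.

The real study cohort (three groups: controls, an IPF-like fibrotic group and
a CTD-ILD-like group) is not publicly deposited, so every statistical claim
the pipeline makes is exercised against cohorts generated here, for which the
planted truth — peak catalog, discriminatory compound sets, dilution factors
and the latent clinical coupling — is known exactly.

Signal model per sample::

    I(scan, mz) = dilution * [ baseline(scan)
                  + sum_c  A_c * N(scan; apex_c + jitter, width_c) * S_c(mz) ]
                  * (1 + noise_cv * eps),   eps ~ N(0,1), clipped at 0

where ``N`` is a unit-area Gaussian in retention time (so the TIC area of a
compound equals its abundance ``A_c``), ``S_c`` a unit-sum mass spectrum with
5-15 nonzero integer m/z lines, and the multiplicative noise is
heteroscedastic by construction — exactly the noise a log transform is meant
to stabilize.

Abundances are log-normal: ``log A = base_c + group shift + subject effect``.
Discriminatory compounds receive a signed shift of ``effect_size`` units of
the between-subject SD on the contrast they discriminate. Compounds in the
A<->B contrast additionally load on a latent per-subject severity score that
also drives the coupled clinical columns (TLC and 6MWD analogues by default),
so canonical-correlation recovery can be tested against a known latent model;
controls carry their own latent draw so the within-class covariance structure
is identical across groups.

Geometry defaults are scaled down (11-min equivalent, 3300 scans) to keep
simulations fast; ``SimulationConfig.full_scale()`` restores the instrument's
33-min, 9900-scan, m/z 35-350 acquisition.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    LUNG_FUNCTION_COLUMNS,
    ChromatogramRun,
    ConfigurationError,
    FeatureMatrix,
    write_chromatogram_csv,
)

_BETWEEN_SUBJECT_SD = 0.5  # SD of log-abundance across subjects, per compound

# Table-style clinical column means/SDs (percent predicted; PaO2/PaCO2 mm Hg)
_CLINICAL_MEANS = {
    "VC": (77, 22), "TLC": (73, 15), "FRC": (76, 16), "FEV1": (79, 23),
    "DLCO": (49, 17), "PaO2": (77, 10), "PaCO2": (40, 4), "SixMWD": (83, 20),
}


@dataclass
class SimulationConfig:
    """Cohort geometry, planted effects and noise levels.

    effect_size is the mean log-abundance shift of a discriminatory compound
    in units of the between-subject SD; clinical_coupling the correlation
    between the latent severity score, the A<->B compounds, and the coupled
    clinical columns.
    """

    n_per_group: tuple = (51, 53, 51)  # (control, groupA, groupB)
    n_compounds: int = 200
    n_disc_A: int = 10    # control <-> A contrast
    n_disc_B: int = 10    # control <-> B contrast
    n_disc_AB: int = 10   # A <-> B contrast
    effect_size: float = 1.5
    mz_min: int = 35
    mz_max: int = 350
    scan_rate: float = 5.0
    run_seconds: float = 660.0  # scaled-down default; full run is 1980 s
    noise_cv: float = 0.1
    baseline_amp: float = 0.1  # relative to median peak apex height
    rt_jitter_sd: float = 2.0  # scans
    dilution_sd: float = 0.2   # SD of log dilution factor
    clinical_coupling: float = 0.7
    coupled_columns: tuple = ("TLC", "SixMWD")
    seed: int = 0

    @classmethod
    def full_scale(cls, **kw) -> "SimulationConfig":
        """Full instrument geometry: 33 min at 5 scans/sec, m/z 35-350."""
        kw.setdefault("run_seconds", 1980.0)
        return cls(**kw)

    @property
    def n_scans(self) -> int:
        return int(round(self.scan_rate * self.run_seconds))

    @property
    def mz_axis(self) -> np.ndarray:
        return np.arange(self.mz_min, self.mz_max + 1)

    def validate(self) -> None:
        if len(self.n_per_group) != 3 or any(int(n) <= 0 for n in self.n_per_group):
            raise ConfigurationError("n_per_group: need three positive counts")
        if self.n_compounds <= 0:
            raise ConfigurationError("n_compounds: must be positive")
        for name in ("n_disc_A", "n_disc_B", "n_disc_AB"):
            v = getattr(self, name)
            if v < 0 or v > self.n_compounds:
                raise ConfigurationError(f"{name}: must be in [0, n_compounds]")
        if self.mz_min >= self.mz_max:
            raise ConfigurationError("mz_min: must be below mz_max")
        if self.scan_rate <= 0:
            raise ConfigurationError("scan_rate: must be positive")
        if self.run_seconds <= 0:
            raise ConfigurationError("run_seconds: must be positive")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size: must be non-negative")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv: must be non-negative")
        if not -1 <= self.clinical_coupling <= 1:
            raise ConfigurationError("clinical_coupling: must be a correlation in [-1, 1]")
        unknown = set(self.coupled_columns) - set(LUNG_FUNCTION_COLUMNS)
        if unknown:
            raise ConfigurationError(f"coupled_columns: unknown column(s) {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger: what was planted, per compound and per sample."""

    config: SimulationConfig
    apex_scans: np.ndarray        # (n_compounds,)
    widths: np.ndarray            # (n_compounds,) Gaussian sigma in scans
    spectra: np.ndarray           # (n_compounds, n_channels), rows sum to 1
    base_log_abundance: np.ndarray
    disc_sets: dict               # contrast -> {"indices": array, "effects": array}
    groups: list                  # per-sample group label
    sample_ids: list
    dilutions: np.ndarray         # (n_samples,)
    log_abundances: np.ndarray    # (n_samples, n_compounds), pre-dilution
    severity: np.ndarray          # (n_samples,) latent impairment score
    clinical_loadings: dict       # column -> coupling strength
    rt_jitter: np.ndarray = field(default=None)  # (n_samples, n_compounds)

    @property
    def abundances(self) -> np.ndarray:
        return np.exp(self.log_abundances)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_feature_matrix(self) -> FeatureMatrix:
        """Noise-free abundance table (samples x compounds), bypassing the
        chromatogram render — the fast path for model-level simulations."""
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            peak_ids=[f"compound_{i:03d}" for i in range(self.config.n_compounds)],
            areas=self.abundances,
            groups=list(self.groups),
        )

    def to_json_dict(self) -> dict:
        d = {
            "config": dataclasses.asdict(self.config),
            "apex_scans": self.apex_scans.tolist(),
            "widths": self.widths.tolist(),
            "base_log_abundance": self.base_log_abundance.tolist(),
            "disc_sets": {
                k: {"indices": v["indices"].tolist(), "effects": v["effects"].tolist()}
                for k, v in self.disc_sets.items()
            },
            "groups": self.groups,
            "sample_ids": self.sample_ids,
            "dilutions": self.dilutions.tolist(),
            "severity": self.severity.tolist(),
            "clinical_loadings": self.clinical_loadings,
        }
        return d


def _make_spectra(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-sum mass spectra, 5-15 lines each; distinct compounds share lines
    with probability ~0.2 so spectral-correlation merging is nontrivial."""
    n_chan = cfg.mz_axis.size
    pool_size = max(5, n_chan // 5)
    shared_pool = rng.choice(n_chan, size=min(pool_size, n_chan), replace=False)
    spectra = np.zeros((cfg.n_compounds, n_chan))
    for c in range(cfg.n_compounds):
        n_lines = int(rng.integers(5, 16))
        n_lines = min(n_lines, n_chan)
        from_pool = rng.random(n_lines) < 0.2
        lines = np.empty(n_lines, dtype=int)
        n_pool = int(from_pool.sum())
        if n_pool:
            lines[from_pool] = rng.choice(shared_pool, size=n_pool, replace=False if n_pool <= shared_pool.size else True)
        lines[~from_pool] = rng.choice(n_chan, size=n_lines - n_pool, replace=False)
        lines = np.unique(lines)
        weights = rng.dirichlet(np.ones(lines.size))
        spectra[c, lines] = weights
    return spectra


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw the cohort's ground truth (no chromatograms rendered yet)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ctrl, n_a, n_b = (int(n) for n in config.n_per_group)
    n_samples = n_ctrl + n_a + n_b
    n_scans = config.n_scans

    # peak catalog: apexes on a jittered grid (chromatograms spread compounds
    # over the run; the grid keeps dense catalogs from collapsing into one
    # unresolvable clump), widths uniform 3-10 scans capped so that sparse
    # catalogs stay baseline-resolved
    margin = max(30, n_scans // 50)
    spacing = (n_scans - 2 * margin) / config.n_compounds
    centers = margin + spacing * (np.arange(config.n_compounds) + 0.5)
    apex = centers + rng.uniform(-0.2, 0.2, size=config.n_compounds) * spacing
    w_hi = float(np.clip(spacing / 8.0, 3.001, 10.0))
    widths = rng.uniform(3.0, w_hi, size=config.n_compounds)
    spectra = _make_spectra(config, rng)
    base_log = rng.uniform(np.log(1e4), np.log(1e6), size=config.n_compounds)

    # discriminatory sets: overlap between contrasts allowed
    disc_sets = {}
    for key, count in (("ctrl_vs_A", config.n_disc_A),
                       ("ctrl_vs_B", config.n_disc_B),
                       ("A_vs_B", config.n_disc_AB)):
        idx = rng.choice(config.n_compounds, size=count, replace=False)
        signs = rng.choice([-1.0, 1.0], size=count)
        disc_sets[key] = {"indices": np.sort(idx),
                          "effects": signs[np.argsort(idx)] * config.effect_size}

    groups = (["control"] * n_ctrl + ["IPF-like"] * n_a + ["CTD-like"] * n_b)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    is_a = np.array([g == "IPF-like" for g in groups])
    is_b = np.array([g == "CTD-like" for g in groups])
    is_patient = is_a | is_b

    # latent severity: patients only (controls get an uncoupled draw)
    severity = rng.standard_normal(n_samples)

    sd = _BETWEEN_SUBJECT_SD
    log_ab = np.tile(base_log, (n_samples, 1))
    subject_noise = rng.standard_normal((n_samples, config.n_compounds)) * sd
    rho = config.clinical_coupling

    # group mean shifts: half the signed effect on each side of a contrast
    for key, pos_mask, neg_mask in (
        ("ctrl_vs_A", is_a, ~is_a & ~is_b),
        ("ctrl_vs_B", is_b, ~is_a & ~is_b),
        ("A_vs_B", is_a, is_b),
    ):
        idx = disc_sets[key]["indices"]
        eff = disc_sets[key]["effects"] * sd
        log_ab[np.ix_(pos_mask, idx)] += eff / 2
        log_ab[np.ix_(neg_mask, idx)] -= eff / 2

    # couple A<->B compounds to the latent severity: the subject effect
    # becomes sd * (rho*z + sqrt(1-rho^2)*eps) so corr(log A, z) = rho.
    # Applied to every subject (controls carry their own latent draw), so
    # the within-class covariance structure is identical across groups and
    # an effect_size=0 cohort is a true null for the discriminant layer.
    ab_idx = disc_sets["A_vs_B"]["indices"]
    if ab_idx.size and rho != 0:
        z = severity[:, None]
        eps = subject_noise[:, ab_idx] / sd
        subject_noise[:, ab_idx] = sd * (rho * z + np.sqrt(1 - rho**2) * eps)
    log_ab += subject_noise

    dilutions = np.exp(rng.normal(0.0, config.dilution_sd, size=n_samples))
    rt_jitter = rng.normal(0.0, config.rt_jitter_sd, size=(n_samples, config.n_compounds))

    clinical_loadings = {c: rho for c in config.coupled_columns}
    return SyntheticTruth(
        config=config, apex_scans=apex, widths=widths, spectra=spectra,
        base_log_abundance=base_log, disc_sets=disc_sets, groups=groups,
        sample_ids=sample_ids, dilutions=dilutions, log_abundances=log_ab,
        severity=severity, clinical_loadings=clinical_loadings, rt_jitter=rt_jitter,
    )


def render_run(truth: SyntheticTruth, sample_index: int) -> ChromatogramRun:
    """Render one subject's chromatogram from the truth ledger.

    Deterministic: the noise stream is derived from (config.seed, sample_index).
    """
    cfg = truth.config
    if not 0 <= sample_index < truth.n_samples:
        raise IndexError(f"sample_index {sample_index} out of range")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7919, sample_index)))
    n_scans, mz_axis = cfg.n_scans, cfg.mz_axis
    scans = np.arange(n_scans, dtype=float)

    abundances = truth.abundances[sample_index]
    apex = truth.apex_scans + truth.rt_jitter[sample_index]
    sig = truth.widths

    intens = np.zeros((n_scans, mz_axis.size))
    for c in np.flatnonzero(abundances > 0):
        lo = max(0, int(apex[c] - 6 * sig[c]))
        hi = min(n_scans, int(apex[c] + 6 * sig[c]) + 1)
        if hi <= lo:
            continue
        g = np.exp(-0.5 * ((scans[lo:hi] - apex[c]) / sig[c]) ** 2)
        g *= abundances[c] / (sig[c] * np.sqrt(2 * np.pi))
        intens[lo:hi] += np.outer(g, truth.spectra[c])

    if cfg.baseline_amp > 0:
        med_apex = np.median(truth.abundances.mean(axis=0) / (sig * np.sqrt(2 * np.pi)))
        t = scans / n_scans
        phase = rng.uniform(0, 2 * np.pi, size=3)
        drift = sum(np.sin(2 * np.pi * (k + 1) * t / 4 + phase[k]) / (k + 1) for k in range(3))
        drift = drift - drift.min()
        baseline = cfg.baseline_amp * med_apex * drift
        # spread the baseline over all channels so the TIC carries it
        intens += baseline[:, None] / mz_axis.size

    if cfg.noise_cv > 0:
        eps = rng.standard_normal(intens.shape)
        intens = np.clip(intens * (1.0 + cfg.noise_cv * eps), 0.0, None)

    intens *= truth.dilutions[sample_index]
    scan_times = (np.arange(n_scans) + 1) / cfg.scan_rate
    return ChromatogramRun(truth.sample_ids[sample_index], scan_times, mz_axis, intens)


def generate_clinical(truth: SyntheticTruth) -> pd.DataFrame:
    """Clinical table with Table-style covariates.

    Coupled lung-function columns are rho*z + sqrt(1-rho^2)*noise scaled to
    the column's mean/SD (z = latent severity, an impairment score); controls
    carry NA in lung-function columns, as in the study table.
    """
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 104729)))
    rho = cfg.clinical_coupling
    groups = np.asarray(truth.groups)
    n = truth.n_samples
    is_patient = groups != "control"

    age_params = {"control": (53, 10), "IPF-like": (69, 9), "CTD-like": (57, 12)}
    male_frac = {"control": 0.68, "IPF-like": 0.75, "CTD-like": 0.26}
    rows = {
        "sample_id": truth.sample_ids,
        "group": truth.groups,
        "age": [rng.normal(*age_params[g]) for g in truth.groups],
        "sex": ["male" if rng.random() < male_frac[g] else "female" for g in truth.groups],
        "smoking": [str(rng.choice(["never", "ex", "current"], p=[0.5, 0.35, 0.15]))
                    for _ in truth.groups],
    }
    df = pd.DataFrame(rows)
    for col in LUNG_FUNCTION_COLUMNS:
        mean, sd = _CLINICAL_MEANS[col]
        load = truth.clinical_loadings.get(col, 0.0)
        latent = load * truth.severity + np.sqrt(max(0.0, 1 - load**2)) * rng.standard_normal(n)
        vals = mean + sd * latent
        vals = np.clip(vals, 1.0, None)  # percent-predicted stays positive
        vals[~is_patient] = np.nan
        df[col] = vals
    return df


def generate_cohort(config: SimulationConfig):
    """Full cohort: (runs, clinical DataFrame, truth ledger).

    Deterministic: identical (config, seed) regenerates identical output.
    """
    truth = generate_truth(config)
    runs = [render_run(truth, i) for i in range(truth.n_samples)]
    clinical = generate_clinical(truth)
    return runs, clinical, truth


def write_cohort(config: SimulationConfig, out_dir) -> SyntheticTruth:
    """Write one matrix-CSV per subject plus clinical.csv and truth.json."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runs, clinical, truth = generate_cohort(config)
    for run in runs:
        write_chromatogram_csv(run, out / f"{run.sample_id}.csv")
    clinical.to_csv(out / "clinical.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh)
    return truth
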