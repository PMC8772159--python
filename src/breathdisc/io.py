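"""Chromatogram, clinical-table and feature-matrix I/O.

Containers
----------
:class:`ChromatogramRun`
    One subject's scan-time x m/z intensity matrix with acquisition axes and a
    pipeline-stage tag. Intensities are non-negative reals; stages advance in
    the fixed order raw -> logged -> denoised -> baseline_corrected ->
    aligned -> normalized.
:class:`FeatureMatrix`
    The analysis table: participants as rows, peak areas as columns, with
    group labels.

Formats
-------
* mzML (read only, via pyteomics); centroided peaks are binned to the nearest
  integer m/z channel within the configured window.
* A plain matrix-CSV dialect (read/write): row 1 is the integer m/z header,
  column 1 the scan time in seconds, the body the intensity matrix. Chosen so
  cohorts stay inspectable with ordinary spreadsheet tools.
* Feature-matrix CSV: header ``sample_id,group,<peak ids...>``.
* Clinical CSV: one row per subject, Table-style lung-function columns in
  percent predicted (PaO2/PaCO2 in mm Hg); controls may carry NA there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("breathdisc")

#: Pipeline stages in the only order they may be applied.
STAGES = ("raw", "logged", "denoised", "baseline_corrected", "aligned", "normalized")

#: Clinical lung-function roster (percent predicted; PaO2/PaCO2 in mm Hg).
LUNG_FUNCTION_COLUMNS = ("VC", "TLC", "FRC", "FEV1", "DLCO", "PaO2", "PaCO2", "SixMWD")

GROUPS = ("control", "IPF-like", "CTD-like")


class ValidationError(ValueError):
    """Raised when an input would silently corrupt the analysis."""


class ConfigurationError(ValueError):
    """Raised for invalid parameter values, naming the offending field."""


class StageError(RuntimeError):
    """Raised when a preprocessing stage is applied out of order."""


def require_stage(run: "ChromatogramRun", expected: str) -> None:
    if run.stage != expected:
        raise StageError(
            f"run {run.sample_id!r} is at stage {run.stage!r}, expected {expected!r}"
        )


@dataclass
class ChromatogramRun:
    """One subject's chromatogram: scans x integer m/z channels."""

    sample_id: str
    scan_times: np.ndarray  # seconds, uniform spacing
    mz_axis: np.ndarray  # ascending integer m/z
    intensities: np.ndarray  # (n_scans, n_channels), >= 0
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        self.mz_axis = np.asarray(self.mz_axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.intensities.shape != (self.scan_times.size, self.mz_axis.size):
            raise ValidationError(
                f"intensity matrix {self.intensities.shape} does not match axes "
                f"({self.scan_times.size} scans, {self.mz_axis.size} channels)"
            )
        if self.scan_times.size > 1 and not np.all(np.diff(self.scan_times) > 0):
            raise ValidationError("scan times must be strictly increasing")
        if not np.all(np.diff(self.mz_axis) > 0):
            raise ValidationError("m/z axis must be strictly ascending")
        if np.isnan(self.intensities).any():
            raise ValidationError("intensity matrix contains NaN")

    @property
    def n_scans(self) -> int:
        return self.scan_times.size

    @property
    def n_channels(self) -> int:
        return self.mz_axis.size

    def tic(self) -> np.ndarray:
        """Total ion current: per-scan sum over all m/z channels."""
        return self.intensities.sum(axis=1)

    def with_intensities(self, intensities: np.ndarray, stage: str) -> "ChromatogramRun":
        return replace(self, intensities=intensities, stage=stage)


@dataclass
class FeatureMatrix:
    """Participants x peak-areas table with group labels."""

    sample_ids: list
    peak_ids: list
    areas: np.ndarray  # (n_samples, n_peaks)
    groups: list
    features: list = field(default_factory=list)  # optional PeakFeature metadata

    def __post_init__(self) -> None:
        self.areas = np.atleast_2d(np.asarray(self.areas, dtype=float))
        if self.areas.size == 0:
            self.areas = self.areas.reshape(len(self.sample_ids), 0)
        if self.areas.shape != (len(self.sample_ids), len(self.peak_ids)):
            raise ValidationError(
                f"area matrix {self.areas.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.peak_ids)} peaks"
            )
        if len(self.groups) != len(self.sample_ids):
            raise ValidationError("group labels do not match sample ids")
        if np.isnan(self.areas).any():
            raise ValidationError("feature matrix contains NaN")
        seen, dupes = set(), []
        for sid in self.sample_ids:
            if sid in seen:
                dupes.append(sid)
            seen.add(sid)
        if dupes:
            raise ValidationError(f"duplicate sample id(s): {sorted(set(dupes))}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    def subset(self, sample_mask=None, peak_indices=None) -> "FeatureMatrix":
        sm = np.arange(self.n_samples) if sample_mask is None else np.asarray(sample_mask)
        if sm.dtype == bool:
            sm = np.flatnonzero(sm)
        pk = np.arange(self.n_peaks) if peak_indices is None else np.asarray(peak_indices)
        return FeatureMatrix(
            sample_ids=[self.sample_ids[i] for i in sm],
            peak_ids=[self.peak_ids[j] for j in pk],
            areas=self.areas[np.ix_(sm, pk)],
            groups=[self.groups[i] for i in sm],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.areas, columns=self.peak_ids)
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df


# ---------------------------------------------------------------------------
# chromatogram read/write


def write_chromatogram_csv(run: ChromatogramRun, path) -> None:
    """Matrix-CSV dialect: row 1 = m/z header, column 1 = scan time (s)."""
    df = pd.DataFrame(run.intensities, columns=[str(int(m)) for m in run.mz_axis])
    df.insert(0, "scan_time", run.scan_times)
    df.to_csv(path, index=False, float_format="%.17g")


def _read_matrix_csv(path) -> ChromatogramRun:
    df = pd.read_csv(path)
    if df.columns[0] != "scan_time":
        raise ValidationError(f"{path}: first column must be 'scan_time'")
    if df.isna().any().any():
        raise ValidationError(f"{path}: missing values in chromatogram matrix")
    try:
        mz = np.array([int(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-integer m/z header: {exc}") from None
    scan_times = df["scan_time"].to_numpy(dtype=float)
    if scan_times.size > 1 and not np.all(np.diff(scan_times) > 0):
        raise ValidationError(f"{path}: non-monotone scan times")
    sample_id = str(path).rsplit("/", 1)[-1].removesuffix(".csv")
    return ChromatogramRun(sample_id, scan_times, mz, df.iloc[:, 1:].to_numpy(float))


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    import base64
    import zlib

    dtype, compressed = "<f8", False
    for cv in bda.iter():
        if cv.tag.endswith("cvParam"):
            acc = cv.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
    bin_el = next((e for e in bda.iter() if e.tag.endswith("binary")), None)
    raw = base64.b64decode(bin_el.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _iter_mzml_spectra(path):
    """Yield (start_time, mz_array, intensity_array) from an mzML file.

    Minimal namespace-tolerant reader built on lxml; covers centroided MS1
    spectra with base64-encoded float arrays (zlib-compressed or plain).
    """
    from lxml import etree

    for _, spectrum in etree.iterparse(str(path), tag="{*}spectrum"):
        t = None
        for cv in spectrum.iter("{*}cvParam"):
            if cv.get("accession") == "MS:1000016":  # scan start time
                t = float(cv.get("value"))
        mz = inten = None
        for bda in spectrum.iter("{*}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter("{*}cvParam")}
            if "MS:1000514" in accs:
                mz = _decode_binary_array(bda)
            elif "MS:1000515" in accs:
                inten = _decode_binary_array(bda)
        yield t, mz, inten
        spectrum.clear(keep_tail=True)


def _read_mzml(path, mz_min: int, mz_max: int) -> ChromatogramRun:
    scan_times, rows, dropped = [], [], 0
    mz_axis = np.arange(mz_min, mz_max + 1)
    for i, (t, mz, inten) in enumerate(_iter_mzml_spectra(path)):
        if t is None or mz is None or inten is None:
            raise ValidationError(f"{path}: scan {i} lacks a start time or data arrays")
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        # nearest-integer binning, x.5 rounds up
        chan = np.floor(mz + 0.5).astype(int)
        ok = (chan >= mz_min) & (chan <= mz_max)
        dropped += int((~ok).sum())
        row = np.zeros(mz_axis.size)
        np.add.at(row, chan[ok] - mz_min, inten[ok])
        scan_times.append(t)
        rows.append(row)
    if dropped:
        logger.info("%s: dropped %d centroids outside m/z [%d, %d]", path, dropped, mz_min, mz_max)
    scan_times = np.asarray(scan_times)
    if scan_times.size > 1 and not np.all(np.diff(scan_times) > 0):
        raise ValidationError(f"{path}: non-monotone scan times")
    sample_id = str(path).rsplit("/", 1)[-1].removesuffix(".mzML").removesuffix(".mzml")
    run = ChromatogramRun(sample_id, scan_times, mz_axis, np.vstack(rows))
    run.dropped_centroids = dropped
    return run


def read_chromatogram(path, format: str = "matrix_csv", mz_min: int = 35, mz_max: int = 350) -> ChromatogramRun:
    """Read one chromatogram.

    ``format='mzml'`` bins centroided peaks into unit-m/z channels within
    ``[mz_min, mz_max]`` (nearest integer, .5 rounds up); out-of-range masses
    are dropped with a logged count, also exposed as ``run.dropped_centroids``.
    ``format='matrix_csv'`` reads the package's plain-matrix dialect.
    """
    if format == "matrix_csv":
        return _read_matrix_csv(path)
    if format == "mzml":
        return _read_mzml(path, mz_min, mz_max)
    raise ConfigurationError(f"unknown chromatogram format {format!r}")


# ---------------------------------------------------------------------------
# feature matrix and clinical table


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    fm.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValidationError(f"{path}: first two columns must be sample_id, group")
    return FeatureMatrix(
        sample_ids=[str(s) for s in df["sample_id"]],
        peak_ids=list(df.columns[2:]),
        areas=df.iloc[:, 2:].to_numpy(float).reshape(len(df), len(df.columns) - 2),
        groups=[str(g) for g in df["group"]],
    )


def read_clinical_table(path) -> pd.DataFrame:
    """Clinical CSV -> DataFrame indexed by sample_id; group must be present."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValidationError(f"{path}: clinical table needs sample_id and group columns")
    if df["group"].isna().any():
        raise ValidationError(f"{path}: missing group labels")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise ValidationError(f"{path}: duplicate sample id(s): {dupes}")
    return df.set_index("sample_id", drop=False)


def read_params_toml(path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
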