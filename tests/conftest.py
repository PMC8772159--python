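import base64
import struct

import numpy as np
import pytest

from breathdisc.io import ChromatogramRun, FeatureMatrix
from breathdisc.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small noiseless cohort with resolved peaks, shared across tests."""
    cfg = SimulationConfig(
        n_per_group=(4, 4, 4), n_compounds=20, mz_min=35, mz_max=150,
        run_seconds=240, noise_cv=0.0, baseline_amp=0.0, rt_jitter_sd=0.0,
        dilution_sd=0.0, seed=11,
    )
    runs, clinical, truth = generate_cohort(cfg)
    return cfg, runs, clinical, truth


def single_peak_run(apex=100, sigma=3.0, abundance=1000.0, n_scans=300, n_channels=5,
                    stage="raw", sample_id="single"):
    """One Gaussian peak, unit-area in scan units, on an otherwise empty run."""
    scans = np.arange(n_scans, dtype=float)
    g = abundance / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((scans - apex) / sigma) ** 2)
    spec = np.zeros(n_channels)
    spec[1] = 0.6
    spec[3] = 0.4
    intens = np.outer(g, spec)
    return ChromatogramRun(sample_id, scans + 1.0, np.arange(40, 40 + n_channels),
                           intens, stage=stage)


def make_feature_matrix(n_samples=10, n_peaks=6, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    return FeatureMatrix(
        sample_ids=[f"s{i:02d}" for i in range(n_samples)],
        peak_ids=[f"p{j}" for j in range(n_peaks)],
        areas=np.abs(rng.standard_normal((n_samples, n_peaks))) + 0.1,
        groups=groups or ["g"] * n_samples,
    )


def write_mzml(path, scans):
    """Minimal centroided mzML with float64 uncompressed arrays.

    scans: list of (start_time_seconds, mz_list, intensity_list).
    """

    def b64(values):
        raw = struct.pack(f"<{len(values)}d", *values)
        return base64.b64encode(raw).decode()

    spectra = []
    for i, (t, mz, inten) in enumerate(scans):
        spectra.append(f"""
   <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    <scanList count="1">
     <scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{t}"
               unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
     </scan>
    </scanList>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="0">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
      <binary>{b64(mz)}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="0">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
      <binary>{b64(inten)}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>""")
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <run id="run1">
  <spectrumList count="{len(scans)}" defaultDataProcessingRef="dp1">{''.join(spectra)}
  </spectrumList>
 </run>
</mzML>
"""
    path.write_text(doc)
    return path
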