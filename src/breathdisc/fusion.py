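"""Hierarchical fusion of the three binary discrimination models.

A single multi-class forest is harder to optimize and interpret than three
well-validated binary ones, so the three pairwise models (A vs control,
B vs control, A vs B) are fused instead: every cohort sample receives its
coordinates in each model's proximity-PCA space (its own training score when
it belongs to that model's data, the Gower/Nystrom projection otherwise),
the coordinates are concatenated, and a final PCA of the concatenation gives
a 3-D view of all three groups at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .discriminant import BinaryDiscriminantModel, project_sample
from .io import FeatureMatrix, ValidationError

logger = logging.getLogger("breathdisc")


@dataclass
class FusionScores:
    """Per-sample fused coordinates plus the 3-D visualization projection."""

    sample_ids: list
    groups: list
    coordinates: np.ndarray   # (n_samples, 3*k) concatenated binary-model scores
    view3d: np.ndarray        # (n_samples, 3) PCA of the concatenation
    silhouette: float

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates, columns=[f"c{i}" for i in range(k)])
        for i in range(self.view3d.shape[1]):
            df[f"view{i + 1}"] = self.view3d[:, i]
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def _model_coordinates(model: BinaryDiscriminantModel, fm: FeatureMatrix, k: int) -> np.ndarray:
    if model.embedding is None:
        raise ValidationError(f"model {model.class_pair} not embedded")
    n_emb = model.embedding["scores"].shape[1]
    if n_emb < k:
        raise ValidationError(
            f"model {model.class_pair} has {n_emb} embedding components, need {k}"
        )
    own = {sid: i for i, sid in enumerate(model.proximity_ids)}
    coords = np.zeros((fm.n_samples, k))
    X_sel = fm.areas[:, model.feature_indices]
    for i, sid in enumerate(fm.sample_ids):
        if sid in own:
            coords[i] = model.embedding["scores"][own[sid], :k]
        else:
            coords[i] = project_sample(model, X_sel[i])[:k]
    return coords


def fuse_models(models, fm: FeatureMatrix, k: int = 2) -> FusionScores:
    """Concatenate each sample's k proximity-PCA coordinates from the three
    binary models; PCA the concatenation to 3-D; log the group silhouette."""
    models = list(models)
    if len(models) != 3 or any(m is None for m in models):
        raise ValidationError("fusion needs the three fitted binary models")
    blocks = [_model_coordinates(m, fm, k) for m in models]
    coords = np.hstack(blocks)
    n_view = min(3, coords.shape[1], fm.n_samples)
    view = PCA(n_components=n_view, random_state=0).fit_transform(coords)
    sil = float(silhouette_score(view, fm.groups)) if len(set(fm.groups)) > 1 else 0.0
    logger.info("fused space: %d dims, group silhouette %.3f", coords.shape[1], sil)
    return FusionScores(
        sample_ids=list(fm.sample_ids),
        groups=list(fm.groups),
        coordinates=coords,
        view3d=view,
        silhouette=sil,
    )
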