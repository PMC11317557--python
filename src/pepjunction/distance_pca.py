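"""Distance-matrix PCA of junction conformational ensembles.

Every frame is represented by the upper triangle of the Euclidean
distance matrix over the backbone heavy-atom subgraph shared by all
sequences of a given length (17 atoms / 136 distances for tetrapeptides,
21 atoms / 210 distances for pentapeptides).  Feature columns are
Z-score standardized; the ensemble, concatenated across sequences and
holding stages, is decomposed with whitened PCA (each retained
component's projected score variance is exactly one).  Projections
colored by energy or by the canonical i -> i+3 H-bond distance expose
the turn/extended structure of the landscape, and a per-stage
depopulation metric quantifies the loss of short-H-bond regions as the
anchors are pulled apart.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .hbond_conformers import hbond_distance_series
from .peptide_model import shared_backbone_subgraph
from .synthetic_data import Ensemble

__all__ = [
    "FeatureMatrix",
    "PCAModel",
    "featurize",
    "fit_whitened_pca",
    "project",
    "depopulation_metric",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Frames-by-distances matrix with per-row metadata.

    ``columns`` maps each feature column to its subgraph atom pair,
    as ((residue_index, role), (residue_index, role)) in canonical
    (lexicographic over the subgraph ordering) pair order.
    """

    X: np.ndarray  # (n_frames, n_pairs), A
    columns: list[tuple]
    metadata: pd.DataFrame  # sequence, stage, frame, energy, hbond_distance

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.metadata):
            raise ValueError("metadata length does not match X rows")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column map length does not match X columns")


@dataclass
class PCAModel:
    """Fitted standardization + whitened-PCA transform."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (n_components, n_kept_columns)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    kept_columns: np.ndarray  # indices into the FeatureMatrix columns
    whiten: bool = True
    n_input_columns: int = 0

    def to_json(self, path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "explained_variance_ratio":
                self.explained_variance_ratio.tolist(),
            "kept_columns": self.kept_columns.tolist(),
            "whiten": self.whiten,
            "n_input_columns": self.n_input_columns,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["mean"]), np.array(d["scale"]),
                   np.array(d["components"]),
                   np.array(d["explained_variance"]),
                   np.array(d["explained_variance_ratio"]),
                   np.array(d["kept_columns"], dtype=int),
                   d["whiten"], d["n_input_columns"])


def export_features(features: FeatureMatrix, csv_path,
                    sidecar_json_path) -> None:
    """Write the feature matrix (with metadata columns) as compressed
    CSV plus a JSON sidecar mapping column names to atom-role pairs."""
    names = [f"d{j:04d}" for j in range(len(features.columns))]
    df = pd.concat(
        [features.metadata.reset_index(drop=True),
         pd.DataFrame(features.X, columns=names)], axis=1)
    df.to_csv(csv_path, index=False,
              compression="gzip" if str(csv_path).endswith(".gz")
              else None)
    colmap = {name: [list(a), list(b)]
              for name, (a, b) in zip(names, features.columns)}
    with open(sidecar_json_path, "w") as fh:
        json.dump(colmap, fh)


def featurize(ensembles: list[Ensemble],
              subgraph: tuple | None = None) -> FeatureMatrix:
    """Upper-triangle distance features over the shared backbone subgraph.

    All ensembles must have equal residue counts; the subgraph (from
    :func:`shared_backbone_subgraph`) may be passed explicitly or is
    derived from the ensembles' topologies.  Column j holds the distance
    between subgraph atom pair j, pairs ordered lexicographically over
    the documented subgraph atom order.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    topologies = [e.topology for e in ensembles]
    if subgraph is None:
        roles, mappings = shared_backbone_subgraph(topologies)
    else:
        roles, _ = subgraph
        _, mappings = shared_backbone_subgraph(topologies)
    m = len(roles)
    iu = np.triu_indices(m, k=1)
    columns = [(roles[i], roles[j]) for i, j in zip(*iu)]
    blocks, meta = [], []
    for ens, mapping in zip(ensembles, mappings):
        sub = ens.frames[:, mapping, :]  # (n_frames, m, 3)
        diff = sub[:, :, None, :] - sub[:, None, :, :]
        dmat = np.sqrt(np.sum(diff * diff, axis=-1))
        blocks.append(dmat[:, iu[0], iu[1]])
        try:
            hbd = hbond_distance_series(ens).distances
        except ValueError:  # < 4 residues: no i -> i+3 pair exists
            hbd = np.full(ens.n_frames, np.nan)
        meta.append(pd.DataFrame({
            "sequence": ens.sequence,
            "stage": ens.stage,
            "frame": np.arange(ens.n_frames),
            "energy": ens.energies,
            "hbond_distance": hbd,
        }))
    X = np.vstack(blocks)
    metadata = pd.concat(meta, ignore_index=True)
    return FeatureMatrix(X, columns, metadata)


def fit_whitened_pca(features: FeatureMatrix,
                     n_components: int = 2) -> PCAModel:
    """Z-score standardize columns, then fit whitened PCA.

    Zero-variance columns are dropped (with a logged warning) before
    standardization.  Whitening rescales scores so each retained
    component's projected variance is 1.
    """
    X = features.X
    std = X.std(axis=0, ddof=0)
    kept = np.nonzero(std > 1e-12)[0]
    if len(kept) < X.shape[1]:
        logger.warning("dropping %d zero-variance feature column(s)",
                       X.shape[1] - len(kept))
    Xk = X[:, kept]
    mean = Xk.mean(axis=0)
    scale = std[kept]
    Z = (Xk - mean) / scale
    pca = PCA(n_components=n_components, whiten=True, svd_solver="full")
    pca.fit(Z)
    return PCAModel(mean=mean, scale=scale, components=pca.components_,
                    explained_variance=pca.explained_variance_,
                    explained_variance_ratio=pca.explained_variance_ratio_,
                    kept_columns=kept, whiten=True,
                    n_input_columns=X.shape[1])


def project(model: PCAModel, features: FeatureMatrix) -> pd.DataFrame:
    """Project frames onto the fitted components.

    Returns the metadata with pc1..pcK score columns appended; scores of
    the training matrix have unit variance per component (whitening).
    """
    if features.X.shape[1] != model.n_input_columns:
        raise ValueError(
            f"feature matrix has {features.X.shape[1]} columns; model "
            f"was fitted on {model.n_input_columns}")
    Z = (features.X[:, model.kept_columns] - model.mean) / model.scale
    scores = Z @ model.components.T
    if model.whiten:
        # ddof=1 matches scikit-learn's explained_variance_ convention
        scores = scores / np.sqrt(model.explained_variance)
    out = features.metadata.copy()
    for k in range(scores.shape[1]):
        out[f"pc{k + 1}"] = scores[:, k]
    return out


def reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """De-whiten and invert the transform back to feature space
    (kept columns only)."""
    s = np.asarray(scores, dtype=float)
    if model.whiten:
        s = s * np.sqrt(model.explained_variance)
    return (s @ model.components) * model.scale + model.mean


def hbond_loading_rank(model: PCAModel, features: FeatureMatrix) -> dict:
    """Combined PC1-2 loading magnitude of the i -> i+3 H-bond proxy
    columns (O_i to N_{i+3} distances within the subgraph) vs all columns.

    Returns the proxy columns' mean loading, the median column loading,
    and their ratio — a ranking diagnostic for how strongly the turn
    coordinate is captured by the leading components.
    """
    load = np.sqrt(np.sum(model.components[:2] ** 2, axis=0))
    cols = [features.columns[k] for k in model.kept_columns]
    n_res = max(r for (r, _role), _ in cols)
    proxy = []
    for idx, ((ra, roa), (rb, rob)) in enumerate(cols):
        pair = {(ra, roa), (rb, rob)}
        for i in range(1, n_res - 2):
            if {(i, "O"), (i + 3, "N")} == pair:
                proxy.append(idx)
    if not proxy:
        raise ValueError("no i -> i+3 proxy columns in feature set")
    return {
        "proxy_mean_loading": float(load[proxy].mean()),
        "median_loading": float(np.median(load)),
        "ratio": float(load[proxy].mean() / np.median(load)),
        "proxy_columns": proxy,
    }


def depopulation_metric(metadata: pd.DataFrame,
                        threshold: float = 3.0,
                        stages: list[float] | None = None) -> pd.Series:
    """Per-stage fraction of frames whose canonical i -> i+3 H-bond
    distance is below threshold, ordered by stage.

    ``metadata`` is a FeatureMatrix.metadata or projection frame with
    "stage" and "hbond_distance" columns.
    """
    if stages is None:
        stages = sorted(metadata["stage"].unique())
    known = set(metadata["stage"].unique())
    unknown = [s for s in stages if s not in known]
    if unknown:
        raise ValueError(f"unknown stage label(s) {unknown}")
    out = {}
    for s in stages:
        sel = metadata[metadata["stage"] == s]
        out[s] = float((sel["hbond_distance"] < threshold).mean())
    return pd.Series(out, name="hbond_fraction")
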