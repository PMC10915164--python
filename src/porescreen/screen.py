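"""Real-sample screening cascade.

Events measured from a complex sample (fruit juice) are pushed through:

1. min-max scaling against the frozen training reference (the DBSCAN
   epsilon values only make sense in a normalized feature space);
2. DBSCAN denoising on the (blockage ratio, std) plane — background noise
   events are non-clustered by nature and are labeled noise;
3. a one-class SVM (radial-basis kernel, nu = 0.05) trained on the standard
   event library splits the kept events into inliers and outliers;
4. inliers are identified with the trained bagged-tree classifier;
5. outliers are re-clustered with DBSCAN: each surviving cluster is
   registered as an unidentified analyte (U1, U2, ... by descending size),
   and clusters can be matched against a separately measured reference
   (the sucrose workflow) with a second one-class SVM.

Per-sample DBSCAN presets: fresh juice eps 0.17 / min_samples 18, kiwifruit
0.1 / 10, commercial juice 0.3 / 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.svm import OneClassSVM

from .classify import ClassifierModel, predict
from .features import FEATURE_COLUMNS, FeatureMatrix

__all__ = [
    "ScreeningParams",
    "SCREENING_PRESETS",
    "FeatureScaler",
    "NoveltyModel",
    "ScreenResult",
    "scale_features",
    "dbscan_denoise",
    "fit_novelty",
    "split_inliers",
    "discover_unknowns",
    "match_cluster",
    "screen_sample",
]


@dataclass(frozen=True)
class ScreeningParams:
    """Cascade tuning: DBSCAN radius/density and one-class-SVM nu."""

    dbscan_eps: float = 0.17
    dbscan_min_samples: int = 18
    ocsvm_nu: float = 0.05
    denoise_features: tuple[str, ...] = ("ratio", "std")
    outlier_features: tuple[str, ...] = tuple(FEATURE_COLUMNS)

    def __post_init__(self) -> None:
        if self.dbscan_eps <= 0:
            raise ValueError("eps must be > 0")
        if self.dbscan_min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if not (0.0 < self.ocsvm_nu < 1.0):
            raise ValueError("nu must lie in (0, 1)")


SCREENING_PRESETS = {
    "fresh_juice": ScreeningParams(dbscan_eps=0.17, dbscan_min_samples=18),
    "kiwifruit": ScreeningParams(dbscan_eps=0.10, dbscan_min_samples=10),
    "commercial": ScreeningParams(dbscan_eps=0.30, dbscan_min_samples=30),
}


@dataclass(frozen=True)
class FeatureScaler:
    """Min-max scaling frozen to a training reference."""

    mins: pd.Series
    maxs: pd.Series

    @staticmethod
    def fit(reference: FeatureMatrix, features: tuple[str, ...] = tuple(FEATURE_COLUMNS)) -> "FeatureScaler":
        df = reference.data[list(features)]
        mins, maxs = df.min(), df.max()
        zero = maxs - mins == 0
        if zero.any():
            raise ValueError(f"zero-range reference features: {list(mins.index[zero])}")
        return FeatureScaler(mins=mins, maxs=maxs)

    def transform(self, matrix: FeatureMatrix, features: tuple[str, ...] | None = None) -> pd.DataFrame:
        cols = list(features) if features is not None else list(self.mins.index)
        sub = matrix.data[cols]
        return (sub - self.mins[cols]) / (self.maxs[cols] - self.mins[cols])


def scale_features(matrix: FeatureMatrix, reference: FeatureMatrix) -> pd.DataFrame:
    """Map each feature by (x - ref min) / (ref range); probes outside the
    reference range may exceed [0, 1] (no clipping)."""
    return FeatureScaler.fit(reference).transform(matrix)


@dataclass
class NoveltyModel:
    """One-class SVM boundary with its frozen scaling reference."""

    svm: OneClassSVM
    scaler: FeatureScaler
    features: tuple[str, ...]
    nu: float
    n_train: int
    metadata: dict = field(default_factory=dict)


def dbscan_denoise(
    scaled: pd.DataFrame, params: ScreeningParams
) -> tuple[np.ndarray, np.ndarray]:
    """DBSCAN noise removal on already-scaled features.

    Returns (kept mask, noise mask) over the rows; points DBSCAN labels as
    noise (-1) are the removed non-clustered background.
    """
    cols = [c for c in params.denoise_features if c in scaled.columns]
    X = scaled[cols].to_numpy(dtype=float)
    if X.shape[0] == 0:
        empty = np.zeros(0, dtype=bool)
        return empty, empty
    labels = DBSCAN(eps=params.dbscan_eps, min_samples=params.dbscan_min_samples).fit_predict(X)
    noise = labels == -1
    return ~noise, noise


def fit_novelty(
    train: FeatureMatrix, nu: float = 0.05, features: tuple[str, ...] = tuple(FEATURE_COLUMNS)
) -> NoveltyModel:
    """Fit the one-class SVM on the standard event library.

    All five features, min-max scaled to the training reference; RBF kernel
    with bandwidth from the feature variance (sklearn ``gamma='scale'``). By
    construction about a fraction ``nu`` of the training events fall outside
    the fitted boundary.
    """
    if len(train) < 50:
        raise ValueError(f"novelty training needs n >= 50, got {len(train)}")
    scaler = FeatureScaler.fit(train, features)
    X = scaler.transform(train, features).to_numpy(dtype=float)
    svm = OneClassSVM(kernel="rbf", gamma="scale", nu=nu)
    svm.fit(X)
    return NoveltyModel(
        svm=svm, scaler=scaler, features=tuple(features), nu=nu, n_train=len(train)
    )


def split_inliers(model: NoveltyModel, matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Partition rows into (inlier mask, outlier mask) under the trained
    boundary, using the model's frozen scaling."""
    if len(matrix) == 0:
        empty = np.zeros(0, dtype=bool)
        return empty, empty
    X = model.scaler.transform(matrix, model.features).to_numpy(dtype=float)
    pred = model.svm.predict(X)
    inlier = pred == 1
    return inlier, ~inlier


def discover_unknowns(
    outliers: FeatureMatrix, params: ScreeningParams, scaler: FeatureScaler
) -> dict[str, np.ndarray]:
    """Cluster the outlier events; register clusters as unidentified analytes.

    DBSCAN runs on the scaled denoise-feature plane. Each cluster is named
    U1, U2, ... by descending size (ties broken by first row index);
    unclustered outliers are discarded as noise. Returns name -> row indices
    (into ``outliers``).
    """
    if len(outliers) == 0:
        return {}
    cols = tuple(c for c in params.denoise_features)
    X = scaler.transform(outliers, cols).to_numpy(dtype=float)
    labels = DBSCAN(eps=params.dbscan_eps, min_samples=params.dbscan_min_samples).fit_predict(X)
    clusters = []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        idx = np.flatnonzero(labels == lab)
        clusters.append((len(idx), idx[0], idx))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    return {f"U{i + 1}": idx for i, (_, _, idx) in enumerate(clusters)}


def match_cluster(
    cluster: FeatureMatrix,
    reference_events: FeatureMatrix,
    nu: float = 0.05,
    accept_fraction: float = 0.5,
) -> bool:
    """Does an unknown cluster match a separately measured reference analyte?

    A one-class SVM is fitted on the reference events; the cluster matches
    iff at least ``accept_fraction`` of its events are judged inliers.
    """
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    model = fit_novelty(reference_events, nu=nu)
    inlier, _ = split_inliers(model, cluster)
    return float(inlier.mean()) >= accept_fraction


@dataclass
class ScreenResult:
    """Full cascade output with all masks retained for audit.

    Masks are over the original input rows; ``unknown_registry`` maps
    U-names to original row indices; ``proportions`` covers predicted
    classes and registered unknowns and sums to 1.
    """

    kept_mask: np.ndarray
    noise_mask: np.ndarray
    inlier_mask: np.ndarray
    outlier_mask: np.ndarray
    inlier_labels: np.ndarray          # aligned to inlier rows (original order)
    unknown_registry: dict[str, np.ndarray]
    proportions: dict[str, float]
    params: ScreeningParams

    @property
    def n_input(self) -> int:
        return self.kept_mask.size

    def conservation_ok(self) -> bool:
        n_clustered = sum(len(v) for v in self.unknown_registry.values())
        n_unclustered = int(self.outlier_mask.sum()) - n_clustered
        return (
            self.n_input
            == int(self.noise_mask.sum()) + int(self.inlier_mask.sum()) + n_clustered + n_unclustered
        )


def screen_sample(
    matrix: FeatureMatrix,
    classifier: ClassifierModel,
    novelty: NoveltyModel,
    params: ScreeningParams | None = None,
) -> ScreenResult:
    """Run the full cascade on one sample's event table.

    scale -> DBSCAN denoise -> inlier/outlier split -> classify inliers ->
    cluster outliers into unknowns -> per-class proportions over
    {predicted classes} union {registered unknowns}.
    """
    params = params or ScreeningParams()
    n = len(matrix)
    scaled = novelty.scaler.transform(matrix, novelty.features)
    kept_local, noise_local = dbscan_denoise(scaled, params)

    kept_idx = np.flatnonzero(kept_local)
    kept_mask = np.zeros(n, dtype=bool)
    kept_mask[kept_idx] = True
    noise_mask = ~kept_mask

    kept_fm = matrix.subset(kept_mask)
    in_local, out_local = split_inliers(novelty, kept_fm)
    inlier_mask = np.zeros(n, dtype=bool)
    outlier_mask = np.zeros(n, dtype=bool)
    inlier_mask[kept_idx[in_local]] = True
    outlier_mask[kept_idx[out_local]] = True

    inlier_fm = matrix.subset(inlier_mask)
    inlier_labels = predict(classifier, inlier_fm)

    outlier_fm = matrix.subset(outlier_mask)
    registry_local = discover_unknowns(outlier_fm, params, novelty.scaler)
    out_idx = np.flatnonzero(outlier_mask)
    registry = {name: out_idx[idx] for name, idx in registry_local.items()}

    tallies: dict[str, int] = {}
    for lab in inlier_labels:
        tallies[str(lab)] = tallies.get(str(lab), 0) + 1
    for name, idx in registry.items():
        tallies[name] = len(idx)
    total = sum(tallies.values())
    proportions = {k: v / total for k, v in tallies.items()} if total else {}

    return ScreenResult(
        kept_mask=kept_mask,
        noise_mask=noise_mask,
        inlier_mask=inlier_mask,
        outlier_mask=outlier_mask,
        inlier_labels=inlier_labels,
        unknown_registry=registry,
        proportions=proportions,
        params=params,
    )
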