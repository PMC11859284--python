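"""K-Means distance-threshold outlier analysis and contamination experiments.

Feature vectors are clustered with K-Means (default c = 3, one cluster per
expected motion type).  Each row's Euclidean distance to its nearest
centroid is computed; the outlier threshold is

    t = mu_d + 2 sigma_d

with mu_d / sigma_d the mean and population standard deviation of those
distances, and rows strictly beyond t are flagged.  Per-cluster mean and
max member distances describe cluster tightness.  A penalized variant of
the NT-Xent loss quantifies (diagnostically) how flagged anchors inflate
the contrastive denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .augment import AugmentConfig
from .contrastive import (
    NTXentConfig,
    PretrainConfig,
    ProjectorConfig,
    anchor_terms,
    pretrain,
)
from .encoder import EncoderConfig
from .landmarks import N_LANDMARKS, FeatureMatrix
from .probe import ProbeConfig, cross_validate
from .synth import MotionClassSpec, inject_outliers, outlier_class

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterModel",
    "OutlierReport",
    "kmeans",
    "nearest_centroid_distances",
    "outlier_threshold",
    "cluster_spread_stats",
    "flag_outliers",
    "analyze",
    "landmark_outlier_analysis",
    "penalized_nt_xent",
    "outlier_experiment",
]


@dataclass
class ClusterModel:
    n_clusters: int
    centroids: np.ndarray  # (c, d)
    assignments: np.ndarray  # per-row cluster index in [0, c)
    wcss: float  # within-cluster sum of squared distances


@dataclass
class OutlierReport:
    distances: np.ndarray
    threshold: float
    mean_distance: float
    sd_distance: float
    cluster_mean_distance: np.ndarray  # per-cluster mu_d^i
    cluster_max_distance: np.ndarray  # per-cluster M_d^i
    outlier_mask: np.ndarray
    outlier_fraction: float
    model: ClusterModel | None = None


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, FeatureMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=np.float64)


def kmeans(matrix, c: int = 3, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """Cluster rows into c groups minimizing WCSS (Lloyd, best of n_init)."""
    X = _as_array(matrix)
    if len(X) < c:
        raise ValueError(f"need at least c={c} rows, got {len(X)}")
    km = KMeans(n_clusters=c, n_init=n_init, random_state=seed % (2**32), algorithm="lloyd")
    assignments = km.fit_predict(X)
    return ClusterModel(
        n_clusters=c,
        centroids=km.cluster_centers_.astype(np.float64),
        assignments=assignments,
        wcss=float(km.inertia_),
    )


def nearest_centroid_distances(matrix, model: ClusterModel) -> np.ndarray:
    """Euclidean distance from each row to its closest centroid."""
    X = _as_array(matrix)
    diffs = X[:, None, :] - model.centroids[None, :, :]
    return np.sqrt((diffs**2).sum(axis=2)).min(axis=1)


def outlier_threshold(distances: np.ndarray) -> tuple[float, float, float]:
    """(t, mu_d, sigma_d) with t = mu_d + 2 sigma_d, population sigma."""
    d = np.asarray(distances, dtype=np.float64)
    if d.size == 0:
        raise ValueError("distances must be nonempty")
    mu = float(d.mean())
    sigma = float(d.std())  # population standard deviation (ddof=0)
    return mu + 2.0 * sigma, mu, sigma


def cluster_spread_stats(matrix, model: ClusterModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster mean and max member-to-own-centroid distance."""
    X = _as_array(matrix)
    dists = np.linalg.norm(X - model.centroids[model.assignments], axis=1)
    means = np.zeros(model.n_clusters)
    maxes = np.zeros(model.n_clusters)
    for i in range(model.n_clusters):
        members = dists[model.assignments == i]
        if members.size == 0:
            warnings.warn(f"cluster {i} is empty; stats reported as 0", stacklevel=2)
            continue
        means[i] = members.mean()
        maxes[i] = members.max()
    return means, maxes


def flag_outliers(distances: np.ndarray, threshold: float) -> tuple[np.ndarray, float]:
    """Strict rule: d > t is an outlier; boundary points are inliers."""
    d = np.asarray(distances, dtype=np.float64)
    mask = d > threshold
    return mask, float(mask.mean()) if d.size else 0.0


def analyze(
    matrix, c: int = 3, seed: int = 0, n_init: int = 10, model: ClusterModel | None = None
) -> OutlierReport:
    """Full distance-threshold audit of a feature matrix.

    By default the cluster model is fitted on ``matrix`` itself (in-sample
    audit).  Pass a ``model`` fitted on reference data to score new frames
    against known-clean structure — with heavy, concentrated contamination an
    in-sample fit can absorb the contaminant into its own cluster, so the
    reference-model form is preferred when clean data are available.
    """
    if model is None:
        model = kmeans(matrix, c=c, seed=seed, n_init=n_init)
    X = _as_array(matrix)
    dist_all = np.sqrt(((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2))
    distances = dist_all.min(axis=1)
    # re-derive assignments so stats stay valid when scoring with a model
    # fitted on different (reference) data
    scored = ClusterModel(
        n_clusters=model.n_clusters,
        centroids=model.centroids,
        assignments=dist_all.argmin(axis=1),
        wcss=float((distances**2).sum()),
    )
    t, mu, sigma = outlier_threshold(distances)
    means, maxes = cluster_spread_stats(X, scored)
    mask, frac = flag_outliers(distances, t)
    return OutlierReport(
        distances=distances,
        threshold=t,
        mean_distance=mu,
        sd_distance=sigma,
        cluster_mean_distance=means,
        cluster_max_distance=maxes,
        outlier_mask=mask,
        outlier_fraction=frac,
        model=scored,
    )


def landmark_outlier_analysis(matrix, c: int = 3, seed: int = 0) -> dict:
    """Run the audit independently on each landmark's (x, y, z) sub-vector.

    Some outlier motions move only a few joints, so a whole-vector audit can
    miss them; auditing per landmark localizes the deviation.  The aggregate
    ``pct_outlier_landmarks`` is the mean flagged fraction across the ten
    landmark-level audits; mean/max outlier distance summarize the distances
    of all flagged landmark observations.
    """
    X = _as_array(matrix)
    fractions = np.empty(N_LANDMARKS)
    flagged_distances: list[np.ndarray] = []
    reports = []
    for j in range(N_LANDMARKS):
        sub = X[:, 3 * j : 3 * j + 3]
        report = analyze(sub, c=c, seed=seed)
        fractions[j] = report.outlier_fraction
        flagged_distances.append(report.distances[report.outlier_mask])
        reports.append(report)
    flagged = np.concatenate(flagged_distances) if flagged_distances else np.empty(0)
    return {
        "per_landmark_fraction": fractions,
        "pct_outlier_landmarks": float(fractions.mean()),
        "mean_outlier_distance": float(flagged.mean()) if flagged.size else 0.0,
        "max_outlier_distance": float(flagged.max()) if flagged.size else 0.0,
        "reports": reports,
    }


def penalized_nt_xent(
    z1: np.ndarray,
    z2: np.ndarray,
    temperature: float,
    omega: np.ndarray,
    lam: float,
    delta: float = 1.0,
) -> float:
    """Outlier-penalized NT-Xent diagnostic.

    For anchors flagged as outliers (omega = 1) the contrastive denominator
    gains an additive term lambda * delta, where lambda is the mean
    outlier-to-centroid distance and delta a weight; with omega = 0
    everywhere the value reduces exactly to the unpenalized loss.  This is
    an analysis tool — training always minimizes the unpenalized loss.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    lse, pos = anchor_terms(z1, z2, temperature)
    b = len(lse) // 2
    omega = np.asarray(omega, dtype=np.float64)
    if omega.shape == (b,):
        omega = np.tile(omega, 2)  # both views of a sample share its flag
    if omega.shape != (2 * b,):
        raise ValueError(f"omega must have length {b} or {2 * b}")
    pen = lam * delta * omega
    log_denom = lse.copy()
    hit = pen > 0
    log_denom[hit] = np.logaddexp(lse[hit], np.log(pen[hit]))
    return float(np.mean(log_denom - pos))


@dataclass
class OutlierExperimentRow:
    n_outliers: int
    pct_outlier_landmarks: float
    mean_outlier_distance: float
    max_outlier_distance: float
    accuracy: float
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "n_outliers": self.n_outliers,
            "pct_outlier_landmarks": self.pct_outlier_landmarks,
            "mean_outlier_distance": self.mean_outlier_distance,
            "max_outlier_distance": self.max_outlier_distance,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def outlier_experiment(
    matrix: FeatureMatrix,
    outlier_counts: list[int],
    outlier_spec: MotionClassSpec | None = None,
    encoder_config: EncoderConfig = EncoderConfig(),
    projector_config: ProjectorConfig = ProjectorConfig(),
    ntxent_config: NTXentConfig = NTXentConfig(),
    pretrain_config: PretrainConfig = PretrainConfig(),
    probe_config: ProbeConfig = ProbeConfig(),
    augment_config: AugmentConfig = AugmentConfig(),
    seed: int = 0,
) -> list[OutlierExperimentRow]:
    """Contamination study: inject outliers, pretrain, probe, audit.

    For each count, outlier-motion frames are appended to the *pretraining*
    data (the labeled probe data stays clean), the full pipeline is rerun,
    and the per-landmark outlier audit plus held-out classification metrics
    are reported.  The count-0 row is the uncontaminated pipeline.
    """
    if matrix.labels is None:
        raise ValueError("labeled base matrix required")
    if outlier_spec is None:
        outlier_spec = outlier_class()
    rows: list[OutlierExperimentRow] = []
    for count in outlier_counts:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 4, count)))
        contaminated, _ = inject_outliers(matrix, outlier_spec, count, rng)
        audit = landmark_outlier_analysis(contaminated, c=3, seed=seed)
        result = pretrain(
            contaminated,
            encoder_config,
            projector_config,
            ntxent_config,
            pretrain_config,
            augment_config,
        )
        _, mean_metrics = cross_validate(result.encoder, matrix, probe_config)
        rows.append(
            OutlierExperimentRow(
                n_outliers=count,
                pct_outlier_landmarks=audit["pct_outlier_landmarks"],
                mean_outlier_distance=audit["mean_outlier_distance"],
                max_outlier_distance=audit["max_outlier_distance"],
                accuracy=mean_metrics.accuracy,
                precision=mean_metrics.precision,
                recall=mean_metrics.recall,
                f1=mean_metrics.f1,
            )
        )
        logger.info(
            "outlier experiment: count=%d accuracy=%.3f pct_outlier_landmarks=%.3f",
            count,
            rows[-1].accuracy,
            rows[-1].pct_outlier_landmarks,
        )
    return rows
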