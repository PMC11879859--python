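"""Bootstrap projection of trial participants onto reference clusters.

The pathophysiological subgroups (MARD-, SIRD-, MOD-, SIDD-like) come from
k-means clustering of a large reference cohort on five continuous clinical
features (BMI, age, fasting glucose, C-peptide, HbA1c).  GADA status, a
binary feature of the source model, is uniformly negative in this trial
population and is therefore excluded from the distance computation.

Procedure: features are z-scored against the reference cohort; a canonical
k-means model is fitted to the full standardized reference; then, in each of
B bootstrap rounds, 60% of the reference is subsampled without replacement
and re-clustered, the round's centroids are matched to the canonical ones by
minimum-cost bipartite (Hungarian) matching, and every trial participant is
assigned to the nearest round centroid in standardized Euclidean space.
Per-participant assignment counts over the B rounds give the modal cluster
and a cluster alignment score max(count)/B ∈ (0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .datamodel import DomainError

log = logging.getLogger("bsetrial")

DEFAULT_FEATURES = ("bmi", "age", "glucose", "c_peptide", "hba1c")


@dataclass
class FeatureSpec:
    names: tuple = DEFAULT_FEATURES
    transforms: dict = field(default_factory=dict)  # name -> callable

    def __post_init__(self) -> None:
        if not self.names:
            raise DomainError("feature names must be nonempty")
        if len(set(self.names)) != len(self.names):
            raise DomainError("feature names must be unique")

    def matrix(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.names if f not in table.columns]
        if missing:
            raise DomainError(f"missing clustering features: {missing}")
        cols = []
        for name in self.names:
            col = table[name].to_numpy(dtype=float)
            if name in self.transforms:
                col = self.transforms[name](col)
            cols.append(col)
        x = np.column_stack(cols)
        if np.isnan(x).any():
            rows = np.flatnonzero(np.isnan(x).any(axis=1))
            raise DomainError(
                f"missing feature values in rows {rows.tolist()[:10]}"
            )
        return x


@dataclass
class ScalingParams:
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise DomainError("scaling SDs must be positive")

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd


@dataclass
class ClusterModel:
    k: int
    canonical_centroids: np.ndarray       # k × p, standardized space
    labels: tuple                          # cluster names, canonical order
    scaling: ScalingParams
    feature_spec: FeatureSpec


@dataclass
class AssignmentResult:
    """Per-participant bootstrap assignment summary (one row each)."""

    table: pd.DataFrame  # counts per cluster, modal_label, alignment_score, tie

    @property
    def alignment_scores(self) -> pd.Series:
        return self.table["alignment_score"]

    @property
    def modal_labels(self) -> pd.Series:
        return self.table["modal_label"]


def _check_reference(x: np.ndarray, k: int, names: Sequence[str]) -> None:
    if x.shape[0] < k:
        raise DomainError(f"reference has {x.shape[0]} rows < k={k}")
    sds = x.std(axis=0, ddof=0)
    zero = [names[i] for i in np.flatnonzero(sds == 0)]
    if zero:
        raise DomainError(f"zero-variance clustering feature(s): {zero}")
    if np.unique(x, axis=0).shape[0] < k:
        raise DomainError("fewer distinct reference points than k")


def _kmeans(z: np.ndarray, k: int, seed, n_init: int = 10) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                max_iter=300, tol=1e-6, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km.fit(z)
    return km.cluster_centers_


def fit_canonical_model(reference: pd.DataFrame, k: int,
                        feature_spec: Optional[FeatureSpec] = None,
                        seed: int = 0,
                        labels: Optional[Sequence[str]] = None) -> ClusterModel:
    """Standardize the reference cohort, k-means it (10 restarts), and
    return the canonical model.

    Canonical centroid order is lexicographic over the standardized centroid
    coordinates (first feature primary), a deterministic rule independent of
    k-means label arbitrariness.  Optional ``labels`` name the clusters in
    that canonical order.
    """
    feature_spec = feature_spec or FeatureSpec()
    x = feature_spec.matrix(reference)
    _check_reference(x, k, feature_spec.names)
    scaling = ScalingParams(mean=x.mean(axis=0), sd=x.std(axis=0, ddof=0))
    z = scaling.transform(x)
    centroids = _kmeans(z, k, seed)
    order = np.lexsort(centroids.T[::-1])  # sort rows by first column, then next
    centroids = centroids[order]
    if labels is None:
        labels = tuple(f"cluster_{i}" for i in range(k))
    elif len(labels) != k:
        raise DomainError("labels length must equal k")
    return ClusterModel(k=k, canonical_centroids=centroids, labels=tuple(labels),
                        scaling=scaling, feature_spec=feature_spec)


def match_to_canonical(round_centroids: np.ndarray,
                       canonical: np.ndarray) -> np.ndarray:
    """Reorder round centroids to canonical cluster identity by Hungarian
    matching on Euclidean cost."""
    cost = cdist(canonical, round_centroids)
    rows, cols = linear_sum_assignment(cost)
    out = np.empty_like(round_centroids)
    out[rows] = round_centroids[cols]
    return out


def bootstrap_round(reference_z: np.ndarray, model: ClusterModel,
                    subsample_frac: float, rng: np.random.Generator,
                    n_init: int = 10, max_retries: int = 20) -> np.ndarray:
    """One bootstrap round: subsample floor(frac·n) reference rows without
    replacement, k-means the subsample, and return centroids matched to the
    canonical order."""
    if not 0 < subsample_frac <= 1:
        raise DomainError("subsample_frac must be in (0, 1]")
    n = reference_z.shape[0]
    m = int(np.floor(subsample_frac * n))
    if m < model.k:
        raise DomainError("subsample smaller than k")
    for attempt in range(max_retries):
        idx = rng.choice(n, size=m, replace=False)
        sub = reference_z[idx]
        if np.unique(sub, axis=0).shape[0] >= model.k:
            break
        log.warning("bootstrap subsample had < k distinct points; redrawing")
    else:
        raise DomainError("could not draw a subsample with k distinct points")
    seed = int(rng.integers(2**31 - 1))
    centroids = _kmeans(sub, model.k, seed, n_init=n_init)
    return match_to_canonical(centroids, model.canonical_centroids)


def assign_nearest(participants: pd.DataFrame | np.ndarray,
                   centroids: np.ndarray,
                   scaling: Optional[ScalingParams] = None,
                   feature_spec: Optional[FeatureSpec] = None) -> np.ndarray:
    """Nearest-centroid assignment in standardized space; ties break to the
    lowest canonical cluster index."""
    if isinstance(participants, pd.DataFrame):
        feature_spec = feature_spec or FeatureSpec()
        x = feature_spec.matrix(participants)
    else:
        x = np.asarray(participants, dtype=float)
    z = scaling.transform(x) if scaling is not None else x
    d = cdist(z, centroids)
    # argmin returns the first (lowest-index) minimizer: the documented tie rule
    assign = d.argmin(axis=1)
    ties = (d == d[np.arange(len(z)), assign][:, None]).sum(axis=1) > 1
    if ties.any():
        log.info("tie-broken nearest-centroid assignments: %d", int(ties.sum()))
    return assign


def run_bootstrap_assignment(reference: pd.DataFrame, participants: pd.DataFrame,
                             k: int = 4, B: int = 1000, subsample_frac: float = 0.6,
                             seed: int = 0,
                             feature_spec: Optional[FeatureSpec] = None,
                             labels: Optional[Sequence[str]] = None,
                             n_init: int = 10) -> tuple[ClusterModel, AssignmentResult]:
    """Full bootstrap assignment: canonical fit, B matched bootstrap rounds,
    per-participant counts, modal label and alignment score."""
    if B < 1:
        raise DomainError("B must be >= 1")
    model = fit_canonical_model(reference, k, feature_spec, seed=seed, labels=labels)
    ref_z = model.scaling.transform(model.feature_spec.matrix(reference))
    part_z = model.scaling.transform(model.feature_spec.matrix(participants))
    rng = np.random.default_rng(seed)
    counts = np.zeros((part_z.shape[0], k), dtype=int)
    for _ in range(B):
        centroids = bootstrap_round(ref_z, model, subsample_frac, rng,
                                    n_init=n_init)
        assign = assign_nearest(part_z, centroids)
        counts[np.arange(len(assign)), assign] += 1
    modal = counts.argmax(axis=1)
    tie = (counts == counts.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if tie.any():
        log.warning("modal-label ties for %d participants (lowest index used)",
                    int(tie.sum()))
    table = pd.DataFrame(counts, columns=[f"count_{lab}" for lab in model.labels])
    if "participant_id" in participants.columns:
        table.insert(0, "participant_id",
                     participants["participant_id"].to_numpy())
    table["modal_label"] = [model.labels[i] for i in modal]
    table["alignment_score"] = counts.max(axis=1) / B
    table["modal_tie"] = tie
    return model, AssignmentResult(table=table)
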