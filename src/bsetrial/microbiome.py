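"""Community- and gene-level microbiome statistics.

Implements the statistical layer applied to the trial's faecal metagenomes:
Bray–Curtis dissimilarity at the species level, principal coordinates
(classical metric scaling), one-factor PERMANOVA with seeded permutations,
the two-group permutation test used for BT2160 operon abundance, per-sample
gene richness, and the within-group dissimilarity (dispersion) change test.

Permutation p-values follow the add-one convention (1 + b)/(1 + m) so that
p is never 0; the gene test additionally reports the literal proportion of
permuted statistics at least as extreme as the observed one.  For small
samples both tests switch to exhaustive enumeration of all distinct label
arrangements.  Bray–Curtis is a semimetric: the triangle inequality is not
guaranteed and is not asserted anywhere.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datamodel import DomainError


@dataclass
class AbundanceTable:
    """Samples × features relative abundances with per-sample metadata."""

    values: pd.DataFrame                 # index: sample ids, columns: feature ids
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise DomainError("sample ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise DomainError("abundances must be non-negative")
        if len(self.metadata) and not self.metadata.index.equals(self.values.index):
            self.metadata = self.metadata.reindex(self.values.index)

    @property
    def sample_ids(self):
        return self.values.index

    @property
    def feature_ids(self):
        return self.values.columns


def bray_curtis(table: AbundanceTable | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarity d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)."""
    if isinstance(table, AbundanceTable):
        values = table.values.to_numpy(dtype=float)
        ids = list(table.sample_ids)
    elif isinstance(table, pd.DataFrame):
        values, ids = table.to_numpy(dtype=float), list(table.index)
    else:
        values, ids = np.asarray(table, dtype=float), None
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        bad = [ids[i] if ids else i for i in np.flatnonzero(totals <= 0)]
        raise DomainError(f"samples with zero total abundance: {bad}")
    return squareform(pdist(values, metric="braycurtis"))


@dataclass
class PCoAResult:
    coordinates: np.ndarray       # n × n_axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray       # all eigenvalues, non-increasing (incl. negatives)
    proportion_explained: np.ndarray


def pcoa(d: np.ndarray, n_axes: Optional[int] = None) -> PCoAResult:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centres the Gower matrix −½ J D² J, eigendecomposes it, and
    scales eigenvectors by √eigenvalue.  Axes with non-positive eigenvalues
    (possible for semimetrics like Bray–Curtis) are reported in the
    eigenvalue vector but dropped from the coordinates.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2 or d.shape[0] != d.shape[1]:
        raise DomainError("need a square dissimilarity matrix with n >= 2")
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12 * abs(eigval[0]), 0)
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating"
        )
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    denom = eigval[eigval > 0].sum()
    prop = np.where(eigval > 0, eigval / denom if denom > 0 else 0.0, 0.0)
    return PCoAResult(coordinates=coords, eigenvalues=eigval,
                      proportion_explained=prop)


def _pseudo_f(d2: np.ndarray, groups: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances (one factor)."""
    n = d2.shape[0]
    labels, counts = np.unique(groups, return_counts=True)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for lab, cnt in zip(labels, counts):
        idx = np.flatnonzero(groups == lab)
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(cnt, 1)].sum() / cnt
    ssa = sst - ssw
    a = len(labels)
    if ssw == 0:  # perfectly separated groups
        return np.inf
    return (ssa / (a - 1)) / (ssw / (n - a))


def permanova(d: np.ndarray, groups, n_perm: int = 10_000,
              seed: int = 0) -> tuple[float, float]:
    """One-factor PERMANOVA on a distance matrix.

    Returns ``(pseudo_F, p)`` with p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)
    under random permutation of group labels; deterministic under ``seed``.
    """
    d = np.asarray(d, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise DomainError("PERMANOVA needs at least 2 groups")
    if np.any(counts < 1):
        raise DomainError("every group must be nonempty")
    d2 = d**2
    f_obs = _pseudo_f(d2, groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _pseudo_f(d2, rng.permutation(groups)) >= f_obs
    return float(f_obs), (1 + hits) / (1 + n_perm)


def gene_permutation_test(abundance, groups, n_perm: int = 10_000, seed: int = 0,
                          alternative: str = "two-sided",
                          exhaustive: Optional[bool] = None) -> dict:
    """Two-group permutation test on the difference in mean abundance.

    The statistic is mean(group A) − mean(group B).  Significance is the
    proportion of permuted statistics at least as extreme as the observed
    one (two-sided on |difference| by default; ``greater``/``less`` for
    one-sided).  Returns both the literal proportion (``p_proportion``) and
    the add-one variant (``p``).  Small samples (≤ 8 by default) are
    enumerated exhaustively over all group splits.
    """
    x = np.asarray(abundance, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise DomainError("gene permutation test needs exactly 2 groups")
    n = x.size
    na = int((groups == labels[0]).sum())
    if na == 0 or na == n:
        raise DomainError("both groups must be nonempty")

    def stat(mask_a: np.ndarray) -> float:
        return x[mask_a].mean() - x[~mask_a].mean()

    obs = stat(groups == labels[0])
    if np.ptp(x) == 0:
        warnings.warn("constant abundance: permutation test degenerate, p = 1")
        return {"observed": float(obs), "p": 1.0, "p_proportion": 1.0,
                "n_perm": 0, "exhaustive": True}

    def extreme(s: float) -> bool:
        if alternative == "two-sided":
            return abs(s) >= abs(obs) - 1e-12
        if alternative == "greater":
            return s >= obs - 1e-12
        if alternative == "less":
            return s <= obs + 1e-12
        raise DomainError("alternative must be two-sided/greater/less")

    if exhaustive is None:
        exhaustive = n <= 8
    if exhaustive:
        hits = total = 0
        for combo in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            total += 1
            hits += extreme(stat(mask))
        # the observed arrangement is in the enumeration, so hits >= 1 and
        # the exact p needs no add-one correction
        return {"observed": float(obs), "p": hits / total,
                "p_proportion": hits / total, "n_perm": total,
                "exhaustive": True}
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=na, replace=False)] = True
        hits += extreme(stat(mask))
    return {"observed": float(obs), "p": (1 + hits) / (1 + n_perm),
            "p_proportion": hits / n_perm, "n_perm": n_perm,
            "exhaustive": False}


def gene_richness(table: AbundanceTable | pd.DataFrame,
                  detection_threshold: float = 0.0) -> pd.Series:
    """Per-sample count of features with abundance strictly above the
    detection threshold."""
    if detection_threshold < 0:
        raise DomainError("detection threshold must be >= 0")
    values = table.values if isinstance(table, AbundanceTable) else table
    return (values > detection_threshold).sum(axis=1)


def dispersion_change(d: np.ndarray, group_mask, timepoints, n_perm: int = 10_000,
                      seed: int = 0, post_label: Optional[str] = None) -> dict:
    """Change in mean pairwise within-group dissimilarity, post − pre.

    ``timepoints`` holds two labels; ``post_label`` names the
    post-treatment one (default ``"post"`` when present, otherwise it must
    be given).  p is obtained by permuting timepoint labels within the group
    (exhaustive for ≤ 8 group samples).  A negative statistic means the
    group's samples became more similar to each other after treatment.
    """
    d = np.asarray(d, dtype=float)
    group_mask = np.asarray(group_mask, dtype=bool)
    timepoints = np.asarray(timepoints)
    idx = np.flatnonzero(group_mask)
    tp = timepoints[idx]
    labs = np.unique(tp)
    if len(labs) != 2:
        raise DomainError("need exactly two timepoint labels within the group")
    if post_label is None:
        if "post" not in labs:
            raise DomainError(
                f"ambiguous timepoints {labs.tolist()}: pass post_label")
        post_label = "post"
    elif post_label not in labs:
        raise DomainError(f"post_label {post_label!r} not among {labs.tolist()}")
    post_lab = post_label
    sub = d[np.ix_(idx, idx)]
    m = len(idx)
    n_post = int((tp == post_lab).sum())
    if n_post < 2 or m - n_post < 2:
        raise DomainError("need >= 2 samples per timepoint in the group")

    def stat(post_mask: np.ndarray) -> float:
        def mean_within(mask):
            k = mask.sum()
            block = sub[np.ix_(np.flatnonzero(mask), np.flatnonzero(mask))]
            return block[np.triu_indices(k, 1)].mean()
        return mean_within(post_mask) - mean_within(~post_mask)

    obs = stat(tp == post_lab)
    if m <= 8:
        hits = total = 0
        for combo in itertools.combinations(range(m), n_post):
            mask = np.zeros(m, dtype=bool)
            mask[list(combo)] = True
            total += 1
            hits += abs(stat(mask)) >= abs(obs) - 1e-12
        return {"statistic": float(obs), "p": hits / total, "exhaustive": True}
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        mask = np.zeros(m, dtype=bool)
        mask[rng.choice(m, size=n_post, replace=False)] = True
        hits += abs(stat(mask)) >= abs(obs) - 1e-12
    return {"statistic": float(obs), "p": (1 + hits) / (1 + n_perm),
            "exhaustive": False}
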