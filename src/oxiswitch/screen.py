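"""Feature-FTOE correlation screening and multivariate structure analysis.

Per-feature Pearson correlations against FTOE are pooled over all
patient-timepoint samples; significance uses the raw two-sided p from the
t-distribution (n-2 df) with the strict p < 0.05 and |r| > 0.5 rule, with
no multiple-testing correction.  Multivariate views are PCA on autoscaled
intensities and Euclidean/Ward hierarchical clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from oxiswitch.errors import ValidationError
from oxiswitch.peaktable import STUDY, FeatureTable, PipelineConfig

CLASS_POSITIVE = "positive"
CLASS_NEGATIVE = "negative"
CLASS_NONSIG = "nonsignificant"


def pearson_with_ftoe(
    table: FeatureTable, ftoe: dict[tuple[str, str], float]
) -> pd.DataFrame:
    """Per-feature Pearson r and two-sided p against FTOE.

    ``ftoe`` maps ``(patient_id, timepoint)`` to the FTOE value; every
    study sample in the table must be matched.  Constant features get
    NaN r/p and a ``constant`` flag.  Returns a data frame with columns
    ``feature_id, mz, rt, mode, r, p, n, constant``.
    """
    study_mask = table.role_mask(STUDY)
    study = [inj for inj in table.injections if inj.role == STUDY]
    unmatched = [
        (inj.patient_id, inj.timepoint)
        for inj in study
        if (inj.patient_id, inj.timepoint) not in ftoe
    ]
    if unmatched:
        raise ValidationError(f"study samples without FTOE value: {sorted(set(unmatched))}")
    y = np.array([ftoe[(inj.patient_id, inj.timepoint)] for inj in study], dtype=float)
    n = y.size
    if n < 3:
        raise ValidationError(f"need at least 3 study samples, got {n}")
    X = table.intensities[:, study_mask]

    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    constant = sx == 0
    r = np.full(X.shape[0], np.nan)
    if sy == 0:
        constant[:] = True
    else:
        ok = ~constant
        r[ok] = (Xc[ok] @ yc) / (sx[ok] * sy)
    r = np.clip(r, -1.0, 1.0)
    p = np.full_like(r, np.nan)
    ok = ~np.isnan(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r[ok] * np.sqrt((n - 2) / (1.0 - r[ok] ** 2))
    p_ok = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p_ok[np.abs(r[ok]) >= 1.0] = 0.0
    p[ok] = np.minimum(p_ok, 1.0)

    frame = table.features_frame()
    frame["r"] = r
    frame["p"] = p
    frame["n"] = n
    frame["constant"] = constant
    return frame


def classify_significant(results: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Partition features into positive / negative / nonsignificant.

    Strict inequalities: significant iff p < ``corr_p_threshold`` and
    |r| > ``corr_r_threshold``; the sign of r picks the class.
    """
    config = config or PipelineConfig()
    out = results.copy()
    r = out["r"].to_numpy()
    p = out["p"].to_numpy()
    sig = (p < config.corr_p_threshold) & (np.abs(r) > config.corr_r_threshold)
    cls = np.where(sig & (r > 0), CLASS_POSITIVE, np.where(sig, CLASS_NEGATIVE, CLASS_NONSIG))
    cls[~np.isfinite(r) | ~np.isfinite(p)] = CLASS_NONSIG
    out["class"] = cls
    return out


def autoscale(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each row (feature) to mean 0, sample sd 1.

    Zero-variance rows become all-zero and are flagged.  Returns
    ``(scaled, zero_variance_flags)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValidationError("autoscale needs a 2-D matrix with >= 2 samples")
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    scaled = (matrix - mean) / sd
    scaled[flat, :] = 0.0
    return scaled, flat


@dataclass
class ScoresMatrix:
    """PCA sample scores with explained-variance fractions."""

    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray  # components x features

    def __post_init__(self):
        evf = self.explained_variance_fraction
        if np.any(np.diff(evf) > 1e-12) or evf.sum() > 1 + 1e-9:
            raise ValidationError("explained-variance fractions must be nonincreasing, sum <= 1")


def pca_scores(matrix: np.ndarray, n_components: int = 2, sample_ids=None) -> ScoresMatrix:
    """PCA scores of the samples (columns) of an autoscaled matrix.

    Computed by singular value decomposition of the sample-centered data.
    Deterministic sign convention: the largest-magnitude loading of each
    component is made positive.
    """
    matrix = np.asarray(matrix, dtype=float)
    X = matrix.T  # samples x features
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; truncating", stacklevel=2
        )
        n_components = max(rank, 1)
    # sign convention
    for k in range(min(n_components, Vt.shape[0])):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U[:, :n_components] * s[:n_components]
    total = (s**2).sum()
    evf = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n_samples)]
    return ScoresMatrix(list(sample_ids), scores, evf, Vt[:n_components])


def ward_cluster(matrix: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of samples (columns), Euclidean + Ward.

    Returns ``(labels, linkage_matrix)`` where labels are the k-cluster
    cut (1-based, scipy convention).
    """
    if k < 1:
        raise ValidationError("cluster count k must be >= 1")
    X = np.asarray(matrix, dtype=float).T  # samples x features
    if X.shape[0] < k:
        raise ValidationError(f"need at least k={k} samples, got {X.shape[0]}")
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return labels, Z


def dendrogram_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    n = len(leaf_names)
    nodes: dict[int, str] = {i: leaf_names[i] for i in range(n)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    for row_idx, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + row_idx] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + row_idx] = h
    return nodes[n + len(Z) - 1] + ";"
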