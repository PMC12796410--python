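"""Dimensionality reduction and hierarchical clustering of network profiles.

The per-band feature table holds 10 columns per participant (the five graph
metrics, pre and post).  Features are z-scored (sample SD, ddof=1), checked
for sampling adequacy (KMO, Bartlett's sphericity), reduced to two principal
components of the feature correlation matrix, and clustered with Ward's
minimum-variance method on Euclidean distances.  Cluster-count evidence
(inertia elbow, silhouette) is emitted, not auto-selected.  Cluster
reliability is quantified by bootstrap subsampling with per-cluster mean
Jaccard overlap against the reference solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2 as chi2_dist
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "PCAResult",
    "ClusterSolution",
    "StabilityReport",
    "zscore",
    "kmo",
    "bartlett_sphericity",
    "pca2",
    "ward_cluster",
    "bootstrap_stability",
    "stability_category",
]


@dataclass
class FeatureTable:
    """Z-scored participants x features matrix for one band."""

    values: pd.DataFrame  # index = participant ids, columns = feature names
    band: str = ""

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def zscore(features: pd.DataFrame, band: str = "") -> FeatureTable:
    """Columnwise (x - mean) / SD standardization with sample SD (ddof=1).

    A constant column cannot be standardized and raises, naming the column.
    """
    if features.shape[0] < 2:
        raise ValueError("need at least 2 participants to z-score")
    if features.isna().any().any():
        raise ValueError("feature table contains missing values")
    sd = features.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant feature column(s): {constant}")
    z = (features - features.mean()) / sd
    return FeatureTable(values=z, band=band)


def _correlation(z: pd.DataFrame) -> np.ndarray:
    return np.corrcoef(z.to_numpy(), rowvar=False)


def kmo(features: FeatureTable) -> tuple[float, bool]:
    """Overall Kaiser-Meyer-Olkin sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i < j, where q are the
    partial correlations obtained from the inverse correlation matrix,
    q_ij = -A_ij / sqrt(A_ii A_jj).  Returns ``(kmo, used_pseudoinverse)``;
    a singular correlation matrix falls back to the Moore-Penrose inverse
    with a logged warning.
    """
    R = _correlation(features.values)
    p = R.shape[0]
    pseudo = False
    try:
        A = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(R)
        pseudo = True
    if not pseudo and features.n <= features.n_features:
        logger.warning(
            "fewer participants (%d) than features (%d): KMO unstable",
            features.n,
            features.n_features,
        )
    d = np.sqrt(np.abs(np.diag(A)))
    Q = -A / np.outer(d, d)
    iu = np.triu_indices(p, k=1)
    r2 = float((R[iu] ** 2).sum())
    q2 = float((Q[iu] ** 2).sum())
    value = r2 / (r2 + q2) if (r2 + q2) > 0 else 0.0
    return float(np.clip(value, 0.0, 1.0)), pseudo


def bartlett_sphericity(features: FeatureTable) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln|R|, df = p(p-1)/2; upper-tail p-value.
    """
    R = _correlation(features.values)
    n, p = features.n, features.n_features
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    stat = max(stat, 0.0)
    df = p * (p - 1) // 2
    pval = float(chi2_dist.sf(stat, df))
    return float(stat), df, pval


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # features x 2, unit-norm columns
    scores: pd.DataFrame  # participants x 2 (PC1, PC2)
    explained_variance_ratio: np.ndarray  # full spectrum, nonincreasing
    kmo: float
    kmo_pseudoinverse: bool
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def pca2(features: FeatureTable) -> PCAResult:
    """Two-component PCA on the feature correlation matrix.

    Eigendecomposition of R; loadings are the two leading unit-norm
    eigenvectors with the sign fixed so each vector's largest-magnitude
    entry is positive; scores are the z-scored data projected onto them.
    The explained-variance spectrum over *all* components is returned.
    """
    if features.n_features < 2 or features.n < 3:
        raise ValueError("pca2 needs >= 2 features and >= 3 participants")
    R = _correlation(features.values)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    if eigval[1] <= 1e-12:
        raise ValueError("feature matrix has rank < 2")
    ratios = eigval / eigval.sum()
    load = eigvec[:, :2].copy()
    for c in range(2):
        j = int(np.argmax(np.abs(load[:, c])))
        if load[j, c] < 0:
            load[:, c] *= -1
    # re-standardize defensively so scores are exactly zero-mean even if the
    # caller passed a not-quite-standardized table
    raw = features.values.to_numpy()
    Z = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
    scores = Z @ load
    kmo_val, pseudo = kmo(features)
    try:
        chi2, df, pval = bartlett_sphericity(features)
    except ValueError:
        # singular correlation matrix (e.g. fewer participants than
        # features): sphericity is undefined, flag with NaN
        logger.warning("Bartlett sphericity undefined: singular correlation")
        chi2, df, pval = float("nan"), features.n_features * (
            features.n_features - 1
        ) // 2, float("nan")
    cols = ["PC1", "PC2"]
    return PCAResult(
        loadings=pd.DataFrame(load, index=features.values.columns, columns=cols),
        scores=pd.DataFrame(scores, index=features.values.index, columns=cols),
        explained_variance_ratio=ratios,
        kmo=kmo_val,
        kmo_pseudoinverse=pseudo,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
    )


@dataclass
class ClusterSolution:
    labels: np.ndarray  # 1..k, ordered by descending cluster size
    k: int
    linkage_tree: np.ndarray  # scipy linkage matrix
    inertia_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    labels_by_k: dict[int, np.ndarray] = field(default_factory=dict)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..k by descending size; ties by lowest member index."""
    ids = np.unique(labels)
    order = sorted(
        ids, key=lambda c: (-int((labels == c).sum()), int(np.argmax(labels == c)))
    )
    out = np.empty_like(labels)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def _inertia(x: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def ward_cluster(
    scores: np.ndarray | pd.DataFrame,
    k: int = 2,
    k_range: range = range(2, 9),
) -> ClusterSolution:
    """Ward/Euclidean agglomerative clustering with model-selection curves.

    Returns labels for the configured ``k`` plus inertia (within-cluster sum
    of squares) and mean silhouette for every k in ``k_range`` with k < n.
    The cluster count is a configuration input by design — the curves are
    evidence for the analyst, not an automatic selector.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    tree = linkage(x, method="ward")
    inertia_by_k: dict[int, float] = {}
    silhouette_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for kk in k_range:
        if kk >= n:
            continue
        lab = _relabel_by_size(fcluster(tree, t=kk, criterion="maxclust"))
        labels_by_k[kk] = lab
        inertia_by_k[kk] = _inertia(x, lab)
        silhouette_by_k[kk] = (
            float(silhouette_score(x, lab)) if len(np.unique(lab)) > 1 else float("nan")
        )
    if k in labels_by_k:
        labels = labels_by_k[k]
    else:
        labels = _relabel_by_size(fcluster(tree, t=k, criterion="maxclust"))
    return ClusterSolution(
        labels=labels,
        k=k,
        linkage_tree=tree,
        inertia_by_k=inertia_by_k,
        silhouette_by_k=silhouette_by_k,
        labels_by_k=labels_by_k,
    )


#: Jaccard stability bands; boundary values are assigned to the upper band.
def stability_category(j: float) -> str:
    if j >= 0.75:
        return "stable"
    if j >= 0.60:
        return "consistent"
    if j >= 0.50:
        return "unstable"
    return "dissolved"


@dataclass
class StabilityReport:
    mean_jaccard: np.ndarray  # per reference cluster
    sd_jaccard: np.ndarray
    category: list[str]
    n_boot: int
    subsample_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": np.arange(1, len(self.mean_jaccard) + 1),
                "mean_jaccard": self.mean_jaccard,
                "sd_jaccard": self.sd_jaccard,
                "category": self.category,
            }
        )


def bootstrap_stability(
    scores: np.ndarray | pd.DataFrame,
    reference: ClusterSolution,
    n_boot: int = 300,
    frac: float = 0.8,
    seed: int = 0,
) -> StabilityReport:
    """Bootstrap cluster stability by subsampling without replacement.

    Each iteration re-clusters the PC scores of floor(frac * n) participants
    (drawn without replacement) with Ward at the reference k, then records,
    for every reference cluster A (restricted to the subsample), the best
    Jaccard overlap |A∩B| / |A∪B| over the subsample clusters B.  If a
    subsample misses a reference cluster entirely that iteration scores 0
    for it.  Mean ± SD per cluster is reported with the conventional
    categories (>= 0.75 stable, >= 0.60 consistent, >= 0.50 unstable,
    else dissolved).
    """
    if reference.k < 2:
        raise ValueError("reference solution must have k >= 2")
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    m = int(np.floor(frac * n))
    if m < reference.k:
        raise ValueError("subsample smaller than cluster count")
    rng = np.random.default_rng(seed)
    ref = reference.labels
    clusters = np.unique(ref)
    jacc = np.zeros((n_boot, clusters.size))
    for b in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        sub_tree = linkage(x[idx], method="ward")
        sub_lab = fcluster(sub_tree, t=reference.k, criterion="maxclust")
        for ci, c in enumerate(clusters):
            a_mask = ref[idx] == c
            if not a_mask.any():
                logger.warning("iteration %d: subsample misses cluster %d", b, c)
                continue  # jacc stays 0
            best = 0.0
            for s in np.unique(sub_lab):
                b_mask = sub_lab == s
                inter = int((a_mask & b_mask).sum())
                union = int((a_mask | b_mask).sum())
                if union:
                    best = max(best, inter / union)
            jacc[b, ci] = best
    mean = jacc.mean(axis=0)
    sd = jacc.std(axis=0, ddof=1) if n_boot > 1 else np.zeros_like(mean)
    return StabilityReport(
        mean_jaccard=mean,
        sd_jaccard=sd,
        category=[stability_category(v) for v in mean],
        n_boot=n_boot,
        subsample_fraction=frac,
    )
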