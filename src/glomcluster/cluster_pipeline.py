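"""Feature preprocessing, Ward clustering, gap-statistic model selection,
bootstrap stability and cross-modality agreement.

The pipeline mirrors standard practice for unsupervised neuron typing:
morphological parameters are inverse-hyperbolic-sine transformed (they are
strictly positive and heavily skewed), every column is z-scored, cells are
linked agglomeratively with Ward's method on Euclidean distances, and the
number of clusters is chosen with the gap statistic under a generalised
f·SE stopping rule (f = 2 by default).

Two Ward conventions exist in the wild: the "ward.D2" variant (Lance–
Williams on squared Euclidean distances, heights on the distance scale —
scipy's native method) and the older R "ward.D" variant that applies the
recurrence to the raw dissimilarities.  Both are exposed; cutting the tree
gives identical partitions whenever the merge orders agree, but they can
differ on real data, so the variant is an explicit argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessSpec",
    "GapCurve",
    "ClusterLabels",
    "StabilityReport",
    "ConfusionReport",
    "preprocess",
    "ward_cluster",
    "gap_statistic",
    "select_k",
    "jaccard_stability",
    "compare_clusterings",
    "cluster_distance_summary",
    "pairwise_tests",
]


@dataclass(frozen=True)
class PreprocessSpec:
    """Which columns get the asinh transform, and whether to z-score."""

    asinh_columns: frozenset = frozenset()
    scale: bool = True


@dataclass
class GapCurve:
    k_values: np.ndarray
    log_wk: np.ndarray
    expected_log_wk: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    f: float = 2.0

    def __post_init__(self) -> None:
        n = len(self.k_values)
        if not (len(self.log_wk) == len(self.expected_log_wk) == len(self.gap) == len(self.se) == n):
            raise ValueError("gap-curve arrays differ in length")


@dataclass
class ClusterLabels:
    cell_ids: list[str]
    labels: np.ndarray          # contiguous 1..k
    method: str = "ward.D2"
    linkage_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("labels must be contiguous 1..k")

    @property
    def k(self) -> int:
        return int(self.labels.max())

    def sizes(self) -> dict[int, int]:
        return {int(c): int((self.labels == c).sum()) for c in np.unique(self.labels)}


@dataclass
class StabilityReport:
    jaccard: dict[int, float]
    n_boot: int


@dataclass
class ConfusionReport:
    ari: float
    contingency: pd.DataFrame
    per_class: pd.DataFrame      # sensitivity/specificity/accuracy in %


# ---------------------------------------------------------------------------

def preprocess(table: pd.DataFrame, spec: PreprocessSpec) -> np.ndarray:
    """Apply asinh to the flagged columns, then z-score every column.

    Uses the sample SD (ddof=1).  A zero-variance column raises an error
    naming the column, since it cannot be scaled.
    """
    df = table.astype(float).copy()
    for col in spec.asinh_columns:
        if col in df.columns:
            df[col] = np.arcsinh(df[col])
    X = df.to_numpy()
    if spec.scale:
        sd = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if len(dead):
            names = [df.columns[i] for i in dead]
            raise ValueError(f"zero-variance columns cannot be scaled: {names}")
        X = (X - X.mean(axis=0)) / sd
    return X


def _linkage(X: np.ndarray, method: str) -> np.ndarray:
    """Ward linkage under either height convention.

    ``ward.D2``: scipy's native Ward (recurrence on squared Euclidean
    distances, heights reported on the distance scale).  ``ward.D``: the
    recurrence is applied to the raw distances, emulated by feeding
    sqrt-distances to scipy's ward and squaring the heights back (a
    monotone transform, so the dendrogram cuts are exact).
    """
    if method == "ward.D2":
        return linkage(X, method="ward")
    if method == "ward.D":
        d = pdist(X)
        Z = linkage(np.sqrt(d), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
        return Z
    raise ValueError(f"unknown ward variant {method!r}")


def ward_cluster(X: np.ndarray, k: int, cell_ids: list[str] | None = None,
                 method: str = "ward.D2") -> ClusterLabels:
    """Agglomerative Ward clustering cut into k groups (labels 1..k).

    Labels are renumbered by first appearance so they are deterministic and
    contiguous.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(X)
    if k > n:
        raise ValueError("k cannot exceed the number of cells")
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n)]
    if k == 1:
        return ClusterLabels(cell_ids, np.ones(n, dtype=int), method)
    Z = _linkage(np.asarray(X, dtype=float), method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber by first appearance
    mapping, labels = {}, np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        mapping.setdefault(lab, len(mapping) + 1)
        labels[i] = mapping[lab]
    return ClusterLabels(cell_ids, labels, method, linkage_matrix=Z)


def _within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """W_k: summed within-cluster sum of squared distances to the centroid."""
    total = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def gap_statistic(X: np.ndarray, k_max: int = 10, B: int = 100, seed: int = 0,
                  f: float = 2.0, method: str = "ward.D2") -> GapCurve:
    """Gap statistic over k = 1..k_max with a uniform-box reference.

    Reference datasets are drawn uniformly over each feature's observed
    range (the simple reference of the gap-statistic construction), each
    clustered with the same Ward pipeline.  Gap_k = mean(log W*_k) −
    log W_k and se_k = sd(log W*_k)·√(1 + 1/B).
    """
    X = np.asarray(X, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if B < 10:
        raise ValueError("need at least 10 reference draws")
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)
    log_wk = np.array([
        np.log(_within_dispersion(X, ward_cluster(X, int(k), method=method).labels))
        for k in ks
    ])
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_log = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for j, k in enumerate(ks):
            ref_log[b, j] = np.log(_within_dispersion(ref, ward_cluster(ref, int(k), method=method).labels))
    expected = ref_log.mean(axis=0)
    se = ref_log.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)
    return GapCurve(k_values=ks, log_wk=log_wk, expected_log_wk=expected,
                    gap=expected - log_wk, se=se, f=f)


def select_k(curve: GapCurve, f: float | None = None, rule: str = "tibshirani") -> int:
    """Number of clusters from a gap curve.

    ``tibshirani`` (default): the smallest k with
    Gap_k ≥ Gap_{k+1} − f·se_{k+1}, the generalised one-SE stopping rule.
    ``local-max``: the smallest k that is a local maximum of the gap curve
    under the same f·se slack against its successor.
    """
    if f is None:
        f = curve.f
    gap, se, ks = curve.gap, curve.se, curve.k_values
    if rule == "tibshirani":
        for i in range(len(ks) - 1):
            if gap[i] >= gap[i + 1] - f * se[i + 1]:
                return int(ks[i])
        return int(ks[-1])
    if rule == "local-max":
        for i in range(len(ks) - 1):
            left_ok = i == 0 or gap[i] >= gap[i - 1]
            if left_ok and gap[i] >= gap[i + 1] - f * se[i + 1]:
                return int(ks[i])
        return int(ks[-1])
    raise ValueError(f"unknown selection rule {rule!r}")


def jaccard_stability(X: np.ndarray, labels: ClusterLabels, n_boot: int = 500,
                      seed: int = 0, method: str | None = None) -> StabilityReport:
    """Bootstrap cluster-wise Jaccard stability.

    For each bootstrap resample the data are re-clustered with the same k;
    every original cluster records its best Jaccard overlap with any new
    cluster (computed on the unique points present in the resample), and
    the per-cluster means over ``n_boot`` iterations are reported.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    method = method or labels.method
    k = labels.k
    n = len(X)
    originals = {c: set(np.flatnonzero(labels.labels == c)) for c in range(1, k + 1)}
    sums = {c: 0.0 for c in originals}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        unique = np.unique(idx)
        boot = ward_cluster(X[idx], k, method=method)
        # map resampled labels back onto unique original indices
        new_clusters: dict[int, set[int]] = {}
        for pos, orig_idx in enumerate(idx):
            new_clusters.setdefault(int(boot.labels[pos]), set()).add(int(orig_idx))
        uniq_set = set(int(u) for u in unique)
        for c, members in originals.items():
            present = members & uniq_set
            best = 0.0
            for newset in new_clusters.values():
                inter = len(present & newset)
                union = len(present | newset)
                if union:
                    best = max(best, inter / union)
            sums[c] += best
    return StabilityReport(
        jaccard={c: sums[c] / n_boot for c in originals},
        n_boot=n_boot,
    )


def compare_clusterings(labels_a: ClusterLabels, labels_b: ClusterLabels) -> ConfusionReport:
    """Adjusted Rand index plus per-class sensitivity/specificity/accuracy.

    Each class of ``labels_a`` is matched to the ``labels_b`` cluster with
    the largest overlap; rates are reported in percent.
    """
    if labels_a.cell_ids != labels_b.cell_ids:
        raise ValueError("clusterings cover different cell sets")
    a, b = labels_a.labels, labels_b.labels
    ari = float(adjusted_rand_score(a, b))
    cont = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    n = len(a)
    rows = {}
    for c in np.unique(a):
        match = cont.loc[c].idxmax()
        tp = int(((a == c) & (b == match)).sum())
        fn = int(((a == c) & (b != match)).sum())
        fp = int(((a != c) & (b == match)).sum())
        tn = n - tp - fn - fp
        rows[int(c)] = {
            "matched_b": int(match),
            "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
            "specificity": 100.0 * tn / (tn + fp) if tn + fp else np.nan,
            "accuracy": 100.0 * (tp + tn) / n,
        }
    return ConfusionReport(ari=ari, contingency=cont,
                           per_class=pd.DataFrame(rows).T)


def cluster_distance_summary(X: np.ndarray, labels: ClusterLabels) -> pd.DataFrame:
    """k×k table of mean pairwise Euclidean distances within/between clusters.

    Self-pairs (the zero diagonal of the distance matrix) are excluded, so a
    singleton cluster's within-mean is reported as NaN.
    """
    X = np.asarray(X, dtype=float)
    D = squareform(pdist(X))
    lab = labels.labels
    ks = np.unique(lab)
    out = pd.DataFrame(index=ks, columns=ks, dtype=float)
    for ci in ks:
        for cj in ks:
            rows = np.flatnonzero(lab == ci)
            cols = np.flatnonzero(lab == cj)
            block = D[np.ix_(rows, cols)]
            if ci == cj:
                m = len(rows)
                if m < 2:
                    out.loc[ci, cj] = np.nan
                    continue
                vals = block[np.triu_indices(m, k=1)]
            else:
                vals = block.ravel()
            out.loc[ci, cj] = float(np.mean(vals))
    return out


def pairwise_tests(table: pd.DataFrame, labels: ClusterLabels,
                   min_cluster_size: int = 2) -> pd.DataFrame:
    """Per-parameter, per-cluster-pair Wilcoxon rank-sum tests, BH-adjusted.

    The Benjamini–Hochberg correction is applied within each parameter's
    family of cluster pairs.  Pairs touching a cluster smaller than
    ``min_cluster_size`` are skipped (noted as NaN rows).
    """
    lab = labels.labels
    ks = np.unique(lab)
    if len(ks) < 2:
        raise ValueError("need at least two clusters")
    records = []
    for param in table.columns:
        vals = table[param].to_numpy(dtype=float)
        pvals, pairs = [], []
        for i, ci in enumerate(ks):
            for cj in ks[i + 1:]:
                xi, xj = vals[lab == ci], vals[lab == cj]
                if len(xi) < min_cluster_size or len(xj) < min_cluster_size:
                    logger.info("skipping pair (%s,%s) for %s: cluster too small", ci, cj, param)
                    records.append({"parameter": param, "cluster_a": int(ci),
                                    "cluster_b": int(cj), "p_value": np.nan,
                                    "q_value": np.nan})
                    continue
                stat = mannwhitneyu(xi, xj, alternative="two-sided")
                pvals.append(float(stat.pvalue))
                pairs.append((int(ci), int(cj)))
        if pvals:
            _, qvals, *_ = multipletests(pvals, method="fdr_bh")
            for (ci, cj), p, q in zip(pairs, pvals, qvals):
                records.append({"parameter": param, "cluster_a": ci, "cluster_b": cj,
                                "p_value": p, "q_value": float(q)})
    return pd.DataFrame.from_records(records)
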