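"""Per-feature ANOVA with Duncan letters, PCA, hierarchical bi-clustering
with sample grouping, Venn counting and restart-selected k-means.

ANOVA groups are the developmental stages (one-way layout over stages,
replicates as observations). Duncan's multiple range test annotates stage
means with lower-case letters: stages sharing no letter differ at level
alpha. K-means is run from many independent initializations and the
restart with minimal total within-cluster squared distance is kept.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import f as f_dist
from scipy.stats import studentized_range
from sklearn.cluster import KMeans

from .io_formats import AbundanceMatrix, SampleDesign
from .quantify import StageSeries


# --- one-way ANOVA ---------------------------------------------------------


@dataclass
class AnovaResult:
    F: float
    p: float
    group_means: pd.Series  # stage -> mean
    group_n: pd.Series  # stage -> replicate count
    mse: float  # residual mean square
    df_between: int
    df_within: int
    degenerate: bool = False
    letters: dict[str, str] | None = None


def anova_oneway(values: pd.Series, design: SampleDesign) -> AnovaResult:
    """Classical one-way F-test of stage effect on a single feature.

    ``values`` is indexed by sample id. Degenerate layouts are flagged:
    all values identical gives F=0, p=1; zero within-stage variance with
    non-zero between-stage variance gives F=inf, p=0.
    """
    stages = design.stage_order
    groups = [values.loc[design.samples_of_stage(s)].to_numpy(float) for s in stages]
    sizes = np.array([len(g) for g in groups])
    if (sizes < 2).any() or len(groups) < 2:
        raise ValueError("need >= 2 stages with >= 2 replicates each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b = len(groups) - 1
    df_w = int(sizes.sum()) - len(groups)
    mse = ss_within / df_w
    tiny = 1e-14 * max(1.0, float(np.sum((all_vals - grand) ** 2)))
    if ss_within <= tiny:
        if ss_between <= tiny:
            F, p, degenerate = 0.0, 1.0, True
        else:
            F, p, degenerate = math.inf, 0.0, True
    else:
        F = (ss_between / df_b) / mse
        p = float(f_dist.sf(F, df_b, df_w))
        degenerate = False
    return AnovaResult(
        F=F,
        p=p,
        group_means=pd.Series(means, index=stages),
        group_n=pd.Series(sizes, index=stages),
        mse=mse,
        df_between=df_b,
        df_within=df_w,
        degenerate=degenerate,
    )


def anova_table(
    matrix: AbundanceMatrix, design: SampleDesign, alpha: float = 0.05, duncan: bool = True
) -> pd.DataFrame:
    """Per-feature ANOVA (+ Duncan letters) over all features of a matrix."""
    rows = {}
    for fid in matrix.features:
        res = anova_oneway(matrix.values.loc[fid], design)
        row = {"F": res.F, "p": res.p, "mse": res.mse, "degenerate": res.degenerate}
        if duncan and not res.degenerate and res.mse > 0:
            letters = duncan_letters(res.group_means, res.group_n, res.mse, res.df_within, alpha)
            for stage in design.stage_order:
                row[f"letter_{stage}"] = letters[stage]
        rows[fid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature_id"
    return out


# --- Duncan's multiple range test -----------------------------------------


@lru_cache(maxsize=512)
def _duncan_quantiles(k: int, df_e: int, alpha: float) -> tuple[float, ...]:
    """Studentized-range quantiles q(1 - alpha_p; p, df_e) for p = 2..k.

    The quantiles depend only on (k, df_e, alpha), which is shared by
    every feature of a balanced design, so they are cached: the ppf of
    the studentized-range distribution is expensive.
    """
    spans = np.arange(2, k + 1)
    alpha_p = 1.0 - (1.0 - alpha) ** (spans - 1)
    return tuple(studentized_range.ppf(1.0 - alpha_p, spans, df_e))


def duncan_critical_ranges(k: int, n_h: float, mse: float, df_e: int, alpha: float) -> np.ndarray:
    """Critical range R_p for spans p = 2..k (index p-2).

    R_p = q(1 - alpha_p; p, df_e) * sqrt(MSE / n_h) with the span-wise
    protection level alpha_p = 1 - (1 - alpha)^(p-1) and q the
    studentized-range quantile; n_h is the harmonic mean group size.
    """
    q = np.array(_duncan_quantiles(int(k), int(df_e), float(alpha)))
    return q * math.sqrt(mse / n_h)


def duncan_letters(
    group_means: pd.Series,
    group_n,
    mse: float,
    df_e: int,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Duncan multiple-range letter display for the given group means.

    Step-down procedure: the full range of means is tested against the
    critical range for its span; a non-significant stretch is declared
    homogeneous and not subdivided, a significant one is split into its
    two maximal sub-ranges. Maximal homogeneous stretches each receive a
    letter; groups sharing no letter differ at level alpha.
    """
    if df_e < 1:
        raise ValueError("df_e must be >= 1")
    if not mse > 0:
        raise ValueError("MSE must be positive")
    labels = list(group_means.index)
    k = len(labels)
    if np.isscalar(group_n):
        sizes = np.full(k, float(group_n))
    else:
        sizes = np.asarray(pd.Series(group_n).reindex(labels), dtype=float)
    n_h = k / np.sum(1.0 / sizes)

    order = np.argsort(-group_means.to_numpy())
    sorted_means = group_means.to_numpy()[order]
    ranges = duncan_critical_ranges(k, n_h, mse, df_e, alpha) if k >= 2 else np.array([])

    homogeneous: set[tuple[int, int]] = set()
    seen: set[tuple[int, int]] = set()

    def visit(i: int, j: int) -> None:
        if (i, j) in seen:
            return
        seen.add((i, j))
        if i == j:
            homogeneous.add((i, j))
            return
        span = j - i + 1
        if sorted_means[i] - sorted_means[j] <= ranges[span - 2]:
            homogeneous.add((i, j))
        else:
            visit(i, j - 1)
            visit(i + 1, j)

    visit(0, k - 1)
    maximal = [
        (i, j)
        for (i, j) in homogeneous
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in homogeneous)
    ]
    maximal.sort()
    alphabet = string.ascii_lowercase
    letters = {lab: "" for lab in labels}
    for idx, (i, j) in enumerate(maximal):
        letter = alphabet[idx % 26] * (idx // 26 + 1)
        for pos in range(i, j + 1):
            letters[labels[order[pos]]] += letter
    return letters


# --- PCA -------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # feature x component
    variance_explained: np.ndarray  # percentages summing to 100


def pca(data, scale: bool = False) -> PcaResult:
    """PCA by SVD of the column-centered sample x feature matrix.

    Accepts a :class:`StageSeries` (stages become the samples) or any
    sample x feature DataFrame. ``variance_explained`` is in percent and
    sums to 100.
    """
    if isinstance(data, StageSeries):
        X = data.values.T  # stages as samples
    else:
        X = pd.DataFrame(data)
    if X.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    centered = X - X.mean(axis=0)
    if scale:
        sd = centered.std(axis=0, ddof=1).replace(0, 1.0)
        centered = centered / sd
    arr = centered.to_numpy(float)
    if not np.any(arr):
        raise ValueError("matrix is constant; PCA undefined")
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    comp = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(u * s, index=X.index, columns=comp)
    loadings = pd.DataFrame(vt.T, index=X.columns, columns=comp)
    var = s**2
    return PcaResult(scores, loadings, 100.0 * var / var.sum())


# --- hierarchical bi-clustering -------------------------------------------


@dataclass
class SampleGrouping:
    """Partition of the stages/samples from cutting the column dendrogram."""

    k_groups: int
    membership: pd.Series  # sample/stage label -> group id (1..k)

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for label, g in self.membership.items():
            out.setdefault(int(g), []).append(label)
        return out


@dataclass
class BiclusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    grouping: SampleGrouping


def hierarchical_bicluster(
    matrix: pd.DataFrame,
    k_groups: int = 3,
    feature_metric: str = "correlation",
    feature_linkage: str = "average",
    sample_metric: str = "euclidean",
    sample_linkage: str = "average",
) -> BiclusterResult:
    """Agglomerative trees on rows (features) and columns (samples).

    Defaults: correlation distance / average linkage for features,
    Euclidean / average linkage for samples. The sample tree is cut into
    ``k_groups`` groups (default 3, the canonical early / middle / late
    developmental grouping).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    if k_groups > matrix.shape[1]:
        raise ValueError(f"k_groups={k_groups} exceeds number of samples {matrix.shape[1]}")
    row_z = linkage(pdist(matrix.to_numpy(float), metric=feature_metric), method=feature_linkage)
    col_z = linkage(pdist(matrix.to_numpy(float).T, metric=sample_metric), method=sample_linkage)
    labels = fcluster(col_z, t=k_groups, criterion="maxclust")
    # renumber groups 1..k in order of first appearance (stage order)
    remap, nxt = {}, 1
    renum = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        renum.append(remap[lab])
    grouping = SampleGrouping(k_groups, pd.Series(renum, index=matrix.columns))
    return BiclusterResult(row_z, col_z, grouping)


# --- k-means with restart selection ---------------------------------------


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series  # feature -> cluster id (1..k)
    centroids: pd.DataFrame  # cluster x stage
    total_distance: float  # sum of squared point-to-centroid distances
    n_restarts: int
    best_restart_seed: int


def kmeans_restarts(
    series: StageSeries, k: int = 12, restarts: int = 100, seed: int = 0
) -> ClusterModel:
    """Lloyd k-means from ``restarts`` independent k-means++ inits.

    The restart with minimal total within-cluster squared distance is
    returned. Restart seeds form a prefix-stable stream derived from
    ``seed``, so the best total distance is non-increasing in the number
    of restarts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = series.values.to_numpy(float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of features {X.shape[0]}")
    restart_seeds = np.random.SeedSequence(seed).generate_state(restarts) % (2**31)
    best = None
    for rs in restart_seeds:
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=int(rs)).fit(X)
        if best is None or km.inertia_ < best[0]:
            best = (km.inertia_, km, int(rs))
    inertia, km, best_seed = best
    assignments = pd.Series(km.labels_ + 1, index=series.values.index)
    centroids = pd.DataFrame(
        km.cluster_centers_, index=range(1, k + 1), columns=series.values.columns
    )
    return ClusterModel(
        k=k,
        assignments=assignments,
        centroids=centroids,
        total_distance=float(inertia),
        n_restarts=restarts,
        best_restart_seed=best_seed,
    )


# --- group-specific features (Venn) ---------------------------------------


@dataclass
class VennCounts:
    """Detection Venn over sample groups: counts and members per region.

    Region keys are sorted tuples of group ids, e.g. (1,), (1, 3),
    (1, 2, 3); ``common`` is the full-intersection region, ``specific``
    maps each group to its exclusive features. Features detected in no
    group are listed in ``undetected``.
    """

    counts: dict[tuple[int, ...], int]
    members: dict[tuple[int, ...], list[str]]
    undetected: list[str] = field(default_factory=list)

    @property
    def common(self) -> int:
        full = tuple(sorted({g for key in self.counts for g in key}))
        return self.counts.get(full, 0)

    def specific(self, group: int) -> int:
        return self.counts.get((group,), 0)


def group_specific_features(
    matrix: AbundanceMatrix, design: SampleDesign, grouping: SampleGrouping
) -> VennCounts:
    """Venn counts of feature detection across stage groups.

    A feature is detected in group g iff it is non-zero in every
    replicate of at least one stage belonging to g (the presence rule,
    applied within the group).
    """
    from .quantify import presence_mask

    stage_groups = grouping.groups()
    group_ids = sorted(stage_groups)
    detected = {
        g: presence_mask(matrix, design, stages=stage_groups[g]) for g in group_ids
    }
    from itertools import combinations

    counts: dict[tuple[int, ...], int] = {}
    members: dict[tuple[int, ...], list[str]] = {}
    for r in range(1, len(group_ids) + 1):
        for key in combinations(group_ids, r):
            counts[key] = 0
            members[key] = []
    undetected = []
    for fid in matrix.features:
        key = tuple(g for g in group_ids if bool(detected[g][fid]))
        if not key:
            undetected.append(fid)
            continue
        counts[key] += 1
        members[key].append(fid)
    return VennCounts(counts, members, undetected)
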