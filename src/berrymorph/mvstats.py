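"""Group-comparison statistics for trait and shape-score tables.

Implements the statistical toolkit used to discriminate variety groups:

* one-way ANOVA with Duncan's multiple range test (homogeneous-subset
  letters);
* canonical discriminant analysis (CDA): eigen-solve of the
  within^-1 between scatter, canonical correlations, structure matrix and
  resubstitution classification by Mahalanobis distance to the group
  centroids under equal priors;
* MANOVA summary statistics — Wilks' lambda (Rao's F approximation) and
  Pillai's trace — derived from the discriminant eigenvalues;
* Hotelling T^2 pairwise tests with Bonferroni correction and pairwise
  squared Mahalanobis distances on the two-group pooled covariance;
* UPGMA (between-group average linkage) clustering of group centroids on
  Euclidean distances.

The identities Lambda = prod 1/(1+lambda_i) and
Pillai = sum lambda_i/(1+lambda_i) = sum r_i^2 hold exactly and are
exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sstats
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import pdist

__all__ = [
    "DuncanResult",
    "DiscriminantResult",
    "ManovaResult",
    "PairwiseResult",
    "ClusterTree",
    "anova_duncan",
    "cda_fit",
    "manova",
    "manova_from_eigenvalues",
    "hotelling_pairwise",
    "classify_resubstitution",
    "cluster_centroids",
    "wilks_lambda",
    "pillai_trace",
    "canonical_correlations",
    "percent_variance",
]


# ---------------------------------------------------------------------------
# eigenvalue identities

def wilks_lambda(eigenvalues) -> float:
    """Wilks' lambda = prod_i 1 / (1 + lambda_i)."""
    lam = np.asarray(eigenvalues, dtype=float)
    return float(np.prod(1.0 / (1.0 + lam)))


def pillai_trace(eigenvalues) -> float:
    """Pillai's trace = sum_i lambda_i / (1 + lambda_i)."""
    lam = np.asarray(eigenvalues, dtype=float)
    return float(np.sum(lam / (1.0 + lam)))


def canonical_correlations(eigenvalues) -> np.ndarray:
    """r_i = sqrt(lambda_i / (1 + lambda_i)) for each discriminant root."""
    lam = np.asarray(eigenvalues, dtype=float)
    return np.sqrt(lam / (1.0 + lam))


def percent_variance(eigenvalues) -> np.ndarray:
    """Share of between-group separation per root, in percent."""
    lam = np.asarray(eigenvalues, dtype=float)
    return 100.0 * lam / lam.sum()


# ---------------------------------------------------------------------------
# ANOVA + Duncan

@dataclass
class DuncanResult:
    """Group means (descending), subset letters, and the ANOVA F test."""

    means: pd.Series          # sorted descending
    letters: dict[str, str]   # group -> letters; shared letter = not distinct
    alpha: float
    f_statistic: float
    p_value: float
    ms_error: float
    df_error: int


def _duncan_letters(
    means: pd.Series, crit: np.ndarray
) -> dict[str, str]:
    """Letter assignment by the standard sweep over sorted means.

    ``crit[r]`` is the critical range for a span of ``r + 2`` means.  Each
    maximal stretch of means whose endpoints do not differ gets one letter.
    """
    k = len(means)
    vals = means.to_numpy()

    def differ(i: int, j: int) -> bool:
        span = j - i + 1
        return vals[i] - vals[j] > crit[span - 2] if span >= 2 else False

    segments = []
    i = 0
    while i < k:
        j = i
        while j + 1 < k and not differ(i, j + 1):
            j += 1
        if not segments or segments[-1][1] < j:
            segments.append((i, j))
        if j == k - 1:
            break
        i += 1
    letters: dict[str, str] = {g: "" for g in means.index}
    for s, (lo, hi) in enumerate(segments):
        ch = chr(ord("a") + s % 26) * (s // 26 + 1)
        for g in means.index[lo : hi + 1]:
            letters[g] += ch
    return letters


def anova_duncan(values, groups, alpha: float = 0.05) -> DuncanResult:
    """One-way ANOVA followed by Duncan's multiple range test.

    Duncan's critical point for a span of k means uses the studentized
    range at the protection level 1 - (1 - alpha)^(k-1).  With zero
    within-group variance the F statistic is reported infinite and letters
    separate every distinct mean.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)})
    gstat = df.groupby("g")["y"].agg(["mean", "count"])
    k = len(gstat)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if (gstat["count"] < 2).any():
        raise ValueError("every group needs n >= 2")
    n_total = len(df)
    grand = df["y"].mean()
    ss_between = float((gstat["count"] * (gstat["mean"] - grand) ** 2).sum())
    ss_within = float(
        ((df["y"] - df["g"].map(gstat["mean"])) ** 2).sum()
    )
    df_b, df_e = k - 1, n_total - k
    mse = ss_within / df_e
    if mse == 0.0:
        f_stat = np.inf if ss_between > 0 else 0.0
        p_val = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df_b) / mse
        p_val = float(sstats.f.sf(f_stat, df_b, df_e))
    means = gstat["mean"].sort_values(ascending=False)
    n_harm = k / (1.0 / gstat["count"]).sum()
    spans = np.arange(2, k + 1)
    protect = 1.0 - (1.0 - alpha) ** (spans - 1)
    if mse == 0.0:
        crit = np.zeros(k - 1)
    else:
        q = sstats.studentized_range.ppf(1.0 - protect, spans, df_e)
        crit = q * np.sqrt(mse / n_harm)
    letters = _duncan_letters(means, crit)
    return DuncanResult(
        means=means,
        letters=letters,
        alpha=alpha,
        f_statistic=float(f_stat),
        p_value=p_val,
        ms_error=mse,
        df_error=df_e,
    )


# ---------------------------------------------------------------------------
# canonical discriminant analysis

@dataclass
class DiscriminantResult:
    """Canonical discriminant fit.

    ``eigenvalues`` are the min(p, g-1) roots of within^-1 between;
    ``coefficients`` are raw canonical coefficients scaled so discriminant
    scores have unit pooled within-group variance; ``structure`` holds
    pooled within-group correlations between each variable and each
    function.  The confusion matrix is row-percent (rows sum to 100).
    """

    variables: list[str]
    groups: list[str]
    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    canonical_correlations: np.ndarray
    coefficients: np.ndarray        # (p, s)
    grand_mean: np.ndarray
    scores: np.ndarray              # (n, s)
    sample_groups: np.ndarray       # group label per row of scores
    centroids: pd.DataFrame         # (g, s) discriminant-space centroids
    structure: pd.DataFrame         # (p, s)
    pooled_cov: np.ndarray          # (p, p), all-group pooled covariance
    group_means: pd.DataFrame       # (g, p) in original variable space
    confusion: pd.DataFrame
    percent_correct: float


def _as_table(X, variables=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    X = np.asarray(X, dtype=float)
    if variables is None:
        variables = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=variables)


def _scatter_matrices(X: pd.DataFrame, g: pd.Series):
    means = X.groupby(g, observed=True).mean()
    counts = g.value_counts().reindex(means.index)
    grand = X.mean(axis=0)
    centered = X.to_numpy() - means.reindex(g).to_numpy()
    W = centered.T @ centered
    dm = means.to_numpy() - grand.to_numpy()
    B = (dm * counts.to_numpy()[:, None]).T @ dm
    return W, B, means, counts, grand


def _check_invertible(W: np.ndarray, variables: list[str], n_minus_g: int) -> None:
    S = W / n_minus_g
    # name the offending columns instead of failing inside LAPACK
    d = np.sqrt(np.diag(S))
    bad = [v for v, s in zip(variables, d) if s == 0 or not np.isfinite(s)]
    if not bad:
        corr = S / np.outer(d, d)
        if np.linalg.matrix_rank(corr, tol=1e-10) < len(variables):
            # point at the most collinear columns via smallest eigenvector
            w, v = np.linalg.eigh(corr)
            idx = np.argsort(np.abs(v[:, 0]))[::-1][:3]
            bad = [variables[i] for i in idx]
    if bad:
        raise ValueError(
            "pooled within-group covariance is singular; "
            f"collinear/constant columns include: {', '.join(bad)}"
        )


def cda_fit(X, groups, variables: list[str] | None = None) -> DiscriminantResult:
    """Canonical discriminant analysis of samples-by-variables data.

    Solves the generalized eigenproblem B v = lambda W v for the within-
    and between-group scatter matrices and keeps the min(p, g-1) leading
    roots.  Coefficients are scaled to unit pooled within-group variance
    of the scores, and each function's sign is pinned so its largest
    structure correlation is positive.  Classification is by smallest
    Mahalanobis distance to the group centroid in the original variable
    metric (all-group pooled covariance, equal priors).
    """
    X = _as_table(X, variables)
    g = pd.Series(list(groups), index=X.index, name="group")
    variables = list(X.columns)
    p = len(variables)
    group_names = list(pd.unique(g))
    n, gn = len(X), len(group_names)
    if n <= p + gn:
        raise ValueError(
            f"need n > p + g samples (got n={n}, p={p}, g={gn})"
        )
    W, B, means, counts, grand = _scatter_matrices(X, g)
    _check_invertible(W, variables, n - gn)
    s = min(p, gn - 1)
    vals, vecs = sla.eigh(B, W)          # ascending eigenvalues of W^-1 B
    vals, vecs = vals[::-1][:s], vecs[:, ::-1][:, :s]
    vals = np.clip(vals, 0.0, None)
    # eigh normalizes v' W v = 1; rescale to unit within-group *covariance*
    vecs = vecs * np.sqrt(n - gn)
    Xc = X.to_numpy() - grand.to_numpy()
    scores = Xc @ vecs
    # structure matrix: pooled within-group correlations
    centered = X.to_numpy() - means.reindex(g).to_numpy()
    score_centered = centered @ vecs
    Sw = (centered.T @ centered) / (n - gn)
    cov_xy = (centered.T @ score_centered) / (n - gn)
    sd_x = np.sqrt(np.diag(Sw))
    sd_y = np.sqrt((score_centered**2).sum(axis=0) / (n - gn))
    structure = cov_xy / np.outer(sd_x, sd_y)
    # pin signs: largest structure correlation per function positive
    for j in range(s):
        i = np.argmax(np.abs(structure[:, j]))
        if structure[i, j] < 0:
            structure[:, j] *= -1.0
            vecs[:, j] *= -1.0
            scores[:, j] *= -1.0
    centroids = (
        pd.DataFrame(scores, index=g.values, columns=_fn_names(s))
        .groupby(level=0, observed=True)
        .mean()
        .reindex(group_names)
    )
    result = DiscriminantResult(
        variables=variables,
        groups=group_names,
        eigenvalues=vals,
        percent_variance=percent_variance(vals),
        canonical_correlations=canonical_correlations(vals),
        coefficients=vecs,
        grand_mean=grand.to_numpy(),
        scores=scores,
        sample_groups=g.to_numpy(),
        centroids=centroids,
        structure=pd.DataFrame(structure, index=variables, columns=_fn_names(s)),
        pooled_cov=Sw,
        group_means=means.reindex(group_names),
        confusion=pd.DataFrame(),
        percent_correct=float("nan"),
    )
    conf, pc = classify_resubstitution(result, X, g)
    result.confusion, result.percent_correct = conf, pc
    return result


def _fn_names(s: int) -> list[str]:
    return [f"F{i + 1}" for i in range(s)]


def classify_resubstitution(model: DiscriminantResult, X, groups):
    """Confusion matrix (row %) and overall percent correctly classified.

    Samples are assigned to the group with the smallest Mahalanobis
    distance in the original variable metric (equal priors).
    """
    X = _as_table(X, model.variables)
    g = np.asarray(list(groups))
    unknown = set(g) - set(model.groups)
    if unknown:
        raise ValueError(f"unseen group labels: {sorted(unknown)}")
    Sw_inv = np.linalg.inv(model.pooled_cov)
    M = model.group_means.to_numpy()
    D2 = np.empty((len(X), len(model.groups)))
    Xa = X.to_numpy()
    for j in range(M.shape[0]):
        diff = Xa - M[j]
        D2[:, j] = np.einsum("ij,jk,ik->i", diff, Sw_inv, diff)
    pred = np.asarray(model.groups)[np.argmin(D2, axis=1)]
    conf = pd.crosstab(
        pd.Series(g, name="actual"), pd.Series(pred, name="predicted")
    ).reindex(index=model.groups, columns=model.groups, fill_value=0)
    pct = conf.div(conf.sum(axis=1), axis=0) * 100.0
    correct = float((pred == g).mean() * 100.0)
    return pct, correct


# ---------------------------------------------------------------------------
# MANOVA

@dataclass
class ManovaResult:
    wilks_lambda: float
    pillai_trace: float
    df_hypothesis: int
    df_error_wilks: float
    df_error_pillai: int
    f_wilks: float
    f_pillai: float
    p_wilks: float
    p_pillai: float


def manova_from_eigenvalues(
    eigenvalues, n_samples: int, n_groups: int, n_variables: int
) -> ManovaResult:
    """MANOVA statistics from discriminant eigenvalues and the design size.

    Wilks' lambda uses Rao's F approximation; Pillai's trace uses the
    standard F approximation.  Hypothesis df is p (g - 1) for both.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    N, g, p = n_samples, n_groups, n_variables
    q = g - 1
    L = wilks_lambda(lam)
    V = pillai_trace(lam)
    df1 = p * q
    # Rao's approximation for Wilks
    denom = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    w = N - 1 - (p + q + 1) / 2.0
    df2_w = w * t - (p * q - 2) / 2.0
    Lt = L ** (1.0 / t)
    f_w = (1.0 - Lt) / Lt * df2_w / df1
    # Pillai's approximation
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (N - g - p - 1) / 2.0
    df2_p = int(round(s * (2 * nn + s + 1)))
    f_p = (2 * nn + s + 1) / (2 * m + s + 1) * V / (s - V)
    return ManovaResult(
        wilks_lambda=L,
        pillai_trace=V,
        df_hypothesis=df1,
        df_error_wilks=float(df2_w),
        df_error_pillai=df2_p,
        f_wilks=float(f_w),
        f_pillai=float(f_p),
        p_wilks=float(sstats.f.sf(f_w, df1, df2_w)),
        p_pillai=float(sstats.f.sf(f_p, df1, df2_p)),
    )


def manova(X, groups, variables: list[str] | None = None) -> ManovaResult:
    """One-way MANOVA via the canonical discriminant eigenvalues."""
    X = _as_table(X, variables)
    g = pd.Series(list(groups), index=X.index)
    group_names = list(pd.unique(g))
    if len(group_names) < 2:
        # degenerate: no between-group variation to test
        return ManovaResult(1.0, 0.0, 0, 0.0, 0, 0.0, 0.0, 1.0, 1.0)
    fit = cda_fit(X, g)
    return manova_from_eigenvalues(
        fit.eigenvalues, len(X), len(group_names), len(X.columns)
    )


# ---------------------------------------------------------------------------
# Hotelling pairwise

@dataclass
class PairwiseResult:
    """Pairwise two-group statistics as square DataFrames.

    ``d2`` is the squared Mahalanobis distance on the two-group pooled
    covariance; ``p_corrected`` applies a Bonferroni factor of
    g (g - 1) / 2.
    """

    d2: pd.DataFrame
    t2: pd.DataFrame
    f: pd.DataFrame
    p_raw: pd.DataFrame
    p_corrected: pd.DataFrame


def hotelling_pairwise(X, groups, variables: list[str] | None = None) -> PairwiseResult:
    """Hotelling T^2 test and Mahalanobis D^2 for every group pair."""
    X = _as_table(X, variables)
    g = pd.Series(list(groups), index=X.index)
    names = list(pd.unique(g))
    p = X.shape[1]
    for name, cnt in g.value_counts().items():
        if cnt <= p:
            raise ValueError(
                f"group {name!r} has n={cnt} <= p={p}; T^2 is undefined"
            )
    k = len(names)
    n_pairs = k * (k - 1) // 2
    mats = {key: pd.DataFrame(0.0, index=names, columns=names)
            for key in ("d2", "t2", "f", "p_raw", "p_corrected")}
    for i in range(k):
        for j in range(i + 1, k):
            Xi = X[g == names[i]].to_numpy()
            Xj = X[g == names[j]].to_numpy()
            n1, n2 = len(Xi), len(Xj)
            S = (
                (Xi - Xi.mean(0)).T @ (Xi - Xi.mean(0))
                + (Xj - Xj.mean(0)).T @ (Xj - Xj.mean(0))
            ) / (n1 + n2 - 2)
            diff = Xi.mean(0) - Xj.mean(0)
            try:
                d2 = float(diff @ np.linalg.solve(S, diff))
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"singular pooled covariance for pair "
                    f"({names[i]!r}, {names[j]!r})"
                ) from exc
            t2 = n1 * n2 / (n1 + n2) * d2
            f_val = t2 * (n1 + n2 - p - 1) / ((n1 + n2 - 2) * p)
            p_raw = float(sstats.f.sf(f_val, p, n1 + n2 - p - 1))
            for key, val in (
                ("d2", d2),
                ("t2", t2),
                ("f", f_val),
                ("p_raw", p_raw),
                ("p_corrected", min(1.0, p_raw * n_pairs)),
            ):
                mats[key].iloc[i, j] = val
                mats[key].iloc[j, i] = val
    for key in ("p_raw", "p_corrected"):
        np.fill_diagonal(mats[key].values, 1.0)
    return PairwiseResult(**mats)


# ---------------------------------------------------------------------------
# hierarchical clustering of centroids

@dataclass
class ClusterTree:
    """UPGMA tree over group centroids.

    ``linkage`` is the SciPy linkage matrix; ``labels`` orders the leaves.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster id per label when cutting into ``n_clusters``."""
        assign = _hier.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from the merge heights."""
        tree = _hier.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                name = self.labels[node.id].replace(" ", "_")
                return f"{name}:{parent_height:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


def cluster_centroids(table: pd.DataFrame) -> ClusterTree:
    """Average-linkage (UPGMA) clustering of group centroid rows.

    ``table`` is groups x features; distances are Euclidean.  Merge
    heights are nondecreasing (UPGMA is monotone).
    """
    if table.index.duplicated().any():
        raise ValueError("duplicate group labels in centroid table")
    if len(table) < 2:
        raise ValueError("need at least 2 groups to cluster")
    Z = _hier.linkage(pdist(table.to_numpy()), method="average")
    return ClusterTree(linkage=Z, labels=[str(i) for i in table.index])
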