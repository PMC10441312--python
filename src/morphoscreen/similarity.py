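"""Profile similarity: PCA reduction, correlation, complex recall,
link-score binning, hierarchical clustering and UMAP embedding.

Hit-gene profiles are first reduced by PCA to the smallest number of
components capturing at least 70% of the variance (centering only — the
inputs are already MAD-normalized). Pairwise Pearson correlations of the
reduced profiles are then benchmarked against annotation tables: curated
complexes (within-complex vs background correlation distributions) and
pairwise link scores summarized over eight equally spaced correlation
bins. Hierarchical clustering uses Ward linkage on Euclidean distances
over the *rows of the correlation matrix* (the clustermap-on-correlations
convention), and leaf orders can be transferred between screens to build
diagonally merged comparison heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA


class VarianceTargetPCA(BaseEstimator, TransformerMixin):
    """PCA retaining the smallest component count reaching a variance target.

    Components are sign-fixed (the largest-|loading| entry of each component
    is made positive) so results are deterministic across backends. Inputs
    are centered but not rescaled.

    Attributes
    ----------
    n_components_ : retained component count
    explained_variance_ratio_ : per-component ratios of the retained set
    cumulative_explained_ : their sum (>= var_target)
    components_, mean_ : loadings and fitted center
    """

    def __init__(self, var_target: float = 0.70):
        self.var_target = var_target

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows (genes) for PCA")
        if X.shape[1] < 2:
            raise ValueError("need at least 2 feature columns for PCA")
        full = PCA(svd_solver="full").fit(X)
        cum = np.cumsum(full.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.var_target - 1e-12) + 1)
        k = min(k, len(cum))
        components = full.components_[:k].copy()
        flip = np.sign(
            components[np.arange(k), np.argmax(np.abs(components), axis=1)]
        )
        flip[flip == 0] = 1.0
        components *= flip[:, None]
        self.components_ = components
        self.mean_ = full.mean_
        self.n_components_ = k
        self.explained_variance_ratio_ = full.explained_variance_ratio_[:k]
        self.cumulative_explained_ = float(cum[k - 1])
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


@dataclass
class ReducedProfiles:
    """Hit-gene profiles in principal-component space."""

    scores: pd.DataFrame  # genes x components
    explained_variance_ratio: np.ndarray
    cumulative_explained: float
    model: VarianceTargetPCA


def reduce_pca(gene_profiles: pd.DataFrame, var_target: float = 0.70) -> ReducedProfiles:
    """Reduce gene x feature profiles to the variance-target PC space.

    ``gene_profiles`` must be indexed by gene with only numeric feature
    columns (use :func:`morphoscreen.profiling.feature_columns` upstream).
    """
    model = VarianceTargetPCA(var_target=var_target).fit(gene_profiles.to_numpy())
    scores = pd.DataFrame(
        model.transform(gene_profiles.to_numpy()),
        index=gene_profiles.index,
        columns=[f"PC{i + 1}" for i in range(model.n_components_)],
    )
    return ReducedProfiles(
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        cumulative_explained=model.cumulative_explained_,
        model=model,
    )


def pairwise_correlation(reduced: ReducedProfiles | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix over reduced profile rows.

    Zero-variance rows have undefined correlations; they are flagged with a
    warning and left as NaN.
    """
    scores = reduced.scores if isinstance(reduced, ReducedProfiles) else reduced
    if scores.shape[1] < 3:
        warnings.warn("fewer than 3 components; row correlations are degenerate")
    X = scores.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        warnings.warn("zero-variance profile rows; correlations set to NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=scores.index, columns=scores.index)


@dataclass
class ComplexRecallReport:
    """Within-complex vs background correlation comparison."""

    n_complexes: int
    complexes_used: list[str]
    within_pairs: pd.DataFrame  # complex_id, gene_a, gene_b, r
    within_median: float
    background_median: float
    separation_u: float  # Mann-Whitney U statistic, within vs background
    separation_p: float


def complex_recall(
    corr: pd.DataFrame,
    complexes: pd.DataFrame,
    hit_set: list[str] | None = None,
    coverage: float = 2 / 3,
) -> ComplexRecallReport:
    """Benchmark profile correlations against complex co-membership.

    A complex qualifies when at least ``coverage`` of its members (and at
    least 2) are in ``hit_set`` (default: all correlated genes). Within-pair
    correlations from qualifying complexes are compared to the background of
    all hit-pair correlations with a rank-based (Mann-Whitney) separation
    statistic.
    """
    hit_set = list(corr.index) if hit_set is None else [g for g in hit_set if g in corr.index]
    hits = set(hit_set)
    rows, used = [], []
    for cx, grp in complexes.groupby("complex_id"):
        members = list(dict.fromkeys(grp["gene"]))
        present = [g for g in members if g in hits]
        if len(present) < 2 or len(present) / len(members) < coverage:
            continue
        used.append(cx)
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                rows.append(
                    {
                        "complex_id": cx,
                        "gene_a": present[i],
                        "gene_b": present[j],
                        "r": float(corr.loc[present[i], present[j]]),
                    }
                )
    within = pd.DataFrame(rows, columns=["complex_id", "gene_a", "gene_b", "r"])
    sub = corr.loc[hit_set, hit_set].to_numpy()
    iu = np.triu_indices(len(hit_set), k=1)
    background = sub[iu]
    background = background[~np.isnan(background)]
    if not len(within):
        warnings.warn("no complex meets the coverage requirement")
        return ComplexRecallReport(
            n_complexes=0,
            complexes_used=[],
            within_pairs=within,
            within_median=float("nan"),
            background_median=float(np.median(background)) if len(background) else float("nan"),
            separation_u=float("nan"),
            separation_p=float("nan"),
        )
    u, p = stats.mannwhitneyu(
        within["r"].to_numpy(), background, alternative="greater"
    )
    return ComplexRecallReport(
        n_complexes=len(used),
        complexes_used=used,
        within_pairs=within,
        within_median=float(within["r"].median()),
        background_median=float(np.median(background)),
        separation_u=float(u),
        separation_p=float(p),
    )


def bin_by_correlation(
    corr_pairs: pd.DataFrame, link_scores: pd.DataFrame, n_bins: int = 8
) -> pd.DataFrame:
    """Summarize pairwise link scores over equally spaced correlation bins.

    ``corr_pairs`` has columns (gene_a, gene_b, r); ``link_scores`` has
    (gene_a, gene_b, score). Pairs present in both (order-insensitive) are
    binned by r into ``n_bins`` equal-width bins spanning the observed
    range; per bin the pair count and score quartiles are reported, plus a
    monotone-trend statistic (Spearman rho of r vs score over all pairs) in
    ``DataFrame.attrs["trend_rho"]``.
    """
    key = lambda df: df.apply(
        lambda row: tuple(sorted((row["gene_a"], row["gene_b"]))), axis=1
    )
    cp = corr_pairs.copy()
    ls = link_scores.copy()
    cp["pair"] = key(cp)
    ls["pair"] = key(ls)
    merged = cp.merge(ls[["pair", "score"]], on="pair", how="inner")
    if merged.empty:
        raise ValueError("no scored pairs overlap the correlation pairs")
    lo, hi = merged["r"].min(), merged["r"].max()
    edges = np.linspace(lo, hi, n_bins + 1)
    labels = np.clip(np.digitize(merged["r"], edges[1:-1]), 0, n_bins - 1)
    merged["bin"] = labels
    out_rows = []
    for b in range(n_bins):
        grp = merged[merged["bin"] == b]["score"]
        out_rows.append(
            {
                "bin": b,
                "r_low": edges[b],
                "r_high": edges[b + 1],
                "n_pairs": len(grp),
                "q25": grp.quantile(0.25) if len(grp) else np.nan,
                "median": grp.median() if len(grp) else np.nan,
                "q75": grp.quantile(0.75) if len(grp) else np.nan,
            }
        )
    out = pd.DataFrame(out_rows)
    rho, _ = stats.spearmanr(merged["r"], merged["score"])
    out.attrs["trend_rho"] = float(rho)
    return out


def cluster_order(corr: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Ward/Euclidean hierarchical clustering of correlation-matrix rows.

    Each row of the correlation matrix is treated as a vector (the
    clustermap convention); returns (leaf order as gene names, linkage
    matrix).
    """
    if corr.isna().any().any():
        raise ValueError("correlation matrix contains missing values")
    if len(corr) < 2:
        raise ValueError("need at least 2 rows to cluster")
    Z = linkage(corr.to_numpy(), method="ward", metric="euclidean")
    order = [corr.index[i] for i in leaves_list(Z)]
    return order, Z


def merged_heatmap_matrix(
    corr_a: pd.DataFrame, corr_b: pd.DataFrame, order_source: str = "A"
) -> tuple[pd.DataFrame, list[str]]:
    """Diagonally merged two-screen correlation matrix.

    Both matrices must share a gene set. The leaf order is computed from
    the chosen screen and applied to both; the lower triangle of the output
    comes from screen A, the upper from screen B, the diagonal is 1.
    """
    set_a, set_b = set(corr_a.index), set(corr_b.index)
    if set_a != set_b:
        diff = sorted(set_a.symmetric_difference(set_b))
        raise ValueError(f"gene sets differ; symmetric difference: {diff}")
    source = corr_a if order_source.upper() == "A" else corr_b
    order, _ = cluster_order(source)
    A = corr_a.loc[order, order].to_numpy()
    B = corr_b.loc[order, order].to_numpy()
    merged = np.tril(A, k=-1) + np.triu(B, k=1) + np.eye(len(order))
    return pd.DataFrame(merged, index=order, columns=order), order


def embed_umap(
    reduced: ReducedProfiles | pd.DataFrame,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """2-D UMAP embedding of reduced profiles with cosine distances."""
    import umap  # deferred: numba compilation is slow at import

    scores = reduced.scores if isinstance(reduced, ReducedProfiles) else reduced
    if len(scores) < 10:
        raise ValueError("need at least 10 rows to embed")
    if len(scores) <= n_neighbors:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be below the row count {len(scores)}"
        )
    model = umap.UMAP(
        n_components=2,
        metric="cosine",
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    coords = model.fit_transform(scores.to_numpy())
    return pd.DataFrame(coords, index=scores.index, columns=["UMAP1", "UMAP2"])


def knn_complex_enrichment(
    coords: pd.DataFrame, complexes: pd.DataFrame, k: int = 10
) -> float:
    """Same-complex k-NN enrichment of an embedding, relative to chance.

    Fraction of (gene, neighbour) pairs sharing a complex among each gene's
    k nearest embedded neighbours, divided by the fraction expected if
    neighbours were drawn at random. Values > 1 indicate that the embedding
    keeps complex members together.
    """
    cx_of = complexes.set_index("gene")["complex_id"].to_dict()
    genes = [g for g in coords.index if g in cx_of]
    if len(genes) < 2:
        return float("nan")
    X = coords.to_numpy()
    name_to_i = {g: i for i, g in enumerate(coords.index)}
    same, total = 0, 0
    for g in genes:
        i = name_to_i[g]
        d = np.linalg.norm(X - X[i], axis=1)
        d[i] = np.inf
        nn = np.argsort(d)[:k]
        for j in nn:
            other = coords.index[j]
            total += 1
            if cx_of.get(other) == cx_of[g]:
                same += 1
    observed = same / total
    n = len(coords)
    exp_same = 0
    for g in genes:
        members = sum(1 for h in genes if h != g and cx_of[h] == cx_of[g])
        exp_same += members / (n - 1)
    expected = exp_same / len(genes)
    return observed / expected if expected > 0 else float("inf")
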