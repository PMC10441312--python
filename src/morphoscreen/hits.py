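"""Gene-level hit calling against an empirical zero-TPM null.

Per gene and per retained feature, the guide-level profile values of the
gene's guides are compared to the non-targeting guides with a two-sided
Mann-Whitney U-test (normal approximation with tie and continuity
corrections). The per-gene *profile score* counts features with p < alpha
(default 0.001); the *morphological signal score* sums -log10 p over those
significant features. No multiple-testing correction is applied at the
feature level: error control happens at the gene level through an empirical
null — the 95th percentile of profile scores among zero-TPM genes (genes
with no expression in the screened line, whose knockouts are phenotypic
nulls) sets the hit threshold, so ~5% of zero-TPM genes exceed it by
construction (an empirical 5% FDR).

Compartment hits repeat the construction on the feature subset attributed
to one stain channel (texture, intensity, correlation, radial distribution
and granularity features of that channel; correlation features count toward
both of their channels; AreaShape features belong to no compartment), with
the zero-TPM threshold recomputed per compartment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .profiling import NONTARGETING, feature_columns

#: categories whose features are attributed to a stain-channel compartment
COMPARTMENT_CATEGORIES = frozenset(
    {"Texture", "Intensity", "Correlation", "RadialDistribution", "Granularity"}
)


def compartment_spec(
    feature_meta: pd.DataFrame, features: list[str] | None = None
) -> dict[str, list[str]]:
    """Map channel -> feature subset used for compartment hit calling.

    ``feature_meta`` is indexed by feature name with ``category``,
    ``channel`` and ``secondary_channel`` columns. ``features`` restricts to
    the retained (feature-selected) set. Subsets may overlap (a correlation
    feature belongs to its primary and secondary channel); AreaShape
    features appear in no subset.
    """
    meta = feature_meta if features is None else feature_meta.loc[
        [f for f in features if f in feature_meta.index]
    ]
    channels = sorted(
        set(meta["channel"].dropna())
        | set(meta["secondary_channel"].dropna())
    )
    channels = [c for c in channels if c != "none"]
    spec: dict[str, list[str]] = {}
    for ch in channels:
        mask = meta["category"].isin(COMPARTMENT_CATEGORIES) & (
            (meta["channel"] == ch) | (meta["secondary_channel"] == ch)
        )
        subset = list(meta.index[mask])
        if subset:
            spec[ch] = subset
        else:
            warnings.warn(f"channel {ch!r} has no retained compartment features; skipped")
    return spec


def feature_pvalues(
    guide_profiles: pd.DataFrame, gene: str, features: list[str] | None = None
) -> pd.Series:
    """Two-sided Mann-Whitney p-values of one gene's guides vs non-targeting.

    Uses the normal approximation with tie and continuity corrections (the
    control group is large). Features where both samples are completely tied
    get p = 1.
    """
    feats = features if features is not None else feature_columns(guide_profiles)
    gene_rows = guide_profiles[guide_profiles["gene"] == gene]
    nt_rows = guide_profiles[guide_profiles["is_nontargeting"]]
    if len(gene_rows) < 2:
        raise ValueError(f"gene {gene!r} has fewer than 2 guide profiles")
    return _mw_pvalues(
        gene_rows[feats].to_numpy(dtype=float),
        nt_rows[feats].to_numpy(dtype=float),
        feats,
    )


def _mw_pvalues(x: np.ndarray, y: np.ndarray, feats: list[str]) -> pd.Series:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(
            x, y, axis=0, alternative="two-sided", method="asymptotic"
        )
    p = np.asarray(res.pvalue, dtype=float)
    # fully tied columns have zero rank variance -> nan; no evidence -> p=1
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.Series(p, index=feats)


def pvalue_matrix(
    guide_profiles: pd.DataFrame,
    features: list[str] | None = None,
    min_nt: int = 10,
) -> pd.DataFrame:
    """Genes x features matrix of two-sided Mann-Whitney p-values."""
    feats = features if features is not None else feature_columns(guide_profiles)
    nt = guide_profiles[guide_profiles["is_nontargeting"]]
    if len(nt) < min_nt:
        raise ValueError(f"need >= {min_nt} non-targeting guide profiles, got {len(nt)}")
    y = nt[feats].to_numpy(dtype=float)
    rows = {}
    for gene, grp in guide_profiles[~guide_profiles["is_nontargeting"]].groupby(
        "gene", sort=True, observed=True
    ):
        if len(grp) < 2:
            warnings.warn(f"gene {gene!r} has < 2 guides; skipped")
            continue
        rows[gene] = _mw_pvalues(grp[feats].to_numpy(dtype=float), y, feats)
    return pd.DataFrame(rows).T[feats]


def profile_score(pvals: pd.Series | np.ndarray, alpha: float = 0.001) -> int:
    """Count of features with p strictly below ``alpha``."""
    p = np.asarray(pvals, dtype=float)
    return int((p < alpha).sum())


def signal_score(
    pvals: pd.Series | np.ndarray, alpha: float = 0.001, base: float = 10.0
) -> float:
    """Morphological signal score: sum of -log10 p over significant features.

    Zero when no feature is significant. p = 0 (not producible by the rank
    test but guarded anyway) is clamped to the smallest positive float.
    """
    p = np.asarray(pvals, dtype=float)
    if (p == 0).any():
        warnings.warn("p == 0 encountered; clamping to smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, None)
    sig = p[p < alpha]
    if sig.size == 0:
        return 0.0
    return float(-(np.log(sig) / np.log(base)).sum())


def percentile_threshold(scores: np.ndarray, quantile: float = 0.95) -> float:
    """Empirical quantile with linear interpolation between order statistics."""
    return float(np.percentile(np.asarray(scores, dtype=float), 100 * quantile))


def call_hits(
    scores: pd.Series, zero_tpm_genes: list[str], quantile: float = 0.95
) -> tuple[pd.Series, float]:
    """Whole-cell hit flags from per-gene profile scores.

    The threshold T is the empirical ``quantile`` (default 95th percentile,
    linear interpolation) of the zero-TPM genes' scores; a gene is a hit iff
    its score is strictly greater than T.
    """
    zt = [g for g in zero_tpm_genes if g in scores.index]
    if not zt:
        raise ValueError("no zero-TPM genes present among scored genes")
    if len(zt) < 20:
        warnings.warn(
            f"only {len(zt)} zero-TPM genes; the empirical threshold is unstable"
        )
    T = percentile_threshold(scores.loc[zt].to_numpy(), quantile)
    return scores > T, T


class EmpiricalFDRHitCaller(BaseEstimator):
    """Full hit-calling stage as a scikit-learn style estimator.

    Parameters
    ----------
    alpha : per-feature significance threshold for the rank test.
    quantile : zero-TPM empirical-null quantile defining the hit threshold.
    log_base : base of the -log p sum in the signal score.

    Fitted attributes
    -----------------
    pvalues_ : genes x features Mann-Whitney p-value matrix
    hit_table_ : per-gene scores, whole-cell and per-compartment hit flags
    threshold_ : whole-cell zero-TPM threshold
    compartment_thresholds_ : channel -> threshold
    spec_ : channel -> feature subset used
    """

    def __init__(
        self, alpha: float = 0.001, quantile: float = 0.95, log_base: float = 10.0
    ):
        self.alpha = alpha
        self.quantile = quantile
        self.log_base = log_base

    def fit(
        self,
        guide_profiles: pd.DataFrame,
        feature_meta: pd.DataFrame,
        zero_tpm_genes: list[str],
        features: list[str] | None = None,
    ):
        feats = features if features is not None else feature_columns(guide_profiles)
        self.pvalues_ = pvalue_matrix(guide_profiles, feats)
        pv = self.pvalues_

        scores = pd.Series(
            (pv.to_numpy() < self.alpha).sum(axis=1), index=pv.index, name="profile_score"
        )
        signal = pd.Series(
            [signal_score(pv.loc[g], self.alpha, self.log_base) for g in pv.index],
            index=pv.index,
            name="signal_score",
        )
        whole_hits, T = call_hits(scores, zero_tpm_genes, self.quantile)

        table = pd.DataFrame(
            {
                "profile_score": scores,
                "signal_score": signal,
                "whole_cell_hit": whole_hits,
            }
        )

        self.spec_ = compartment_spec(feature_meta, feats)
        self.compartment_thresholds_ = {}
        zt = [g for g in zero_tpm_genes if g in pv.index]
        for ch, subset in self.spec_.items():
            ch_scores = pd.Series(
                (pv[subset].to_numpy() < self.alpha).sum(axis=1), index=pv.index
            )
            T_ch = percentile_threshold(ch_scores.loc[zt].to_numpy(), self.quantile)
            self.compartment_thresholds_[ch] = T_ch
            table[f"{ch}_score"] = ch_scores
            table[f"{ch}_hit"] = ch_scores > T_ch

        self.threshold_ = T
        self.zero_tpm_genes_ = zt
        self.hit_table_ = table
        return self


def compartment_hits(
    pvals: pd.DataFrame,
    spec: dict[str, list[str]],
    zero_tpm_genes: list[str],
    alpha: float = 0.001,
    quantile: float = 0.95,
) -> pd.DataFrame:
    """Per-compartment profile scores and hit flags (standalone form).

    Each channel gets its own zero-TPM threshold recomputed on that
    channel's feature subset. A gene can be a hit in several compartments
    without being a whole-cell hit.
    """
    zt = [g for g in zero_tpm_genes if g in pvals.index]
    if not zt:
        raise ValueError("no zero-TPM genes present among scored genes")
    out = pd.DataFrame(index=pvals.index)
    for ch, subset in spec.items():
        present = [f for f in subset if f in pvals.columns]
        if not present:
            warnings.warn(f"channel {ch!r} has no features in the p-value matrix; skipped")
            continue
        scores = pd.Series((pvals[present].to_numpy() < alpha).sum(axis=1), index=pvals.index)
        T = percentile_threshold(scores.loc[zt].to_numpy(), quantile)
        out[f"{ch}_score"] = scores
        out[f"{ch}_hit"] = scores > T
        out.attrs[f"threshold_{ch}"] = T
    return out


def significant_feature_breakdown(
    pvals: pd.DataFrame,
    spec: dict[str, list[str]],
    gene_set: list[str],
    alpha: float = 0.001,
) -> tuple[pd.Series, int]:
    """Average per-channel share of a gene set's significant features.

    Per gene, the count of significant features in each channel subset is
    normalized by the subset size (so large compartments do not dominate
    merely by feature count), then scaled to sum to 1 across channels.
    Genes with no significant feature in any compartment contribute nothing;
    the count of such excluded genes is returned alongside the averaged
    fractions.
    """
    if not gene_set:
        raise ValueError("gene_set is empty")
    channels = list(spec)
    fractions = []
    excluded = 0
    for g in gene_set:
        p = pvals.loc[g]
        raw = np.array(
            [
                (p[[f for f in spec[ch] if f in p.index]] < alpha).sum() / len(spec[ch])
                for ch in channels
            ],
            dtype=float,
        )
        total = raw.sum()
        if total == 0:
            excluded += 1
            continue
        fractions.append(raw / total)
    if not fractions:
        return pd.Series(0.0, index=channels), excluded
    avg = np.mean(fractions, axis=0)
    return pd.Series(avg, index=channels), excluded
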