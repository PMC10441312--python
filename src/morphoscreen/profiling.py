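"""Single-cell tables -> guide-level and gene-level morphological profiles.

The processing chain follows standard image-based-profiling practice:

1. median-aggregate single cells to one profile per (guide, plate);
2. robust-normalize each plate against its non-targeting controls
   (median / scaled MAD);
3. feature selection (missingness, near-constant, redundancy filters);
4. median-aggregate plates to one profile per guide, then guides to one
   profile per gene.

Profile frames carry their metadata as ordinary columns (``guide_id``,
``gene``, ``plate``, ``cell_count``, ``is_nontargeting``); every other
column is a feature. The normalizer and feature selector are scikit-learn
style estimators (``fit``/``transform``, fitted attributes with trailing
underscores) so they compose with sklearn pipelines; the module-level
functions mirror them for script use.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

NONTARGETING = "nontargeting"

#: reserved metadata columns of profile frames (never treated as features)
PROFILE_META_COLS = [
    "guide_id",
    "gene",
    "plate",
    "cell_count",
    "is_nontargeting",
    "n_plates",
    "n_guides",
]

#: MAD -> SD consistency constant under normality
MAD_CONSISTENCY = 1.4826


def feature_columns(frame: pd.DataFrame) -> list[str]:
    """Columns of a cell/profile frame that are features (non-metadata)."""
    from .synthetic import CELL_META_COLS

    reserved = set(PROFILE_META_COLS) | set(CELL_META_COLS)
    return [c for c in frame.columns if c not in reserved]


def aggregate_cells_to_guides(cells: pd.DataFrame) -> pd.DataFrame:
    """Median-aggregate single cells to one profile per (guide, plate).

    Records the contributing cell count per row. Guides absent from a plate
    simply have no row there (coverage is visible via the plate column).
    """
    feats = feature_columns(cells)
    if "guide_id" not in cells.columns or "plate" not in cells.columns:
        raise ValueError("cell table must have 'guide_id' and 'plate' columns")
    grouped = cells.groupby(["guide_id", "plate"], sort=True, observed=True)
    medians = grouped[feats].median()
    meta = grouped.agg(gene=("gene", "first"), cell_count=("gene", "size"))
    out = pd.concat([meta, medians], axis=1).reset_index()
    out.insert(2, "is_nontargeting", out["gene"] == NONTARGETING)
    cols = ["guide_id", "plate", "gene", "is_nontargeting", "cell_count"] + feats
    return out[cols]


class RobustMADNormalizer(BaseEstimator, TransformerMixin):
    """Per-plate robust z-scoring against non-targeting controls.

    For each plate and feature the center is the median and the scale is
    ``1.4826 x MAD`` of the non-targeting guide profiles on that plate, so
    the scale estimates the SD under normality:

        x' = (x - median_NT) / (1.4826 * MAD_NT)

    Features whose non-targeting MAD is exactly zero on a plate are flagged
    constant-on-plate and their values set to missing for that plate (to be
    resolved by feature selection).

    Attributes
    ----------
    center_, scale_ : DataFrame (plate x feature)
    constant_features_ : dict plate -> list of flagged features
    """

    def __init__(self, consistency: float = MAD_CONSISTENCY, min_nt_rows: int = 2):
        self.consistency = consistency
        self.min_nt_rows = min_nt_rows

    def fit(self, profiles: pd.DataFrame, y=None):
        feats = feature_columns(profiles)
        nt = profiles[profiles["is_nontargeting"]]
        centers, scales, constant = {}, {}, {}
        for plate, grp in nt.groupby("plate", observed=True):
            if len(grp) < self.min_nt_rows:
                raise ValueError(
                    f"plate {plate!r} has {len(grp)} non-targeting rows; "
                    f"need >= {self.min_nt_rows}"
                )
            vals = grp[feats].to_numpy(dtype=float)
            med = np.nanmedian(vals, axis=0)
            mad = np.nanmedian(np.abs(vals - med), axis=0)
            centers[plate] = med
            scales[plate] = self.consistency * mad
            constant[plate] = [f for f, m in zip(feats, mad) if m == 0]
        plates = sorted(centers)
        self.feature_names_ = feats
        self.center_ = pd.DataFrame(
            [centers[p] for p in plates], index=plates, columns=feats
        )
        self.scale_ = pd.DataFrame(
            [scales[p] for p in plates], index=plates, columns=feats
        )
        self.constant_features_ = constant
        return self

    def transform(self, profiles: pd.DataFrame) -> pd.DataFrame:
        feats = self.feature_names_
        out = profiles.copy()
        for plate in out["plate"].unique():
            if plate not in self.center_.index:
                raise ValueError(f"plate {plate!r} was not seen during fit")
            mask = out["plate"] == plate
            center = self.center_.loc[plate].to_numpy()
            scale = self.scale_.loc[plate].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (out.loc[mask, feats].to_numpy(dtype=float) - center) / scale
            z[:, scale == 0] = np.nan
            out.loc[mask, feats] = z
        return out


def robust_normalize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Fit-and-apply :class:`RobustMADNormalizer` on guide-plate profiles."""
    return RobustMADNormalizer().fit(profiles).transform(profiles)


class CorrelationFeatureSelector(BaseEstimator, TransformerMixin):
    """Missingness, near-constant, and redundancy feature filters.

    Applied in order on normalized guide-plate profiles:

    1. drop features with a missing value anywhere (a feature unusable on
       one plate cannot be median-aggregated comparably across plates);
    2. drop near-constant features (most frequent value accounting for more
       than ``max_mode_fraction`` of rows);
    3. greedy redundancy filter: while any retained pair has
       ``|Pearson r| > corr_threshold``, drop from the worst offending pair
       the feature with the larger mean ``|r|`` to all other retained
       features (ties broken lexicographically by name).

    Attributes
    ----------
    selected_features_ : list of retained feature names
    drop_counts_ : dict step -> number of features dropped
    dropped_ : dict step -> list of dropped features
    """

    def __init__(self, corr_threshold: float = 0.9, max_mode_fraction: float = 0.99):
        self.corr_threshold = corr_threshold
        self.max_mode_fraction = max_mode_fraction

    def fit(self, profiles: pd.DataFrame, y=None):
        feats = feature_columns(profiles)
        X = profiles[feats]

        missing = [f for f in feats if X[f].isna().any()]
        kept = [f for f in feats if f not in set(missing)]

        near_constant = []
        n_rows = len(X)
        for f in kept:
            top = X[f].value_counts(dropna=False).iloc[0]
            if top / n_rows > self.max_mode_fraction:
                near_constant.append(f)
        kept = [f for f in kept if f not in set(near_constant)]
        if not kept:
            raise ValueError("all features dropped before redundancy filtering")

        # constant features yield undefined correlations; treat as 0 (they
        # are near-constant-filter escapees with no redundancy signal)
        corr = np.nan_to_num(X[kept].corr().abs().to_numpy())
        np.fill_diagonal(corr, 0.0)
        names = list(kept)
        redundant = []
        while True:
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            if corr[i, j] <= self.corr_threshold:
                break
            mean_i = corr[i].sum() / max(len(names) - 1, 1)
            mean_j = corr[j].sum() / max(len(names) - 1, 1)
            if mean_i > mean_j or (mean_i == mean_j and names[i] > names[j]):
                drop = i
            else:
                drop = j
            redundant.append(names[drop])
            corr = np.delete(np.delete(corr, drop, axis=0), drop, axis=1)
            del names[drop]
        kept = names
        if not kept:
            raise ValueError("all features dropped")

        self.selected_features_ = kept
        self.dropped_ = {
            "missing": missing,
            "near_constant": near_constant,
            "redundant": redundant,
        }
        self.drop_counts_ = {k: len(v) for k, v in self.dropped_.items()}
        return self

    def transform(self, profiles: pd.DataFrame) -> pd.DataFrame:
        meta = [c for c in profiles.columns if c in PROFILE_META_COLS]
        return profiles[meta + self.selected_features_]


def select_features(profiles: pd.DataFrame, corr_threshold: float = 0.9) -> list[str]:
    """Retained feature list after the three filtering steps."""
    sel = CorrelationFeatureSelector(corr_threshold=corr_threshold).fit(profiles)
    return sel.selected_features_


def aggregate_plates(profiles: pd.DataFrame) -> pd.DataFrame:
    """Median-aggregate guide-plate profiles to one profile per guide."""
    feats = feature_columns(profiles)
    grouped = profiles.groupby("guide_id", sort=True, observed=True)
    medians = grouped[feats].median()
    meta = grouped.agg(
        gene=("gene", "first"),
        is_nontargeting=("is_nontargeting", "first"),
        n_plates=("plate", "nunique"),
    )
    return pd.concat([meta, medians], axis=1).reset_index()


def aggregate_guides_to_genes(
    profiles: pd.DataFrame, include_nontargeting: bool = True
) -> pd.DataFrame:
    """Median-aggregate guide-screen profiles to one profile per gene.

    Non-targeting guides aggregate into a single ``"nontargeting"``
    pseudo-gene row (dropped when ``include_nontargeting=False``); the
    contributing guide count is recorded per gene.
    """
    feats = feature_columns(profiles)
    grouped = profiles.groupby("gene", sort=True, observed=True)
    medians = grouped[feats].median()
    meta = grouped.agg(n_guides=("guide_id", "nunique"))
    out = pd.concat([meta, medians], axis=1).reset_index()
    if not include_nontargeting:
        out = out[out["gene"] != NONTARGETING].reset_index(drop=True)
    return out


def profile_pipeline(
    cells: pd.DataFrame, corr_threshold: float = 0.9
) -> dict[str, object]:
    """Run the full cells -> gene-profiles chain; returns all intermediates.

    Keys: ``guide_plate`` (normalized, feature-selected), ``guide_plate_full``
    (normalized, pre-selection), ``guide_screen``, ``gene``, ``features``
    (retained list), ``selector``, ``normalizer``.
    """
    gp = aggregate_cells_to_guides(cells)
    norm = RobustMADNormalizer().fit(gp)
    gp_norm = norm.transform(gp)
    sel = CorrelationFeatureSelector(corr_threshold=corr_threshold).fit(gp_norm)
    gp_sel = sel.transform(gp_norm)
    gs = aggregate_plates(gp_sel)
    gene = aggregate_guides_to_genes(gs)
    return {
        "guide_plate_full": gp_norm,
        "guide_plate": gp_sel,
        "guide_screen": gs,
        "gene": gene,
        "features": sel.selected_features_,
        "selector": sel,
        "normalizer": norm,
    }
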