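"""Gene rankings, preranked set enrichment, and single-feature screens.

Genes are ranked either by morphological signal score (screen-wide signal
strength) or by cosine similarity of their full feature-selected profile
to a query gene's profile. Ranked lists feed a preranked set-enrichment
statistic — the weighted Kolmogorov-Smirnov running sum with a gene-label
permutation null — implemented here directly so the pipeline is
self-contained (normalization details of external enrichment tools are not
reproduced).

Single-feature screens build, per feature, a "Top 20+" list (all genes with
p-value no larger than the 20th smallest, ties included) and assess term
enrichment with one-sided Fisher exact tests, Benjamini-Hochberg correction
across terms per feature, and an additional Bonferroni correction across
features for term-family screens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvals: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvals, dtype=float)
    return multipletests(arr, method="fdr_bh")[1]


def rank_by_signal(hit_table: pd.DataFrame) -> pd.DataFrame:
    """All genes ranked descending by morphological signal score.

    Ties are broken by lexicographic gene id for determinism. Returns a
    frame indexed by gene with a ``value`` column, ``attrs["mode"]`` set.
    """
    if "signal_score" not in hit_table.columns:
        raise ValueError("hit table lacks a 'signal_score' column")
    s = hit_table["signal_score"]
    out = (
        pd.DataFrame({"gene": s.index, "value": s.to_numpy(dtype=float)})
        .sort_values(["value", "gene"], ascending=[False, True], kind="mergesort")
        .set_index("gene")
    )
    out.attrs["mode"] = "signal"
    return out


def rank_by_similarity(gene_profiles: pd.DataFrame, query_gene: str) -> pd.DataFrame:
    """All genes ranked by cosine similarity to the query gene's profile.

    Similarity is computed in the full feature-selected profile space. The
    query ranks first with similarity 1. Zero-norm profiles have undefined
    similarity: they are placed last and flagged in a ``degenerate`` column.
    """
    if query_gene not in gene_profiles.index:
        raise ValueError(f"query gene {query_gene!r} not in profiles")
    X = gene_profiles.to_numpy(dtype=float)
    q = gene_profiles.loc[query_gene].to_numpy(dtype=float)
    qn = np.linalg.norm(q)
    if qn == 0:
        raise ValueError("query gene has a zero-norm profile")
    norms = np.linalg.norm(X, axis=1)
    degenerate = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (X @ q) / (norms * qn)
    sims[degenerate] = -np.inf
    out = pd.DataFrame(
        {
            "gene": gene_profiles.index,
            "value": sims,
            "degenerate": degenerate,
        }
    ).sort_values(["value", "gene"], ascending=[False, True], kind="mergesort")
    out = out.set_index("gene")
    out.loc[out["degenerate"], "value"] = np.nan
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-norm profiles placed last")
    out.attrs["mode"] = f"similarity:{query_gene}"
    return out


def enrichment_score(
    ranked_genes: list[str], values: np.ndarray, gene_set: set[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS running-sum enrichment score for one gene set.

    Hits advance the running sum proportionally to |value|^weight
    (normalized to 1 in total); misses retreat by 1/(N - set size). The ES
    is the maximum-magnitude deviation of the running sum, signed. Returns
    (ES, running sum).
    """
    N = len(ranked_genes)
    is_hit = np.fromiter((g in gene_set for g in ranked_genes), bool, count=N)
    n_hit = int(is_hit.sum())
    if n_hit == 0 or n_hit == N:
        return 0.0, np.zeros(N)
    w = np.abs(np.asarray(values, dtype=float)) ** weight
    w = np.where(np.isnan(w), 0.0, w)
    hit_mass = w * is_hit
    denom = hit_mass.sum()
    if denom == 0:  # all hit weights zero -> uniform increments
        hit_mass = is_hit.astype(float)
        denom = n_hit
    step = hit_mass / denom - (~is_hit) / (N - n_hit)
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


@dataclass
class EnrichmentResult:
    gene_set: str
    size: int
    es: float
    nes: float
    pvalue: float
    qvalue: float
    leading_edge: list[str]


def preranked_enrichment(
    ranked: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    n_perm: int = 2000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 3,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked enrichment over a collection of gene sets.

    ``ranked`` is the output of a ``rank_by_*`` function (descending
    ``value`` per gene). The permutation null shuffles gene labels
    ``n_perm`` times with a fixed seed; p-values are two-sided on |ES|, the
    normalized score divides ES by the mean |ES| of same-sign permutations,
    and q-values are BH across the tested sets.
    """
    genes = list(ranked.index)
    values = ranked["value"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    results = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in set(genes)]
        if not present:
            warnings.warn(f"gene set {name!r} has no genes in the ranked universe; skipped")
            continue
        if not (min_size <= len(present) <= max_size):
            continue
        gs = set(present)
        es, running = enrichment_score(genes, values, gs, weight)
        k = len(present)
        perm_es = np.empty(n_perm)
        gene_arr = np.array(genes)
        for b in range(n_perm):
            perm_set = set(rng.choice(gene_arr, size=k, replace=False))
            perm_es[b], _ = enrichment_score(genes, values, perm_set, weight)
        p = (1 + np.sum(np.abs(perm_es) >= abs(es))) / (n_perm + 1)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        denom = np.mean(np.abs(same_sign)) if len(same_sign) else np.nan
        nes = es / denom if denom and not np.isnan(denom) else 0.0
        # leading edge: hits at or before the running-sum extremum
        i_max = int(np.argmax(np.abs(running)))
        if es >= 0:
            leading = [g for g in genes[: i_max + 1] if g in gs]
        else:
            leading = [g for g in genes[i_max:] if g in gs]
        results.append(
            EnrichmentResult(
                gene_set=name,
                size=k,
                es=es,
                nes=float(nes),
                pvalue=float(p),
                qvalue=np.nan,
                leading_edge=leading,
            )
        )
    if not results:
        return pd.DataFrame(
            columns=["gene_set", "size", "es", "nes", "pvalue", "qvalue", "leading_edge"]
        )
    out = pd.DataFrame([r.__dict__ for r in results])
    out["qvalue"] = bh_adjust(out["pvalue"])
    return out.sort_values("pvalue", kind="mergesort").reset_index(drop=True)


def top20plus(feature_pvals: pd.Series, top_n: int = 20) -> list[str]:
    """All genes with p <= the ``top_n``-th smallest p-value (ties included).

    With fewer than ``top_n`` genes, the whole universe is returned.
    """
    s = feature_pvals.dropna().sort_values(kind="mergesort")
    if len(s) <= top_n:
        return list(s.index)
    cutoff = s.iloc[top_n - 1]
    return list(s.index[s <= cutoff])


def fisher_enrichment(
    gene_list: list[str], term_genes: list[str], universe: list[str]
) -> float:
    """One-sided (enrichment) Fisher exact p for a gene list vs a term."""
    uni = set(universe)
    lst = set(gene_list) & uni
    term = set(term_genes) & uni
    a = len(lst & term)
    b = len(lst - term)
    c = len(term - lst)
    d = len(uni) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def feature_screen_enrichment(
    top_lists: dict[str, list[str]],
    term_sets: dict[str, list[str]],
    universe: list[str],
    alpha: float = 0.05,
    family_bonferroni: bool = True,
) -> pd.DataFrame:
    """Fisher enrichment of term sets in per-feature Top 20+ lists.

    Per (feature, term): one-sided Fisher exact p; BH across terms within
    each feature; optionally an additional Bonferroni correction across
    features (term-family screens). ``enriched`` flags q < alpha (and
    Bonferroni-adjusted p < alpha when enabled).
    """
    n_features = len(top_lists)
    rows = []
    for feature, gene_list in top_lists.items():
        ps, names = [], []
        for term, members in term_sets.items():
            if not members:
                warnings.warn(f"term {term!r} is empty; skipped")
                continue
            ps.append(fisher_enrichment(gene_list, members, universe))
            names.append(term)
        if not ps:
            continue
        qs = bh_adjust(np.array(ps))
        for term, p, q in zip(names, ps, qs):
            p_bonf = min(p * n_features, 1.0) if family_bonferroni else np.nan
            enriched = q < alpha and (not family_bonferroni or p_bonf < alpha)
            rows.append(
                {
                    "feature": feature,
                    "term": term,
                    "pvalue": p,
                    "qvalue": q,
                    "bonferroni_p": p_bonf,
                    "enriched": enriched,
                }
            )
    return pd.DataFrame(
        rows, columns=["feature", "term", "pvalue", "qvalue", "bonferroni_p", "enriched"]
    )


def enrichment_tallies(
    results: pd.DataFrame, feature_meta: pd.DataFrame
) -> pd.DataFrame:
    """Count enriched (feature, term) results per channel and category."""
    if results.empty:
        return pd.DataFrame(columns=["channel", "category", "n_enriched"])
    enriched = results[results["enriched"]]
    meta = feature_meta.loc[[f for f in enriched["feature"] if f in feature_meta.index]]
    tally = (
        meta.groupby(["channel", "category"], observed=True)
        .size()
        .rename("n_enriched")
        .reset_index()
    )
    return tally


def granularity_profile(
    gene_group: list[str],
    profiles: pd.DataFrame,
    feature_meta: pd.DataFrame,
    channel: str,
    hit_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Granularity-spectrum traces for a gene group in one channel.

    ``profiles`` must be gene-level, normalized but *not* feature-selected
    (granularity indices must all be present). Returns one row per
    (gene, granularity index) plus ``"__group_mean__"`` rows; genes outside
    ``hit_genes`` (when given) are flagged ``is_hit=False`` so callers can
    render them dashed.
    """
    gran = feature_meta[
        (feature_meta["category"] == "Granularity") & (feature_meta["channel"] == channel)
    ].copy()
    if gran.empty:
        raise ValueError(f"channel {channel!r} has no granularity features")
    gran = gran.sort_values("granularity_index")
    feats = [f for f in gran.index if f in profiles.columns]
    if not feats:
        raise ValueError(f"profiles lack granularity features for channel {channel!r}")
    idx_of = gran.loc[feats, "granularity_index"]
    hits = set(hit_genes) if hit_genes is not None else None
    rows = []
    for g in gene_group:
        if g not in profiles.index:
            raise ValueError(f"gene {g!r} not in profiles")
        for f in feats:
            rows.append(
                {
                    "gene": g,
                    "granularity_index": int(idx_of[f]),
                    "value": float(profiles.loc[g, f]),
                    "is_hit": True if hits is None else g in hits,
                }
            )
    out = pd.DataFrame(rows)
    mean = (
        out.groupby("granularity_index")["value"].mean().reset_index().assign(
            gene="__group_mean__", is_hit=True
        )
    )
    return pd.concat([out, mean], ignore_index=True)[
        ["gene", "granularity_index", "value", "is_hit"]
    ]


def essentiality_split(
    hit_table: pd.DataFrame, gene_effect: pd.DataFrame, threshold: float = -0.5
) -> dict[str, object]:
    """Split scored genes by essentiality and summarize signal scores.

    Genes with a gene-effect (essentiality) score <= ``threshold`` are
    classed essential. Genes missing from the gene-effect table are
    excluded and counted.
    """
    ge = gene_effect.set_index("gene")["gene_effect"] if "gene" in gene_effect.columns else gene_effect["gene_effect"]
    genes = hit_table.index
    covered = [g for g in genes if g in ge.index]
    missing = len(genes) - len(covered)
    labels = pd.Series(
        np.where(ge.loc[covered].to_numpy() <= threshold, "essential", "nonessential"),
        index=covered,
    )
    summary = {}
    for group in ("essential", "nonessential"):
        members = labels.index[labels == group]
        scores = hit_table.loc[members, "signal_score"]
        summary[group] = {
            "n": int(len(members)),
            "median_signal": float(scores.median()) if len(members) else float("nan"),
            "q25": float(scores.quantile(0.25)) if len(members) else float("nan"),
            "q75": float(scores.quantile(0.75)) if len(members) else float("nan"),
            "hit_rate": float(hit_table.loc[members, "whole_cell_hit"].mean())
            if "whole_cell_hit" in hit_table.columns and len(members)
            else float("nan"),
        }
    n_hits = (
        int(hit_table["whole_cell_hit"].sum())
        if "whole_cell_hit" in hit_table.columns
        else 0
    )
    noness_hits = (
        int(hit_table.loc[labels.index[labels == "nonessential"], "whole_cell_hit"].sum())
        if "whole_cell_hit" in hit_table.columns
        else 0
    )
    return {
        "labels": labels,
        "summary": summary,
        "n_missing": missing,
        "fraction_hits_nonessential": noness_hits / n_hits if n_hits else float("nan"),
    }
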