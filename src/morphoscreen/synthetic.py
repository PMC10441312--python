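"""Synthetic optical pooled-screen generator.

Produces ground-truth-labelled single-cell morphological feature tables with
the statistical structure the downstream pipeline assumes: a pooled guide
library (~4 guides per gene plus a pool of non-targeting controls), multiple
plates with plate-level batch offsets, five stain channels crossed with
CellProfiler-style feature categories, a zero-TPM null gene subset with no
gene-specific effect, effect genes with compartment-biased mean shifts, and
gene groups ("complexes") sharing effect directions.

Two classes of perturbation signal are injected:

* **gene effects** — sparse per-gene mean-shift vectors, concentrated in one
  designated channel, present only for effect genes;
* **a cutting signature** — a fixed sparse shift applied to *every* targeting
  guide (scaled by a per-guide efficiency), absent from non-targeting guides.
  This emulates the generic response to Cas9 cutting that makes any targeting
  knockout differ systematically from non-targeting controls, and is the
  reason empirical hit thresholds are taken from zero-TPM gene knockouts
  rather than from non-targeting guides. Zero-TPM genes carry the cutting
  signature but have an all-zero gene effect vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_CHANNELS = ("DNA", "ER", "Mito", "Actin", "WGA")
DEFAULT_CATEGORIES = (
    "Intensity",
    "Texture",
    "Granularity",
    "Correlation",
    "RadialDistribution",
    "AreaShape",
)

#: metadata (non-feature) columns of a single-cell table
CELL_META_COLS = ["plate", "well", "cell_id", "guide_id", "barcode", "gene"]

_BASES = np.array(list("ACGT"))


@dataclass
class ScreenConfig:
    """Parameters of a synthetic screen.

    Counts must be positive, proportions in [0, 1], and ``guides_per_gene``
    at least 2 (the guide-vs-control rank test needs two targeting values).
    ``n_features`` must cover at least one feature per (category, channel)
    cell so every compartment subset is non-empty.
    """

    n_genes: int = 200
    guides_per_gene: int = 4
    n_nontargeting: int = 60
    nontargeting_fraction: float = 0.10
    n_plates: int = 2
    cells_per_guide_per_plate: int = 30
    n_features: int = 300
    channels: tuple = DEFAULT_CHANNELS
    categories: tuple = DEFAULT_CATEGORIES
    frac_zero_tpm: float = 0.5
    frac_effect_genes: float = 0.8
    effect_size: float = 2.0
    n_effect_features: int = 30
    compartment_specificity: float = 0.8
    n_complexes: int = 5
    complex_size: int = 4
    noise_sd: float = 1.0
    cutting_effect_size: float = 0.5
    cutting_signature_frac: float = 0.10
    plate_effect_sd: float = 0.3  # as a multiple of noise_sd; 0 disables
    heavy_tails: bool = False  # Student-t (df=5) cell noise instead of Gaussian
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "guides_per_gene": self.guides_per_gene,
            "n_nontargeting": self.n_nontargeting,
            "n_plates": self.n_plates,
            "cells_per_guide_per_plate": self.cells_per_guide_per_plate,
            "n_features": self.n_features,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        props = {
            "nontargeting_fraction": self.nontargeting_fraction,
            "frac_zero_tpm": self.frac_zero_tpm,
            "frac_effect_genes": self.frac_effect_genes,
            "compartment_specificity": self.compartment_specificity,
            "cutting_signature_frac": self.cutting_signature_frac,
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.guides_per_gene < 2:
            raise ValueError("guides_per_gene must be >= 2")
        n_cells_grid = len(self.channels) * len(self.categories)
        if self.n_features < n_cells_grid:
            raise ValueError(
                f"n_features={self.n_features} cannot cover all "
                f"{n_cells_grid} (category, channel) combinations"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0 or self.cutting_effect_size < 0:
            raise ValueError("effect sizes must be non-negative")


@dataclass
class GroundTruth:
    """Per-gene ground truth of a synthetic screen.

    ``genes`` carries one row per gene with is_effect / is_zero_tpm flags, the
    designated effect channel, complex membership, TPM and essentiality
    (gene-effect) scores. ``effect_vectors`` is the genes x features matrix of
    injected mean shifts (all-zero rows for null and zero-TPM genes).
    ``cutting_signature`` is the fixed per-feature shift shared by all
    targeting guides; ``guide_efficiency`` maps guide_id -> efficiency.
    """

    genes: pd.DataFrame
    effect_vectors: pd.DataFrame
    cutting_signature: pd.Series
    guide_efficiency: pd.Series

    @property
    def effect_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_effect"]])

    @property
    def zero_tpm_genes(self) -> list[str]:
        return list(self.genes.index[self.genes["is_zero_tpm"]])

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.reset_index().to_dict(orient="list"),
            "effect_vectors": {
                "index": list(self.effect_vectors.index),
                "columns": list(self.effect_vectors.columns),
                "values": self.effect_vectors.to_numpy().tolist(),
            },
            "cutting_signature": self.cutting_signature.to_dict(),
            "guide_efficiency": self.guide_efficiency.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genes = pd.DataFrame(payload["genes"]).set_index("gene")
        ev = payload["effect_vectors"]
        vectors = pd.DataFrame(
            np.asarray(ev["values"]), index=ev["index"], columns=ev["columns"]
        )
        return cls(
            genes=genes,
            effect_vectors=vectors,
            cutting_signature=pd.Series(payload["cutting_signature"]),
            guide_efficiency=pd.Series(payload["guide_efficiency"]),
        )


def make_feature_metadata(config: ScreenConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Feature metadata table: name, category, channel, secondary channel.

    Features are distributed round-robin over the (category, channel) grid;
    AreaShape features have channel "none". Correlation features additionally
    get a secondary channel (a different stain measured against the primary).
    Granularity features carry a granularity (structure-size) index.
    """
    combos = []
    for cat in config.categories:
        if cat == "AreaShape":
            combos.append((cat, "none"))
        else:
            for ch in config.channels:
                combos.append((cat, ch))
    rows = []
    gran_counters: dict[str, int] = {}
    for i in range(config.n_features):
        cat, ch = combos[i % len(combos)]
        name = f"{cat}_{ch}_{i}"
        secondary = None
        gran_index = None
        if cat == "Correlation" and ch != "none":
            others = [c for c in config.channels if c != ch]
            secondary = others[int(rng.integers(len(others)))]
        if cat == "Granularity":
            k = gran_counters.get(ch, 0)
            gran_index = k % 16 + 1
            gran_counters[ch] = k + 1
        rows.append(
            {
                "feature_name": name,
                "category": cat,
                "channel": ch,
                "secondary_channel": secondary,
                "granularity_index": gran_index,
            }
        )
    return pd.DataFrame(rows).set_index("feature_name")


def _random_barcodes(n: int, length: int, prefix_len: int, rng: np.random.Generator) -> list[str]:
    """Random DNA sequences with pairwise-distinct prefixes (rejection sampled)."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        if seq[:prefix_len] in seen:
            continue
        seen.add(seq[:prefix_len])
        out.append(seq)
    return out


def _make_guide_library(config: ScreenConfig, genes: list[str], rng: np.random.Generator) -> pd.DataFrame:
    guide_ids, guide_genes = [], []
    for g in genes:
        for k in range(config.guides_per_gene):
            guide_ids.append(f"{g}_g{k + 1}")
            guide_genes.append(g)
    for k in range(config.n_nontargeting):
        guide_ids.append(f"NT_{k + 1:04d}")
        guide_genes.append("nontargeting")
    seqs = _random_barcodes(len(guide_ids), 19, 12, rng)
    return pd.DataFrame(
        {
            "guide_id": guide_ids,
            "sequence": seqs,
            "gene": guide_genes,
            "prefix12": [s[:12] for s in seqs],
            "source_pool": "synthetic",
        }
    ).set_index("guide_id")


def _make_ground_truth(
    config: ScreenConfig, features: pd.DataFrame, rng: np.random.Generator
) -> GroundTruth:
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    n_zero = int(round(config.frac_zero_tpm * config.n_genes))
    perm = rng.permutation(config.n_genes)
    zero_idx = set(perm[:n_zero].tolist())
    nonnull_order = [i for i in perm if i not in zero_idx]
    n_eff = int(round(config.frac_effect_genes * len(nonnull_order)))
    eff_idx = set(nonnull_order[:n_eff])

    feat_names = list(features.index)
    n_f = config.n_features
    vectors = np.zeros((config.n_genes, n_f))
    channel_of = features["channel"].to_numpy()

    # complex templates: shared feature subset + sign pattern per complex
    n_cx = min(config.n_complexes, n_eff // max(config.complex_size, 1))
    cx_assign: dict[int, int] = {}
    eff_list = sorted(eff_idx)
    rng.shuffle(eff_list)
    for c in range(n_cx):
        for j in range(config.complex_size):
            cx_assign[eff_list[c * config.complex_size + j]] = c

    gene_channel = [None] * config.n_genes
    cx_channel: dict[int, str] = {}
    cx_template: dict[int, np.ndarray] = {}
    for gi in sorted(eff_idx):
        cx = cx_assign.get(gi)
        if cx is not None and cx in cx_template:
            base = cx_template[cx]
            chan = cx_channel[cx]
            scale = rng.uniform(0.8, 1.2)
            vectors[gi] = base * scale
            gene_channel[gi] = chan
            continue
        chan = config.channels[int(rng.integers(len(config.channels)))]
        in_chan = np.flatnonzero(channel_of == chan)
        out_chan = np.flatnonzero(channel_of != chan)
        n_sel = min(config.n_effect_features, n_f)
        k_chan = min(int(round(config.compartment_specificity * n_sel)), len(in_chan))
        k_out = min(n_sel - k_chan, len(out_chan))
        chosen = np.concatenate(
            [
                rng.choice(in_chan, size=k_chan, replace=False),
                rng.choice(out_chan, size=k_out, replace=False),
            ]
        )
        vec = np.zeros(n_f)
        vec[chosen] = config.effect_size * rng.choice([-1.0, 1.0], size=len(chosen))
        gene_channel[gi] = chan
        if cx is not None:
            cx_template[cx] = vec.copy()
            cx_channel[cx] = chan
            vec = vec * rng.uniform(0.8, 1.2)
        vectors[gi] = vec

    n_sig = int(round(config.cutting_signature_frac * n_f))
    sig = np.zeros(n_f)
    if n_sig > 0 and config.cutting_effect_size > 0:
        sig_idx = rng.choice(n_f, size=n_sig, replace=False)
        sig[sig_idx] = config.cutting_effect_size * rng.choice([-1.0, 1.0], size=n_sig)

    tpm = np.where(
        [i in zero_idx for i in range(config.n_genes)],
        0.0,
        np.round(rng.lognormal(mean=2.3, sigma=1.0, size=config.n_genes), 3),
    )
    gene_effect = np.round(rng.normal(-0.2, 0.4, size=config.n_genes), 4)

    genes_df = pd.DataFrame(
        {
            "gene": genes,
            "is_effect": [i in eff_idx for i in range(config.n_genes)],
            "is_zero_tpm": [i in zero_idx for i in range(config.n_genes)],
            "effect_channel": gene_channel,
            "complex_id": [
                f"CPX{cx_assign[i] + 1}" if i in cx_assign else None
                for i in range(config.n_genes)
            ],
            "tpm": tpm,
            "gene_effect": gene_effect,
        }
    ).set_index("gene")

    return GroundTruth(
        genes=genes_df,
        effect_vectors=pd.DataFrame(vectors, index=genes, columns=feat_names),
        cutting_signature=pd.Series(sig, index=feat_names),
        guide_efficiency=pd.Series(dtype=float),  # filled by generate_screen
    )


def generate_screen(
    config: ScreenConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a single-cell feature table with guide/gene metadata.

    Returns ``(cells, feature_metadata, guide_library, ground_truth)``.
    The cell table has exactly
    ``n_plates * (n_genes * guides_per_gene + n_nontargeting) *
    cells_per_guide_per_plate`` rows. Each cell's feature vector is
    baseline plate offset + guide shift + noise, where the guide shift is
    ``efficiency * (gene effect vector + cutting signature)`` for targeting
    guides and zero for non-targeting guides. Regeneration with the same
    config (including seed) is bit-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    features = make_feature_metadata(config, rng)
    truth = _make_ground_truth(config, features, rng)
    library = _make_guide_library(config, list(truth.genes.index), rng)

    n_guides = len(library)
    n_f = config.n_features
    eff = rng.uniform(0.5, 1.0, size=n_guides)
    eff[library["gene"].to_numpy() == "nontargeting"] = 0.0
    truth.guide_efficiency = pd.Series(eff, index=library.index)

    # per-guide shift matrix
    vec_lookup = truth.effect_vectors.to_numpy()
    gene_pos = {g: i for i, g in enumerate(truth.genes.index)}
    sig = truth.cutting_signature.to_numpy()
    shifts = np.zeros((n_guides, n_f))
    for i, (gid, gene) in enumerate(zip(library.index, library["gene"])):
        if gene == "nontargeting":
            continue
        shifts[i] = eff[i] * (vec_lookup[gene_pos[gene]] + sig)

    n_cells = config.cells_per_guide_per_plate
    rows_per_plate = n_guides * n_cells
    total = config.n_plates * rows_per_plate

    if config.heavy_tails:
        # Student-t df=5 scaled to unit variance, then by noise_sd
        noise = rng.standard_t(5, size=(total, n_f)) * (config.noise_sd / np.sqrt(5 / 3))
    else:
        noise = rng.normal(0.0, config.noise_sd, size=(total, n_f))

    X = noise
    # guide shifts are identical across plates; add plate-block-wise
    block = np.repeat(shifts, n_cells, axis=0)
    for p in range(config.n_plates):
        X[p * rows_per_plate : (p + 1) * rows_per_plate] += block

    if config.plate_effect_sd > 0:
        offsets = rng.normal(
            0.0, config.plate_effect_sd * config.noise_sd, size=(config.n_plates, n_f)
        )
        for p in range(config.n_plates):
            X[p * rows_per_plate : (p + 1) * rows_per_plate] += offsets[p]

    wells = [f"{r}{c}" for r in "AB" for c in (1, 2, 3)]
    guide_wells = [wells[i % len(wells)] for i in range(n_guides)]
    meta = {
        "plate": np.repeat([f"P{p + 1}" for p in range(config.n_plates)], rows_per_plate),
        "well": np.tile(np.repeat(guide_wells, n_cells), config.n_plates),
        "cell_id": np.arange(total),
        "guide_id": np.tile(np.repeat(library.index.to_numpy(), n_cells), config.n_plates),
        "barcode": np.tile(
            np.repeat(library["prefix12"].to_numpy(), n_cells), config.n_plates
        ),
        "gene": np.tile(np.repeat(library["gene"].to_numpy(), n_cells), config.n_plates),
    }
    cells = pd.DataFrame(meta)
    cells = pd.concat(
        [cells, pd.DataFrame(X, columns=list(features.index))], axis=1
    )
    return cells, features, library.reset_index(), truth


def generate_annotations(
    truth: GroundTruth, seed: int = 0, n_random_pairs: int = 2000
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic annotation tables mirroring complex / link / expression /
    essentiality resources.

    Returns ``(complexes, link_scores, tpm, gene_effect)``. Link scores are
    drawn so same-complex pairs score higher in expectation than random
    pairs (synthetic stand-ins for curated resources; not real annotations).
    """
    rng = np.random.default_rng(seed)
    genes = list(truth.genes.index)

    cx_rows = [
        {"complex_id": cx, "gene": g}
        for g, cx in truth.genes["complex_id"].items()
        if cx is not None and not (isinstance(cx, float) and np.isnan(cx))
    ]
    complexes = pd.DataFrame(cx_rows, columns=["complex_id", "gene"])

    cx_of = truth.genes["complex_id"].to_dict()
    pairs: set[tuple[str, str]] = set()
    for cx, grp in complexes.groupby("complex_id"):
        members = list(grp["gene"])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.add(tuple(sorted((members[i], members[j]))))
    target = len(pairs) + n_random_pairs
    max_pairs = len(genes) * (len(genes) - 1) // 2
    while len(pairs) < min(target, max_pairs):
        a, b = rng.choice(genes, size=2, replace=False)
        pairs.add(tuple(sorted((a, b))))
    link_rows = []
    for a, b in sorted(pairs):
        base = rng.uniform(150, 450)
        if cx_of.get(a) is not None and cx_of.get(a) == cx_of.get(b):
            base += rng.uniform(250, 500)
        link_rows.append({"gene_a": a, "gene_b": b, "score": round(min(base, 999.0), 1)})
    link_scores = pd.DataFrame(link_rows)

    tpm = truth.genes[["tpm"]].reset_index()
    gene_effect = truth.genes[["gene_effect"]].reset_index()
    return complexes, link_scores, tpm, gene_effect
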