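"""End-to-end orchestration: simulate -> design -> profile -> hits ->
similarity -> enrichment, from one structured config.

A run config is a plain nested dict (usually loaded from YAML) with one
block per stage plus global ``seed``/``out`` settings; every tunable has a
default so an empty config runs the desk-scale screen. Each run writes its
outputs, the verbatim config, and a manifest with per-file SHA-256
checksums; deterministic stages reproduce identical checksums on re-run,
and unchanged stages are skipped when their outputs already match the
config hash.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, hits, io, library, profiling, similarity, synthetic

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out": "morphoscreen_run",
    "screen": {},  # ScreenConfig field overrides
    "library_design": {"prefix_len": 12, "min_dist": 2, "guides_per_gene": 4},
    "profiling": {"corr_threshold": 0.9},
    "hit_calling": {"alpha": 0.001, "quantile": 0.95},
    "similarity": {"var_target": 0.70, "n_bins": 8, "order_source": "A"},
    "enrichment": {"n_perm": 2000, "rank_by": "signal", "query": None},
    "stages": [
        "simulate",
        "profile",
        "call-hits",
        "similarity",
        "enrich",
    ],
}

_SCHEMAS = {
    "cells": {"required": ["plate", "well", "cell_id", "guide_id", "barcode", "gene"]},
    "guide_library": {"required": ["guide_id", "sequence", "gene"]},
    "guide_profiles": {
        "required": ["guide_id", "plate", "gene", "is_nontargeting"],
        "unique": ["guide_id", "plate"],
    },
    "feature_metadata": {"required": ["feature_name", "category", "channel"]},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(config, user)
    if overrides:
        _deep_update(config, overrides)
    _validate_config(config)
    return config


def _deep_update(base: dict, update: dict) -> None:
    for k, v in update.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _validate_config(config: dict) -> None:
    known = set(DEFAULT_CONFIG)
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    hc = config["hit_calling"]
    if not 0 < hc["alpha"] < 1:
        raise ValueError("hit_calling.alpha must be in (0, 1)")
    if not 0 < hc["quantile"] < 1:
        raise ValueError("hit_calling.quantile must be in (0, 1)")
    if not 0 < config["similarity"]["var_target"] <= 1:
        raise ValueError("similarity.var_target must be in (0, 1]")
    sc = {f.name for f in synthetic.ScreenConfig.__dataclass_fields__.values()}
    bad = set(config["screen"]) - sc
    if bad:
        raise ValueError(f"unknown screen config fields: {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def validate_inputs(paths: dict[str, str], schemas: dict | None = None) -> list[dict]:
    """Schema-check input tables; returns a list of violations (empty = ok)."""
    schemas = schemas or _SCHEMAS
    violations = []
    for kind, path in paths.items():
        schema = schemas.get(kind)
        if schema is None:
            continue
        try:
            df = io.read_table(path)
        except Exception as exc:  # unreadable file is an error, not a violation
            raise OSError(f"cannot read {kind} table at {path}: {exc}") from exc
        for col in schema.get("required", []):
            if col not in df.columns:
                violations.append(
                    {"file": str(path), "kind": kind, "violation": f"missing column {col!r}"}
                )
        uniq = schema.get("unique")
        if uniq and all(c in df.columns for c in uniq):
            dup = df.duplicated(subset=uniq).sum()
            if dup:
                violations.append(
                    {
                        "file": str(path),
                        "kind": kind,
                        "violation": f"{dup} duplicated rows on key {tuple(uniq)}",
                    }
                )
    return violations


def run_pipeline(config: dict, force: bool = False) -> dict:
    """Execute the configured stages in dependency order; return the manifest.

    Stage outputs live under ``config['out']``. A stage is skipped when its
    outputs already exist and were produced under the same config hash
    (checksum cache); ``force=True`` re-runs everything.
    """
    out = Path(config["out"])
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)

    manifest_path = out / "manifest.json"
    previous = io.read_json(manifest_path) if manifest_path.exists() and not force else {}
    cached = previous.get("config_hash") == chash
    manifest: dict = {
        "artifact": "morphoscreen",
        "config_hash": chash,
        "seed": config["seed"],
        "stages": {},
    }

    stages = list(config["stages"])
    order = ["simulate", "design-library", "profile", "call-hits", "similarity", "enrich", "feature-screen"]
    stages.sort(key=order.index)
    deps = {
        "profile": ["simulate"],
        "call-hits": ["simulate", "profile"],
        "similarity": ["profile", "call-hits"],
        "enrich": ["profile", "call-hits"],
        "feature-screen": ["call-hits"],
    }
    runnable = set(stages)
    for s in stages:
        for d in deps.get(s, []):
            if d not in runnable and not (out / d).exists():
                raise RuntimeError(f"stage {s!r} requires upstream stage {d!r}")

    state: dict = {}
    for stage in stages:
        # pull upstream state from disk when the dep ran in an earlier call
        for d in deps.get(stage, []):
            if d not in runnable and d not in state.get("_loaded", set()):
                _load_stage_state(d, out / d, state)
                state.setdefault("_loaded", set()).add(d)
        stage_dir = out / stage
        t0 = time.time()
        if cached and stage in previous.get("stages", {}) and stage_dir.exists() and not force:
            ok = all(
                Path(f).exists() and _sha256(Path(f)) == h
                for f, h in previous["stages"][stage]["outputs"].items()
            )
            if ok:
                manifest["stages"][stage] = previous["stages"][stage]
                _load_stage_state(stage, stage_dir, state)
                continue
        stage_dir.mkdir(parents=True, exist_ok=True)
        outputs = _run_stage(stage, config, stage_dir, state)
        manifest["stages"][stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "elapsed_s": round(time.time() - t0, 2),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    io.write_json(manifest, manifest_path)
    return manifest


def _load_stage_state(stage: str, stage_dir: Path, state: dict) -> None:
    if stage == "simulate":
        state["cells"] = io.read_table(stage_dir / "cells.parquet")
        state["features"] = io.read_table(stage_dir / "feature_metadata.csv").set_index(
            "feature_name"
        )
        state["truth"] = synthetic.GroundTruth.from_json(stage_dir / "ground_truth.json")
    elif stage == "profile":
        state["profiles"] = {
            "guide_plate_full": io.read_table(stage_dir / "guide_plate_full.parquet"),
            "guide_plate": io.read_table(stage_dir / "guide_plate.parquet"),
            "guide_screen": io.read_table(stage_dir / "guide_screen.parquet"),
            "gene": io.read_table(stage_dir / "gene.parquet"),
        }
        state["profiles"]["features"] = profiling.feature_columns(
            state["profiles"]["guide_screen"]
        )
    elif stage == "call-hits":
        state["hit_table"] = io.read_table(stage_dir / "hit_table.csv").set_index("gene")
        state["pvalues"] = io.read_table(stage_dir / "pvalues.parquet").set_index("gene")


def _run_stage(stage: str, config: dict, stage_dir: Path, state: dict) -> list[Path]:
    seed = config["seed"]
    outputs: list[Path] = []

    if stage == "simulate":
        screen_cfg = synthetic.ScreenConfig(**{**config["screen"], "seed": seed})
        cells, features, lib, truth = synthetic.generate_screen(screen_cfg)
        complexes, links, tpm, gene_effect = synthetic.generate_annotations(truth, seed)
        io.write_table(cells, stage_dir / "cells.parquet")
        io.write_table(features.reset_index(), stage_dir / "feature_metadata.csv")
        io.write_table(lib, stage_dir / "guide_library.csv")
        io.write_table(complexes, stage_dir / "complexes.csv")
        io.write_table(links, stage_dir / "link_scores.csv")
        io.write_table(tpm, stage_dir / "tpm.csv")
        io.write_table(gene_effect, stage_dir / "gene_effect.csv")
        truth.to_json(stage_dir / "ground_truth.json")
        state.update(cells=cells, features=features, truth=truth)
        outputs = sorted(stage_dir.iterdir())

    elif stage == "design-library":
        ld = config["library_design"]
        rng = np.random.default_rng(seed)
        n_genes = config["screen"].get("n_genes", synthetic.ScreenConfig.n_genes)
        candidates, gene_map = [], []
        bases = np.array(list("ACGT"))
        for gi in range(n_genes):
            for _ in range(2 * ld["guides_per_gene"]):
                candidates.append("".join(bases[rng.integers(0, 4, size=19)]))
                gene_map.append(f"G{gi + 1:04d}")
        result = library.select_barcodes(
            candidates,
            gene_map,
            prefix_len=ld["prefix_len"],
            min_dist=ld["min_dist"],
            guides_per_gene=ld["guides_per_gene"],
            seed=seed,
        )
        io.write_table(result.library, stage_dir / "designed_library.csv")
        io.write_table(result.rejects, stage_dir / "rejects.csv")
        io.write_table(
            result.composition.frequencies.reset_index(), stage_dir / "composition.csv"
        )
        outputs = sorted(stage_dir.iterdir())

    elif stage == "profile":
        res = profiling.profile_pipeline(
            state["cells"], corr_threshold=config["profiling"]["corr_threshold"]
        )
        for key in ("guide_plate_full", "guide_plate", "guide_screen", "gene"):
            io.write_table(res[key], stage_dir / f"{key}.parquet")
        io.write_json({"retained_features": res["features"]}, stage_dir / "features.json")
        state["profiles"] = res
        outputs = sorted(stage_dir.iterdir())

    elif stage == "call-hits":
        hc = config["hit_calling"]
        caller = hits.EmpiricalFDRHitCaller(alpha=hc["alpha"], quantile=hc["quantile"])
        caller.fit(
            state["profiles"]["guide_screen"],
            state["features"],
            state["truth"].zero_tpm_genes,
        )
        io.write_table(caller.hit_table_.reset_index(names="gene"), stage_dir / "hit_table.csv")
        io.write_table(
            caller.pvalues_.reset_index(names="gene"), stage_dir / "pvalues.parquet"
        )
        summary = {
            "whole_cell_threshold": caller.threshold_,
            "n_whole_cell_hits": int(caller.hit_table_["whole_cell_hit"].sum()),
            "compartment_thresholds": caller.compartment_thresholds_,
            "n_compartment_hits": {
                ch: int(caller.hit_table_[f"{ch}_hit"].sum()) for ch in caller.spec_
            },
            "n_zero_tpm": len(caller.zero_tpm_genes_),
        }
        io.write_json(summary, stage_dir / "summary.json")
        state["hit_table"] = caller.hit_table_
        state["pvalues"] = caller.pvalues_
        state["caller"] = caller
        outputs = sorted(stage_dir.iterdir())

    elif stage == "similarity":
        sim_cfg = config["similarity"]
        gene_profiles = state["profiles"]["gene"].set_index("gene")
        feats = state["profiles"]["features"]
        hits_idx = state["hit_table"].index[state["hit_table"]["whole_cell_hit"]]
        hit_profiles = gene_profiles.loc[[g for g in hits_idx], feats]
        if len(hit_profiles) < 3:
            warnings.warn("fewer than 3 hit genes; similarity stage skipped")
            io.write_json({"skipped": "too few hits"}, stage_dir / "summary.json")
            return sorted(stage_dir.iterdir())
        reduced = similarity.reduce_pca(hit_profiles, var_target=sim_cfg["var_target"])
        corr = similarity.pairwise_correlation(reduced)
        order, _ = similarity.cluster_order(corr)
        io.write_table(reduced.scores.reset_index(names="gene"), stage_dir / "reduced.csv")
        io.write_table(corr.reset_index(names="gene"), stage_dir / "correlations.csv")
        io.write_json(
            {
                "cumulative_explained": reduced.cumulative_explained,
                "n_components": int(reduced.scores.shape[1]),
                "leaf_order": list(order),
            },
            stage_dir / "summary.json",
        )
        state["reduced"] = reduced
        state["corr"] = corr
        outputs = sorted(stage_dir.iterdir())

    elif stage == "enrich":
        en = config["enrichment"]
        if en["rank_by"] == "signal":
            ranked = enrichment.rank_by_signal(state["hit_table"])
        else:
            gene_profiles = state["profiles"]["gene"].set_index("gene")
            feats = state["profiles"]["features"]
            ranked = enrichment.rank_by_similarity(gene_profiles[feats], en["query"])
        io.write_rnk(ranked, stage_dir / "ranked.rnk")
        # synthetic complexes double as gene sets at desk scale
        cx_path = Path(config["out"]) / "simulate" / "complexes.csv"
        if cx_path.exists():
            cx = io.read_table(cx_path)
            gene_sets = {
                str(c): list(grp["gene"]) for c, grp in cx.groupby("complex_id")
            }
            res = enrichment.preranked_enrichment(
                ranked, gene_sets, n_perm=en["n_perm"], seed=seed
            )
            io.write_table(res.assign(leading_edge=res["leading_edge"].map(",".join)) if len(res) else res, stage_dir / "enrichment.csv")
        outputs = sorted(stage_dir.iterdir())

    elif stage == "feature-screen":
        pv = state["pvalues"]
        top_lists = {f: enrichment.top20plus(pv[f]) for f in pv.columns}
        cx_path = Path(config["out"]) / "simulate" / "complexes.csv"
        term_sets = {}
        if cx_path.exists():
            cx = io.read_table(cx_path)
            term_sets = {str(c): list(grp["gene"]) for c, grp in cx.groupby("complex_id")}
        res = enrichment.feature_screen_enrichment(
            top_lists, term_sets, universe=list(pv.index)
        )
        io.write_table(res, stage_dir / "feature_screen.csv")
        outputs = sorted(stage_dir.iterdir())

    else:
        raise ValueError(f"unknown stage {stage!r}")

    return outputs
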