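"""Barcode (sgRNA prefix) library design and read assignment.

In an optical pooled screen the expressed guide sequence doubles as the
barcode read out by cyclic in situ sequencing, one base per cycle. A usable
library therefore needs (i) pairwise-distinct prefixes at the sequenced
length (complete deconvolution) and (ii) a minimum pairwise Levenshtein
distance between prefixes so that single read errors are detectable or
correctable, while keeping the per-position base composition balanced for
reliable optical base calling.

Distances are computed on the sequenced prefix only (default 12 bases), not
on the full-length guide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_VALID_READ = set("ACGTN")
_VALID_BASE = set("ACGT")


def levenshtein(a: str, b: str, limit: int | None = None) -> int:
    """Edit distance between ``a`` and ``b`` (unit-cost insertions,
    deletions, substitutions).

    ``N`` never matches any character (it counts as a mismatch even against
    another ``N``), so reads containing no-calls pay a substitution per
    ambiguous base. With ``limit`` set, returns ``limit + 1`` as soon as the
    distance provably exceeds ``limit`` (band shortcut for library audits).
    """
    if a == b and "N" not in a:
        return 0
    la, lb = len(a), len(b)
    if limit is not None and abs(la - lb) > limit:
        return limit + 1
    if la == 0 or lb == 0:
        return max(la, lb)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        ca_ok = ca != "N"
        best = cur[0]
        for j in range(1, lb + 1):
            cb = b[j - 1]
            cost = 0 if (ca_ok and ca == cb and cb != "N") else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if cur[j] < best:
                best = cur[j]
        if limit is not None and best > limit:
            return limit + 1
        prev = cur
    return prev[lb]


@dataclass
class CompositionMatrix:
    """Per-position base frequencies of a prefix set."""

    frequencies: pd.DataFrame  # positions x (A, C, G, T)
    max_deviation: float  # max |freq - 0.25| over positions and bases

    def __post_init__(self):
        sums = self.frequencies.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-position base frequencies must sum to 1")


def base_composition(prefixes: list[str] | pd.Series) -> CompositionMatrix:
    """Per-position base-frequency matrix and its worst deviation from 0.25."""
    prefixes = list(prefixes)
    if not prefixes:
        raise ValueError("empty library")
    length = len(prefixes[0])
    counts = np.zeros((length, 4))
    idx = {b: k for k, b in enumerate("ACGT")}
    for seq in prefixes:
        for pos, ch in enumerate(seq):
            counts[pos, idx[ch]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freqs, columns=list("ACGT"))
    df.index = np.arange(1, length + 1)
    df.index.name = "position"
    return CompositionMatrix(frequencies=df, max_deviation=float(np.abs(freqs - 0.25).max()))


@dataclass
class DesignResult:
    """Outcome of a barcode-selection run."""

    library: pd.DataFrame  # guide_id, sequence, gene, prefix12, source_pool
    rejects: pd.DataFrame  # gene, n_requested, n_selected, reason
    composition: CompositionMatrix
    prefix_len: int
    min_dist: int


def _composition_penalty(counts: np.ndarray, seq: str, idx: dict, total: int) -> float:
    """Sum of |freq - 0.25| after hypothetically adding ``seq``."""
    pen = 0.0
    denom = total + 1
    for pos, ch in enumerate(seq):
        for b, k in idx.items():
            c = counts[pos, k] + (1 if ch == b else 0)
            pen += abs(c / denom - 0.25)
    return pen


def select_barcodes(
    candidates: list[str],
    gene_map: list[str],
    prefix_len: int = 12,
    min_dist: int = 2,
    guides_per_gene: int = 4,
    seed: int = 0,
    balance_weight: float = 1.0,
) -> DesignResult:
    """Greedily select a barcode library with distinct, well-separated prefixes.

    Genes are visited in a seeded random order; within a gene, candidates
    compatible with the already-selected set (prefix unused and pairwise
    Levenshtein distance >= ``min_dist`` to every selected prefix) are ranked
    by how much they improve per-position base balance, and the first
    ``guides_per_gene`` are accepted. Genes for which fewer compatible
    candidates exist are reported in ``rejects``, never silently dropped.
    """
    if not candidates:
        raise ValueError("empty candidate pool")
    if len(candidates) != len(gene_map):
        raise ValueError("candidates and gene_map must align")
    for seq in candidates:
        if len(seq) < prefix_len:
            raise ValueError(f"candidate {seq!r} shorter than prefix_len={prefix_len}")
        if not set(seq) <= _VALID_BASE:
            raise ValueError(f"candidate {seq!r} contains non-ACGT characters")

    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[str]] = {}
    for seq, gene in zip(candidates, gene_map):
        by_gene.setdefault(gene, []).append(seq)
    genes = sorted(by_gene)
    rng.shuffle(genes)

    idx = {b: k for k, b in enumerate("ACGT")}
    counts = np.zeros((prefix_len, 4))
    selected_prefixes: list[str] = []
    prefix_set: set[str] = set()
    rows, reject_rows = [], []

    for gene in genes:
        n_taken = 0
        pool = list(by_gene[gene])
        while n_taken < guides_per_gene and pool:
            compatible = []
            for seq in pool:
                pfx = seq[:prefix_len]
                if pfx in prefix_set:
                    continue
                ok = all(
                    levenshtein(pfx, other, limit=min_dist - 1) >= min_dist
                    for other in selected_prefixes
                )
                if ok:
                    compatible.append(seq)
            if not compatible:
                break
            if balance_weight > 0 and len(compatible) > 1:
                pens = [
                    _composition_penalty(counts, s[:prefix_len], idx, len(selected_prefixes))
                    for s in compatible
                ]
                best = compatible[int(np.argmin(pens))]
            else:
                best = compatible[0]
            pfx = best[:prefix_len]
            selected_prefixes.append(pfx)
            prefix_set.add(pfx)
            for pos, ch in enumerate(pfx):
                counts[pos, idx[ch]] += 1
            n_taken += 1
            rows.append(
                {
                    "guide_id": f"{gene}_g{n_taken}",
                    "sequence": best,
                    "gene": gene,
                    "prefix12": pfx,
                    "source_pool": "designed",
                }
            )
            pool.remove(best)
        if n_taken < guides_per_gene:
            reject_rows.append(
                {
                    "gene": gene,
                    "n_requested": guides_per_gene,
                    "n_selected": n_taken,
                    "reason": "insufficient compatible candidates",
                }
            )

    library = pd.DataFrame(
        rows, columns=["guide_id", "sequence", "gene", "prefix12", "source_pool"]
    )
    rejects = pd.DataFrame(
        reject_rows, columns=["gene", "n_requested", "n_selected", "reason"]
    )
    comp = base_composition(library["prefix12"]) if len(library) else CompositionMatrix(
        frequencies=pd.DataFrame(
            np.full((prefix_len, 4), 0.25), columns=list("ACGT")
        ),
        max_deviation=0.0,
    )
    return DesignResult(
        library=library,
        rejects=rejects,
        composition=comp,
        prefix_len=prefix_len,
        min_dist=min_dist,
    )


def min_deconvolution_prefix(sequences: list[str] | pd.Series) -> float:
    """Smallest prefix length at which all library sequences are distinct.

    Returns ``math.inf`` (with a warning) if two full-length sequences
    collide, i.e. the library cannot be deconvolved at any cycle count.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty library")
    if len(set(seqs)) < len(seqs):
        warnings.warn("duplicate full-length sequences; library is not deconvolvable")
        return math.inf
    max_len = max(len(s) for s in seqs)
    for k in range(1, max_len + 1):
        prefixes = {s[:k] for s in seqs}
        if len(prefixes) == len(seqs):
            return k
    return math.inf


UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"


def match_read(
    read: str, library: pd.DataFrame, max_dist: int = 1, prefix_col: str = "prefix12"
) -> str:
    """Assign a sequencing read to a library guide with error correction.

    Exact prefix matches win immediately. Otherwise the read is assigned to
    the unique library prefix within Levenshtein distance ``max_dist``;
    equidistant nearest neighbours yield ``"ambiguous"`` and reads farther
    than ``max_dist`` from everything yield ``"unassigned"``.
    """
    if not set(read) <= _VALID_READ:
        raise ValueError(f"read contains characters outside ACGTN: {read!r}")
    prefixes = library[prefix_col]
    if "N" not in read:
        exact = library.index[prefixes == read]
        if len(exact) == 1:
            return (
                library.loc[exact[0], "guide_id"]
                if "guide_id" in library.columns
                else str(exact[0])
            )
    best_d = max_dist + 1
    best_ids: list[str] = []
    for row_idx, pfx in prefixes.items():
        d = levenshtein(read, pfx, limit=max_dist)
        if d < best_d:
            best_d = d
            gid = (
                library.loc[row_idx, "guide_id"]
                if "guide_id" in library.columns
                else str(row_idx)
            )
            best_ids = [gid]
        elif d == best_d and d <= max_dist:
            gid = (
                library.loc[row_idx, "guide_id"]
                if "guide_id" in library.columns
                else str(row_idx)
            )
            best_ids.append(gid)
    if best_d > max_dist:
        return UNASSIGNED
    if len(best_ids) > 1:
        return AMBIGUOUS
    return best_ids[0]
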