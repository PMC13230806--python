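"""Preranked set enrichment on association results.

Rank metric: -ln(p) * sign(effect). Enrichment score: weighted
running-sum walk down the ranked list (hits advance by |metric|^exponent
normalized by their total, misses retreat by 1/(N - N_hits)); the reported
ES is the extremum of the walk. Significance and normalization come from
gene-label permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import bh_adjust

__all__ = [
    "RankedList",
    "build_ranked_list",
    "enrichment_score",
    "permutation_nes",
]


@dataclass
class RankedList:
    """Genes ordered by descending rank metric, one entry per gene."""

    genes: np.ndarray
    metrics: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metrics):
            raise ValueError("genes and metrics must align")
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("ranked list must have one entry per gene")

    def __len__(self) -> int:
        return len(self.genes)


def build_ranked_list(
    associations: pd.DataFrame,
    p_col: str = "p",
    effect_col: str = "effect",
    gene_col: str = "gene",
) -> RankedList:
    """Collapse aptamers to genes (keep smallest p), compute the signed
    -ln(p) metric, order descending with lexicographic tie-break."""
    df = associations[[gene_col, p_col, effect_col]].dropna().copy()
    if df.empty:
        raise ValueError("no usable association records")
    zero = df[p_col] == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero p-values clamped to smallest positive float",
            stacklevel=2,
        )
        df.loc[zero, p_col] = np.nextafter(0.0, 1.0)
    df = df.sort_values([gene_col, p_col], kind="mergesort").drop_duplicates(
        gene_col, keep="first"
    )
    metric = -np.log(df[p_col].to_numpy()) * np.sign(df[effect_col].to_numpy())
    df = df.assign(metric=metric)
    df = df.sort_values(
        ["metric", gene_col], ascending=[False, True], kind="mergesort"
    )
    return RankedList(df[gene_col].to_numpy(), df["metric"].to_numpy())


def _walk_extremum(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> tuple[float, int]:
    """Signed extremum of the running sum evaluated only where it can be
    extremal: immediately before and at each hit, and the terminal value.

    ``positions`` are sorted 0-based hit indices; ``weights`` their
    normalized increments (summing to 1). Returns (ES, extremum index in
    the list)."""
    n_hits = len(positions)
    miss_step = 1.0 / (n_total - n_hits) if n_total > n_hits else 0.0
    cum_w = np.cumsum(weights)
    k = np.arange(n_hits)
    at_hit = cum_w - (positions - k) * miss_step
    before_hit = np.concatenate(([0.0], cum_w[:-1])) - (positions - k) * miss_step
    cand = np.concatenate((at_hit, before_hit, [0.0]))
    cand_pos = np.concatenate((positions, np.maximum(positions - 1, 0), [n_total - 1]))
    best_abs = np.abs(cand).max()
    tied = np.flatnonzero(np.abs(cand) >= best_abs - 1e-9 * max(best_abs, 1.0))
    # exact-tie convention: the positive extremum wins, then earliest position
    pos_tied = tied[cand[tied] > 0]
    pool = pos_tied if len(pos_tied) else tied
    i = int(pool[np.argmin(cand_pos[pool])])
    return float(cand[i]), int(cand_pos[i])


def enrichment_score(
    ranked: RankedList, gene_set, exponent: float = 1.0, mode: str = "signed_max_dev"
) -> tuple[float, list[str]]:
    """ES and leading-edge genes for one set.

    ``mode='signed_max_dev'`` (default) reports the running-sum value of
    maximal absolute deviation from zero; ``mode='max'`` reports the
    maximum of the running sum only.
    """
    if mode not in ("signed_max_dev", "max"):
        raise ValueError("mode must be 'signed_max_dev' or 'max'")
    members = set(gene_set)
    hit_mask = np.isin(ranked.genes, list(members))
    if not hit_mask.any():
        raise ValueError("gene set does not intersect the ranked list")
    n = len(ranked)
    positions = np.flatnonzero(hit_mask)
    w = np.abs(ranked.metrics[positions]) ** exponent
    total = w.sum()
    weights = w / total if total > 0 else np.full(len(w), 1.0 / len(w))

    if mode == "max":
        es, ext = _walk_max(positions, weights, n)
    else:
        es, ext = _walk_extremum(positions, weights, n)
    if es >= 0:
        leading = ranked.genes[positions[positions <= ext]]
    else:
        leading = ranked.genes[positions[positions >= ext]]
    return es, list(leading)


def _walk_max(positions: np.ndarray, weights: np.ndarray, n_total: int):
    n_hits = len(positions)
    miss_step = 1.0 / (n_total - n_hits) if n_total > n_hits else 0.0
    cum_w = np.cumsum(weights)
    k = np.arange(n_hits)
    at_hit = cum_w - (positions - k) * miss_step
    i = int(np.argmax(at_hit))
    return float(at_hit[i]), int(positions[i])


def _null_es(
    n: int,
    size: int,
    abs_metrics: np.ndarray,
    exponent: float,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null ES distribution for a set of given size via gene-label
    permutations (uniform random position subsets)."""
    out = np.empty(n_perm)
    pow_metrics = abs_metrics**exponent
    for b in range(n_perm):
        positions = np.sort(rng.choice(n, size=size, replace=False))
        w = pow_metrics[positions]
        total = w.sum()
        weights = w / total if total > 0 else np.full(size, 1.0 / size)
        out[b], _ = _walk_extremum(positions, weights, n)
    return out


def permutation_nes(
    ranked: RankedList,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    exponent: float = 1.0,
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation-normalized enrichment over a GMT-style collection.

    NES = ES / mean(|null ES| of matching sign); permutation p uses the
    same-sign null tail with a +1 pseudo-count; BH adjustment across the
    tested sets. Null distributions are shared across sets of equal size
    (they depend on size only), which keeps the procedure deterministic
    and fast.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if n_perm < 1000:
        warnings.warn("n_perm < 1000: limited p-value resolution", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(ranked)
    gene_index = set(ranked.genes)
    abs_metrics = np.abs(ranked.metrics)

    present_sizes: dict[str, int] = {}
    for name, members in gene_sets.items():
        inside = [g for g in members if g in gene_index]
        if len(members) > n:
            raise ValueError(f"gene set {name!r} larger than the ranked list")
        if not (min_size <= len(inside) <= max_size):
            continue
        present_sizes[name] = len(inside)

    null_by_size = {
        size: _null_es(n, size, abs_metrics, exponent, n_perm, rng)
        for size in sorted(set(present_sizes.values()))
    }

    records = []
    for name, size in present_sizes.items():
        inside = [g for g in gene_sets[name] if g in gene_index]
        es, leading = enrichment_score(ranked, inside, exponent)
        null = null_by_size[size]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.abs(same).mean() if len(same) else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        p = (1.0 + (np.abs(same) >= abs(es)).sum()) / (1.0 + len(same))
        records.append(
            {
                "set": name,
                "size": size,
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": ",".join(leading),
            }
        )
    out = pd.DataFrame.from_records(records)
    if not out.empty:
        out["padj"] = bh_adjust(out["p"].to_numpy())
        out = out[["set", "size", "es", "nes", "p", "padj", "leading_edge"]]
    return out
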