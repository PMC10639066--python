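"""Preranked gene-set enrichment: weighted running-sum ES, NES, permutation FDR.

Genes are ranked by score (descending; ties broken by gene id so runs are
reproducible). Walking down the ranking, hitting a set member increments the
running sum by |score|^p / sum_hits |score|^p and missing decrements by
1 / (N - Nh); the enrichment score (ES) is the running sum's maximum signed
deviation from zero. Significance comes from a random-gene-set permutation
null (the appropriate scheme for preranked input, where no sample labels
exist): NES normalizes ES against the mean |null ES| of matching sign, and
nominal p and FDR q are computed separately within the positive and negative
ES pools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import log

__all__ = ["RankedList", "EnrichmentResult", "rank_genes", "enrichment_score", "permutation_fdr"]


@dataclass
class RankedList:
    """Genes in descending score order with lexicographic tie-breaking."""

    genes: np.ndarray   # object array of gene ids
    scores: np.ndarray  # float, same order

    def __len__(self) -> int:
        return self.genes.size

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def rank_genes(scores: pd.Series | Mapping[str, float]) -> RankedList:
    """Order genes by descending score, then ascending gene id; no duplicates."""
    s = pd.Series(scores, dtype=float)
    if s.index.duplicated().any():
        raise ValueError("duplicate genes in ranked input")
    df = pd.DataFrame({"gene": s.index.astype(str), "score": s.to_numpy()})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return RankedList(df["gene"].to_numpy(dtype=object), df["score"].to_numpy())


def _es_from_hits(scores: np.ndarray, hit_mask: np.ndarray, weight_p: float) -> tuple[float, np.ndarray]:
    n = scores.size
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set must intersect the ranking but not equal it")
    w = np.abs(scores) ** weight_p
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit scores are exactly zero: fall back to equal hit weights
        hit_w = hit_mask.astype(float)
        denom = float(nh)
    steps = hit_w / denom - np.where(hit_mask, 0.0, 1.0 / (n - nh))
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(np.clip(es, -1.0, 1.0)), running


def enrichment_score(
    ranked: RankedList, gene_set: set[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES of one gene set against a ranked list; returns (ES, running sum)."""
    hit_mask = np.fromiter((g in gene_set for g in ranked.genes), dtype=bool, count=len(ranked))
    return _es_from_hits(ranked.scores, hit_mask, weight_p)


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p: float
    q: float


def _null_es(
    scores: np.ndarray, set_size: int, weight_p: float, nperm: int, rng: np.random.Generator
) -> np.ndarray:
    n = scores.size
    out = np.empty(nperm)
    for i in range(nperm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=set_size, replace=False)] = True
        out[i], _ = _es_from_hits(scores, mask, weight_p)
    return out


def permutation_fdr(
    ranked: RankedList,
    collection: Mapping[str, set[str]],
    weight_p: float = 1.0,
    nperm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """ES/NES/p/q per gene set via a random-gene-set permutation null.

    For each set size, ``nperm`` random same-size sets give the null ES
    distribution. NES = ES / mean(|null ES| of matching sign); the nominal p
    is the same-sign tail fraction. FDR q compares, within each sign pool,
    the null NES tail fraction with the observed NES tail fraction.
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    rng = np.random.default_rng(seed)
    universe = set(ranked.genes.tolist())
    n = len(ranked)

    names, sizes, es_obs, null_by_set = [], [], [], []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        if not members or len(members) >= n:
            log(f"gsea: set {name!r} skipped (size {len(members)} outside 1..{n - 1})")
            continue
        es, _ = enrichment_score(ranked, members, weight_p)
        names.append(name)
        sizes.append(len(members))
        es_obs.append(es)
    # one null batch per distinct set size, reused across sets of that size
    size_null: dict[int, np.ndarray] = {}
    for k in sorted(set(sizes)):
        size_null[k] = _null_es(ranked.scores, k, weight_p, nperm, rng)
    for k in sizes:
        null_by_set.append(size_null[k])

    nes_obs = np.empty(len(names))
    nes_null_pools: dict[int, list[np.ndarray]] = {+1: [], -1: []}
    p_nom = np.empty(len(names))
    nes_null_by_set = []
    for i, (es, null) in enumerate(zip(es_obs, null_by_set)):
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        nes_null = np.where(null > 0, null / pos_mean, null / neg_mean)
        nes_null_by_set.append(nes_null)
        if es >= 0:
            nes_obs[i] = es / pos_mean if np.isfinite(pos_mean) else np.nan
            same = null[null >= 0]
            p_nom[i] = ((same >= es).sum() + 1) / (same.size + 1) if same.size else 1.0
        else:
            nes_obs[i] = es / neg_mean if np.isfinite(neg_mean) else np.nan
            same = null[null < 0]
            p_nom[i] = ((same <= es).sum() + 1) / (same.size + 1) if same.size else 1.0

    all_null_nes = np.concatenate(nes_null_by_set) if nes_null_by_set else np.empty(0)
    q = np.empty(len(names))
    for i, nes in enumerate(nes_obs):
        if not np.isfinite(nes):
            q[i] = 1.0
            continue
        if nes >= 0:
            null_pool = all_null_nes[all_null_nes >= 0]
            obs_pool = nes_obs[nes_obs >= 0]
            null_frac = (null_pool >= nes).mean() if null_pool.size else 1.0
            obs_frac = (obs_pool >= nes).mean()
        else:
            null_pool = all_null_nes[all_null_nes < 0]
            obs_pool = nes_obs[nes_obs < 0]
            null_frac = (null_pool <= nes).mean() if null_pool.size else 1.0
            obs_frac = (obs_pool <= nes).mean()
        q[i] = min(null_frac / obs_frac, 1.0) if obs_frac > 0 else 1.0

    out = pd.DataFrame(
        {"size": sizes, "ES": es_obs, "NES": nes_obs, "p": p_nom, "q": q},
        index=pd.Index(names, name="set"),
    )
    return out
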