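"""Average engaged-polymerase profiles: TSS-anchored, scaled body, CPS-anchored.

Each gene contributes its sense-strand per-nucleotide density in
transcription orientation (minus-strand genes are reversed so downstream is
always to the right). Three panels are produced:

* TSS panel: 10-nt bins over [-1000, +1000) around the TSS (200 bins);
* body panel: the gene-body window split into 50 equal fractions, each bin
  the mean density within its fraction;
* CPS panel: 10-nt bins over [-1000, +2000) around the CPS (300 bins).

The profile is the unweighted mean across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome_io import CoverageTrack, GeneModel
from .quant import BODY_CPS_OFFSET, PROMOTER_FLANK

__all__ = ["MetageneProfile", "metagene_profile"]

TSS_SPAN = (-1000, 1000)
CPS_SPAN = (-1000, 2000)
BIN_NT = 10
N_BODY_BINS = 50
N_TSS_BINS = (TSS_SPAN[1] - TSS_SPAN[0]) // BIN_NT   # 200
N_CPS_BINS = (CPS_SPAN[1] - CPS_SPAN[0]) // BIN_NT   # 300


@dataclass
class MetageneProfile:
    tss_bins: np.ndarray   # (200,) mean density per 10-nt bin
    body_bins: np.ndarray  # (50,) mean density per 1/50 body fraction
    cps_bins: np.ndarray   # (300,) mean density per 10-nt bin
    n_genes: int
    normalization: str = "none"

    def __post_init__(self):
        assert self.tss_bins.shape == (N_TSS_BINS,)
        assert self.body_bins.shape == (N_BODY_BINS,)
        assert self.cps_bins.shape == (N_CPS_BINS,)


def _oriented_density(track: CoverageTrack, gene: GeneModel, tx_start: int, tx_end: int) -> np.ndarray:
    """Per-nt sense-strand density over transcription coordinates [tx_start, tx_end)."""
    if gene.strand == "+":
        g0 = gene.tss + tx_start
        g1 = gene.tss + tx_end
        return track.dense(gene.chrom, "+", g0, g1)
    g0 = gene.tss - tx_end + 1
    g1 = gene.tss - tx_start + 1
    return track.dense(gene.chrom, "-", g0, g1)[::-1]


def _cps_oriented_density(track: CoverageTrack, gene: GeneModel, rel_start: int, rel_end: int) -> np.ndarray:
    """Per-nt density over CPS-relative coordinates [rel_start, rel_end)."""
    if gene.strand == "+":
        return track.dense(gene.chrom, "+", gene.cps + rel_start, gene.cps + rel_end)
    return track.dense(gene.chrom, "-", gene.cps - rel_end + 1, gene.cps - rel_start + 1)[::-1]


def _bin_means(vec: np.ndarray, width: int) -> np.ndarray:
    return vec.reshape(-1, width).mean(axis=1)


def _body_bins(vec: np.ndarray) -> np.ndarray:
    """Split a per-nt density vector into 50 equal fractions (mean per bin)."""
    edges = (np.arange(N_BODY_BINS + 1) * vec.size) // N_BODY_BINS
    return np.array([vec[a:b].mean() if b > a else 0.0 for a, b in zip(edges[:-1], edges[1:])])


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    size_factor: float = 1.0,
    min_len: int = 3000,
) -> MetageneProfile:
    """Unweighted mean profile of one track over eligible genes.

    Genes shorter than ``min_len`` are excluded so the fixed TSS/CPS windows
    do not swallow the scaled body (default 3000 nt). Densities are divided
    by ``size_factor`` (median-of-ratios normalization upstream).
    """
    eligible = [g for g in genes if g.length >= min_len]
    if not eligible:
        raise ValueError(f"no genes of length >= {min_len} to profile")
    tss_sum = np.zeros(N_TSS_BINS)
    body_sum = np.zeros(N_BODY_BINS)
    cps_sum = np.zeros(N_CPS_BINS)
    for g in eligible:
        tss_vec = _oriented_density(track, g, TSS_SPAN[0], TSS_SPAN[1])
        tss_sum += _bin_means(tss_vec, BIN_NT)
        body_vec = _oriented_density(track, g, PROMOTER_FLANK, g.length - BODY_CPS_OFFSET)
        body_sum += _body_bins(body_vec)
        cps_vec = _cps_oriented_density(track, g, CPS_SPAN[0], CPS_SPAN[1])
        cps_sum += _bin_means(cps_vec, BIN_NT)
    n = len(eligible)
    return MetageneProfile(
        tss_bins=tss_sum / n / size_factor,
        body_bins=body_sum / n / size_factor,
        cps_bins=cps_sum / n / size_factor,
        n_genes=n,
        normalization="size_factor" if size_factor != 1.0 else "none",
    )


def average_profiles(profiles: Sequence[MetageneProfile]) -> MetageneProfile:
    """Mean of replicate profiles (replicates averaged after profiling)."""
    if not profiles:
        raise ValueError("no profiles to average")
    return MetageneProfile(
        tss_bins=np.mean([p.tss_bins for p in profiles], axis=0),
        body_bins=np.mean([p.body_bins for p in profiles], axis=0),
        cps_bins=np.mean([p.cps_bins for p in profiles], axis=0),
        n_genes=profiles[0].n_genes,
        normalization=profiles[0].normalization,
    )


def profile_table(profiles: Mapping[str, MetageneProfile]):
    """Long-format table of bin label -> value per condition (for TSV export)."""
    import pandas as pd

    rows = []
    for label, prof in profiles.items():
        for i, v in enumerate(prof.tss_bins):
            rows.append((label, "tss", TSS_SPAN[0] + i * BIN_NT, v))
        for i, v in enumerate(prof.body_bins):
            rows.append((label, "body", i, v))
        for i, v in enumerate(prof.cps_bins):
            rows.append((label, "cps", CPS_SPAN[0] + i * BIN_NT, v))
    return pd.DataFrame(rows, columns=["condition", "panel", "bin", "density"])
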