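"""Promoter-proximal / gene-body windows, strand-matched counting, pausing indices.

The quantification windows follow the convention used throughout nascent-RNA
work on promoter-proximal pausing:

* promoter-proximal window: 500 nt centred on the TSS (-250 to +250 in
  transcription coordinates);
* gene-body window: +250 nt downstream of the TSS to 500 nt upstream of the
  CPS, so a gene must be longer than 750 nt to have a non-empty body.

The pausing index (PI) of a gene is the Pol II density (reads/nt) in the
promoter window divided by the density across the body window; dPI is
PI(treatment) - PI(time-matched vehicle control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CountMatrix, CoverageTrack, GeneModel, log

__all__ = [
    "RegionWindows",
    "define_windows",
    "count_window",
    "build_count_matrix",
    "identify_active_genes",
    "pausing_index",
    "delta_pi",
    "pausing_table",
]

PROMOTER_FLANK = 250     # nt either side of the TSS
BODY_CPS_OFFSET = 500    # body stops this many nt upstream of the CPS
MIN_QUANT_LENGTH = PROMOTER_FLANK + BODY_CPS_OFFSET + 1  # body must be non-empty


@dataclass(frozen=True)
class RegionWindows:
    """Genomic promoter and body intervals (half-open) for one gene."""

    gene_id: str
    chrom: str
    strand: str
    promoter: tuple[int, int]
    body: tuple[int, int]

    @property
    def promoter_length(self) -> int:
        return self.promoter[1] - self.promoter[0]

    @property
    def body_length(self) -> int:
        return self.body[1] - self.body[0]


def define_windows(gene: GeneModel) -> RegionWindows | None:
    """Window arithmetic for one gene; short genes are skipped, not an error.

    Plus strand:  promoter [TSS-250, TSS+250), body [TSS+250, CPS-500+1).
    Minus strand: the mirror image in genomic coordinates, so transcription
    -coordinate semantics are identical on both strands.
    """
    if gene.length <= PROMOTER_FLANK + BODY_CPS_OFFSET:
        log(f"skip {gene.gene_id}: length {gene.length} <= {PROMOTER_FLANK + BODY_CPS_OFFSET}, "
            "body window would be empty")
        return None
    if gene.strand == "+":
        promoter = (gene.start - PROMOTER_FLANK, gene.start + PROMOTER_FLANK)
        body = (gene.start + PROMOTER_FLANK, gene.end - BODY_CPS_OFFSET)
    else:
        promoter = (gene.end - PROMOTER_FLANK, gene.end + PROMOTER_FLANK)
        body = (gene.start + BODY_CPS_OFFSET, gene.end - PROMOTER_FLANK)
    return RegionWindows(gene.gene_id, gene.chrom, gene.strand, promoter, body)


def count_window(track: CoverageTrack, chrom: str, window: tuple[int, int], strand: str) -> float:
    """Sum of per-nt counts on one strand within a half-open interval."""
    return track.count_range(chrom, strand, window[0], window[1])


def build_count_matrix(
    genes: Sequence[GeneModel],
    tracks: Mapping[str, CoverageTrack],
    conditions: Mapping[str, str],
    region: str,
) -> CountMatrix:
    """Count strand-matched signal per gene and sample in one region kind."""
    if region not in ("promoter", "body"):
        raise ValueError("region must be 'promoter' or 'body'")
    windows = [w for w in (define_windows(g) for g in genes) if w is not None]
    data = {}
    for sample, track in tracks.items():
        col = np.empty(len(windows))
        for i, w in enumerate(windows):
            interval = w.promoter if region == "promoter" else w.body
            col[i] = count_window(track, w.chrom, interval, w.strand)
        data[sample] = col
    df = pd.DataFrame(data, index=pd.Index([w.gene_id for w in windows], name="gene_id"))
    return CountMatrix(df, region=region, conditions=dict(conditions))


def identify_active_genes(
    promoter_counts: CountMatrix,
    control_condition: str,
    genes: Sequence[GeneModel] | None = None,
    min_total: float = 20.0,
    min_body_len: int = 500,
) -> list[str]:
    """Threshold rule standing in for model-based initiation-site calling.

    A gene is active iff its promoter counts summed over the control
    replicates reach ``min_total`` and its body window is at least
    ``min_body_len`` nt long.
    """
    control_samples = promoter_counts.samples_for(control_condition)
    if not control_samples:
        raise ValueError(f"no samples for control condition {control_condition!r}")
    total = promoter_counts.counts[control_samples].sum(axis=1)
    eligible = set(total.index[total >= min_total])
    if genes is not None:
        long_enough = set()
        for g in genes:
            w = define_windows(g)
            if w is not None and w.body_length >= min_body_len:
                long_enough.add(g.gene_id)
        eligible &= long_enough
    return sorted(eligible)


def pausing_index(
    promoter_count: float,
    promoter_len: int,
    body_count: float,
    body_len: int,
    pseudocount: float = 0.5,
) -> float | None:
    """Promoter density over body density; None when the body signal is zero.

    With pseudocount 0 this is exactly promoter-density / body-density and is
    invariant to scaling both counts by the same factor.
    """
    if promoter_len <= 0 or body_len <= 0:
        raise ValueError("window lengths must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    num = (promoter_count + pseudocount) / promoter_len
    den = (body_count + pseudocount) / body_len
    if den == 0:
        log("pausing index undefined (zero body signal and zero pseudocount)")
        return None
    return num / den


def delta_pi(pi_treatment: float | None, pi_control: float | None) -> float | None:
    """PI(treatment) - PI(control); None if either PI is undefined."""
    if pi_treatment is None or pi_control is None:
        return None
    return pi_treatment - pi_control


def pausing_table(
    promoter_counts: CountMatrix,
    body_counts: CountMatrix,
    windows: Mapping[str, RegionWindows],
    contrasts: Sequence[tuple[str, str]],
    pseudocount: float = 0.5,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Per-gene PI per condition plus dPI for each (treatment, control) pair.

    By default the PI of a condition is computed from replicate-summed counts,
    which stabilises low-count genes; ``per_replicate=True`` averages
    per-replicate PIs instead.
    """
    genes = promoter_counts.counts.index.intersection(body_counts.counts.index)
    conditions = sorted(set(promoter_counts.conditions.values()))
    out = pd.DataFrame(index=genes)
    for cond in conditions:
        samples = promoter_counts.samples_for(cond)
        pis = np.full(len(genes), np.nan)
        for i, gid in enumerate(genes):
            w = windows[gid]
            if per_replicate:
                vals = [
                    pausing_index(
                        promoter_counts.counts.at[gid, s], w.promoter_length,
                        body_counts.counts.at[gid, s], w.body_length, pseudocount,
                    )
                    for s in samples
                ]
                vals = [v for v in vals if v is not None]
                pis[i] = float(np.mean(vals)) if vals else np.nan
            else:
                p = promoter_counts.counts.loc[gid, samples].sum()
                b = body_counts.counts.loc[gid, samples].sum()
                pi = pausing_index(p, w.promoter_length, b, w.body_length, pseudocount)
                pis[i] = np.nan if pi is None else pi
        out[f"PI_{cond}"] = pis
    for treatment, control in contrasts:
        dpi = out[f"PI_{treatment}"] - out[f"PI_{control}"]
        out[f"dPI_{treatment}_vs_{control}"] = dpi
    out.index.name = "gene_id"
    return out
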