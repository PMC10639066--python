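"""Readers/writers and in-memory containers for the formats the pipeline touches.

Coordinate conventions used everywhere in this package:

* genomic intervals are 0-based, half-open ``[start, end)``;
* for a gene on ``+``, the transcription start site (TSS) is ``start`` and the
  cleavage-and-polyadenylation site (CPS) is ``end - 1``;
* for a gene on ``-``, TSS is ``end - 1`` and CPS is ``start``.

Coverage tracks hold strand-specific single-nucleotide counts of polymerase
3' ends, one value per covered position, kept sparse (position/count arrays).
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "CoverageTrack",
    "CountMatrix",
    "read_genes",
    "write_genes",
    "read_bedgraph",
    "write_bedgraph",
    "read_gmt",
    "read_rnk",
    "gtf_to_genes",
]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """A gene as an oriented genomic interval; the anchor for all windows."""

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str
    gene_name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.gene_name is None:
            object.__setattr__(self, "gene_name", self.gene_id)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cps(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


class CoverageTrack:
    """Sparse per-(chrom, strand) single-nucleotide counts for one sample.

    Internally each (chrom, strand) maps to a pair of parallel arrays:
    sorted unique positions (int64) and their counts (float64, >= 0).
    """

    def __init__(self, sample: str = "", normalized: bool = False):
        self.sample = sample
        self.normalized = normalized
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    # -- construction ------------------------------------------------------

    def add(self, chrom: str, strand: str, positions: np.ndarray, counts: np.ndarray) -> None:
        """Accumulate counts at positions (duplicates allowed, summed)."""
        if strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        positions = np.asarray(positions, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.float64)
        if positions.shape != counts.shape:
            raise ValueError("positions and counts must have equal length")
        if np.any(counts < 0):
            raise ValueError("negative counts are not allowed")
        key = (chrom, strand)
        if key in self._data:
            p0, c0 = self._data[key]
            positions = np.concatenate([p0, positions])
            counts = np.concatenate([c0, counts])
        upos, inverse = np.unique(positions, return_inverse=True)
        ucnt = np.zeros(upos.size, dtype=np.float64)
        np.add.at(ucnt, inverse, counts)
        keep = ucnt > 0
        self._data[key] = (upos[keep], ucnt[keep])

    # -- queries -----------------------------------------------------------

    def keys(self) -> Iterable[tuple[str, str]]:
        return self._data.keys()

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64))
        return self._data.get((chrom, strand), empty)

    def count_range(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Total signal on one strand within half-open interval [start, end)."""
        if end <= start:
            return 0.0
        pos, cnt = self.arrays(chrom, strand)
        if pos.size == 0:
            return 0.0
        lo, hi = np.searchsorted(pos, [start, end])
        return float(cnt[lo:hi].sum())

    def dense(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Per-nucleotide count vector for [start, end) on one strand."""
        out = np.zeros(max(end - start, 0), dtype=np.float64)
        pos, cnt = self.arrays(chrom, strand)
        if pos.size == 0 or end <= start:
            return out
        lo, hi = np.searchsorted(pos, [start, end])
        out[pos[lo:hi] - start] = cnt[lo:hi]
        return out

    @property
    def total_signal(self) -> float:
        return float(sum(c.sum() for _, c in self._data.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        """Return a copy with every count divided by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        out = CoverageTrack(sample=self.sample, normalized=True)
        for (chrom, strand), (pos, cnt) in self._data.items():
            out._data[(chrom, strand)] = (pos.copy(), cnt / factor)
        return out


@dataclass
class CountMatrix:
    """Gene-by-sample counts for one region kind (promoter or body)."""

    counts: pd.DataFrame            # rows gene_id, columns sample
    region: str                     # "promoter" | "body"
    conditions: Mapping[str, str]   # sample -> condition label
    field_checked: bool = field(default=False, repr=False)

    def __post_init__(self):
        if self.counts.isna().any().any():
            raise ValueError("count matrix must have no missing cells")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition assignment: {sorted(missing)}")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


# ---------------------------------------------------------------------------
# BED6 gene annotation
# ---------------------------------------------------------------------------

def read_genes(path: str | Path) -> list[GeneModel]:
    """Parse a BED6 file into GeneModels; validates coordinates and ids."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated BED fields")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            if start_i >= end_i:
                raise ValueError(f"{path}:{lineno}: start >= end ({start_i} >= {end_i})")
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {name!r}")
            seen.add(name)
            genes.append(GeneModel(chrom, start_i, end_i, name, strand))
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def gtf_to_genes(path: str | Path) -> list[GeneModel]:
    """Convert GTF ``gene`` records to GeneModels (utility, not a core path)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = {}
            for item in f[8].strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError("GTF gene record without gene_id attribute")
            genes.append(
                GeneModel(f[0], int(f[3]) - 1, int(f[4]), gid, f[6], attrs.get("gene_name"))
            )
    return genes


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, strand: str, sample: str = "", track: CoverageTrack | None = None) -> CoverageTrack:
    """Read one per-strand bedGraph into (or onto) a CoverageTrack.

    Interval value ``v`` over ``[a, b)`` expands to a per-nucleotide count of
    ``v`` at every position in the interval. Overlapping intervals and
    negative values are rejected.
    """
    if strand not in STRANDS:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    out = track if track is not None else CoverageTrack(sample=sample)
    last_end: dict[str, int] = {}
    pos_chunks: dict[str, list[np.ndarray]] = {}
    cnt_chunks: dict[str, list[np.ndarray]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, a, b, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage value {v}")
            if b <= a:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            if a < last_end.get(chrom, 0):
                raise ValueError(f"{path}:{lineno}: overlapping or unsorted intervals on {chrom}")
            last_end[chrom] = b
            if v == 0:
                continue
            pos_chunks.setdefault(chrom, []).append(np.arange(a, b, dtype=np.int64))
            cnt_chunks.setdefault(chrom, []).append(np.full(b - a, v, dtype=np.float64))
    for chrom in pos_chunks:
        out.add(chrom, strand, np.concatenate(pos_chunks[chrom]), np.concatenate(cnt_chunks[chrom]))
    return out


def write_bedgraph(track: CoverageTrack, strand: str, path: str | Path) -> None:
    """Write one strand of a track as bedGraph, merging equal adjacent values."""
    with open(path, "w") as fh:
        chroms = sorted({c for c, s in track.keys() if s == strand})
        for chrom in chroms:
            pos, cnt = track.arrays(chrom, strand)
            if pos.size == 0:
                continue
            # run breaks: position jump or value change
            breaks = np.flatnonzero((np.diff(pos) != 1) | (np.diff(cnt) != 0)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [pos.size]])
            for i0, i1 in zip(starts, ends):
                v = cnt[i0]
                fv = int(v) if float(v).is_integer() else v
                fh.write(f"{chrom}\t{pos[i0]}\t{pos[i1 - 1] + 1}\t{fv}\n")


# ---------------------------------------------------------------------------
# GMT gene sets and RNK ranked scores
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT collection: name, description, members. Members de-duplicated."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(set(members))]) + "\n")


def read_rnk(path: str | Path) -> pd.Series:
    """Read a two-column RNK file into a gene -> score Series (order preserved)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "score"], dtype={"gene": str})
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].unique()[:5]
        raise ValueError(f"{path}: duplicate genes in RNK file: {list(dupes)}")
    if df["score"].isna().any():
        raise ValueError(f"{path}: non-numeric score in RNK file")
    return pd.Series(df["score"].to_numpy(dtype=float), index=df["gene"], name="score")


def log(msg: str) -> None:
    print(f"[pausekit] {msg}", file=sys.stderr)
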