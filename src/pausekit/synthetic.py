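"""Synthetic strand-specific nascent-transcription data with known truth.

The generator emulates the structure of a PRO-seq experiment on cultured
cells: every gene carries a promoter-proximal paused peak (a narrow pileup of
polymerase 3' ends 30-60 nt downstream of the TSS) over a lower, roughly
uniform gene-body occupancy. Region-level read counts are drawn from a
negative binomial (replicate variability), then spread to single-nucleotide
positions. Treatment conditions rescale the expected promoter-peak and
gene-body signal of an affected subset of genes, which lets them model either
pause release (promoter down, body up) or a pause-release block (promoter up,
body down). A uniform Poisson background exercises active-gene filtering.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GeneModel

__all__ = [
    "ScenarioEffect",
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticExperiment",
    "generate_annotation",
    "simulate_sample",
    "simulate_experiment",
    "DoseMatrix",
    "simulate_dose_matrix",
]

_WINDOW_BUFFER = 1000  # genes stay disjoint even after +-1000 nt extension


@dataclass(frozen=True)
class ScenarioEffect:
    """One treatment condition's effect on the affected genes.

    ``pause_multiplier`` scales the expected promoter-peak signal and
    ``body_multiplier`` the expected gene-body density, relative to vehicle.
    Pause release is (pause < 1, body > 1); a pause-release block is the
    opposite. The vehicle condition must be (1, 1).
    """

    label: str
    affected_fraction: float = 0.0
    pause_multiplier: float = 1.0
    body_multiplier: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise ValueError("affected_fraction must be in [0, 1]")
        if self.pause_multiplier <= 0 or self.body_multiplier <= 0:
            raise ValueError("effect multipliers must be > 0")


def _default_conditions() -> tuple[ScenarioEffect, ...]:
    # A four-arm design: vehicle, a pause-release agent (CDK12i-like), a
    # pause-release blocker (P-TEFb-inhibitor-like), and the blocker layered
    # on top of the releaser (multipliers compose on the shared affected set).
    return (
        ScenarioEffect("DMSO"),
        ScenarioEffect("CDK12i", 0.3, 0.6, 1.5),
        ScenarioEffect("PTEFbi", 0.3, 1.3, 0.5),
        ScenarioEffect("CDK12i+PTEFbi", 0.3, 0.6 * 1.3, 1.5 * 0.5),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Length/offset units are nucleotides; ``expression_law`` is the log-normal
    law of mean gene-body density in arbitrary pre-scaling units (the overall
    scale is set by ``depth_per_sample``); ``pi_law`` is the log-normal law of
    the true pausing index; ``dispersion`` is the NB alpha (Var = mu +
    alpha*mu^2), 0 meaning Poisson.
    """

    n_genes: int = 2000
    genome_length: int = 40_000_000
    gene_length_meanlog: float = 8.6
    gene_length_sdlog: float = 0.6
    min_gene_length: int = 1250
    pause_offset_range: tuple[int, int] = (30, 60)
    pause_width: int = 40
    expression_meanlog: float = -3.9
    expression_sdlog: float = 0.75
    pi_meanlog: float = 1.386
    pi_sdlog: float = 0.5
    dispersion: float = 0.01
    depth_per_sample: float = 2_000_000.0
    n_replicates: int = 2
    conditions: tuple[ScenarioEffect, ...] = field(default_factory=_default_conditions)
    background_rate: float = 0.001  # Poisson reads/nt per strand
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.min_gene_length < 1250:
            raise ValueError("min_gene_length must be >= 1250 so the body window is >= 500 nt")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth_per_sample < 0:
            raise ValueError("depth_per_sample must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        labels = [c.label for c in self.conditions]
        if len(labels) != len(set(labels)):
            raise ValueError("condition labels must be unique")
        lo, hi = self.pause_offset_range
        if not (0 <= lo <= hi):
            raise ValueError("pause_offset_range must be a non-negative increasing pair")

    @property
    def vehicle(self) -> str:
        for c in self.conditions:
            if c.pause_multiplier == 1.0 and c.body_multiplier == 1.0:
                return c.label
        raise ValueError("config has no vehicle condition (multipliers 1, 1)")

    def condition(self, label: str) -> ScenarioEffect:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(f"unknown condition label {label!r}")


@dataclass
class SyntheticTruth:
    """Ground truth per (gene, condition).

    ``table`` columns: gene_id, condition, affected, expected_promoter_count
    (expected reads in the 500-nt promoter window), expected_body_density
    (expected reads/nt over the body), true_pi, body_fc (expected body
    fold-change vs vehicle). ``params`` holds the per-gene draws (pause
    offset, base density, base PI, affected-threshold uniform).
    """

    table: pd.DataFrame
    params: pd.DataFrame
    scale: float

    def per_condition(self, label: str) -> pd.DataFrame:
        sub = self.table[self.table["condition"] == label]
        return sub.set_index("gene_id")


def _child_seed(seed: int, *keys: int) -> int:
    """Deterministic sub-stream seed below 2**31."""
    mask = (1 << 64) - 1
    h = (int(seed) * 0x9E3779B97F4A7C15) & mask
    for k in keys:
        h = ((h ^ (int(k) + 1)) * 0xBF58476D1CE4E5B9) & mask
    return h % (2**31 - 1)


def generate_annotation(config: SimulationConfig) -> list[GeneModel]:
    """Place non-overlapping genes (with +-1000 nt buffers) on one chromosome.

    Genes are laid out left to right with random gaps, which guarantees
    pairwise disjointness after window extension; strands alternate randomly.
    """
    rng = np.random.default_rng(_child_seed(config.seed, 1))
    n = config.n_genes
    if n == 0:
        return []
    lengths = np.maximum(
        rng.lognormal(config.gene_length_meanlog, config.gene_length_sdlog, n).astype(np.int64),
        config.min_gene_length,
    )
    mean_len = float(np.exp(config.gene_length_meanlog + config.gene_length_sdlog**2 / 2))
    if n * mean_len > config.genome_length / 2:
        raise ValueError(
            f"genome too small: {n} genes x mean length {mean_len:.0f} nt needs "
            f">= {2 * n * mean_len:.0f} nt, genome is {config.genome_length}"
        )
    required = int(lengths.sum()) + (n + 1) * 2 * _WINDOW_BUFFER
    if required > config.genome_length:
        raise ValueError(
            f"genome too small to place genes: need {required} nt, have {config.genome_length}"
        )
    slack = config.genome_length - required
    w = rng.random(n + 1)
    gaps = 2 * _WINDOW_BUFFER + np.floor(w / w.sum() * slack).astype(np.int64)
    strands = rng.choice(["+", "-"], size=n)
    genes = []
    cursor = 0
    for i in range(n):
        cursor += int(gaps[i])
        start = cursor
        end = start + int(lengths[i])
        genes.append(GeneModel("chr1", start, end, f"G{i + 1:05d}", str(strands[i])))
        cursor = end
    return genes


def _gene_params(config: SimulationConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    lo, hi = config.pause_offset_range
    return pd.DataFrame(
        {
            "pause_offset": rng.integers(lo, hi + 1, n),
            "body_density": rng.lognormal(config.expression_meanlog, config.expression_sdlog, n),
            "true_pi_base": rng.lognormal(config.pi_meanlog, config.pi_sdlog, n),
            "affect_u": rng.random(n),
        }
    )


def build_truth(config: SimulationConfig, genes: Sequence[GeneModel]) -> SyntheticTruth:
    """Expected signals, PI and fold-changes for every gene and condition.

    A gene is affected by a condition iff its per-gene uniform draw falls
    below the condition's ``affected_fraction``; conditions with equal
    fractions therefore share the affected set, so layered treatments hit the
    same genes. The depth scale is calibrated on the vehicle condition.
    """
    rng = np.random.default_rng(_child_seed(config.seed, 2))
    n = len(genes)
    params = _gene_params(config, rng, n)
    params.index = pd.Index([g.gene_id for g in genes], name="gene_id")
    lengths = np.array([g.length for g in genes], dtype=float)
    body_len = lengths - 750.0  # quantification body window length

    d = params["body_density"].to_numpy()
    pi = params["true_pi_base"].to_numpy()
    prom_count = pi * d * 500.0  # expected reads in the 500-nt promoter window
    # body reads are spread over [TSS+250, gene end): length L - 250
    vehicle_total = float((prom_count + d * (lengths - 250.0)).sum())
    scale = (config.depth_per_sample / vehicle_total) if vehicle_total > 0 else 0.0

    rows = []
    for cond in config.conditions:
        affected = params["affect_u"].to_numpy() < cond.affected_fraction
        pm = np.where(affected, cond.pause_multiplier, 1.0)
        bm = np.where(affected, cond.body_multiplier, 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": params.index,
                    "condition": cond.label,
                    "affected": affected,
                    "expected_promoter_count": prom_count * pm * scale,
                    "expected_body_density": d * bm * scale,
                    "true_pi": (prom_count * pm / 500.0) / (d * bm),
                    "body_fc": bm,
                    "body_window_length": body_len,
                }
            )
        )
    return SyntheticTruth(table=pd.concat(rows, ignore_index=True), params=params, scale=scale)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    size_param = 1.0 / alpha
    p = size_param / (size_param + np.maximum(mean, 0.0))
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size_param, p[pos])
    return out


def simulate_sample(
    genes: Sequence[GeneModel],
    truth: SyntheticTruth,
    config: SimulationConfig,
    condition: str,
    replicate: int,
    seed: int,
) -> CoverageTrack:
    """One replicate coverage track for one condition.

    Per gene, the promoter-peak read count and the body read count are drawn
    NB(expected, alpha); peak reads land uniformly in the pause window
    (offset +- width/2 downstream of the TSS, in transcription coordinates),
    body reads uniformly over [TSS+250, gene end). A Poisson background
    floor covers the genome on both strands.
    """
    config.condition(condition)  # raises KeyError for unknown labels
    rng = np.random.default_rng(seed)
    track = CoverageTrack(sample=f"{condition}_rep{replicate}")
    expected = truth.per_condition(condition)

    pos_by_strand: dict[str, list[np.ndarray]] = {"+": [], "-": []}
    cnt_by_strand: dict[str, list[np.ndarray]] = {"+": [], "-": []}
    half_w = config.pause_width // 2
    for g in genes:
        row = expected.loc[g.gene_id]
        offset = int(truth.params.at[g.gene_id, "pause_offset"])
        mu_prom = float(row["expected_promoter_count"])
        mu_body = float(row["expected_body_density"]) * (g.length - 250)
        n_prom = int(_nb_draw(rng, np.array([mu_prom]), config.dispersion)[0])
        n_body = int(_nb_draw(rng, np.array([mu_body]), config.dispersion)[0])
        # transcription-coordinate intervals mapped to genomic positions
        if g.strand == "+":
            peak_start = g.tss + offset - half_w
            body_start = g.tss + 250
            peak = peak_start + rng.integers(0, config.pause_width, n_prom)
            body = body_start + rng.integers(0, g.length - 250, n_body)
        else:
            peak_end = g.tss - offset + half_w
            peak = peak_end - rng.integers(0, config.pause_width, n_prom)
            body = g.tss - 250 - rng.integers(0, g.length - 250, n_body)
        allpos = np.concatenate([peak, body])
        if allpos.size:
            pos_by_strand[g.strand].append(allpos)
            cnt_by_strand[g.strand].append(np.ones(allpos.size))

    for strand in "+-":
        n_noise = rng.poisson(config.background_rate * config.genome_length)
        if n_noise > 0:
            noise = rng.integers(0, config.genome_length, n_noise)
            pos_by_strand[strand].append(noise)
            cnt_by_strand[strand].append(np.ones(n_noise))
        if pos_by_strand[strand]:
            track.add(
                "chr1",
                strand,
                np.concatenate(pos_by_strand[strand]),
                np.concatenate(cnt_by_strand[strand]),
            )
    return track


@dataclass
class SyntheticExperiment:
    """Self-describing bundle: annotation, truth and all replicate tracks."""

    config: SimulationConfig
    genes: list[GeneModel]
    truth: SyntheticTruth
    tracks: dict[str, CoverageTrack]        # sample label -> track
    conditions: dict[str, str]              # sample label -> condition


def simulate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Generate the full design: every condition x replicate track."""
    genes = generate_annotation(config)
    truth = build_truth(config, genes)
    tracks: dict[str, CoverageTrack] = {}
    cond_map: dict[str, str] = {}
    for ci, cond in enumerate(config.conditions):
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond.label}_rep{rep}"
            tracks[sample] = simulate_sample(
                genes, truth, config, cond.label, rep, _child_seed(config.seed, 3, ci, rep)
            )
            cond_map[sample] = cond.label
    return SyntheticExperiment(config, genes, truth, tracks, cond_map)


# ---------------------------------------------------------------------------
# Dose-response matrices
# ---------------------------------------------------------------------------

@dataclass
class DoseMatrix:
    """Replicated fraction-affected readouts over a dose grid (incl. vehicle)."""

    doses_a: tuple[float, ...]
    doses_b: tuple[float, ...]
    values: np.ndarray  # shape (len(doses_a), len(doses_b), n_replicates)
    kind: str = "cytotoxicity"

    def __post_init__(self):
        if 0 not in self.doses_a or 0 not in self.doses_b:
            raise ValueError("dose grids must include 0 (vehicle)")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[:2] != (len(self.doses_a), len(self.doses_b)):
            raise ValueError("values shape must match the dose grid")

    def replicate_mean(self) -> np.ndarray:
        return self.values.mean(axis=2)


def simulate_dose_matrix(
    fa: Sequence[float],
    fb: Sequence[float],
    doses_a: Sequence[float] | None = None,
    doses_b: Sequence[float] | None = None,
    true_excess: np.ndarray | None = None,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[DoseMatrix, np.ndarray]:
    """Observed fraction = Bliss expectation + planted excess + Gaussian noise.

    ``fa``/``fb`` are the single-agent fractions affected along each dose
    axis (first entry, the vehicle, must be 0). Returns the matrix and the
    planted excess (the retained truth). Values are clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if np.any((fa < 0) | (fa > 1)) or np.any((fb < 0) | (fb > 1)):
        raise ValueError("single-agent fractions must lie in [0, 1]")
    if fa[0] != 0 or fb[0] != 0:
        raise ValueError("vehicle (dose 0) single-agent fraction must be 0")
    na, nb = fa.size, fb.size
    doses_a = tuple(doses_a) if doses_a is not None else tuple(range(na))
    doses_b = tuple(doses_b) if doses_b is not None else tuple(range(nb))
    excess = np.zeros((na, nb)) if true_excess is None else np.asarray(true_excess, dtype=float)
    expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=(na, nb, n_replicates)) if noise_sd > 0 else 0.0
    vals = np.clip(expected[:, :, None] + excess[:, :, None] + noise, 0.0, 1.0)
    return DoseMatrix(doses_a, doses_b, vals), excess


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["conditions"] = [asdict(c) for c in config.conditions]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    d["conditions"] = tuple(ScenarioEffect(**c) for c in d.get("conditions", []))
    if not d["conditions"]:
        d.pop("conditions")
    for key in ("pause_offset_range",):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
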