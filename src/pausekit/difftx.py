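"""Differential transcription: normalization, NB Wald test, BH, classification.

The test is a deliberately simple negative-binomial Wald pipeline:

1. median-of-ratios size factors (per-sample scale factors computed against
   per-gene geometric means over genes observed in every sample);
2. per-gene log2 fold-change of group means of normalized counts
   (pseudocount 0.5, no shrinkage);
3. NB dispersion alpha from the fitted mean-dispersion trend a0 + a1/mu
   (least squares on per-gene method-of-moments estimates), clamped to
   [1e-8, 10]; a per-gene max(MoM, trend) mode is available but not the
   default, because at 2 replicates the MoM estimate has ~2 degrees of
   freedom and taking a per-gene max converts its noise into systematic
   dispersion inflation, roughly halving power;
4. Wald z = log2FC / se with the standard error from the NB Fisher
   information, two-sided normal p-value;
5. Benjamini-Hochberg adjustment.

Classification rules follow the two threshold sets used for nascent
(gene-body Pol II) and steady-state RNA comparisons respectively:
DTG: padj <= 0.05 and FC >= 1.25 (UP) or FC <= 0.8 (DOWN);
DEG: padj <= 0.001 and |log2FC| >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CountMatrix, log

__all__ = [
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "classify_dtg",
    "classify_deg",
    "ma_table",
    "length_summary",
    "LengthSummary",
]

DTG_PADJ = 0.05
DTG_FC_UP = 1.25
DTG_FC_DOWN = 0.8
DEG_PADJ = 0.001
DEG_LOG2FC = 1.0

_DISPERSION_FLOOR = 1e-8
_DISPERSION_CEIL = 10.0


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios sample scale factors.

    Reference is the per-gene geometric mean across samples, computed over
    genes with nonzero counts in every sample; each sample's factor is the
    median ratio of its counts to the reference.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    mat = df.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; consider adding a pseudocount"
        )
    logs = np.log(mat[all_nonzero])
    ref = logs.mean(axis=1, keepdims=True)  # log geometric mean per gene
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def _fit_dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mu over informative genes."""
    ok = (mu > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 2:
        return 0.0, 0.0
    x = 1.0 / mu[ok]
    y = np.clip(alpha_mom[ok], 0.0, _DISPERSION_CEIL)
    X = np.column_stack([np.ones(x.size), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(max(coef[0], 0.0)), float(max(coef[1], 0.0))


def nb_wald_test(
    counts: pd.DataFrame | CountMatrix,
    design: dict[str, str],
    treatment: str,
    control: str,
    factors: pd.Series | None = None,
    dispersion_mode: str = "trend",
) -> pd.DataFrame:
    """Per-gene NB Wald test of treatment vs control on a count matrix.

    ``design`` maps sample -> group label. Returns a DataFrame indexed by
    gene with columns baseMean, log2FC, se, p (class assignment is a separate
    step). ``dispersion_mode`` is "trend" (fitted mean-dispersion trend,
    the default and the only option meaningful at one replicate per group)
    or "max" (per-gene max of the MoM estimate and the trend; conservative,
    costly in power at low replication).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    t_samples = [s for s in df.columns if design.get(s) == treatment]
    c_samples = [s for s in df.columns if design.get(s) == control]
    if not t_samples or not c_samples:
        raise ValueError("both groups need at least one sample present in the matrix")
    if (len(t_samples) < 2 or len(c_samples) < 2) and dispersion_mode != "trend":
        log("fewer than 2 replicates per group: falling back to trended dispersion only")
        dispersion_mode = "trend"
    if factors is None:
        factors = size_factors(df[t_samples + c_samples])

    sf = factors.reindex(t_samples + c_samples).to_numpy()
    raw = df[t_samples + c_samples].to_numpy(dtype=float)
    norm = raw / sf
    nt, nc = len(t_samples), len(c_samples)
    norm_t, norm_c = norm[:, :nt], norm[:, nt:]

    mean_t = norm_t.mean(axis=1)
    mean_c = norm_c.mean(axis=1)
    base_mean = norm.mean(axis=1)
    log2fc = np.log2(mean_t + 0.5) - np.log2(mean_c + 0.5)

    # Method-of-moments dispersion from within-group variability of
    # normalized counts: Var(K/s) ~= mu/s + alpha*mu^2, pooled across groups.
    mu_gene = base_mean
    inv_s = (1.0 / sf).mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        var_w = np.zeros(df.shape[0])
        dof = 0
        if nt > 1:
            var_w += norm_t.var(axis=1, ddof=1) * (nt - 1)
            dof += nt - 1
        if nc > 1:
            var_w += norm_c.var(axis=1, ddof=1) * (nc - 1)
            dof += nc - 1
        var_w = var_w / dof if dof > 0 else np.full(df.shape[0], np.nan)
        alpha_mom = (var_w - mu_gene * inv_s) / np.square(mu_gene)
    a0, a1 = _fit_dispersion_trend(mu_gene, alpha_mom)
    with np.errstate(divide="ignore"):
        alpha_trend = np.where(mu_gene > 0, a0 + a1 / np.maximum(mu_gene, 1e-300), a0)
    if dispersion_mode == "trend":
        alpha = alpha_trend
    elif dispersion_mode == "max":
        alpha = np.fmax(np.nan_to_num(alpha_mom, nan=0.0), alpha_trend)
    else:
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
    alpha = np.clip(alpha, _DISPERSION_FLOOR, _DISPERSION_CEIL)

    # Wald se of log2FC via the NB Fisher information for a group mean:
    # Var(mean of K_j/s_j) = (1/n^2) * sum_j (mu/s_j + alpha*mu^2)
    def group_var(mean, samples_sf):
        n = samples_sf.size
        return (mean[:, None] / samples_sf + alpha[:, None] * np.square(mean)[:, None]).sum(axis=1) / n**2

    mt = np.maximum(mean_t, 0.5)
    mc = np.maximum(mean_c, 0.5)
    var_log_t = group_var(mt, sf[:nt]) / np.square(mt)
    var_log_c = group_var(mc, sf[nt:]) / np.square(mc)
    se = np.sqrt(var_log_t + var_log_c) / np.log(2.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = (raw.sum(axis=1) == 0)
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    if all_zero.any():
        log(f"{int(all_zero.sum())} all-zero genes flagged (log2FC=0, p=1)")

    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "se": se,
            "dispersion": alpha,
            "p": np.clip(p, 0.0, 1.0),
            "allZero": all_zero,
        },
        index=df.index,
    )
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with monotonicity."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def classify_dtg(fold_change: float, padj: float) -> str:
    """Nascent-transcription (gene-body Pol II) classification, inclusive bounds."""
    if padj <= DTG_PADJ and fold_change >= DTG_FC_UP:
        return "UP"
    if padj <= DTG_PADJ and fold_change <= DTG_FC_DOWN:
        return "DOWN"
    return "NS"


def classify_deg(log2fc: float, padj: float) -> str:
    """Steady-state RNA classification, inclusive bounds."""
    if padj <= DEG_PADJ and log2fc >= DEG_LOG2FC:
        return "UP"
    if padj <= DEG_PADJ and log2fc <= -DEG_LOG2FC:
        return "DOWN"
    return "NS"


def classify_results(results: pd.DataFrame, rule: str = "dtg") -> pd.Series:
    """Vectorised classification of an nb_wald_test result table."""
    if rule == "dtg":
        fc = np.exp2(results["log2FC"].to_numpy())
        cls = [classify_dtg(f, q) for f, q in zip(fc, results["padj"])]
    elif rule == "deg":
        cls = [classify_deg(l, q) for l, q in zip(results["log2FC"], results["padj"])]
    else:
        raise ValueError("rule must be 'dtg' or 'deg'")
    return pd.Series(cls, index=results.index, name="class")


def ma_table(results: pd.DataFrame) -> pd.DataFrame:
    """MA summary: x = log2 mean gene-body counts, y = log2FC, plus class."""
    out = pd.DataFrame(index=results.index)
    out["A"] = np.log2(results["baseMean"].to_numpy())
    out["M"] = results["log2FC"]
    if "class" in results.columns:
        out["class"] = results["class"]
    return out


@dataclass(frozen=True)
class LengthSummary:
    """Tukey boxplot statistics for one class of gene lengths."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def length_summary(lengths_by_class: dict[str, "np.ndarray | list"]) -> dict[str, LengthSummary]:
    """Boxplot summaries of gene lengths per class.

    Quartiles use type-7 linear interpolation; whiskers sit at the most
    extreme data points within 1.5*IQR of the box; points beyond that are
    listed as outliers. Empty classes are omitted with a log record.
    """
    out: dict[str, LengthSummary] = {}
    for cls, lengths in lengths_by_class.items():
        arr = np.asarray(lengths, dtype=float)
        if arr.size == 0:
            log(f"length_summary: class {cls!r} empty, omitted")
            continue
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # type-7 default
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
        out[cls] = LengthSummary(
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            whisker_low=float(inside.min()),
            whisker_high=float(inside.max()),
            outliers=tuple(sorted(arr[(arr < lo_fence) | (arr > hi_fence)])),
        )
    return out
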