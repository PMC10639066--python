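"""Plate-assay normalization, Bliss-independence synergy, ddCt quantification.

Bliss independence says two non-interacting drugs with single-agent
fractions affected fA and fB should jointly affect E = fA + fB - fA*fB of
cells; the excess fAB - E of the observed combination over E quantifies
synergy (positive) or antagonism (negative). Scores are reported as
100 x excess, the scale synergy screens conventionally print.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import DoseMatrix

__all__ = ["normalize_to_vehicle", "bliss_excess", "synergy_map", "BlissMap", "ddct"]

READOUT_KINDS = ("cytotoxicity", "viability", "apoptosis")


def normalize_to_vehicle(
    matrix: DoseMatrix, max_signal: float | None = None
) -> np.ndarray:
    """Convert raw readouts to fractions affected in [0, 1], vehicle -> 0.

    Death-type readouts (cytotoxicity, apoptosis: signal rises with effect)
    use f = (x - vehicle) / (max_signal - vehicle) when a max-kill reference
    is supplied, else the documented fallback f = clip(x/vehicle - 1, 0, 1).
    Viability (signal falls with effect) uses f = 1 - clip(x/vehicle, 0, 1).
    Replicates are averaged on the fraction scale.
    """
    if matrix.kind not in READOUT_KINDS:
        raise ValueError(f"unknown readout kind {matrix.kind!r}")
    vehicle = matrix.values[matrix.doses_a.index(0), matrix.doses_b.index(0), :].mean()
    if vehicle <= 0:
        raise ValueError("vehicle mean must be > 0 for normalization")
    x = matrix.values
    if matrix.kind == "viability":
        frac = 1.0 - np.clip(x / vehicle, 0.0, 1.0)
    elif max_signal is not None:
        if max_signal <= vehicle:
            raise ValueError("max_signal reference must exceed the vehicle mean")
        frac = np.clip((x - vehicle) / (max_signal - vehicle), 0.0, 1.0)
    else:
        frac = np.clip(x / vehicle - 1.0, 0.0, 1.0)
    return frac.mean(axis=2)


def bliss_excess(fa: float, fb: float, fab: float) -> tuple[float, float, float]:
    """(expected, excess, score): E = fA + fB - fA*fB; score = 100*(fAB - E)."""
    for name, v in (("fA", fa), ("fB", fb), ("fAB", fab)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]; clip before scoring (got {v})")
    expected = fa + fb - fa * fb
    excess = fab - expected
    return expected, excess, 100.0 * excess


@dataclass
class BlissMap:
    """Per-cell Bliss scores for a dose matrix plus scalar summaries."""

    table: pd.DataFrame          # dose_a, dose_b, fa, fb, fab, expected, excess, score
    max_pair: tuple[float, float]
    max_score: float
    mean_score: float


def synergy_map(matrix: DoseMatrix, max_signal: float | None = None,
                fractions: np.ndarray | None = None) -> BlissMap:
    """Score every non-vehicle combination cell of a dose matrix.

    Single-agent fractions come from the first row (drug B alone) and first
    column (drug A alone); pass ``fractions`` to skip normalization when the
    matrix already holds fractions affected.
    """
    frac = normalize_to_vehicle(matrix, max_signal) if fractions is None else np.asarray(fractions)
    ia0 = matrix.doses_a.index(0)
    ib0 = matrix.doses_b.index(0)
    rows = []
    for i, da in enumerate(matrix.doses_a):
        for j, db in enumerate(matrix.doses_b):
            if i == ia0 or j == ib0:
                continue
            fa = float(np.clip(frac[i, ib0], 0.0, 1.0))
            fb = float(np.clip(frac[ia0, j], 0.0, 1.0))
            fab = float(np.clip(frac[i, j], 0.0, 1.0))
            expected, excess, score = bliss_excess(fa, fb, fab)
            rows.append((da, db, fa, fb, fab, expected, excess, score))
    if not rows:
        raise ValueError("dose matrix has no combination cells beyond the single agents")
    table = pd.DataFrame(
        rows, columns=["dose_a", "dose_b", "fa", "fb", "fab", "expected", "excess", "score"]
    )
    best = table.loc[table["score"].idxmax()]
    return BlissMap(
        table=table,
        max_pair=(float(best["dose_a"]), float(best["dose_b"])),
        max_score=float(best["score"]),
        mean_score=float(table["score"].mean()),
    )


def ddct(
    target_ct_treated: float,
    ref_ct_treated: float,
    target_ct_control: float,
    ref_ct_control: float,
) -> float:
    """Relative quantity by the ddCt method (reference-gene and vehicle normalized).

    RQ = 2^-[(Ct_target,T - Ct_ref,T) - (Ct_target,C - Ct_ref,C)].
    """
    for v in (target_ct_treated, ref_ct_treated, target_ct_control, ref_ct_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    delta_delta = (target_ct_treated - ref_ct_treated) - (target_ct_control - ref_ct_control)
    return float(2.0 ** (-delta_delta))
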