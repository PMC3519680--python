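"""Amplification-curve preprocessing and reaction-efficiency estimation.

A well's raw fluorescence trace is baseline-corrected (mean of the early
cycles), normalized to its maximum at the final cycle, and the fractional
cycle at which it first crosses a pair of relative thresholds (3% and 6% of
the plateau by default) is found by log-linear interpolation.  The reaction
efficiency follows from the spacing of the two crossings:

    E = (R_B / R_A) ** (1 / (Ct_B - Ct_A)) - 1

where R_B / R_A is the ratio of the two thresholds.  For a perfectly
doubling reaction the crossings are exactly one cycle apart and E = 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AmplificationCurve",
    "ThresholdPair",
    "CtResult",
    "EfficiencyEstimate",
    "NoAmplificationError",
    "baseline_correct",
    "normalize_relative",
    "preprocess",
    "ct_at_threshold",
    "estimate_efficiency",
    "process_plate",
    "summarize_gene_efficiency",
]


class NoAmplificationError(ValueError):
    """Raised when a curve shows no signal above baseline (non-positive max)."""


@dataclass(frozen=True)
class AmplificationCurve:
    """One well's fluorescence trace over consecutive PCR cycles."""

    well_id: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        cycles = np.asarray(self.cycles, dtype=np.int64)
        fluor = np.asarray(self.fluorescence, dtype=np.float64)
        if cycles.ndim != 1 or fluor.ndim != 1:
            raise ValueError("cycles and fluorescence must be 1-D")
        if len(cycles) != len(fluor):
            raise ValueError(
                f"well {self.well_id!r}: {len(cycles)} cycles but "
                f"{len(fluor)} fluorescence values"
            )
        if len(cycles) == 0:
            raise ValueError(f"well {self.well_id!r}: empty trace")
        if np.any(np.diff(cycles) != 1):
            raise ValueError(
                f"well {self.well_id!r}: cycles must be consecutive integers"
            )
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "fluorescence", fluor)

    def __len__(self) -> int:
        return len(self.cycles)

    def with_fluorescence(self, fluor: np.ndarray) -> "AmplificationCurve":
        return AmplificationCurve(self.well_id, self.cycles, fluor)


@dataclass(frozen=True)
class ThresholdPair:
    """Two relative fluorescence thresholds (fractions of the plateau max)."""

    frac_a: float = 0.03
    frac_b: float = 0.06

    def __post_init__(self) -> None:
        if not (0.0 < self.frac_a < self.frac_b < 1.0):
            raise ValueError(
                f"thresholds must satisfy 0 < frac_a < frac_b < 1, "
                f"got ({self.frac_a}, {self.frac_b})"
            )


@dataclass(frozen=True)
class CtResult:
    """Fractional cycle at which a normalized curve first reaches a threshold."""

    well_id: str
    threshold_frac: float
    ct: float
    censored: bool = False


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Per-well efficiency with the two threshold crossings it came from.

    ``flagged`` marks estimates that are numerically defined but outside the
    plausible range (0, 1.1], or with non-increasing crossings; ``censored``
    marks wells where a threshold was never reached.
    """

    well_id: str
    e: float
    ct_a: float
    ct_b: float
    censored: bool = False
    flagged: bool = False


def baseline_correct(
    curve: AmplificationCurve, baseline_cycles: tuple[int, int] = (1, 5)
) -> AmplificationCurve:
    """Subtract the mean fluorescence over ``baseline_cycles`` (inclusive)."""
    lo, hi = baseline_cycles
    if lo > hi:
        raise ValueError(f"invalid baseline range ({lo}, {hi})")
    mask = (curve.cycles >= lo) & (curve.cycles <= hi)
    if mask.sum() != hi - lo + 1:
        raise ValueError(
            f"well {curve.well_id!r}: baseline cycles {lo}-{hi} not fully "
            f"contained in trace (cycles {curve.cycles[0]}-{curve.cycles[-1]})"
        )
    return curve.with_fluorescence(
        curve.fluorescence - curve.fluorescence[mask].mean()
    )


def normalize_relative(curve: AmplificationCurve) -> AmplificationCurve:
    """Scale so the maximum (the plateau at the final cycles) equals 1."""
    m = curve.fluorescence.max()
    if m <= 0:
        raise NoAmplificationError(
            f"well {curve.well_id!r}: no amplification (max fluorescence "
            f"{m:g} after baseline correction)"
        )
    return curve.with_fluorescence(curve.fluorescence / m)


def preprocess(
    curve: AmplificationCurve, baseline_cycles: tuple[int, int] = (1, 5)
) -> AmplificationCurve:
    """Baseline-correct then normalize to the plateau maximum."""
    return normalize_relative(baseline_correct(curve, baseline_cycles))


def ct_at_threshold(
    curve: AmplificationCurve, frac: float, min_cycle: int | None = None
) -> CtResult:
    """First crossing of a preprocessed curve above ``frac``.

    The crossing is located between the last cycle below and the first cycle
    at/above the threshold, and interpolated log-linearly (exponential growth
    is linear in log fluorescence).  If the lower bracket is non-positive
    (noise), plain linear interpolation is used for that bracket.  Crossings
    are searched from ``min_cycle`` on (default: the first cycle after the
    standard 1-5 baseline window) so that baseline noise cannot register as
    an early crossing.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError(f"threshold fraction must be in (0, 1), got {frac}")
    if min_cycle is None:
        min_cycle = 6
    f = curve.fluorescence
    cycles = curve.cycles
    start = int(np.searchsorted(cycles, min_cycle))
    for i in range(start, len(f)):
        if f[i] >= frac:
            if i == 0:
                ct = float(cycles[0])
            else:
                lo, hi = f[i - 1], f[i]
                if lo >= frac:
                    # already above threshold when the search window opens
                    ct = float(cycles[i])
                elif lo <= 0.0:
                    ct = cycles[i - 1] + (frac - lo) / (hi - lo)
                else:
                    ct = cycles[i - 1] + math.log(frac / lo) / math.log(hi / lo)
            return CtResult(curve.well_id, frac, float(ct), censored=False)
    return CtResult(curve.well_id, frac, float("nan"), censored=True)


def estimate_efficiency(
    curve: AmplificationCurve,
    thresholds: ThresholdPair = ThresholdPair(),
    min_cycle: int | None = None,
    flag_range: tuple[float, float] = (0.0, 1.1),
) -> EfficiencyEstimate:
    """Two-threshold efficiency of a preprocessed curve."""
    a = ct_at_threshold(curve, thresholds.frac_a, min_cycle)
    b = ct_at_threshold(curve, thresholds.frac_b, min_cycle)
    if a.censored or b.censored:
        return EfficiencyEstimate(
            curve.well_id, float("nan"), a.ct, b.ct, censored=True
        )
    if b.ct <= a.ct:
        return EfficiencyEstimate(
            curve.well_id, float("nan"), a.ct, b.ct, flagged=True
        )
    e = (thresholds.frac_b / thresholds.frac_a) ** (1.0 / (b.ct - a.ct)) - 1.0
    lo, hi = flag_range
    return EfficiencyEstimate(
        curve.well_id, e, a.ct, b.ct, flagged=not (lo < e <= hi)
    )


def process_plate(
    curves: Iterable[AmplificationCurve],
    thresholds: ThresholdPair = ThresholdPair(),
    baseline_cycles: tuple[int, int] = (1, 5),
) -> pd.DataFrame:
    """Preprocess every well and tabulate Ct values and efficiencies.

    Returns one row per well with columns ``well_id``, ``ct_a``, ``ct_b``,
    ``efficiency``, ``censored``, ``flagged``.  Wells with no signal above
    baseline are kept as censored rows rather than raising.
    """
    min_cycle = baseline_cycles[1] + 1
    rows = []
    for curve in curves:
        try:
            prepped = preprocess(curve, baseline_cycles)
        except NoAmplificationError:
            rows.append(
                dict(
                    well_id=curve.well_id,
                    ct_a=np.nan,
                    ct_b=np.nan,
                    efficiency=np.nan,
                    censored=True,
                    flagged=False,
                )
            )
            continue
        est = estimate_efficiency(prepped, thresholds, min_cycle)
        rows.append(
            dict(
                well_id=curve.well_id,
                ct_a=est.ct_a,
                ct_b=est.ct_b,
                efficiency=est.e,
                censored=est.censored,
                flagged=est.flagged,
            )
        )
    return pd.DataFrame(rows)


def summarize_gene_efficiency(
    well_table: pd.DataFrame,
    gene_map: Mapping[str, str] | pd.Series | None = None,
    drop_flagged: bool = True,
) -> pd.DataFrame:
    """Arithmetic mean efficiency per gene over usable wells.

    ``well_table`` must contain ``efficiency`` and ``censored`` columns plus
    either a ``gene`` column or a ``gene_map`` from well_id to gene.  One
    efficiency per gene is the value carried into the Pfaffl and inter-gene
    calculations.  A gene with zero usable (non-censored, non-flagged) wells
    raises, naming the gene.
    """
    tab = well_table.copy()
    if "gene" not in tab.columns:
        if gene_map is None:
            raise ValueError("well_table has no 'gene' column and no gene_map given")
        tab["gene"] = tab["well_id"].map(dict(gene_map))
    usable = tab[~tab["censored"] & tab["efficiency"].notna()]
    if drop_flagged and "flagged" in usable.columns:
        usable = usable[~usable["flagged"]]
    out = (
        usable.groupby("gene")["efficiency"]
        .agg(efficiency="mean", sd="std", n_wells="count")
        .reset_index()
    )
    missing = sorted(set(tab["gene"].dropna()) - set(out["gene"]))
    if missing:
        raise ValueError(
            "no usable efficiency estimates for gene(s): " + ", ".join(missing)
        )
    return out
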