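"""Synthetic qPCR plates and gel-area tables with known ground truth.

The generator emulates a tenocyte dose-response study: a 17-gene primer
panel, four TGF-beta1 doses (0/1/10/100 ng/mL), four timepoints
(0/6/24/48 h), 6 biological samples per group and triplicate technical
wells, with gene-specific amplification efficiencies and amplicon lengths.

Curve mechanism
---------------
Product copies grow exponentially and saturate at a reagent-limited
capacity::

    D_c = min(t0 * (1 + e0) ** c, d_max)

and measured fluorescence is ``baseline + alpha * amplicon_len * D_c``
plus optional additive Gaussian noise.  Below capacity the trace is exactly
exponential, so the two-threshold efficiency estimator is unbiased on
noiseless curves.  In the study simulator the capacity is shared between
genes as a dsDNA *mass* budget: ``d_max = mass_capacity / amplicon_len``,
which makes the plateau fluorescence (and hence any fixed fraction of it)
the same absolute level for every gene — the premise of the inter-gene
common-threshold analysis.

Biological replicates perturb ``t0`` with a mean-one log-normal multiplier
(configurable CV); technical replicate wells share their sample's ``t0``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import AmplificationCurve

__all__ = [
    "SimCurveParams",
    "GeneSimSpec",
    "StudyDesign",
    "TruthTable",
    "simulate_curve",
    "simulate_study",
    "simulate_gel_areas",
    "default_curve_params",
    "default_study",
    "default_effect_table",
    "noise_sd_for_fraction",
    "DEFAULT_GENE_PANEL",
    "DEFAULT_CONTRACTION",
]

DOSES = (0.0, 1.0, 10.0, 100.0)  # ng/mL TGF-beta1
TIMEPOINTS = (0.0, 6.0, 24.0, 48.0)  # hours


@dataclass(frozen=True)
class SimCurveParams:
    """Ground-truth parameters for one simulated well."""

    t0: float = 1000.0  # initial transcript copies
    e0: float = 0.95  # per-cycle efficiency in (0, 1]
    amplicon_len: int = 100  # bp
    d_max: float = 1e13  # plateau capacity, copies
    alpha: float = 1e-9  # fluorescence units per (bp * copy)
    baseline: float = 100.0  # additive background fluorescence
    noise_sd: float = 0.0  # additive Gaussian noise (fluorescence units)
    n_cycles: int = 40
    detection_limit: float = 1e-6  # of plateau signal; below this, no signal registers

    def __post_init__(self) -> None:
        if self.t0 < 1:
            raise ValueError(f"t0 must be >= 1, got {self.t0}")
        if not (0.0 < self.e0 <= 1.0):
            raise ValueError(f"e0 must be in (0, 1], got {self.e0}")
        if self.amplicon_len <= 0:
            raise ValueError(f"amplicon_len must be positive, got {self.amplicon_len}")
        if self.t0 >= self.d_max:
            raise ValueError("t0 must be below the plateau capacity d_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cycles < 10:
            raise ValueError("n_cycles must be >= 10")
        if not (0.0 <= self.detection_limit < 0.01):
            raise ValueError(
                f"detection_limit must be in [0, 0.01), got {self.detection_limit}"
            )

    @property
    def plateau_fluorescence(self) -> float:
        """Baseline-corrected fluorescence at saturation."""
        return self.alpha * self.amplicon_len * self.d_max


@dataclass(frozen=True)
class GeneSimSpec:
    """Per-gene truth: amplicon length, efficiency, and 0-hour copy number."""

    symbol: str
    amplicon_len: int
    e0: float
    t0_base: float


@dataclass(frozen=True)
class StudyDesign:
    """Layout and ground-truth effect structure of a simulated study."""

    genes: tuple[GeneSimSpec, ...]
    treatments: tuple[float, ...] = DOSES
    timepoints: tuple[float, ...] = TIMEPOINTS
    n_biological: int = 6
    n_wells: int = 3
    effect_table: Mapping[tuple[str, float, float], float] = field(
        default_factory=dict
    )
    housekeeping_gene: str = "Eef1a1"
    bio_cv: float = 0.2

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols: {', '.join(dupes)}")
        if self.housekeeping_gene not in symbols:
            raise ValueError(
                f"housekeeping gene {self.housekeeping_gene!r} not in panel"
            )
        if self.n_biological < 1 or self.n_wells < 1:
            raise ValueError("n_biological and n_wells must be >= 1")
        if self.bio_cv < 0:
            raise ValueError("bio_cv must be >= 0")
        for (gene, dose, tp), fold in self.effect_table.items():
            if fold <= 0:
                raise ValueError(
                    f"effect_table fold for ({gene}, {dose}, {tp}) must be > 0"
                )
            if gene == self.housekeeping_gene and fold != 1.0:
                raise ValueError(
                    "housekeeping gene fold change must be exactly 1 everywhere"
                )

    def effect(self, gene: str, dose: float, timepoint: float) -> float:
        """True fold change of ``gene`` relative to 0 hours; defaults to 1."""
        if timepoint == 0.0:
            return 1.0
        return float(self.effect_table.get((gene, dose, timepoint), 1.0))


@dataclass(frozen=True)
class TruthTable:
    """Simulator ground truth for parameter-recovery tests."""

    per_gene: pd.DataFrame  # gene, amplicon_len, e0, d_max
    per_sample: pd.DataFrame  # gene, sample_id, treatment, timepoint, t0


def simulate_curve(params: SimCurveParams, seed: int) -> AmplificationCurve:
    """Simulate one well; same params and seed give identical traces.

    Signal below ``detection_limit`` of the plateau is reported as pure
    baseline (the detector's resolution floor); once detectable, the full
    dye signal registers, so the sub-plateau trace is exactly exponential.
    """
    cycles = np.arange(1, params.n_cycles + 1)
    copies = np.minimum(params.t0 * (1.0 + params.e0) ** cycles, params.d_max)
    signal = params.alpha * params.amplicon_len * copies
    signal[signal < params.detection_limit * params.plateau_fluorescence] = 0.0
    fluor = params.baseline + signal
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        fluor = fluor + rng.normal(0.0, params.noise_sd, params.n_cycles)
    return AmplificationCurve(f"sim-{seed}", cycles, fluor)


# Default panel: Table-style primer amplicon lengths with simulator truth.
# e0 and t0_base are simulation conventions chosen so that (a) the 3%/6%
# thresholds sit in the pure exponential phase for every well, (b) every
# well saturates before cycle 40, and (c) 0-hour copy numbers span a
# 100-fold range (inter-gene ratios from 1e-2 to 1e2) with 0-hour
# composition echoing the tenocyte study (ECM:MMP ~2.7, MMP-14 ~58% of MMP
# transcripts, biglycan ~90% of proteoglycan transcripts).
DEFAULT_GENE_PANEL: tuple[GeneSimSpec, ...] = (
    GeneSimSpec("Bgn", 112, 0.97, 1700.0),
    GeneSimSpec("Col1a1", 103, 0.94, 700.0),
    GeneSimSpec("Col3a1", 154, 0.96, 1200.0),
    GeneSimSpec("Col5a1", 97, 0.98, 90.0),
    GeneSimSpec("Col12a1", 111, 0.97, 110.0),
    GeneSimSpec("Dcn", 81, 0.95, 180.0),
    GeneSimSpec("Eef1a1", 70, 0.95, 2500.0),
    GeneSimSpec("Fn1", 105, 0.95, 1500.0),
    GeneSimSpec("Lum", 147, 1.00, 30.0),
    GeneSimSpec("Mkx", 73, 1.00, 60.0),
    GeneSimSpec("Mmp2", 171, 0.93, 650.0),
    GeneSimSpec("Mmp3", 192, 0.95, 120.0),
    GeneSimSpec("Mmp14", 119, 0.96, 1180.0),
    GeneSimSpec("Mmp16", 101, 0.97, 82.0),
    GeneSimSpec("Scx", 237, 1.00, 25.0),
    GeneSimSpec("Serpine1", 116, 0.94, 400.0),
    GeneSimSpec("Timp2", 142, 0.92, 800.0),
)

# True fold changes vs 0 h per gene and dose: {gene: {dose: (f6h, f24h, f48h)}}.
# Magnitudes follow the qualitative dose/time structure reported for the
# tenocyte gels: ECM genes up at 10/100 ng/mL by 24-48 h, decorin's control
# rise suppressed by TGF-beta1, MMP-16 down dose-dependently, PAI-1 up early,
# Scx/Mkx up strongly, housekeeping flat.
_EFFECTS: dict[str, dict[float, tuple[float, float, float]]] = {
    "Fn1": {0: (1.0, 1.2, 1.3), 1: (1.1, 1.5, 1.6), 10: (1.3, 4, 5), 100: (1.5, 5, 7)},
    "Col1a1": {0: (1.0, 1.1, 1.2), 1: (1.1, 2.5, 2.5), 10: (1.2, 5, 6), 100: (1.3, 6, 10)},
    "Col3a1": {0: (1.0, 1.2, 1.3), 1: (1.2, 5, 5), 10: (1.3, 6, 8), 100: (1.4, 7, 10)},
    "Col5a1": {0: (1.0, 1.1, 1.2), 1: (1.1, 1.5, 2), 10: (1.2, 4, 6), 100: (1.3, 5, 8)},
    "Col12a1": {0: (1.0, 1.1, 1.2), 1: (1.1, 2, 3), 10: (1.2, 4, 6), 100: (1.3, 5, 9)},
    "Bgn": {0: (1.0, 1.3, 1.5), 1: (1.1, 1.8, 2), 10: (1.2, 3, 4.5), 100: (1.3, 3.5, 5)},
    "Dcn": {0: (1.5, 8, 14), 1: (1.5, 8, 14), 10: (1.2, 2.5, 3), 100: (1.1, 2, 2.5)},
    "Lum": {0: (1.0, 1.3, 1.5), 1: (1.2, 2, 2.5), 10: (1.2, 2, 2.5), 100: (1.0, 1.2, 1.3)},
    "Mmp2": {0: (1.2, 2, 3), 1: (1.2, 2, 3.5), 10: (1.3, 2.5, 4), 100: (1.3, 2.5, 4)},
    "Mmp3": {0: (1.5, 4, 6), 1: (2, 6, 15), 10: (1.8, 5, 12), 100: (1.8, 5, 12)},
    "Mmp14": {0: (1.2, 1.8, 2.5), 1: (1.2, 2, 3), 10: (1.3, 2.2, 3.5), 100: (1.3, 2.5, 4)},
    "Mmp16": {0: (1.2, 4, 5), 1: (1.2, 4, 4.5), 10: (1.0, 1.5, 1.5), 100: (0.9, 0.8, 0.8)},
    "Serpine1": {0: (1.0, 1.1, 1.1), 1: (2, 1.3, 1.2), 10: (2.2, 1.5, 1.3), 100: (2.5, 2.5, 2.5)},
    "Timp2": {0: (1.2, 1.5, 2), 1: (1.2, 1.5, 2), 10: (1.3, 1.6, 2), 100: (1.3, 1.6, 2)},
    "Scx": {0: (1.0, 1.1, 1.1), 1: (1.3, 1.5, 1.5), 10: (1.5, 4, 5), 100: (3, 5, 6)},
    "Mkx": {0: (1.0, 1.1, 1.2), 1: (1.5, 1.8, 2), 10: (2, 4, 6), 100: (2, 5, 8)},
    "Eef1a1": {0: (1, 1, 1), 1: (1, 1, 1), 10: (1, 1, 1), 100: (1, 1, 1)},
}

# Mean gel area ratios vs 0 h per dose at (6, 24, 48) h; 48-h values echo the
# reported contraction to 83% (control) and 57/49/47% (1/10/100 ng/mL).
DEFAULT_CONTRACTION: dict[float, tuple[float, float, float]] = {
    0.0: (0.97, 0.90, 0.83),
    1.0: (0.80, 0.65, 0.57),
    10.0: (0.75, 0.58, 0.49),
    100.0: (0.73, 0.56, 0.47),
}


def default_effect_table() -> dict[tuple[str, float, float], float]:
    table: dict[tuple[str, float, float], float] = {}
    for gene, per_dose in _EFFECTS.items():
        for dose, folds in per_dose.items():
            for tp, fold in zip((6.0, 24.0, 48.0), folds):
                table[(gene, float(dose), tp)] = float(fold)
    return table


def default_curve_params(**overrides) -> SimCurveParams:
    return replace(SimCurveParams(), **overrides) if overrides else SimCurveParams()


def default_study(
    n_biological: int = 6, n_wells: int = 3, bio_cv: float = 0.2
) -> StudyDesign:
    """The full 17-gene x 4-dose x 4-timepoint default design."""
    return StudyDesign(
        genes=DEFAULT_GENE_PANEL,
        effect_table=default_effect_table(),
        n_biological=n_biological,
        n_wells=n_wells,
        bio_cv=bio_cv,
    )


def noise_sd_for_fraction(curve_defaults: SimCurveParams, frac: float) -> float:
    """Additive noise SD equal to ``frac`` of the plateau fluorescence."""
    return frac * curve_defaults.plateau_fluorescence


def simulate_study(
    design: StudyDesign,
    curve_defaults: SimCurveParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate every well of a study.

    Returns ``(raw_plate, sample_sheet, truth)`` where ``raw_plate`` is a
    wide table (first column ``cycle``, one column per well),
    ``sample_sheet`` maps wells to (gene, treatment, timepoint, biological
    sample, technical replicate) and ``truth`` records all ground-truth
    parameters.  The shared dsDNA mass capacity is
    ``curve_defaults.d_max * curve_defaults.amplicon_len`` and each gene's
    copy capacity is that mass divided by its amplicon length.
    """
    if curve_defaults is None:
        curve_defaults = default_curve_params()
    mass_capacity = curve_defaults.d_max * curve_defaults.amplicon_len
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log(1.0 + design.bio_cv**2)))

    n_cycles = curve_defaults.n_cycles
    cycles = np.arange(1, n_cycles + 1, dtype=np.int64)

    sheet_rows = []
    gene_rows = []
    sample_rows = []
    t0s, e0s, amps, well_seeds = [], [], [], []

    for gene in design.genes:
        cap = mass_capacity / gene.amplicon_len
        gene_rows.append(
            dict(
                gene=gene.symbol,
                amplicon_len=gene.amplicon_len,
                e0=gene.e0,
                d_max=cap,
            )
        )

    well_idx = 0
    for gene in design.genes:
        cap = mass_capacity / gene.amplicon_len
        for dose in design.treatments:
            for tp in design.timepoints:
                for bio in range(1, design.n_biological + 1):
                    sample_id = f"d{dose:g}_t{tp:g}_b{bio}"
                    mult = 1.0
                    if design.bio_cv > 0:
                        mult = float(
                            np.exp(rng.normal(-0.5 * sigma**2, sigma))
                        )
                    t0 = gene.t0_base * design.effect(gene.symbol, dose, tp) * mult
                    sample_rows.append(
                        dict(
                            gene=gene.symbol,
                            sample_id=sample_id,
                            treatment_ng_per_ml=dose,
                            timepoint_h=tp,
                            biological_id=bio,
                            t0=t0,
                        )
                    )
                    for rep in range(1, design.n_wells + 1):
                        well_idx += 1
                        well = f"W{well_idx:05d}"
                        sheet_rows.append(
                            dict(
                                well=well,
                                gene=gene.symbol,
                                treatment_ng_per_ml=dose,
                                timepoint_h=tp,
                                biological_id=bio,
                                tech_rep=rep,
                                sample_id=sample_id,
                            )
                        )
                        t0s.append(t0)
                        e0s.append(gene.e0)
                        amps.append(gene.amplicon_len)
                        well_seeds.append(
                            int(rng.integers(0, 2**31))
                        )

    n_total = len(sheet_rows)
    t0_arr = np.asarray(t0s)
    e0_arr = np.asarray(e0s)
    amp_arr = np.asarray(amps, dtype=np.float64)
    # copies per well, saturating at the gene's copy capacity
    growth = t0_arr[None, :] * (1.0 + e0_arr[None, :]) ** cycles[:, None]
    copies = np.minimum(growth, (mass_capacity / amp_arr)[None, :])
    signal = curve_defaults.alpha * amp_arr[None, :] * copies
    plateau = curve_defaults.alpha * mass_capacity  # same level for all genes
    signal[signal < curve_defaults.detection_limit * plateau] = 0.0
    fluor = curve_defaults.baseline + signal
    if curve_defaults.noise_sd > 0:
        for j in range(n_total):
            wrng = np.random.default_rng(well_seeds[j])
            fluor[:, j] += wrng.normal(0.0, curve_defaults.noise_sd, n_cycles)

    sheet = pd.DataFrame(sheet_rows)
    plate = pd.DataFrame(fluor, columns=sheet["well"].tolist())
    plate.insert(0, "cycle", cycles)
    truth = TruthTable(
        per_gene=pd.DataFrame(gene_rows),
        per_sample=pd.DataFrame(sample_rows),
    )
    return plate, sheet, truth


def simulate_gel_areas(
    treatments: Sequence[float] = DOSES,
    timepoints: Sequence[float] = TIMEPOINTS,
    n_gels: int = 6,
    seed: int = 0,
    contraction: Mapping[float, tuple[float, float, float]] | None = None,
    area_0h: float = 120.0,
    area_cv: float = 0.08,
    noise_cv: float = 0.04,
) -> pd.DataFrame:
    """Tabulated gel areas (mm^2) for the contraction analysis.

    Each gel starts near ``area_0h`` and shrinks toward the dose-specific
    mean ratio trajectory with small log-normal measurement noise.
    """
    if contraction is None:
        contraction = DEFAULT_CONTRACTION
    rng = np.random.default_rng(seed)
    rows = []
    for dose in treatments:
        traj = dict(zip((6.0, 24.0, 48.0), contraction[dose]))
        traj[0.0] = 1.0
        for gel in range(1, n_gels + 1):
            gel_id = f"gel_d{dose:g}_{gel}"
            a0 = area_0h * float(rng.lognormal(0.0, np.sqrt(np.log(1 + area_cv**2))))
            for tp in timepoints:
                ratio = traj.get(float(tp), 1.0)
                noise = float(
                    rng.lognormal(0.0, np.sqrt(np.log(1 + noise_cv**2)))
                ) if tp > 0 else 1.0
                rows.append(
                    dict(
                        gel_id=gel_id,
                        treatment_ng_per_ml=dose,
                        timepoint_h=tp,
                        area=a0 * ratio * noise,
                    )
                )
    return pd.DataFrame(rows)
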