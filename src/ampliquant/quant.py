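"""Efficiency-corrected expression ratios and inter-gene transcript comparison.

Single-gene quantification uses the efficiency-corrected (Pfaffl) ratio

    ratio = (1 + E_tar) ** (Ct_ctl,tar - Ct_sample,tar)
          / (1 + E_ref) ** (Ct_ctl,ref - Ct_sample,ref)

with the housekeeping gene as reference and the pre-treatment (0-hour)
group as control.

Inter-gene comparison exploits that all genes share the same relative
fluorescence threshold, hence the same absolute amount of dsDNA *mass* at
their crossing.  With SYBR-type fluorescence proportional to
amplicon_length x copies, equating the threshold fluorescence of two genes
and solving for the ratio of starting transcripts gives

    T0_x / T0_y = (Amp_y * (1 + E_y) ** Ct_y) / (Amp_x * (1 + E_x) ** Ct_x)

which reduces to the familiar (1 + E) ** (Ct_y - Ct_x) when amplicon sizes
and efficiencies match.  From these pairwise ratios the module derives
within-sample composition shares for gene panels and the summed ECM/MMP
expression balance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleMeasurement",
    "PfafflInput",
    "InterGeneInput",
    "GeneSet",
    "COLLAGENS",
    "PROTEOGLYCANS",
    "ECM",
    "MMPS",
    "DEFAULT_GENE_SETS",
    "aggregate_replicates",
    "pfaffl_ratio",
    "normalize_expression",
    "intergene_ratio",
    "relative_transcripts",
    "sample_abundance_table",
    "relative_abundance",
    "ecm_mmp_ratio",
    "group_shares",
    "group_ratio",
    "timecourse_normalize",
]


@dataclass(frozen=True)
class SampleMeasurement:
    """Mean Ct (6% threshold) of one gene in one biological sample."""

    gene: str
    sample_id: str
    ct: float
    n_wells: int = 1

    def __post_init__(self) -> None:
        if not self.ct > 0 and not math.isnan(self.ct):
            raise ValueError(f"ct must be positive, got {self.ct}")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")


@dataclass(frozen=True)
class PfafflInput:
    e_tar: float
    e_ref: float
    ct_ctl_tar: float
    ct_sample_tar: float
    ct_ctl_ref: float
    ct_sample_ref: float

    def __post_init__(self) -> None:
        for name in ("e_tar", "e_ref"):
            e = getattr(self, name)
            if not (0.0 < e <= 1.1):
                raise ValueError(f"{name} must be in (0, 1.1], got {e}")


@dataclass(frozen=True)
class InterGeneInput:
    """One gene's amplicon length, efficiency, and Ct within one sample."""

    gene: str
    amp: int
    e: float
    ct: float

    def __post_init__(self) -> None:
        if self.amp <= 0:
            raise ValueError(f"amplicon length must be positive, got {self.amp}")
        if not (0.0 < self.e <= 1.1):
            raise ValueError(f"efficiency must be in (0, 1.1], got {self.e}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


COLLAGENS = GeneSet("collagens", ("Col1a1", "Col3a1", "Col5a1", "Col12a1"))
PROTEOGLYCANS = GeneSet("proteoglycans", ("Bgn", "Dcn", "Lum"))
ECM = GeneSet("ecm", COLLAGENS.members + ("Fn1",) + PROTEOGLYCANS.members)
MMPS = GeneSet("mmp", ("Mmp2", "Mmp3", "Mmp14", "Mmp16"))
DEFAULT_GENE_SETS: dict[str, GeneSet] = {
    s.name: s for s in (COLLAGENS, PROTEOGLYCANS, ECM, MMPS)
}


def aggregate_replicates(well_table: pd.DataFrame) -> pd.DataFrame:
    """Mean 6%-threshold Ct per (gene, sample) over technical wells.

    ``well_table`` needs columns ``gene``, ``sample_id``, ``ct_b`` and
    ``censored``; censored wells are dropped before averaging and a sample
    with no usable well gets a missing Ct.  Sample metadata columns
    (treatment, timepoint, biological id) are carried through.
    """
    meta_cols = [
        c
        for c in ("treatment_ng_per_ml", "timepoint_h", "biological_id")
        if c in well_table.columns
    ]
    usable = well_table[~well_table["censored"]]
    agg = (
        usable.groupby(["gene", "sample_id"] + meta_cols, as_index=False)
        .agg(ct=("ct_b", "mean"), n_wells=("ct_b", "count"))
    )
    # keep a row (with missing ct) for fully-censored (gene, sample) pairs
    all_pairs = well_table[["gene", "sample_id"] + meta_cols].drop_duplicates()
    out = all_pairs.merge(agg, on=["gene", "sample_id"] + meta_cols, how="left")
    out["n_wells"] = out["n_wells"].fillna(0).astype(int)
    return out


def pfaffl_ratio(inp: PfafflInput) -> float:
    """Efficiency-corrected expression ratio of a sample vs the control group."""
    cts = (inp.ct_ctl_tar, inp.ct_sample_tar, inp.ct_ctl_ref, inp.ct_sample_ref)
    if any(math.isnan(c) for c in cts):
        return float("nan")
    num = (1.0 + inp.e_tar) ** (inp.ct_ctl_tar - inp.ct_sample_tar)
    den = (1.0 + inp.e_ref) ** (inp.ct_ctl_ref - inp.ct_sample_ref)
    return num / den


def _efficiency_lookup(
    efficiencies: Mapping[str, float] | pd.Series | pd.DataFrame,
) -> pd.Series:
    if isinstance(efficiencies, pd.DataFrame):
        return efficiencies.set_index("gene")["efficiency"]
    return pd.Series(dict(efficiencies))


def normalize_expression(
    measurements: pd.DataFrame,
    efficiencies: Mapping[str, float] | pd.Series | pd.DataFrame,
    housekeeping: str = "Eef1a1",
    control_samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pfaffl ratio for every (gene, sample) against the control-group mean.

    ``measurements`` holds one row per (gene, sample) with a ``ct`` column
    (see :func:`aggregate_replicates`); ``control_samples`` lists the
    sample_ids of the control group (typically the 0-hour samples).
    Samples lacking a housekeeping Ct are excluded (flagged in the
    ``excluded_samples`` attribute of the result).  Censored target Cts
    propagate as missing ratios.
    """
    eff = _efficiency_lookup(efficiencies)
    if housekeeping not in set(measurements["gene"]):
        raise ValueError(f"housekeeping gene {housekeeping!r} not measured")
    if control_samples is None or len(control_samples) == 0:
        raise ValueError("control group is empty")
    control_samples = list(control_samples)

    ct = measurements.pivot_table(
        index="sample_id", columns="gene", values="ct", aggfunc="mean",
        dropna=False,
    )
    missing_ctl = sorted(set(control_samples) - set(ct.index))
    if missing_ctl:
        raise ValueError(f"control samples not measured: {missing_ctl}")

    hk_ct = ct[housekeeping]
    excluded = hk_ct[hk_ct.isna()].index.tolist()
    ct = ct.drop(index=excluded)
    ctl_mean = ct.loc[[s for s in control_samples if s in ct.index]].mean()

    rows = []
    for sample_id, row in ct.iterrows():
        den = (1.0 + eff[housekeeping]) ** (
            ctl_mean[housekeeping] - row[housekeeping]
        )
        for gene in ct.columns:
            num = (1.0 + eff[gene]) ** (ctl_mean[gene] - row[gene])
            rows.append(
                dict(gene=gene, sample_id=sample_id, ratio=num / den)
            )
    out = pd.DataFrame(rows)
    meta_cols = [
        c
        for c in ("treatment_ng_per_ml", "timepoint_h", "biological_id")
        if c in measurements.columns
    ]
    if meta_cols:
        meta = measurements[["sample_id"] + meta_cols].drop_duplicates()
        out = out.merge(meta, on="sample_id", how="left")
    out.attrs["excluded_samples"] = excluded
    return out


def relative_transcripts(x: InterGeneInput) -> float:
    """Starting transcripts on an arbitrary common within-sample scale.

    Proportional to T0 with the same constant for every gene measured at the
    common fluorescence threshold: 1 / (Amp * (1 + E) ** Ct).
    """
    if math.isnan(x.ct):
        return float("nan")
    return 1.0 / (x.amp * (1.0 + x.e) ** x.ct)


def intergene_ratio(x: InterGeneInput, y: InterGeneInput) -> float:
    """Ratio of starting transcript numbers T0_x / T0_y within one sample."""
    if math.isnan(x.ct) or math.isnan(y.ct):
        return float("nan")
    return (y.amp * (1.0 + y.e) ** y.ct) / (x.amp * (1.0 + x.e) ** x.ct)


def _panel_lookup(panel: Iterable[InterGeneInput]) -> dict[str, InterGeneInput]:
    return {p.gene: p for p in panel}


def relative_abundance(
    panel: Iterable[InterGeneInput],
    gene_set: GeneSet,
    anchor: str | None = None,
) -> pd.Series:
    """Within-sample composition shares of a gene set (sum to 1).

    Every member's transcripts are expressed relative to a fixed anchor gene
    via :func:`intergene_ratio` and normalized to the set total; the result
    is anchor-invariant.
    """
    lookup = _panel_lookup(panel)
    missing = [g for g in gene_set.members if g not in lookup]
    if missing:
        raise ValueError(
            f"gene set {gene_set.name!r}: panel lacks {', '.join(missing)}"
        )
    if anchor is None:
        anchor = gene_set.members[0]
    if anchor not in lookup:
        raise ValueError(f"anchor gene {anchor!r} not in panel")
    ref = lookup[anchor]
    rel = pd.Series(
        {g: intergene_ratio(lookup[g], ref) for g in gene_set.members},
        name="share",
    )
    return rel / rel.sum()


def ecm_mmp_ratio(
    panel: Iterable[InterGeneInput],
    ecm: GeneSet = ECM,
    mmp: GeneSet = MMPS,
) -> float:
    """Summed ECM transcripts over summed MMP transcripts within a sample."""
    lookup = _panel_lookup(panel)
    for gs in (ecm, mmp):
        missing = [g for g in gs.members if g not in lookup]
        if missing:
            raise ValueError(
                f"gene set {gs.name!r}: panel lacks {', '.join(missing)}"
            )
    anchor = lookup[mmp.members[0]]
    num = sum(intergene_ratio(lookup[g], anchor) for g in ecm.members)
    den = sum(intergene_ratio(lookup[g], anchor) for g in mmp.members)
    if den == 0:
        raise ValueError("MMP transcript sum is zero")
    return num / den


def sample_abundance_table(
    measurements: pd.DataFrame,
    efficiencies: Mapping[str, float] | pd.Series | pd.DataFrame,
    amplicons: Mapping[str, int] | pd.Series,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-(sample, gene) relative starting transcripts.

    Values share one arbitrary scale across all genes and samples (they are
    1 / (Amp (1+E)^Ct)), so any two rows can be divided to give an
    inter-gene or inter-sample transcript ratio.
    """
    eff = _efficiency_lookup(efficiencies)
    amp = pd.Series(dict(amplicons))
    tab = measurements if genes is None else measurements[
        measurements["gene"].isin(genes)
    ]
    out = tab.copy()
    e = out["gene"].map(eff).astype(float)
    a = out["gene"].map(amp).astype(float)
    out["rel_t0"] = 1.0 / (a * (1.0 + e) ** out["ct"])
    return out


def group_shares(
    abundance: pd.DataFrame,
    gene_set: GeneSet,
    by: Sequence[str] = ("treatment_ng_per_ml", "timepoint_h"),
) -> pd.DataFrame:
    """Group-mean composition shares: per-sample shares averaged per group."""
    tab = abundance[abundance["gene"].isin(gene_set.members)].copy()
    totals = tab.groupby("sample_id")["rel_t0"].transform("sum")
    tab["share"] = tab["rel_t0"] / totals
    return (
        tab.groupby(list(by) + ["gene"], as_index=False)
        .agg(share=("share", "mean"), n=("share", "count"))
    )


def group_ratio(
    abundance: pd.DataFrame,
    gene_x: str,
    gene_y: str,
    by: Sequence[str] = ("treatment_ng_per_ml", "timepoint_h"),
) -> pd.DataFrame:
    """Group-level T0_x / T0_y: geometric mean of per-sample ratios.

    Ratios of log-normal quantities are summarized geometrically; the
    arithmetic mean would be biased upward by the replicate dispersion.
    """
    wide = abundance.pivot_table(
        index=["sample_id"] + list(by), columns="gene", values="rel_t0"
    ).reset_index()
    wide["pair_ratio"] = wide[gene_x] / wide[gene_y]
    grp = wide.groupby(list(by))["pair_ratio"]
    out = grp.apply(
        lambda s: float(np.exp(np.log(s.dropna()).mean()))
    ).reset_index(name="ratio")
    out["n"] = grp.count().values
    return out


def timecourse_normalize(
    group_values: pd.DataFrame,
    value: str = "share",
    reference_timepoint: float = 0.0,
    by: Sequence[str] = ("gene", "treatment_ng_per_ml"),
    timepoint: str = "timepoint_h",
) -> pd.DataFrame:
    """Divide each group-level value by its value at the reference timepoint."""
    tab = group_values.copy()
    ref = tab[tab[timepoint] == reference_timepoint]
    if ref.empty:
        raise ValueError(
            f"reference timepoint {reference_timepoint} not present"
        )
    ref = ref.set_index(list(by))[value]
    key = pd.MultiIndex.from_frame(tab[list(by)])
    ref_vals = ref.reindex(key).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(ref_vals > 0, tab[value] / ref_vals, np.nan)
    tab[value + "_vs_0h"] = normalized
    return tab
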