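"""Tabular readers/writers, the packaged primer table, configuration,
and the end-to-end pipeline driver.

File dialects are deliberately plain: UTF-8, '.' decimal, header row;
fluorescence plates are wide CSV (first column ``cycle``, one column per
well), everything else is TSV.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import AmplificationCurve, ThresholdPair, process_plate, summarize_gene_efficiency
from .quant import (
    DEFAULT_GENE_SETS,
    GeneSet,
    aggregate_replicates,
    group_ratio,
    group_shares,
    normalize_expression,
    sample_abundance_table,
    timecourse_normalize,
)
from .study import area_ratio_table, summarize_groups, two_way_anova

logger = logging.getLogger("ampliquant")

__all__ = [
    "PrimerRecord",
    "PipelineConfig",
    "read_fluorescence_csv",
    "write_fluorescence_csv",
    "curves_from_plate",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_primer_table",
    "read_areas",
    "run_pipeline",
]

_VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class PrimerRecord:
    """One primer pair and the length of the fragment it amplifies."""

    gene: str
    forward: str
    reverse: str
    amplicon_len: int

    def __post_init__(self) -> None:
        for name in ("forward", "reverse"):
            seq = getattr(self, name)
            bad = set(seq) - _VALID_BASES
            if bad or not seq:
                raise ValueError(
                    f"{self.gene}: {name} primer contains invalid "
                    f"characters {sorted(bad)}" if bad
                    else f"{self.gene}: empty {name} primer"
                )
        if self.amplicon_len <= 0:
            raise ValueError(
                f"{self.gene}: amplicon length must be positive, "
                f"got {self.amplicon_len}"
            )
        if self.amplicon_len < max(len(self.forward), len(self.reverse)):
            raise ValueError(
                f"{self.gene}: amplicon ({self.amplicon_len} bp) shorter "
                f"than a primer"
            )


def read_primer_table(path: str | Path | None = None) -> list[PrimerRecord]:
    """Read a primer TSV; with no path, load the packaged 17-gene panel."""
    if path is None:
        source = resources.files("ampliquant.data").joinpath("primers.tsv")
        with resources.as_file(source) as p:
            tab = pd.read_csv(p, sep="\t")
    else:
        tab = pd.read_csv(path, sep="\t")
    required = {"gene", "forward", "reverse", "amplicon_len"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"primer table lacks columns: {sorted(missing)}")
    return [
        PrimerRecord(
            gene=str(r.gene),
            forward=str(r.forward),
            reverse=str(r.reverse),
            amplicon_len=int(r.amplicon_len),
        )
        for r in tab.itertuples()
    ]


def primer_amplicons(records: Sequence[PrimerRecord]) -> dict[str, int]:
    return {r.gene: r.amplicon_len for r in records}


def read_fluorescence_csv(path: str | Path) -> list[AmplificationCurve]:
    """Read a wide plate CSV into per-well curves, validating the layout."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    if not header or header[0].strip().lower() != "cycle":
        raise ValueError(f"{path}: first column must be 'cycle'")
    wells = [w.strip() for w in header[1:]]
    dupes = sorted({w for w in wells if wells.count(w) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate well columns: {', '.join(dupes)}")

    tab = pd.read_csv(path, float_precision="round_trip")
    tab.columns = ["cycle"] + wells
    cycles = tab["cycle"].to_numpy()
    expected = np.arange(cycles.min(), cycles.min() + len(cycles))
    if not np.array_equal(cycles, expected):
        missing = sorted(set(range(int(cycles.min()), int(cycles.max()) + 1))
                         - set(cycles.tolist()))
        raise ValueError(
            f"{path}: cycle column must be gap-free"
            + (f"; missing cycle(s) {missing}" if missing else "")
        )
    for well in wells:
        col = pd.to_numeric(tab[well], errors="coerce")
        bad = tab.index[col.isna() & tab[well].notna()]
        if len(bad) or col.isna().any():
            row = int((bad[0] if len(bad) else col.index[col.isna()][0]))
            raise ValueError(
                f"{path}: non-numeric or missing value in column "
                f"{well!r}, row {row + 2}"
            )
        tab[well] = col
    return [
        AmplificationCurve(well, cycles, tab[well].to_numpy())
        for well in wells
    ]


def curves_from_plate(plate: pd.DataFrame) -> list[AmplificationCurve]:
    """Split a wide plate table (first column ``cycle``) into per-well curves."""
    cycles = plate["cycle"].to_numpy()
    return [
        AmplificationCurve(str(w), cycles, plate[w].to_numpy())
        for w in plate.columns
        if w != "cycle"
    ]


def write_fluorescence_csv(plate: pd.DataFrame, path: str | Path) -> None:
    """Write a wide plate table (column 1 = cycle) at full float precision."""
    plate.to_csv(path, index=False, float_format="%.17g")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {
        "well", "gene", "treatment_ng_per_ml", "timepoint_h",
        "biological_id", "tech_rep",
    }
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet lacks columns {sorted(missing)}")
    if sheet["well"].duplicated().any():
        dupes = sheet.loc[sheet["well"].duplicated(), "well"].tolist()
        raise ValueError(f"{path}: duplicate wells {dupes}")
    if "sample_id" not in sheet.columns:
        sheet["sample_id"] = (
            "d" + sheet["treatment_ng_per_ml"].astype(str)
            + "_t" + sheet["timepoint_h"].astype(str)
            + "_b" + sheet["biological_id"].astype(str)
        )
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_areas(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    required = {"gel_id", "treatment_ng_per_ml", "timepoint_h", "area"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: areas table lacks columns {sorted(missing)}")
    if (tab["area"] <= 0).any():
        raise ValueError(f"{path}: areas must be positive")
    return tab


@dataclass
class PipelineConfig:
    """Settings of the quantification pipeline (defaults follow the study:
    3%/6% thresholds, Eef1a1 reference, 0-hour control group, alpha 0.05)."""

    frac_a: float = 0.03
    frac_b: float = 0.06
    baseline_cycles: tuple[int, int] = (1, 5)
    housekeeping: str = "Eef1a1"
    control_timepoint_h: float = 0.0
    alpha: float = 0.05
    log_transform: bool = False
    per_sample_efficiency: bool = False
    gene_sets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            name: gs.members for name, gs in DEFAULT_GENE_SETS.items()
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        ThresholdPair(self.frac_a, self.frac_b)  # validates ordering
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        self.baseline_cycles = tuple(self.baseline_cycles)  # type: ignore[assignment]
        self.gene_sets = {k: tuple(v) for k, v in self.gene_sets.items()}

    @property
    def thresholds(self) -> ThresholdPair:
        return ThresholdPair(self.frac_a, self.frac_b)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["baseline_cycles"] = list(self.baseline_cycles)
        d["gene_sets"] = {k: list(v) for k, v in self.gene_sets.items()}
        return d


def _write_tsv(tab: pd.DataFrame, path: Path) -> None:
    tab.to_csv(path, sep="\t", index=False, float_format="%.17g")


def run_pipeline(
    config: PipelineConfig,
    plate_csv: str | Path,
    sample_sheet: str | Path,
    outdir: str | Path,
    areas_tsv: str | Path | None = None,
    primer_table: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Execute curves -> quantification -> statistics and write all outputs.

    Returns the result tables keyed by output name; writes each as TSV under
    ``outdir`` together with a ``manifest.json`` recording the config hash,
    software version and per-stage counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    primers = read_primer_table(primer_table)
    amplicons = primer_amplicons(primers)
    if config.housekeeping not in amplicons:
        raise ValueError(
            f"housekeeping gene {config.housekeeping!r} not in primer table"
        )

    curves = read_fluorescence_csv(plate_csv)
    sheet = read_sample_sheet(sample_sheet)
    unknown_genes = sorted(set(sheet["gene"]) - set(amplicons))
    if unknown_genes:
        raise ValueError(
            f"sample sheet genes missing from primer table: {unknown_genes}"
        )
    logger.info("curves stage: %d wells read", len(curves))

    well_table = process_plate(curves, config.thresholds, config.baseline_cycles)
    well_table = well_table.rename(columns={"well_id": "well"}).merge(
        sheet, on="well", how="left"
    )
    n_censored = int(well_table["censored"].sum())
    logger.info(
        "curves stage: %d censored wells, %d flagged",
        n_censored, int(well_table["flagged"].sum()),
    )

    gene_eff = summarize_gene_efficiency(well_table)
    eff_map = gene_eff.set_index("gene")["efficiency"]

    measurements = aggregate_replicates(well_table)
    control_samples = (
        sheet.loc[sheet["timepoint_h"] == config.control_timepoint_h, "sample_id"]
        .unique()
        .tolist()
    )
    if config.per_sample_efficiency:
        eff_for_ratio = (
            well_table[~well_table["censored"] & ~well_table["flagged"]]
            .groupby("gene")["efficiency"].mean().rename("efficiency")
            .reset_index()
        )
    else:
        eff_for_ratio = eff_map
    ratios = normalize_expression(
        measurements, eff_for_ratio,
        housekeeping=config.housekeeping,
        control_samples=control_samples,
    )
    logger.info(
        "quant stage: %d samples excluded (missing housekeeping)",
        len(ratios.attrs.get("excluded_samples", [])),
    )

    group_summary = (
        ratios.groupby(["gene"], group_keys=False)[ratios.columns]
        .apply(
            lambda g: summarize_groups(g, "ratio").assign(gene=g.name)
        )
        .reset_index(drop=True)
    )

    anova_rows, posthoc_rows = [], []
    for gene, sub in ratios.groupby("gene"):
        if gene == config.housekeeping:
            continue
        res = two_way_anova(
            sub, "ratio", alpha=config.alpha, log_transform=config.log_transform
        )
        anova_rows.append(res.anova.assign(gene=gene))
        posthoc_rows.append(res.posthoc.assign(gene=gene))
    anova_table = pd.concat(anova_rows, ignore_index=True)
    posthoc_table = pd.concat(posthoc_rows, ignore_index=True)

    abundance = sample_abundance_table(measurements, eff_map, amplicons)
    measured_genes = set(measurements["gene"])
    share_tables = []
    skipped_sets = []
    for name, members in config.gene_sets.items():
        if not set(members) <= measured_genes:
            skipped_sets.append(name)
            logger.warning(
                "gene set %r skipped: members not fully measured", name
            )
            continue
        gs = GeneSet(name, tuple(members))
        shares = group_shares(abundance, gs).assign(gene_set=name)
        share_tables.append(shares)
    shares_table = (
        pd.concat(share_tables, ignore_index=True)
        if share_tables
        else pd.DataFrame()
    )

    results: dict[str, pd.DataFrame] = {
        "well_table": well_table,
        "gene_efficiency": gene_eff,
        "sample_ratios": ratios,
        "group_summary": group_summary,
        "anova": anova_table,
        "posthoc": posthoc_table,
        "gene_set_shares": shares_table,
    }

    if (
        "ecm" in config.gene_sets
        and "mmp" in config.gene_sets
        and "ecm" not in skipped_sets
        and "mmp" not in skipped_sets
    ):
        ecm = GeneSet("ecm", config.gene_sets["ecm"])
        mmp = GeneSet("mmp", config.gene_sets["mmp"])
        wide = abundance.pivot_table(
            index=["sample_id", "treatment_ng_per_ml", "timepoint_h"],
            columns="gene", values="rel_t0",
        ).reset_index()
        wide["ecm_mmp_ratio"] = (
            wide[list(ecm.members)].sum(axis=1)
            / wide[list(mmp.members)].sum(axis=1)
        )
        results["ecm_mmp_ratio"] = summarize_groups(wide, "ecm_mmp_ratio")

    if areas_tsv is not None:
        areas = read_areas(areas_tsv)
        aratios = area_ratio_table(areas)
        results["area_ratios"] = aratios
        results["area_summary"] = summarize_groups(aratios, "area_ratio")
        post0 = aratios[aratios["timepoint_h"] > 0]
        if post0["timepoint_h"].nunique() >= 2:
            ares = two_way_anova(post0, "area_ratio", alpha=config.alpha)
            results["area_anova"] = ares.anova
            results["area_posthoc"] = ares.posthoc
        else:
            logger.warning(
                "area ANOVA skipped: fewer than two post-treatment timepoints"
            )

    for name, tab in results.items():
        _write_tsv(tab, outdir / f"{name}.tsv")

    config_json = json.dumps(config.as_dict(), sort_keys=True)
    manifest = dict(
        software="ampliquant",
        version=__version__,
        config=config.as_dict(),
        config_sha256=hashlib.sha256(config_json.encode()).hexdigest(),
        n_wells=len(curves),
        n_censored_wells=n_censored,
        n_excluded_samples=len(ratios.attrs.get("excluded_samples", [])),
        skipped_gene_sets=sorted(skipped_sets),
        outputs=sorted(results),
    )
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
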