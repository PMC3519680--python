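import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ampliquant import curves, simdata
from ampliquant.io import curves_from_plate, read_primer_table

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def primer_records():
    return read_primer_table()


def make_mini_design(bio_cv: float = 0.0) -> simdata.StudyDesign:
    """A 4-gene, 2-dose, 2-timepoint design for fast end-to-end tests."""
    genes = (
        simdata.GeneSimSpec("Eef1a1", 70, 0.95, 2500.0),
        simdata.GeneSimSpec("Bgn", 112, 0.97, 1700.0),
        simdata.GeneSimSpec("Dcn", 81, 0.95, 180.0),
        simdata.GeneSimSpec("Scx", 237, 1.00, 25.0),
    )
    effects = {
        ("Bgn", 0.0, 48.0): 1.5,
        ("Bgn", 100.0, 48.0): 5.0,
        ("Dcn", 0.0, 48.0): 14.0,
        ("Dcn", 100.0, 48.0): 2.5,
        ("Scx", 0.0, 48.0): 1.1,
        ("Scx", 100.0, 48.0): 6.0,
    }
    return simdata.StudyDesign(
        genes=genes,
        treatments=(0.0, 100.0),
        timepoints=(0.0, 48.0),
        n_biological=2,
        n_wells=2,
        effect_table=effects,
        bio_cv=bio_cv,
    )


def make_small_full_design() -> simdata.StudyDesign:
    """All 17 genes but only 2 doses, 2 timepoints, duplicate samples/wells."""
    return simdata.StudyDesign(
        genes=simdata.DEFAULT_GENE_PANEL,
        treatments=(0.0, 100.0),
        timepoints=(0.0, 48.0),
        n_biological=2,
        n_wells=2,
        effect_table=simdata.default_effect_table(),
        bio_cv=0.0,
    )


@pytest.fixture(scope="session")
def mini_study():
    design = make_mini_design()
    plate, sheet, truth = simdata.simulate_study(
        design, simdata.default_curve_params(), seed=11
    )
    return design, plate, sheet, truth


@pytest.fixture(scope="session")
def mini_well_table(mini_study):
    _, plate, sheet, _ = mini_study
    tab = curves.process_plate(curves_from_plate(plate))
    return tab.rename(columns={"well_id": "well"}).merge(sheet, on="well")


def pure_exponential_curve(
    factor: float,
    t0: float = 100.0,
    alpha: float = 1e-6,
    baseline: float = 50.0,
    n_cycles: int = 40,
    well_id: str = "exp",
) -> curves.AmplificationCurve:
    """A noiseless curve with exact per-cycle growth ``factor`` (no plateau).

    As in real traces (and the simulator), signal far below the final level
    (<1e-6 of it) is not resolved by the detector and reads as baseline, so
    the baseline window carries no signal.
    """
    c = np.arange(1, n_cycles + 1)
    signal = alpha * t0 * factor**c
    signal[signal < 1e-6 * signal[-1]] = 0.0
    return curves.AmplificationCurve(well_id, c, baseline + signal)
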