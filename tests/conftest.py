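import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import synscreen as ss
from synscreen.synthetic_data import PlantedEffect, ScreenSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_plate_df(wells, plate_id="P1", cell_line="CL1", dose="high"):
    """Build a plate-record DataFrame from (row, col, drug1, drug2, is_control, count)."""
    return pd.DataFrame(
        [
            {
                "plate_id": plate_id,
                "row": r,
                "col": c,
                "cell_line": cell_line,
                "dose_level": dose,
                "drug1": d1,
                "drug2": d2,
                "is_control": ctrl,
                "count": cnt,
            }
            for (r, c, d1, d2, ctrl, cnt) in wells
        ]
    )


@pytest.fixture
def tiny_plate() -> ss.PlateTable:
    """2x2 plate: two DMSO wells, one singlet, one pair."""
    df = make_plate_df(
        [
            (1, 1, None, None, True, 1000.0),
            (1, 2, None, None, True, 1000.0),
            (2, 1, "erlotinib", "dasatinib", False, 250.0),
            (2, 2, "erlotinib", None, False, 500.0),
        ]
    )
    return ss.PlateTable(records=df, plate_shape=(2, 2))


@pytest.fixture(scope="session")
def noiseless_screen():
    """12-drug, 2-cell-line, 2-dose screen with zero noise and no artifacts."""
    spec = ScreenSpec(
        n_drugs=12,
        n_cell_lines=2,
        noise_sd_w=0.0,
        cross_dose_jitter_sd=0.0,
        singlet_well_noise_multiplier=1.0,
        row_col_artifact_sd=0.0,
        seed=7,
    )
    plates, truth = ss.generate_screen(spec)
    return spec, plates, truth


@pytest.fixture(scope="session")
def small_noisy_screen():
    """20-drug screen, one cell line, both doses, one planted synergy."""
    spec = ScreenSpec(
        n_drugs=20,
        n_cell_lines=1,
        noise_sd_w=0.05,
        row_col_artifact_sd=0.0,
        planted_synergies=(PlantedEffect("D01", "D02", 0.25),),
        seed=11,
    )
    plates, truth = ss.generate_screen(spec)
    assays = ss.compute_viabilities(plates, polish=False)
    return spec, truth, assays
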