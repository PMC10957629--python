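import numpy as np
import pandas as pd
import pytest

from prandial.dataio import StudyTable
from prandial.synthdata import simulate_study, supro_like_design
from prandial.woodcurve import FitSettings, fit_all


@pytest.fixture(scope="session")
def sim_study():
    """One default synthetic crossover study plus its ground truth."""
    return simulate_study(supro_like_design(seed=20240917))


@pytest.fixture(scope="session")
def sim_fits(sim_study):
    """Wood fits of the shared synthetic study (reduced starts for speed)."""
    table, _ = sim_study
    return fit_all(table, FitSettings(n_starts=40, n_refine=3, seed=20240917))


@pytest.fixture()
def tiny_table():
    """2 participants x 1 period x 3 times x 2 analytes, fully observed."""
    rows = []
    for pid in ("P1", "P2"):
        for t in (0.0, 30.0, 60.0):
            for analyte, val in (("Leu", 100.0 + t), ("Lys", 200.0 + t)):
                rows.append((pid, 1, "REF", t, analyte, val))
    df = pd.DataFrame(rows, columns=["participant", "period", "intervention",
                                     "time", "analyte", "value"])
    return StudyTable(df, reference_intervention="REF")


@pytest.fixture()
def wide_csv(tmp_path, tiny_table):
    from prandial.dataio import write_study
    path = tmp_path / "study_wide.csv"
    write_study(tiny_table, path, format="wide")
    return path
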