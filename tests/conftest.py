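import pandas as pd
import pytest

from pmforge import compute_emissions, default_config, generate_scenario


@pytest.fixture(scope="session")
def default_tables():
    return generate_scenario(default_config(), seed=0)


@pytest.fixture(scope="session")
def default_emissions(default_tables):
    return compute_emissions(*default_tables)


def single_cell_tables(
    amount=1.0,
    share=1.0,
    ef_tsp=10.0,
    f=(0.3, 0.2, 0.5),
    bc_frac=0.0,
    oc_frac=0.0,
    controls=(),
    year=2000,
):
    """One (year, source, technology) cell with optional control records.

    ``controls`` is a sequence of (control_type, penetration, eta_fine,
    eta_mid, eta_coarse) tuples.
    """
    activities = pd.DataFrame(
        [(year, "sec", "src", "fuel", amount)],
        columns=["year", "sector", "source", "fuel_or_process", "amount"],
    )
    splits = pd.DataFrame(
        [(year, "src", "tech", share)], columns=["year", "source", "technology", "share"]
    )
    efs = pd.DataFrame(
        [("src", "tech", ef_tsp, *f, bc_frac, oc_frac, 0.0)],
        columns=["source", "technology", "ef_tsp", "f_fine", "f_mid", "f_coarse",
                 "bc_frac", "oc_frac", "cv"],
    )
    ctrl_rows = [(year, "src", "tech", c[0], c[1], c[2], c[3], c[4]) for c in controls]
    controls_df = pd.DataFrame(
        ctrl_rows,
        columns=["year", "source", "technology", "control_type", "penetration",
                 "eta_fine", "eta_mid", "eta_coarse"],
    )
    return activities, splits, efs, controls_df
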