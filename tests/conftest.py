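import numpy as np
import pandas as pd
import pytest

from ciequity import (
    PanelTable,
    SyntheticPanelConfig,
    VariableRoles,
    generate_panel,
)


@pytest.fixture
def toy_roles():
    return VariableRoles(
        outcomes=["BPK"], need=["MMR"], non_need=["PCGDP"], rank_var="PCGDP"
    )


@pytest.fixture
def toy_panel(toy_roles):
    """4 regions x 2 years, fully observed."""
    rows = []
    for year in (2009, 2010):
        for i, region in enumerate(["A", "B", "C", "D"]):
            rows.append(
                {
                    "region": region,
                    "year": year,
                    "BPK": 2.0 + i + 0.1 * (year - 2009),
                    "MMR": 30.0 - 2 * i,
                    "PCGDP": 10.0 * (i + 1),
                }
            )
    return PanelTable(data=pd.DataFrame(rows), roles=toy_roles)


@pytest.fixture(scope="session")
def synth_default():
    """One default synthetic panel shared across tests (seed fixed)."""
    return generate_panel(SyntheticPanelConfig(seed=11))


def make_single_determinant_panel():
    """4 regions, y = 2x exactly, x = (1,2,3,4) in rank order."""
    data = pd.DataFrame(
        {
            "region": ["A", "B", "C", "D"],
            "year": [2009] * 4,
            "x": [1.0, 2.0, 3.0, 4.0],
            "ses": [1.0, 2.0, 3.0, 4.0],
            "y": [2.0, 4.0, 6.0, 8.0],
        }
    )
    roles = VariableRoles(outcomes=["y"], need=[], non_need=["x"], rank_var="ses")
    return PanelTable(data=data, roles=roles)
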