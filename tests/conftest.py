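import pathlib
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(pathlib.Path(__file__).parent))

settings.register_profile("det", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("det")


@pytest.fixture
def balanced_toy():
    """One environment, 3 lines x 2 reps with known ANOVA solution."""
    vals = {"L1": (4.0, 6.0), "L2": (8.0, 10.0), "L3": (12.0, 14.0)}
    rows = []
    col = 1
    for line, (a, b) in vals.items():
        for rep, v in enumerate((a, b)):
            rows.append({"env": "E1", "line": line, "rep": rep + 1,
                         "row": 1, "col": col, "value": v})
            col += 1
    return pd.DataFrame(rows), ["L1", "L2", "L3"]


@pytest.fixture
def tiny_map():
    from metqtl import GeneticMap
    t = pd.DataFrame({
        "marker": ["m1", "m2", "m3", "m4", "m5", "n1", "n2"],
        "group": ["1B"] * 5 + ["2A"] * 2,
        "pos_cM": [0.0, 10.0, 20.0, 30.0, 40.0, 0.0, 25.0],
    })
    return GeneticMap(t)
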