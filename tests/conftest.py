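import numpy as np
import pandas as pd
import pytest

# Published validation cross-tabulations for three rosters (four cells
# each plus the printed statistics), used to reconstruct fixture
# rosters and to check every derivable statistic exactly.
REFERENCE_TABLES = {
    "abf2021": {
        "n": 2622,
        "cells": (2296, 10, 0, 316),
        "chi2": 2530.549,
        "sensitivity_pct": "100%",
        "specificity_pct": "96.9%",
        "sens_ci_pct": ("99.8%", "100%"),
        "spec_ci_pct": ("94.4%", "98.5%"),
        "gold_rate_pct": "87.6%",
        "hash_rate_pct": "87.9%",
    },
    "abf2022": {
        "n": 2513,
        "cells": (2344, 9, 0, 160),
        "chi2": 2370.071,
        "sensitivity_pct": "100%",
        "specificity_pct": "94.7%",
        "sens_ci_pct": ("99.8%", "100%"),
        "spec_ci_pct": ("90.1%", "97.5%"),
        "gold_rate_pct": "93.3%",
        "hash_rate_pct": "93.6%",
    },
    "rnbt": {
        "n": 26684,
        "cells": (6601, 142, 0, 19941),
        "chi2": 25937.365,
        "sensitivity_pct": "100%",
        "specificity_pct": "99.3%",
        "sens_ci_pct": ("99.9%", "100%"),
        "spec_ci_pct": ("99.2%", "99.4%"),
        "gold_rate_pct": "24.7%",
        "hash_rate_pct": "25.3%",
    },
}


@pytest.fixture(scope="session")
def reference_tables():
    return REFERENCE_TABLES


@pytest.fixture
def tiny_roster():
    """Five contacts, two persons sharing a number cross-gender."""
    return pd.DataFrame(
        {
            "gender": ["M", " female ", "m", "F", "M"],
            "service_number": ["AB123456", "cd 987654", "ab123456", "CD987654", "AB123456"],
            "name": ["a", "b", "c", "d", "e"],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
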