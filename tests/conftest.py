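import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from phosphokin import KinaseSubstrateMap


@pytest.fixture
def worked_fold_changes():
    """The six-site fold-change fixture with mu = 0 and s = sqrt(2.4)."""
    return pd.Series(
        {"P1_S1": 1.0, "P2_S2": -1.0, "P3_S3": 1.0, "P4_S4": -1.0, "P5_S5": 2.0, "P6_S6": -2.0}
    )


@pytest.fixture
def worked_ksmap():
    """One kinase whose substrates carry the fold changes {1, 2}."""
    return KinaseSubstrateMap({"KIN1": frozenset({"P1_S1", "P5_S5"})})


@pytest.fixture
def tiny_evidence():
    """Two site groups x two fragments x four samples, fully observed."""
    rows = []
    rng = np.random.default_rng(42)
    for site, protein in [("P1_S45", "P1"), ("P2_T10", "P2")]:
        for frag in ("f1", "f2"):
            for j, (sample, cond) in enumerate(
                [("s1", "A"), ("s2", "A"), ("s3", "B"), ("s4", "B")]
            ):
                rows.append(
                    {
                        "peptide": f"pep_{site}",
                        "protein": protein,
                        "phosphosites": site,
                        "fragment": f"{site}.{frag}",
                        "sample": sample,
                        "condition": cond,
                        "intensity": float(2.0 ** rng.normal(20, 1)),
                    }
                )
    return pd.DataFrame(rows)


def make_design(replicates: int, conditions=("A", "B")) -> pd.Series:
    return pd.Series(
        {f"{c}_{r + 1}": c for c in conditions for r in range(replicates)}, dtype=object
    )
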