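"""Shared fixtures: small deterministic libraries and graphs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from repomatch.dgem import Condition, DrugSignature, SignatureLibrary
from repomatch.signatures import DiseaseSignature, SignatureConfig

GENES20 = [f"g{i:02d}" for i in range(20)]


@pytest.fixture(scope="session")
def small_library() -> SignatureLibrary:
    """Four drugs over a 20-gene universe with hand-placed rankings.

    * reverser: disease up-genes at the bottom, down-genes at the top
    * mimic: up-genes at the top, down-genes at the bottom
    * nullish: a fixed arbitrary permutation
    * shuffler: another fixed permutation
    """
    up = GENES20[:4]  # g00..g03
    down = GENES20[4:8]  # g04..g07
    rest = GENES20[8:]
    rng = np.random.default_rng(123)
    perm1 = list(rng.permutation(GENES20))
    perm2 = list(rng.permutation(GENES20))
    rankings = {
        "reverser": down + rest + up,
        "mimic": up + rest + down,
        "nullish": perm1,
        "shuffler": perm2,
    }
    sigs = [
        DrugSignature(name, Condition("cellA", 10.0, "uM", "r1"), ranking)
        for name, ranking in sorted(rankings.items())
    ]
    return SignatureLibrary(sigs)


@pytest.fixture(scope="session")
def small_signature() -> DiseaseSignature:
    return DiseaseSignature(
        "toy_contrast",
        SignatureConfig("split", n_up=4, n_down=4),
        GENES20[:4],
        GENES20[4:8],
    )


@pytest.fixture()
def gene_table() -> pd.DataFrame:
    """Deterministic 12-gene table: 3 strong up, 3 strong down, 6 null."""
    rng = np.random.default_rng(7)
    rows = []
    for i in range(12):
        if i < 3:
            lfc, p = 2.0 + 0.1 * i, 1e-5
        elif i < 6:
            lfc, p = -2.0 - 0.1 * i, 1e-5
        else:
            lfc, p = float(rng.normal(0, 0.1)), float(rng.uniform(0.3, 1.0))
        rows.append({"gene_id": f"g{i:02d}", "log_fc": lfc, "p_value": p})
    table = pd.DataFrame(rows)
    table.attrs["contrast_id"] = "tiny"
    return table
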