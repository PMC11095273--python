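"""Packaged data: the published MACE reclassification count table.

The registry study published the paired 4x4 risk-category counts for MACE
when moving from the CatLet score to the Clinical CatLet score (categories
<=10%, 10-20%, 20-40%, >40% predicted risk, split by event status). Those
counts are shipped as a CSV so the category-dependent NRI can be recomputed
from them end to end.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .reclassification import ReclassificationTable

_CATEGORY_LABELS = ("le10", "gt10_le20", "gt20_le40", "gt40")


def mace_reclassification_table() -> ReclassificationTable:
    """Published MACE reclassification counts (CatLet -> Clinical CatLet)."""
    path = resources.files("catlet.data") / "mace_reclassification_counts.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    matrices = {}
    for status in ("event", "nonevent"):
        block = df[df["status"] == status].set_index("old_category")
        block = block.loc[list(_CATEGORY_LABELS), list(_CATEGORY_LABELS)]
        matrices[status] = block.to_numpy(dtype=int)
    return ReclassificationTable(
        events=matrices["event"],
        nonevents=matrices["nonevent"],
        labels=_CATEGORY_LABELS,
    )
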