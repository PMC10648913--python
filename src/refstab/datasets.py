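"""Bundled worked-example data.

``gelsemium_hormone_ranks`` ships the per-method stability rank
positions (GeNorm, NormFinder, BestKeeper, comparative dCT) of ten
candidate reference genes in *Gelsemium elegans* leaves, for six sample
groups (Control and four hormone treatments plus Total), as published
in a hormone-induction reference-gene study.  The GeNorm column follows
the tied-top-pair convention: the final two genes both hold rank 1.

The ``published_consensus`` column is the study's reported
comprehensive stability value (geometric mean of the four ranks,
2 decimals); it is carried for cross-checking and is never used as an
input to computation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .consensus import ConsensusRanking, MethodRanking, reffinder

RANK_COLUMNS = ("genorm", "normfinder", "bestkeeper", "deltact")
_METHOD_OF_COLUMN = dict(genorm="GeNorm", normfinder="NormFinder",
                         bestkeeper="BestKeeper", deltact="DeltaCT")


def gelsemium_hormone_ranks() -> pd.DataFrame:
    """Per-method rank positions for 6 groups x 10 genes (long format)."""
    with resources.files("refstab.data").joinpath(
        "gelsemium_hormone_ranks.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def rankings_for_group(table: pd.DataFrame, group: str) -> list[MethodRanking]:
    """Build the four MethodRanking objects for one group of a rank table."""
    block = table[table["group"] == group]
    if block.empty:
        raise ValueError(f"group {group!r} not in table")
    return [
        MethodRanking(_METHOD_OF_COLUMN[col],
                      dict(zip(block["gene"], block[col].astype(float))))
        for col in RANK_COLUMNS
    ]


def consensus_for_group(group: str,
                        table: pd.DataFrame | None = None) -> ConsensusRanking:
    """Geometric-mean-of-ranks consensus for one group of the bundled table."""
    if table is None:
        table = gelsemium_hormone_ranks()
    return reffinder(rankings_for_group(table, group))
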