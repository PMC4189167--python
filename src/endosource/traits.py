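"""Group summaries of the binary isolate-by-trait matrix.

Cultured isolates are scored 1 (activity) or 0 (none) for each in-vitro
trait (phosphate solubilisation, nitrogen-free growth, siderophores,
auxin, ACC deaminase, acetoin/butanediol, antifungal antagonism,
RNase, pectinase, cellulase, ...).  Summaries report, per
genotype x substrate group and trait, the positive count, group size,
fraction, and a display shading bin:

    none (0 positives), <25%  [0,25), 25-50% [25,50),
    50-75% [50,75), 75-100% [75,100]

Boundary fractions fall in the upper bin (25% exactly -> "25-50%").
The binary matrix can also be handed to covariance PCA with isolates as
observations and traits as variables.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

METADATA_COLUMNS = ("isolate_id", "genotype", "substrate", "tissue")

BIN_NONE = "none"
BIN_LABELS = ("<25%", "25-50%", "50-75%", "75-100%")


def shading_bin(positives: int, size: int) -> str:
    """Display bin of a positive fraction; zero positives bin 'none'."""
    if size <= 0:
        raise ValueError("group size must be positive")
    if positives == 0:
        return BIN_NONE
    pct = 100.0 * positives / size
    if pct < 25.0:
        return BIN_LABELS[0]
    if pct < 50.0:
        return BIN_LABELS[1]
    if pct < 75.0:
        return BIN_LABELS[2]
    return BIN_LABELS[3]


def read_trait_matrix(path) -> pd.DataFrame:
    """Read a TSV trait matrix: metadata columns plus binary trait columns."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait matrix missing metadata column(s) {missing}")
    validate_trait_matrix(df)
    return df


def trait_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in METADATA_COLUMNS]


def validate_trait_matrix(matrix: pd.DataFrame) -> None:
    traits = trait_columns(matrix)
    if not traits:
        raise ValueError("trait matrix has no trait columns")
    if len(set(traits)) != len(traits):
        raise ValueError("trait names must be unique")
    bad = [c for c in traits if not matrix[c].isin([0, 1]).all()]
    if bad:
        raise ValueError(f"trait column(s) {bad} contain values outside {{0, 1}}")


def summarize_traits(
    matrix: pd.DataFrame,
    grouping: Sequence[str] = ("genotype", "substrate"),
) -> pd.DataFrame:
    """Per-group, per-trait positive counts, fractions and shading bins.

    Returns a long DataFrame with columns: the grouping keys, ``trait``,
    ``positives``, ``group_size``, ``fraction``, ``bin``.
    """
    missing = [g for g in grouping if g not in matrix.columns]
    if missing:
        raise ValueError(f"grouping key(s) {missing} not in trait matrix")
    validate_trait_matrix(matrix)
    traits = trait_columns(matrix)
    rows = []
    for keys, group in matrix.groupby(list(grouping), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        size = len(group)
        for trait in traits:
            pos = int(group[trait].sum())
            rows.append(
                dict(zip(grouping, keys))
                | {
                    "trait": trait,
                    "positives": pos,
                    "group_size": size,
                    "fraction": pos / size,
                    "bin": shading_bin(pos, size),
                }
            )
    return pd.DataFrame(rows)


def traits_feature_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Binary matrix for ordination: rows isolates (observations), columns traits."""
    validate_trait_matrix(matrix)
    out = matrix.set_index("isolate_id")[trait_columns(matrix)].astype(float)
    return out
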