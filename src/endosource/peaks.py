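"""Reading, filtering and replicate aggregation of TRFLP peak tables.

A raw peak table is one row per called electropherogram peak:
``sample_id, bio_rep, tech_rep, dye, size_bp, height``.  The dye channel
identifies the labelled primer (6FAM = forward 799f, Max550 = reverse
1492rh).  Preprocessing applies, in order:

1. a fluorescence height cutoff (peaks below 35 units are discarded),
2. primer-dimer removal (integer fragment sizes 1-26 bp),
3. optional removal of organellar size windows (chloroplast 16S /
   mitochondrial 18S fragments predicted in silico),
4. water-control subtraction of per-category intensities,
5. replicate aggregation into presence/absence counts of PCR trials,
   where a fragment-size category only counts as present when it was
   detected in more than one trial.

Fragment sizes are binned to integer base pairs (round half up); the unit
of all downstream analysis is the (dye, integer size) category.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

logger = logging.getLogger(__name__)

DYES = ("6FAM", "Max550")
REQUIRED_COLUMNS = ("sample_id", "bio_rep", "tech_rep", "dye", "size_bp", "height")

#: default fluorescence height cutoff, units
HEIGHT_CUTOFF = 35.0
#: largest fragment size (bp, inclusive) treated as primer dimer
DIMER_MAX = 26
#: a category is "present" when detected in at least this many PCR trials
MIN_TRIALS_PRESENT = 2


class PeakTableError(ValueError):
    """Raised for schema or content problems in a peak table."""


def read_peak_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV peak table into a validated DataFrame.

    Parameters
    ----------
    path : str or Path
        File with the columns in :data:`REQUIRED_COLUMNS`.
    sep : str, optional
        Field separator; inferred from the extension when omitted
        (``.tsv`` -> tab, otherwise comma).

    Returns
    -------
    DataFrame with one row per raw peak.

    Raises
    ------
    PeakTableError
        If a required column is missing, a dye token is unknown, or rows
        are malformed (reported with 1-based file line numbers).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(
            f"{path}: missing required column(s) {missing}; "
            f"expected {list(REQUIRED_COLUMNS)}"
        )
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()

    bad_lines: list[int] = []
    for col in ("bio_rep", "tech_rep", "size_bp", "height"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend(df.index[coerced.isna()] + 2)  # +1 header, +1 one-based
        df[col] = coerced
    if bad_lines:
        raise PeakTableError(
            f"{path}: malformed numeric value(s) on line(s) {sorted(set(bad_lines))}"
        )
    bad_dye = ~df["dye"].isin(DYES)
    if bad_dye.any():
        tokens = sorted(df.loc[bad_dye, "dye"].unique())
        raise PeakTableError(
            f"{path}: unknown dye token(s) {tokens}; allowed dyes are {list(DYES)}"
        )
    if (df["height"] < 0).any() or (df["size_bp"] < 0).any():
        lines = sorted((df.index[(df["height"] < 0) | (df["size_bp"] < 0)] + 2).tolist())
        raise PeakTableError(f"{path}: negative size or height on line(s) {lines}")
    df["bio_rep"] = df["bio_rep"].astype(int)
    df["tech_rep"] = df["tech_rep"].astype(int)
    return df


def bin_sizes(peaks: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``size_cat`` integer column (round half up)."""
    out = peaks.copy()
    out["size_cat"] = round_half_up(out["size_bp"].to_numpy())
    return out


def filter_peaks(
    peaks: pd.DataFrame,
    height_cutoff: float = HEIGHT_CUTOFF,
    dimer_max: int = DIMER_MAX,
) -> pd.DataFrame:
    """Apply the height cutoff and primer-dimer removal.

    Retains peaks with ``height >= height_cutoff`` whose integer-binned
    size exceeds ``dimer_max`` (i.e. removes bins 1..dimer_max).  Row
    order is preserved; the result carries a ``size_cat`` column.
    """
    if height_cutoff <= 0 or dimer_max <= 0:
        raise ValueError("height_cutoff and dimer_max must be positive")
    out = peaks if "size_cat" in peaks.columns else bin_sizes(peaks)
    keep = (out["height"] >= height_cutoff) & (out["size_cat"] > dimer_max)
    return out.loc[keep].copy()


def remove_excluded_sizes(
    peaks: pd.DataFrame,
    exclusions: Iterable[tuple[str, tuple[int, int]]],
) -> pd.DataFrame:
    """Remove peaks whose (dye, binned size) falls in an excluded range.

    ``exclusions`` is an iterable of ``(dye, (lo, hi))`` with inclusive
    integer bounds; overlapping ranges union.  Typical use: windows of
    chloroplast 16S or mitochondrial 18S terminal fragments predicted by
    :mod:`endosource.digest`.
    """
    out = peaks if "size_cat" in peaks.columns else bin_sizes(peaks)
    drop = pd.Series(False, index=out.index)
    for dye, (lo, hi) in exclusions:
        if lo > hi:
            raise ValueError(f"malformed exclusion range ({lo}, {hi})")
        drop |= (out["dye"] == dye) & (out["size_cat"] >= lo) & (out["size_cat"] <= hi)
    return out.loc[~drop].copy()


def trial_intensities(trial_peaks: pd.DataFrame) -> pd.Series:
    """Sum peak heights per (dye, size_cat) within one PCR trial."""
    df = trial_peaks if "size_cat" in trial_peaks.columns else bin_sizes(trial_peaks)
    if df.empty:
        idx = pd.MultiIndex.from_arrays([[], []], names=("dye", "size_cat"))
        return pd.Series(dtype=float, index=idx)
    return df.groupby(["dye", "size_cat"])["height"].sum()


def subtract_water_control(
    sample: pd.Series, control: pd.Series | None
) -> pd.Series:
    """Water-control subtraction of per-category intensities for one trial.

    adjusted = max(0, sample - control) per category; categories only in
    the control yield 0.  A missing control passes the sample through
    unchanged with a logged warning (intensities then stay uncorrected).
    """
    if control is None:
        logger.warning("no water control for trial; intensities passed through")
        return sample.copy()
    idx = sample.index.union(control.index)
    adjusted = (
        sample.reindex(idx, fill_value=0.0) - control.reindex(idx, fill_value=0.0)
    ).clip(lower=0.0)
    adjusted.index.names = ("dye", "size_cat")
    return adjusted


@dataclass(frozen=True)
class SampleProfile:
    """Aggregated TRFLP profile of one sample.

    ``table`` is indexed by (dye, size_cat) with columns ``trial_count``
    (number of PCR trials, 0..n_trials, in which the category was
    detected), ``present`` (trial_count >= min_trials_present) and
    ``mean_adjusted_intensity`` (control-subtracted intensity averaged
    over all n_trials; trials without the category contribute 0).
    """

    sample_id: str
    n_trials: int
    table: pd.DataFrame

    def present_set(self, dyes: Sequence[str] | None = None) -> frozenset:
        """Set of (dye, size_cat) categories flagged present."""
        tab = self.table[self.table["present"]]
        if dyes is not None:
            tab = tab[tab.index.get_level_values("dye").isin(dyes)]
        return frozenset(tab.index)

    @property
    def trial_counts(self) -> pd.Series:
        return self.table["trial_count"]


def aggregate_profile(
    peaks: pd.DataFrame,
    n_trials: int | None = None,
    controls: Mapping[tuple[int, int], pd.Series] | None = None,
    min_trials_present: int = MIN_TRIALS_PRESENT,
) -> SampleProfile:
    """Aggregate one sample's filtered peaks into a :class:`SampleProfile`.

    Parameters
    ----------
    peaks : DataFrame
        Filtered peaks of a single sample (all rows share ``sample_id``);
        trials are identified by (bio_rep, tech_rep).
    n_trials : int, optional
        Total number of PCR trials performed (6 for plant tissues,
        3 for seed pools, 4 for the short replicate cell).  Defaults to
        the number of distinct trials observed in ``peaks``.
    controls : mapping, optional
        Per-trial water-control intensity series keyed by
        (bio_rep, tech_rep), used for intensity subtraction.  Detection
        (hence presence) is based on surviving peaks, not on the
        adjusted intensity.
    """
    if peaks.empty:
        raise ValueError("cannot aggregate a sample with zero trials")
    sample_ids = peaks["sample_id"].unique()
    if len(sample_ids) != 1:
        raise ValueError(f"aggregate_profile expects one sample, got {sorted(sample_ids)}")
    df = peaks if "size_cat" in peaks.columns else bin_sizes(peaks)

    trial_keys = sorted(set(map(tuple, df[["bio_rep", "tech_rep"]].itertuples(index=False))))
    if n_trials is None:
        n_trials = len(trial_keys)
    if len(trial_keys) > n_trials:
        raise ValueError(
            f"observed {len(trial_keys)} trials but n_trials={n_trials}"
        )

    counts: dict[tuple, int] = {}
    intensity_sum: dict[tuple, float] = {}
    for key, trial_df in df.groupby(["bio_rep", "tech_rep"]):
        raw = trial_intensities(trial_df)
        control = controls.get(tuple(key)) if controls is not None else None
        adjusted = subtract_water_control(raw, control) if controls is not None else raw
        for cat in raw.index:  # detection: any surviving peak in the bin
            counts[cat] = counts.get(cat, 0) + 1
        for cat, val in adjusted.items():
            intensity_sum[cat] = intensity_sum.get(cat, 0.0) + float(val)

    cats = sorted(set(counts) | set(intensity_sum))
    index = pd.MultiIndex.from_tuples(cats, names=("dye", "size_cat"))
    table = pd.DataFrame(
        {
            "trial_count": [counts.get(c, 0) for c in cats],
            "mean_adjusted_intensity": [intensity_sum.get(c, 0.0) / n_trials for c in cats],
        },
        index=index,
    )
    table["present"] = table["trial_count"] >= min_trials_present
    table = table[["trial_count", "present", "mean_adjusted_intensity"]]
    return SampleProfile(sample_id=str(sample_ids[0]), n_trials=n_trials, table=table)


def mean_intensity_profile(
    peaks: pd.DataFrame,
    controls: Mapping[tuple[int, int], pd.Series] | None = None,
    n_trials: int | None = None,
) -> pd.Series:
    """Forward-channel pseudo-profile for display.

    Control-subtracted 6FAM intensities averaged over all PCR trials
    (trials lacking a category contribute 0); the reverse channel is
    excluded.  Returns a Series indexed by integer size category.
    """
    df = peaks if "size_cat" in peaks.columns else bin_sizes(peaks)
    fwd = df[df["dye"] == "6FAM"]
    if fwd.empty:
        warnings.warn("no 6FAM peaks; pseudo-profile is empty", stacklevel=2)
        return pd.Series(dtype=float)
    trial_keys = sorted(set(map(tuple, df[["bio_rep", "tech_rep"]].itertuples(index=False))))
    if n_trials is None:
        n_trials = len(trial_keys)
    total: dict[int, float] = {}
    for key, trial_df in fwd.groupby(["bio_rep", "tech_rep"]):
        raw = trial_intensities(trial_df)
        control = controls.get(tuple(key)) if controls is not None else None
        adjusted = subtract_water_control(raw, control) if controls is not None else raw
        for (dye, cat), val in adjusted.items():
            if dye != "6FAM":
                continue
            total[cat] = total.get(cat, 0.0) + float(val)
    out = pd.Series(total, dtype=float).sort_index() / n_trials
    out.index.name = "size_cat"
    return out


def profiles_to_matrix(
    profiles: Sequence[SampleProfile], value: str = "trial_count"
) -> pd.DataFrame:
    """Wide matrix: rows = (dye, size_cat) categories, columns = samples.

    ``value`` selects ``trial_count`` (0..n_trials counts, the input the
    covariance PCA expects) or ``present`` (binary 0/1).
    """
    if value not in ("trial_count", "present"):
        raise ValueError("value must be 'trial_count' or 'present'")
    cols = {}
    for prof in profiles:
        if prof.sample_id in cols:
            raise ValueError(f"duplicate sample_id {prof.sample_id!r}")
        cols[prof.sample_id] = prof.table[value].astype(int)
    mat = pd.DataFrame(cols).fillna(0).astype(int)
    mat = mat.sort_index()
    mat.index.names = ("dye", "size_cat")
    return mat
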