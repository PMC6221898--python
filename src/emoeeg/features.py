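"""Feature construction: frontal asymmetries, midline powers, feature sets.

Asymmetry is right-hemisphere power minus left-hemisphere power of a
homologous pair (e.g. F3/F4 theta asymmetry = theta at F4 − theta at F3),
computed on baseline-normalized powers.  The composite frontal channels
average the two sites of each hemisphere: F_left = (FP1 + F3)/2,
F_right = (FP2 + F4)/2.

Feature sets
------------
original75   3 bands × 25 whole-scalp electrodes (midline excluded)
plus_midline original75 + 15 midline powers (3 bands × FZ/FCZ/CZ/CPZ/PZ)
plus_asym    original75 + 4 asymmetries (FP1/FP2 and F3/F4, theta & alpha)
plus_all19   original75 + all 19 new features
new19        the 15 midline powers + 4 asymmetries only
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .layout import FRONTAL_PAIRS, MIDLINE_SITES, ORIGINAL75_ELECTRODES
from .signal import BandPowerTable
from .synth import CONDITIONS

FEATURE_BANDS = ("theta", "alpha", "beta")
ASYM_BANDS = ("theta", "alpha")

SET_IDS = ("original75", "plus_midline", "plus_asym", "plus_all19", "new19")

EXPECTED_WIDTH = {"original75": 75, "plus_midline": 90, "plus_asym": 79,
                  "plus_all19": 94, "new19": 19}


@dataclass
class FeatureTable:
    """Named feature vectors per subject × condition."""

    data: pd.DataFrame            # index (subject, condition), named columns
    set_id: str

    def __post_init__(self) -> None:
        if self.set_id in EXPECTED_WIDTH and \
                self.data.shape[1] != EXPECTED_WIDTH[self.set_id]:
            raise ValueError(
                f"set {self.set_id!r} must have {EXPECTED_WIDTH[self.set_id]} "
                f"columns, got {self.data.shape[1]}")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


def _wide(table: BandPowerTable, value: str) -> pd.DataFrame:
    wide = table.pivot(value)
    wide.columns = [f"{band}_{electrode}" for band, electrode in wide.columns]
    return wide


def power_feature(table: BandPowerTable, electrode: str, band: str,
                  value: str = "normalized") -> pd.Series:
    """Band power at one electrode per subject × condition."""
    wide = _wide(table, value)
    col = f"{band}_{electrode}"
    if col not in wide.columns:
        raise KeyError(f"no power for electrode {electrode!r}, band {band!r}")
    return wide[col]


def asymmetry(table: BandPowerTable, pair: tuple[str, str] = ("F3", "F4"),
              band: str = "theta", value: str = "normalized") -> pd.Series:
    """Right-minus-left band power for a homologous electrode pair."""
    left, right = pair
    s = power_feature(table, right, band, value) - power_feature(table, left, band, value)
    s.name = f"asym_{band}_{left}{right}"
    return s


def composite_frontal(table: BandPowerTable, bands=ASYM_BANDS,
                      value: str = "normalized") -> pd.DataFrame:
    """Hemisphere-averaged frontal channels F_left = (FP1+F3)/2, F_right = (FP2+F4)/2."""
    out = {}
    for band in bands:
        out[f"Fleft_{band}"] = (power_feature(table, "FP1", band, value)
                                + power_feature(table, "F3", band, value)) / 2.0
        out[f"Fright_{band}"] = (power_feature(table, "FP2", band, value)
                                 + power_feature(table, "F4", band, value)) / 2.0
    return pd.DataFrame(out)


def assemble_feature_set(table: BandPowerTable, set_id: str,
                         value: str = "normalized") -> FeatureTable:
    """Build one of the five named feature sets from a band-power table."""
    if set_id not in SET_IDS:
        raise ValueError(f"unknown set_id {set_id!r}; choose from {SET_IDS}")
    wide = _wide(table, value)

    def power_cols(electrodes) -> list[str]:
        cols, missing = [], []
        for band in FEATURE_BANDS:
            for e in electrodes:
                col = f"{band}_{e}"
                (cols if col in wide.columns else missing).append(col)
        if missing:
            raise ValueError(f"missing electrodes/bands for set {set_id!r}: {missing}")
        return cols

    def asym_block() -> pd.DataFrame:
        return pd.concat(
            [asymmetry(table, pair, band, value)
             for pair in FRONTAL_PAIRS for band in ASYM_BANDS], axis=1)

    blocks: list[pd.DataFrame] = []
    if set_id != "new19":
        blocks.append(wide[power_cols(ORIGINAL75_ELECTRODES)])
    if set_id in ("plus_midline", "plus_all19", "new19"):
        blocks.append(wide[power_cols(MIDLINE_SITES)])
    if set_id in ("plus_asym", "plus_all19", "new19"):
        blocks.append(asym_block())
    return FeatureTable(data=pd.concat(blocks, axis=1), set_id=set_id)


def hit_rate(ratings: pd.DataFrame, film: str) -> float:
    """Fraction of raters scoring the film's target emotion at least one
    point above every non-target emotion."""
    rows = ratings[ratings["condition"] == film]
    if rows.empty:
        raise ValueError(f"no ratings for film {film!r}")
    target = rows[f"des_{film}"]
    others = rows[[f"des_{e}" for e in CONDITIONS if e != film]]
    hits = target >= others.max(axis=1) + 1
    return float(hits.mean())
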