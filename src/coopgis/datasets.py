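"""Bundled observed hen dataset.

Published per-hen summaries from a study of nine Hy-Line Brown laying
hens in two identical 6 m x 4.5 m non-cage rooms, observed over 48-h
periods at 48 and 66 weeks of age:

* time budgets — percent of observed time per behavior label per hen-age;
* home ranges — 95th-style isopleth range size (m^2), proportion of the
  room used, and proportion of the range overlapped by conspecifics;
* pairwise overlaps — total overlap area (m^2) between within-room pairs.

These printed summaries are the inputs to the package's statistics layer
(paired t-tests, Pearson correlations, cross-hen means and SEMs); the raw
sensor fixes behind them were never deposited.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("coopgis.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_hen_time_budgets() -> pd.DataFrame:
    """Per-hen time budgets (%) at 48 and 66 wk; columns mirror the ethogram."""
    return _read("hen_time_budgets.csv")


def load_hen_home_ranges() -> pd.DataFrame:
    """Per-hen home-range size, room proportion and conspecific overlap."""
    return _read("hen_home_ranges.csv")


def load_hen_range_overlaps() -> pd.DataFrame:
    """Pairwise home-range overlap areas (m^2) at both ages."""
    return _read("hen_range_overlaps.csv")
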