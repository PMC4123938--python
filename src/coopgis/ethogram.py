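"""Bout segmentation, time budgets, and the welfare statistics.

Annotations are instantaneous 1-s state samples scored inside the
observation windows.  They are segmented into bouts with the 5-second
rule: an animal is considered to have started a new posture/behavior/
resource state when it stopped performing the previous one for more than
5 s or performed a new one for more than 5 s.  Conventions (the rule text
leaves these open; see the package docs):

* a run of a label opens a bout immediately when no bout is open
  (recording starts at the first sample);
* while a bout of L is open, an interruption (gap or other labels)
  totalling <= 5 s does not end it; once the time away from L exceeds 5 s
  the bout is closed at the end of its last L sample;
* a different label M sustained for more than 5 s as a single run closes
  the open bout (at the end of its last L sample) and opens a bout of M at
  the start of the run; an M run of <= 5 s over an open bout never opens
  a bout of its own.

Each 1-s sample covers [t, t + 1), so a bout over samples t0..t1 has
duration t1 + 1 - t0.

Time budgets divide each label's bout seconds inside the observation
windows by the total scheduled window seconds; "other" is the residual to
100%.  The inferential statistics are the classical paired t-test between
the two ages and the Pearson correlation over hen-period rows, both
implemented from their closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import BUDGET_LABELS, BehaviorAnnotation
from .schedule import ObservationSchedule

BREAK_S = 5.0  # the ">5 s" rule threshold; exactly 5 s does NOT break a bout


@dataclass(frozen=True)
class BehaviorBout:
    """One contiguous episode of a behavior, [start, end) seconds."""

    animal_id: str
    label: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("bout must have positive duration")


def _runs(samples: Sequence[tuple[float, str | None]]) -> list[tuple[str | None, float, float]]:
    """Maximal runs of identical labels: (label, start, end) with end exclusive.

    Missing seconds between samples are treated as gap (label None).
    """
    runs: list[tuple[str | None, float, float]] = []
    for t, lab in samples:
        if runs and runs[-1][0] == lab and abs(runs[-1][2] - t) < 1e-9:
            runs[-1] = (lab, runs[-1][1], t + 1.0)
        else:
            if runs and t + 1e-9 < runs[-1][2]:
                raise ValueError(f"overlapping samples at t = {t}")
            if runs and t > runs[-1][2] + 1e-9:
                runs.append((None, runs[-1][2], t))  # implicit gap
            runs.append((lab, t, t + 1.0))
    return [r for r in runs if r[0] is not None or r[2] > r[1]]


def segment_bouts(
    annotations: Sequence[BehaviorAnnotation],
    animal_id: str | None = None,
    category: str = "behavior",
) -> list[BehaviorBout]:
    """Segment one animal's 1-s samples of one category into bouts.

    Implements the >5-s rule with the conventions in the module docstring.
    Samples must be time-sorted; contradictory duplicate times raise.
    """
    sel = [
        a
        for a in annotations
        if a.category == category and (animal_id is None or a.animal_id == animal_id)
    ]
    if not sel:
        return []
    ids = {a.animal_id for a in sel}
    if len(ids) > 1:
        raise ValueError("annotations span multiple animals; pass animal_id")
    aid = sel[0].animal_id
    seen: dict[float, str] = {}
    for a in sel:
        if a.t in seen and seen[a.t] != a.label:
            raise ValueError(
                f"contradictory {category} samples at t = {a.t} for {aid}"
            )
        seen[a.t] = a.label
    samples = sorted(seen.items())
    runs = _runs(samples)

    bouts: list[BehaviorBout] = []
    cur: str | None = None  # open bout label
    cur_start = 0.0
    last_end = 0.0  # end of the open bout's most recent own run
    for lab, s, e in runs:
        if cur is None:
            if lab is not None:
                cur, cur_start, last_end = lab, s, e
            continue
        if lab == cur:
            if s - last_end > BREAK_S:  # stopped performing cur for > 5 s
                bouts.append(BehaviorBout(aid, cur, cur_start, last_end))
                cur_start = s
            last_end = e
        elif lab is not None and e - s > BREAK_S:
            # new behavior sustained > 5 s: close at the transition, open new
            bouts.append(BehaviorBout(aid, cur, cur_start, last_end))
            cur, cur_start, last_end = lab, s, e
        # short foreign runs and gaps: wait-and-see (the s - last_end check
        # above closes the bout retroactively if the absence exceeded 5 s)
    if cur is not None:
        bouts.append(BehaviorBout(aid, cur, cur_start, last_end))
    return bouts


def compute_time_budget(
    bouts: Sequence[BehaviorBout],
    schedule: ObservationSchedule,
    animal_id: str,
    period: str,
) -> pd.Series:
    """Percent of scheduled observation time per behavior label.

    Bout time is clipped to the observation windows; the denominator is the
    total scheduled window seconds and "other" is the residual to 100.
    """
    total = schedule.total_observed_seconds
    if total <= 0:
        raise ValueError("schedule has zero observation time")
    windows = schedule.absolute_windows()
    seconds: dict[str, float] = {lab: 0.0 for lab in BUDGET_LABELS}
    for b in bouts:
        if b.label not in seconds:
            continue
        inside = sum(
            max(0.0, min(b.end, we) - max(b.start, ws)) for ws, we in windows
        )
        seconds[b.label] += inside
    pct = {lab: 100.0 * s / total for lab, s in seconds.items()}
    named = sum(pct.values())
    if named > 100.0 + 1e-9:
        raise ValueError("behavior bouts exceed the scheduled observation time")
    pct["other"] = 100.0 - named
    out = pd.Series(pct, name=(animal_id, period))
    out["animal_id"] = animal_id
    out["period"] = period
    return out


def budget_table(rows: Sequence[pd.Series]) -> pd.DataFrame:
    """Stack per-animal-period budget rows into a tidy DataFrame."""
    cols = ["animal_id", "period", *BUDGET_LABELS, "other"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(list(rows)).reset_index(drop=True)
    return df[cols]


def paired_t(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, int, float]:
    """Classical paired t-test on per-animal differences.

    Returns (t, df, two-sided p) with df = n - 1.  Animals must be paired
    in order across the two sequences.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d sequences")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences; paired t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * _sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p from the t distribution.

    p is computed from t = r sqrt(n - 2) / sqrt(1 - r^2) on n - 2 degrees
    of freedom.
    """
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.shape != ya.shape or xa.ndim != 1 or len(xa) < 3:
        raise ValueError("need equal-length 1-d sequences with n >= 3")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    r = float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    n = len(xa)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * _sps.t.sf(abs(t), n - 2)
    return r, float(p)


def summarize_budget(
    table: pd.DataFrame, period: str
) -> pd.DataFrame:
    """Across-animal mean and SEM of each budget column for one period.

    SEM uses the n-1 sample standard deviation divided by sqrt(n).
    """
    sub = table[table["period"] == period]
    n = len(sub)
    if n < 2:
        raise ValueError("need at least 2 animals for mean and SEM")
    labels = [*BUDGET_LABELS, "other"]
    mean = sub[labels].mean()
    sem = sub[labels].std(ddof=1) / math.sqrt(n)
    return pd.DataFrame({"mean": mean, "sem": sem})
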