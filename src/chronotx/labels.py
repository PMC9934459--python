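"""Deterministic day / night / twilight labelling of death times.

Donors are binned by clock time of death: day is [08:00, 17:00), night is
[21:00, 05:00) wrapping across midnight, and everything else is twilight
(times near sunrise/sunset where the day-night status of the donor is
uncertain).  Twilight donors are excluded from day-night contrasts but kept,
as a third factor level, in seasonal analyses.  Seasons are taken verbatim
from the metadata — with only a season of death on record there is no date
to infer them from.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DAY = "day"
NIGHT = "night"
TWILIGHT = "twilight"

#: Half-open label intervals in minutes since midnight.
DAY_START, DAY_END = 480, 1020           # [08:00, 17:00)
NIGHT_START, NIGHT_END = 1260, 300       # [21:00, 24:00) u [00:00, 05:00)

SEASONS = ("spring", "summer", "fall", "winter")

MINUTES_PER_DAY = 1440


def classify_daynight(time_of_death: float) -> str:
    """Map a time of death (minutes since midnight) to day/night/twilight.

    Sub-minute inputs are truncated toward zero; labelling operates on whole
    clock minutes.

    Raises
    ------
    ValueError
        If the time is outside [0, 1440).
    """
    if not np.isfinite(time_of_death) or not (0 <= time_of_death < MINUTES_PER_DAY):
        raise ValueError(
            f"time of death must lie in [0, {MINUTES_PER_DAY}) minutes, got {time_of_death!r}"
        )
    t = int(time_of_death)  # truncate toward zero
    if DAY_START <= t < DAY_END:
        return DAY
    if t >= NIGHT_START or t < NIGHT_END:
        return NIGHT
    return TWILIGHT


def label_cohort(cohort: Iterable) -> tuple[pd.Series, dict[str, int]]:
    """Label every donor in a cohort and tally labels.

    Parameters
    ----------
    cohort
        Iterable of :class:`~chronotx.simulate.DonorRecord` (anything with
        ``donor_id`` and ``time_of_death`` attributes).

    Returns
    -------
    labels : pandas.Series
        Day/night/twilight label indexed by donor id.
    counts : dict
        Label -> number of donors; always contains all three keys.
    """
    ids, labs = [], []
    for donor in cohort:
        ids.append(donor.donor_id)
        labs.append(classify_daynight(donor.time_of_death))
    labels = pd.Series(labs, index=pd.Index(ids, name="donor_id"), name="daynight_label", dtype=object)
    counts = {DAY: 0, NIGHT: 0, TWILIGHT: 0}
    counts.update(Counter(labs))
    return labels, counts


def label_times(times_minutes: Sequence[float]) -> pd.Series:
    """Vector version of :func:`classify_daynight` for raw minute values."""
    return pd.Series([classify_daynight(t) for t in times_minutes], dtype=object)


def label_metadata(metadata: pd.DataFrame, time_col: str = "time_of_death") -> pd.DataFrame:
    """Return a copy of a donor metadata table with a ``daynight_label`` column."""
    out = metadata.copy()
    out["daynight_label"] = [classify_daynight(t) for t in out[time_col]]
    return out
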