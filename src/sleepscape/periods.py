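"""Sleep periods: non-overlapping 3-6-night blocks and their 18 features.

Candidate periods tile each individual's record in blocks of 6 consecutive
calendar days, anchored at the first recorded night and advancing by exactly
6 days (gaps do not re-anchor, so period identity is deterministic).  A block
is kept when, after removing nights with no sleep windows, it still holds at
least 3 nights and no contiguous 3-night section accumulates 5 h or more of
non-wear time.  The period feature vector is the mean and population
(ddof=0) standard deviation of each of the nine zero-filled nightly
features, in the frozen order of :data:`PERIOD_FEATURE_NAMES`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import FEATURE_NAMES

#: 18 period feature columns: nine means, then nine sds, in nightly order.
PERIOD_FEATURE_NAMES = tuple(f"{f}_mean" for f in FEATURE_NAMES) + tuple(
    f"{f}_sd" for f in FEATURE_NAMES
)

#: Extra per-period columns describing night composition, used by the
#: rule-based phenotype classifiers.
COMPOSITION_NAMES = (
    "max_lw_count",
    "max_sw_count",
    "any_short_only_night",
    "any_long_short_night",
    "any_multi_long_night",
    "all_short_only",
)


@dataclass(frozen=True)
class SleepPeriod:
    individual_id: str
    period_index: int
    start_date: dt.date
    night_dates: tuple[dt.date, ...]
    feature_vector: np.ndarray  # 18 values, PERIOD_FEATURE_NAMES order

    def __post_init__(self) -> None:
        if not 3 <= len(self.night_dates) <= 6:
            raise ValueError("a sleep period holds 3-6 nights")


def build_candidate_periods(
    nights: pd.DataFrame, block_days: int = 6
) -> pd.DataFrame:
    """Attach a period slot to every night.

    ``nights`` must carry ``individual_id`` and ``night_date``; the returned
    copy adds ``period_index`` (0-based per individual) and
    ``period_start_date`` (first calendar day of the 6-day block).
    """
    out = nights.copy()
    out = out.sort_values(["individual_id", "night_date"], kind="stable")
    idx = np.empty(len(out), dtype=np.int64)
    start = np.empty(len(out), dtype=object)
    pos = 0
    for _, grp in out.groupby("individual_id", sort=False):
        dates = grp["night_date"].to_numpy()
        anchor = dates[0]
        offsets = np.array([(d - anchor).days for d in dates])
        blocks = offsets // block_days
        idx[pos : pos + len(grp)] = blocks
        start[pos : pos + len(grp)] = [
            anchor + dt.timedelta(days=int(b) * block_days) for b in blocks
        ]
        pos += len(grp)
    out["period_index"] = idx
    out["period_start_date"] = start
    return out


def apply_exclusion_criteria(
    block: pd.DataFrame,
    block_start: dt.date,
    *,
    block_days: int = 6,
    section_nights: int = 3,
    max_section_nonwear_h: float = 5.0,
    min_nights: int = 3,
) -> tuple[pd.DataFrame, str | None]:
    """Filter one candidate block; returns ``(kept_nights, drop_reason)``.

    Nights with no sleep windows are removed first; the block is dropped when
    fewer than ``min_nights`` remain or when any contiguous
    ``section_nights``-day section of the block accumulates
    ``max_section_nonwear_h`` or more hours of non-wear.
    """
    has_windows = (block["lw_count"] + block["sw_count"]) > 0
    kept = block[has_windows]
    if len(kept) < min_nights:
        return kept.iloc[0:0], "too_few_nights"
    nonwear_by_day = {
        (row.night_date - block_start).days: row.nonwear_hours
        for row in kept.itertuples()
    }
    for s in range(block_days - section_nights + 1):
        total = sum(nonwear_by_day.get(s + j, 0.0) for j in range(section_nights))
        if total >= max_section_nonwear_h:
            return kept.iloc[0:0], "nonwear"
    return kept, None


def period_features(block: pd.DataFrame) -> np.ndarray:
    """Mean then population sd of the nine nightly features over a block."""
    x = block.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    return np.concatenate([x.mean(axis=0), x.std(axis=0, ddof=0)])


def _composition(block: pd.DataFrame) -> dict:
    lw = block["lw_count"].to_numpy()
    sw = block["sw_count"].to_numpy()
    short_only = (lw == 0) & (sw >= 1)
    return {
        "max_lw_count": int(lw.max()),
        "max_sw_count": int(sw.max()),
        "any_short_only_night": bool(short_only.any()),
        "any_long_short_night": bool(((lw >= 1) & (sw >= 1)).any()),
        "any_multi_long_night": bool((lw > 1).any()),
        "all_short_only": bool(short_only.all()),
    }


def build_periods(
    nights: pd.DataFrame,
    *,
    block_days: int = 6,
    max_section_nonwear_h: float = 5.0,
    min_nights: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble retained sleep periods from a nightly-feature table.

    Returns ``(periods, dropped)``.  ``periods`` has one row per retained
    period: keys, ``n_nights``, ``night_dates`` (tuple), the 18 features and
    the composition flags.  ``dropped`` lists candidate blocks that failed
    the exclusion criteria with their reason.  Every retained night belongs
    to exactly one period.
    """
    tagged = build_candidate_periods(nights, block_days=block_days)
    rows, dropped_rows = [], []
    for (ind, pidx), block in tagged.groupby(["individual_id", "period_index"], sort=True):
        block_start = block["period_start_date"].iloc[0]
        kept, reason = apply_exclusion_criteria(
            block,
            block_start,
            block_days=block_days,
            max_section_nonwear_h=max_section_nonwear_h,
            min_nights=min_nights,
        )
        if reason is not None:
            dropped_rows.append(
                {
                    "individual_id": ind,
                    "period_index": int(pidx),
                    "start_date": block_start,
                    "n_nights": len(block),
                    "reason": reason,
                }
            )
            continue
        row = {
            "individual_id": ind,
            "period_index": int(pidx),
            "start_date": block_start,
            "n_nights": len(kept),
            "night_dates": tuple(kept["night_date"]),
        }
        row.update(dict(zip(PERIOD_FEATURE_NAMES, period_features(kept))))
        row.update(_composition(kept))
        rows.append(row)
    columns = [
        "individual_id",
        "period_index",
        "start_date",
        "n_nights",
        "night_dates",
        *PERIOD_FEATURE_NAMES,
        *COMPOSITION_NAMES,
    ]
    periods = pd.DataFrame(rows, columns=columns)
    dropped = pd.DataFrame(
        dropped_rows,
        columns=["individual_id", "period_index", "start_date", "n_nights", "reason"],
    )
    return periods, dropped
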