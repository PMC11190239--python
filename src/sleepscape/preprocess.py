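"""Night filtering, sleep-window construction and nightly sleep features.

A wearable device reports, for every night, a hypnogram: a sequence of
30-second epochs labelled wake (0), light NREM (1), deep NREM (2) or REM (3),
bracketed by a predicted sleep onset and wake onset.  Downstream analysis only
distinguishes wake from sleep; the three sleep stages are collapsed.

A night is decomposed into *sleep windows* by four rules applied in order to
the binary sleep/wake sequence:

(a) contiguous wake runs shorter than 10 min become sleep,
(b) contiguous sleep runs shorter than 10 min become wake,
(c) sleep segments separated by less than 60 min of contiguous wake are merged
    into a single window; a gap of 60 min or more splits windows,
(d) windows shorter than 3 h are *short* windows, the rest are *long*.

Sleep and wake time inside each window are then measured on the original
(pre-smoothing) labels, so rule (a) does not erase genuine brief awakenings
from the wake-time features.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from ._errors import DataError

EPOCH_SECONDS = 30.0
#: Nightly feature columns, in frozen order (means then sds of these make the
#: 18-dimensional period vector).
FEATURE_NAMES = (
    "sleep_percent",
    "st_long_h",
    "wt_long_h",
    "st_short_h",
    "wt_short_h",
    "lw_count",
    "sw_count",
    "lw_length_h",
    "sw_length_h",
)


@dataclass
class EpochSeries:
    """One night of 30-s sleep-stage epochs for one individual.

    Epochs are contiguous, the first starting at ``sleep_onset`` and the last
    ending at ``wake_onset``.  ``night_date`` is the calendar day the night is
    assigned to (the date of the midnight nearest sleep onset).
    """

    individual_id: str
    night_date: dt.date
    sleep_onset: np.datetime64
    wake_onset: np.datetime64
    stages: np.ndarray  # int8, 0=wake, 1=light, 2=deep, 3=REM
    nonwear_hours: float = 0.0

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int8)
        self.sleep_onset = np.datetime64(self.sleep_onset, "s")
        self.wake_onset = np.datetime64(self.wake_onset, "s")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def epoch_starts(self) -> np.ndarray:
        """UTC start time of every epoch (computed lazily; 30-s spacing)."""
        step = np.timedelta64(int(EPOCH_SECONDS), "s")
        return self.sleep_onset + step * np.arange(self.n_epochs)

    @property
    def duration_h(self) -> float:
        return float((self.wake_onset - self.sleep_onset) / np.timedelta64(1, "h"))

    def sleep_mask(self) -> np.ndarray:
        """Boolean array, True where the epoch is any sleep stage."""
        return self.stages > 0


@dataclass(frozen=True)
class SleepWindow:
    """A contiguous sleep window, half-open ``[start, end)``.

    ``sleep_time_h``/``wake_time_h`` are measured on the original labels
    within the window span; ``kind`` is ``"short"`` iff ``length_h < 3``.
    """

    start: np.datetime64
    end: np.datetime64
    kind: str
    sleep_time_h: float
    wake_time_h: float
    length_h: float
    start_epoch: int = field(default=0, compare=False)
    end_epoch: int = field(default=0, compare=False)


@dataclass(frozen=True)
class NightFeatures:
    """The nine nightly sleep indices.

    Features of an absent window kind are zero-filled, so a night with no
    short windows has ``st_short_h = wt_short_h = sw_count = sw_length_h = 0``.
    """

    sleep_percent: float
    st_long_h: float
    wt_long_h: float
    st_short_h: float
    wt_short_h: float
    lw_count: int
    sw_count: int
    lw_length_h: float
    sw_length_h: float

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


def _runs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode a 1-D boolean array.

    Returns ``(values, starts, lengths)`` for maximal constant runs.
    """
    x = np.asarray(x)
    if x.size == 0:
        return (np.empty(0, bool), np.empty(0, int), np.empty(0, int))
    change = np.flatnonzero(x[1:] != x[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [x.size])))
    return x[starts], starts, lengths


def assign_day(sleep_onset: np.datetime64) -> dt.date:
    """Calendar day of the midnight nearest to ``sleep_onset``.

    A night beginning within 12 h before or after a midnight belongs to that
    midnight's date; an onset at exactly noon breaks toward the later date.
    """
    t = np.datetime64(sleep_onset, "s") + np.timedelta64(12 * 3600, "s")
    day = t.astype("datetime64[D]")
    return day.astype(dt.date)


def filter_nights(nights: list[EpochSeries]) -> list[EpochSeries]:
    """Remove unusable nights.

    Drops nights that are empty or contain only wake epochs, then drops
    nights shorter than 30 min that share a calendar day (nearest-midnight
    rule) with a longer night of the same individual.  The longer night is
    kept; two sub-30-min nights on one day are both kept unless a longer
    night exists.
    """
    usable = [n for n in nights if n.n_epochs > 0 and bool(np.any(n.stages > 0))]

    by_day: dict[tuple[str, dt.date], list[EpochSeries]] = {}
    for n in usable:
        by_day.setdefault((n.individual_id, assign_day(n.sleep_onset)), []).append(n)

    kept: list[EpochSeries] = []
    for group in by_day.values():
        longest = max(g.duration_h for g in group)
        for n in group:
            if n.duration_h < 0.5 and n.duration_h < longest:
                continue
            kept.append(n)
    kept.sort(key=lambda n: (n.individual_id, n.sleep_onset.astype("int64")))
    return kept


def build_windows(
    night: EpochSeries,
    *,
    smooth_min: float = 10.0,
    merge_gap_min: float = 60.0,
    short_threshold_h: float = 3.0,
    merge_strictly_below_gap: bool = True,
) -> list[SleepWindow]:
    """Segment a night into sleep windows with rules (a)-(d).

    ``merge_strictly_below_gap`` controls the rule-(c) boundary: by default a
    wake gap of exactly ``merge_gap_min`` splits windows (merging requires a
    gap strictly below the threshold); set False for the ``<=`` reading.

    Sleep/wake time per window is computed from the original labels within
    the window span.  A night may yield zero windows after smoothing.
    """
    original_sleep = night.sleep_mask()
    n = original_sleep.size
    if n == 0:
        return []
    smooth_epochs = int(round(smooth_min * 60.0 / EPOCH_SECONDS))
    gap_epochs = int(round(merge_gap_min * 60.0 / EPOCH_SECONDS))

    # (a) wake runs < 10 min -> sleep
    smoothed = original_sleep.copy()
    vals, starts, lens = _runs(smoothed)
    for v, s, ln in zip(vals, starts, lens):
        if not v and ln < smooth_epochs:
            smoothed[s : s + ln] = True
    # (b) sleep runs < 10 min -> wake (on the output of (a))
    vals, starts, lens = _runs(smoothed)
    for v, s, ln in zip(vals, starts, lens):
        if v and ln < smooth_epochs:
            smoothed[s : s + ln] = False

    # (c) merge sleep segments separated by short wake gaps
    vals, starts, lens = _runs(smoothed)
    seg_start = starts[vals]
    seg_end = seg_start + lens[vals]
    if seg_start.size == 0:
        return []
    spans: list[tuple[int, int]] = [(int(seg_start[0]), int(seg_end[0]))]
    for s, e in zip(seg_start[1:], seg_end[1:]):
        gap = int(s) - spans[-1][1]
        merge = gap < gap_epochs if merge_strictly_below_gap else gap <= gap_epochs
        if merge:
            spans[-1] = (spans[-1][0], int(e))
        else:
            spans.append((int(s), int(e)))

    # (d) classify and measure on original labels
    step = np.timedelta64(int(EPOCH_SECONDS), "s")
    windows: list[SleepWindow] = []
    for s, e in spans:
        length_h = (e - s) * EPOCH_SECONDS / 3600.0
        st = float(np.count_nonzero(original_sleep[s:e])) * EPOCH_SECONDS / 3600.0
        windows.append(
            SleepWindow(
                start=night.sleep_onset + step * s,
                end=night.sleep_onset + step * e,
                kind="short" if length_h < short_threshold_h else "long",
                sleep_time_h=st,
                wake_time_h=length_h - st,
                length_h=length_h,
                start_epoch=s,
                end_epoch=e,
            )
        )
    return windows


def nightly_features(night: EpochSeries, windows: list[SleepWindow]) -> NightFeatures:
    """Compute the nine nightly features from a night's windows.

    Sleep/wake times per window kind are *sums* over that kind's windows and
    window lengths are *means*, so the sleep-percent numerator (total sleep
    time over all windows) stays consistent when a kind occurs more than once.
    Sleep percent divides by the onset-to-wake-onset span.
    """
    span_h = night.duration_h
    if span_h <= 0:
        raise DataError(
            f"wake onset must follow sleep onset for {night.individual_id} "
            f"on {night.night_date}"
        )
    long_w = [w for w in windows if w.kind == "long"]
    short_w = [w for w in windows if w.kind == "short"]
    total_sleep = sum(w.sleep_time_h for w in windows)
    return NightFeatures(
        sleep_percent=total_sleep / span_h,
        st_long_h=sum(w.sleep_time_h for w in long_w),
        wt_long_h=sum(w.wake_time_h for w in long_w),
        st_short_h=sum(w.sleep_time_h for w in short_w),
        wt_short_h=sum(w.wake_time_h for w in short_w),
        lw_count=len(long_w),
        sw_count=len(short_w),
        lw_length_h=float(np.mean([w.length_h for w in long_w])) if long_w else 0.0,
        sw_length_h=float(np.mean([w.length_h for w in short_w])) if short_w else 0.0,
    )


def nights_to_frame(nights: list[EpochSeries], **window_kwargs):
    """Run window construction + featurization over filtered nights.

    Returns a pandas DataFrame with one row per night: identifiers,
    ``nonwear_hours``, the nine features, and a ``windows`` column holding
    ``(start_epoch, end_epoch, kind)`` tuples for audit.
    """
    import pandas as pd

    rows = []
    for night in nights:
        windows = build_windows(night, **window_kwargs)
        feats = nightly_features(night, windows)
        row = {
            "individual_id": night.individual_id,
            "night_date": night.night_date,
            "nonwear_hours": night.nonwear_hours,
        }
        row.update(dict(zip(FEATURE_NAMES, feats.as_tuple())))
        row["windows"] = tuple(
            (w.start_epoch, w.end_epoch, w.kind) for w in windows
        )
        rows.append(row)
    columns = ["individual_id", "night_date", "nonwear_hours", *FEATURE_NAMES, "windows"]
    return pd.DataFrame(rows, columns=columns)
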