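"""Shared fixtures and independent brute-force oracles.

The oracles here re-implement pipeline math in the most literal way possible
(python loops, direct formulas) so the vectorized implementations can be
checked against them; they must stay independent of the package internals.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sleepscape.preprocess import FEATURE_NAMES, EpochSeries


# ---------------------------------------------------------------------------
# builders


def night_from_mask(
    mask,
    individual_id: str = "t01",
    onset: str = "2020-01-01T23:00:00",
    night_date: dt.date | None = None,
    nonwear_hours: float = 0.0,
) -> EpochSeries:
    """EpochSeries from a binary sleep(1)/wake(0) sequence of 30-s epochs."""
    stages = np.where(np.asarray(mask, dtype=bool), 1, 0).astype(np.int8)
    onset64 = np.datetime64(onset, "s")
    wake = onset64 + np.timedelta64(30 * stages.size, "s")
    if night_date is None:
        night_date = (onset64 + np.timedelta64(12, "h")).astype("datetime64[D]").astype(dt.date)
    return EpochSeries(
        individual_id=individual_id,
        night_date=night_date,
        sleep_onset=onset64,
        wake_onset=wake,
        stages=stages,
        nonwear_hours=nonwear_hours,
    )


def epochs(hours: float) -> int:
    return int(round(hours * 120))


def make_nights_frame(rows: list[dict]) -> pd.DataFrame:
    """Nightly-feature frame from sparse row dicts (features default to a
    plain one-long-window night)."""
    defaults = {
        "individual_id": "a",
        "nonwear_hours": 0.0,
        "sleep_percent": 0.9,
        "st_long_h": 7.0,
        "wt_long_h": 0.5,
        "st_short_h": 0.0,
        "wt_short_h": 0.0,
        "lw_count": 1,
        "sw_count": 0,
        "lw_length_h": 7.5,
        "sw_length_h": 0.0,
    }
    full = []
    for row in rows:
        r = dict(defaults)
        r.update(row)
        full.append(r)
    cols = ["individual_id", "night_date", "nonwear_hours", *FEATURE_NAMES]
    return pd.DataFrame(full, columns=cols)


def day(n: int) -> dt.date:
    return dt.date(2020, 1, 1) + dt.timedelta(days=n)


# ---------------------------------------------------------------------------
# oracles


def oracle_windows(sleep_seq) -> list[tuple[int, int, str]]:
    """Literal application of rules (a)-(d) to a binary epoch sequence.

    Returns (start_epoch, end_epoch, kind) spans.  10 min = 20 epochs,
    60 min = 120 epochs, 3 h = 360 epochs.
    """
    seq = [int(bool(v)) for v in sleep_seq]

    def runs(x):
        out, i = [], 0
        while i < len(x):
            j = i
            while j < len(x) and x[j] == x[i]:
                j += 1
            out.append((x[i], i, j))
            i = j
        return out

    after_a = seq[:]
    for v, i, j in runs(seq):
        if v == 0 and j - i < 20:
            for k in range(i, j):
                after_a[k] = 1
    after_b = after_a[:]
    for v, i, j in runs(after_a):
        if v == 1 and j - i < 20:
            for k in range(i, j):
                after_b[k] = 0
    segments = [(i, j) for v, i, j in runs(after_b) if v == 1]
    merged: list[list[int]] = []
    for i, j in segments:
        if merged and i - merged[-1][1] < 120:
            merged[-1][1] = j
        else:
            merged.append([i, j])
    return [(i, j, "short" if j - i < 360 else "long") for i, j in merged]


def oracle_silhouette(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette (b - a)/max(a, b) by direct definition."""
    n = len(points)
    scores = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores[i] = 0.0
            continue
        a = np.mean([np.linalg.norm(points[i] - points[j]) for j in same])
        b = min(
            np.mean(
                [
                    np.linalg.norm(points[i] - points[j])
                    for j in range(n)
                    if labels[j] == lab
                ]
            )
            for lab in set(labels)
            if lab != labels[i]
        )
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return scores


def oracle_information_gain(counts: np.ndarray) -> float:
    """Mutual information I(P; C) in bits via the joint-distribution formula."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    p = counts / total
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    ig = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                ig += p[i, j] * np.log2(p[i, j] / (pi[i] * pj[j]))
    return ig


# ---------------------------------------------------------------------------
# shared populations


@pytest.fixture(scope="session")
def balanced_population():
    """Five well-separated sd-0 archetypes, identity chain, with truth.

    Session-scoped: one generation serves the landscape and phenotype tests.
    Returns (periods, truth_cluster_per_period, truth).
    """
    from sleepscape.periods import build_periods
    from sleepscape.preprocess import filter_nights, nights_to_frame
    from sleepscape.simulate import GeneratorConfig, generate_population

    config = GeneratorConfig(
        archetypes=("rec", "1-b", "c2", "c3", "c4"),
        truth_transition_matrix=np.eye(5),
        initial_distribution=np.full(5, 0.2),
        n_individuals=60,
        n_nights=60,
        sd_scale=0.0,
        seed=2,
    )
    nights, _, _, truth = generate_population(config)
    frame = nights_to_frame(filter_nights(nights))
    periods, _ = build_periods(frame)
    cluster_of = {"rec": 0, "1-b": 1, "c2": 2, "c3": 3, "c4": 4}
    truth_clusters = np.array(
        [
            cluster_of[truth.period_label(row.individual_id, row.night_dates)]
            for row in periods.itertuples()
        ]
    )
    return periods, truth_clusters, truth


@pytest.fixture(scope="session")
def fitted_landscape(balanced_population):
    """One UMAP+DBSCAN fit of the balanced population (UMAP fits are slow)."""
    from sleepscape.landscape import characterize_clusters, fit_landscape

    periods, truth_clusters, _ = balanced_population
    model = fit_landscape(periods, seed=0, min_periods=100)
    summary, semantic_map = characterize_clusters(model.cluster_id, periods)
    model.semantic_map = semantic_map
    return model, summary, periods, truth_clusters
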