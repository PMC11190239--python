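"""Synthetic hypnogram populations with known latent phenotype dynamics.

The proprietary wearable dataset behind the original analysis is not
available, so this module generates populations of nightly hypnograms whose
ground truth is known: every individual carries a latent sleep-phenotype
archetype that evolves as a Markov chain, each archetype emits nights with a
characteristic window architecture (one long window, long+short, two longs,
short-only, or a mixture), and health conditions perturb the transition
matrix either persistently (chronic) or inside a window around a report date
(acute).

Archetype defaults are calibrated to the published per-subcluster feature
summaries of the reference wearable cohort (sleep percentage, window counts
and window lengths per subcluster).  The latent chain steps once per 6-night
block — the period granularity at which phenotypes are defined downstream —
and the archetype is held constant within a block.

Emission guarantees, by construction:

* wake bouts inside a window are each shorter than 10 min, so smoothing
  rule (a) restores the planned window exactly;
* gaps between windows exceed 60 min of contiguous wake, so rule (c) splits
  exactly where planned.

Hence, for zero-variance archetypes, preprocessing recovers the planned
window count and kinds for every generated night.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigError, GenerationError
from .preprocess import EPOCH_SECONDS, EpochSeries, assign_day

#: Composition of a double-long night (hours); their mean is what the nightly
#: "LW length" feature reports for such nights.
_DOUBLE_LONG_WINDOWS = (4.8, 3.2)
#: Fixed cosmetic split of sleep epochs among light/deep/REM stages.
_STAGE_PROPORTIONS = (0.55, 0.25, 0.20)

NIGHT_TYPES = ("one_long", "short_only", "long_short", "double_long", "double_short")


@dataclass(frozen=True)
class PhenotypeArchetype:
    """Generative parameters of one latent sleep phenotype.

    ``target_sleep_percent``, ``lw_length_h`` and ``sw_length_h`` are
    (mean, sd) pairs; ``night_type_probs`` gives the per-night composition
    distribution and ``defining_types`` lists night types guaranteed to occur
    at least once per 6-night block (so rule-based classification can recover
    the archetype).  ``lw_length_h`` is the mean length of a night's long
    windows as the nightly feature reports it; for archetypes with
    double-long nights the single-long emission length is solved from it.
    """

    name: str
    target_sleep_percent: tuple[float, float]
    lw_length_h: tuple[float, float] | None
    sw_length_h: tuple[float, float] | None
    night_type_probs: dict[str, float]
    night_structure: str
    defining_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sp, _ = self.target_sleep_percent
        if not 0.0 < sp <= 1.0:
            raise ConfigError(f"{self.name}: target sleep percent {sp} not in (0, 1]")
        for pair in (self.lw_length_h, self.sw_length_h):
            if pair is not None and pair[0] <= 0:
                raise ConfigError(f"{self.name}: window lengths must be positive")
        total = sum(self.night_type_probs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.night_type_probs.values()):
            raise ConfigError(f"{self.name}: night type probabilities must form a simplex")
        unknown = set(self.night_type_probs) - set(NIGHT_TYPES)
        if unknown:
            raise ConfigError(f"{self.name}: unknown night types {sorted(unknown)}")

    @property
    def lw_count(self) -> float:
        """Expected long windows per night implied by the composition."""
        p = self.night_type_probs
        return (
            p.get("one_long", 0.0)
            + p.get("long_short", 0.0)
            + 2.0 * p.get("double_long", 0.0)
        )

    @property
    def sw_count(self) -> float:
        """Expected short windows per night implied by the composition."""
        p = self.night_type_probs
        return (
            p.get("short_only", 0.0)
            + p.get("long_short", 0.0)
            + 2.0 * p.get("double_short", 0.0)
        )

    @property
    def single_long_mean_h(self) -> float:
        """Emission length of a lone long window.

        Solved so the per-night mean long-window length, averaged over
        long-containing nights, equals ``lw_length_h[0]`` despite double-long
        nights contributing the (shorter) mean of their two windows.
        """
        if self.lw_length_h is None:
            raise GenerationError(f"{self.name} emits no long windows")
        p = self.night_type_probs
        p_single = p.get("one_long", 0.0) + p.get("long_short", 0.0)
        p_double = p.get("double_long", 0.0)
        if p_single == 0.0:
            return self.lw_length_h[0]
        m_double = float(np.mean(_DOUBLE_LONG_WINDOWS))
        target = self.lw_length_h[0] * (p_single + p_double)
        return (target - p_double * m_double) / p_single

    def with_sd(self, scale: float) -> "PhenotypeArchetype":
        """Copy of this archetype with all standard deviations scaled."""

        def _sc(pair):
            return None if pair is None else (pair[0], pair[1] * scale)

        return dataclasses.replace(
            self,
            target_sleep_percent=_sc(self.target_sleep_percent),
            lw_length_h=_sc(self.lw_length_h),
            sw_length_h=_sc(self.sw_length_h),
        )


def _one_long(name, sp, lw):  # terse builders for the default table
    return PhenotypeArchetype(name, sp, lw, None, {"one_long": 1.0}, "one-long")


#: Default archetypes, calibrated to the published subcluster summaries.
ARCHETYPES: dict[str, PhenotypeArchetype] = {
    a.name: a
    for a in (
        _one_long("rec", (0.870, 0.045), (8.087, 0.842)),
        _one_long("0-A", (0.919, 0.017), (7.702, 0.406)),
        _one_long("0-B", (0.876, 0.016), (7.479, 0.347)),
        _one_long("0-C", (0.921, 0.017), (9.037, 0.436)),
        _one_long("0-D", (0.872, 0.022), (9.745, 0.484)),
        _one_long("0-E", (0.844, 0.031), (7.565, 0.657)),
        _one_long("0-F", (0.789, 0.046), (8.845, 0.921)),
        PhenotypeArchetype(
            "1-a",
            (0.784, 0.073),
            (6.384, 1.034),
            (0.196, 0.12),
            {"one_long": 0.785, "short_only": 0.19, "long_short": 0.025},
            "mixed",
            defining_types=("short_only",),
        ),
        PhenotypeArchetype(
            "1-b",
            (0.700, 0.105),
            (4.606, 1.184),
            (0.405, 0.25),
            {"one_long": 0.60, "short_only": 0.32, "double_short": 0.08},
            "mixed",
            defining_types=("double_short",),
        ),
        PhenotypeArchetype(
            "1-c",
            (0.769, 0.064),
            (7.412, 1.236),
            (0.411, 0.25),
            {"one_long": 0.53, "double_long": 0.25, "short_only": 0.12, "long_short": 0.10},
            "mixed",
            defining_types=("double_long", "short_only"),
        ),
        PhenotypeArchetype(
            "c2",
            (0.821, 0.053),
            (7.757, 1.045),
            (0.331, 0.21),
            {"one_long": 0.80, "long_short": 0.20},
            "long+short",
            defining_types=("long_short",),
        ),
        PhenotypeArchetype(
            "c3",
            (0.824, 0.051),
            (8.250, 0.978),
            None,
            {"one_long": 0.81, "double_long": 0.19},
            "long+long",
            defining_types=("double_long",),
        ),
        PhenotypeArchetype(
            "c4",
            (0.552, 0.167),
            None,
            (0.510, 0.286),
            {"short_only": 1.0},
            "short-only",
        ),
    )
}

#: High-level cluster a rule-based classifier should assign to each archetype.
ARCHETYPE_RULE_CLUSTER = {
    "rec": 0, "0-A": 0, "0-B": 0, "0-C": 0, "0-D": 0, "0-E": 0, "0-F": 0,
    "1-a": 1, "1-b": 1, "1-c": 1, "c2": 2, "c3": 3, "c4": 4,
}
#: Fine label (of the 13 phenotypes) for archetypes a rule-based classifier
#: can distinguish without embedding geometry.
ARCHETYPE_RULE_SUBCLUSTER = {
    "1-a": "1-a", "1-b": "1-b", "1-c": "1-c", "c2": "2", "c3": "3", "c4": "4",
}


@dataclass(frozen=True)
class ConditionEffect:
    """A health condition's perturbation of the latent dynamics.

    ``transition_matrix`` replaces the truth matrix while the condition is
    active: for ``kind="chronic"`` on every chain step of positive
    individuals; for ``kind="acute"`` on steps into blocks whose start date
    falls within ``window_days`` of the individual's report date.
    """

    condition: str
    kind: str  # "chronic" | "acute"
    transition_matrix: np.ndarray
    prevalence: float = 0.1
    window_days: tuple[int, int] = (-14, 14)
    report_day: int | None = None  # acute: fixed day index; None -> sampled
    no_answer_rate: float = 0.3  # chronic survey non-response

    def __post_init__(self) -> None:
        if self.kind not in ("chronic", "acute"):
            raise ConfigError(f"unknown condition kind {self.kind!r}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigError("prevalence must lie in [0, 1]")
        object.__setattr__(
            self, "transition_matrix", _check_stochastic(self.transition_matrix)
        )


@dataclass(frozen=True)
class NonwearSpec:
    """Per-night non-wear hours: zero with prob. ``1 - p_nonzero``, else
    exponential with mean ``mean_h``, clipped to ``max_h``."""

    p_nonzero: float = 0.08
    mean_h: float = 1.0
    max_h: float = 12.0


def _check_stochastic(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConfigError("transition matrix must be square")
    if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
        raise ConfigError("transition probabilities must lie in [0, 1]")
    rows = m.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > 1e-9):
        raise ConfigError("each transition-matrix row must sum to 1")
    return m


def default_transition_matrix(names: tuple[str, ...]) -> np.ndarray:
    """A plausible row-stochastic default over the given archetypes.

    Mimics the qualitative structure reported for the reference cohort:
    recommended sleep is sticky (~0.80 self-transition), alternative
    phenotypes mostly return to recommended sleep, and insomnia-like
    phenotypes lean toward the insomnia-like group sharing their total sleep
    time (short-fractured 1-a/1-b/c4 vs long-fractured 1-c/c2/c3).
    """
    short_frac = {"1-a", "1-b", "c4"}
    long_frac = {"1-c", "c2", "c3"}
    k = len(names)
    m = np.zeros((k, k))
    idx = {n: i for i, n in enumerate(names)}
    for i, src in enumerate(names):
        w = np.full(k, 0.02)
        if src == "rec":
            w[i] = 0.80
        elif src in short_frac | long_frac:
            w[i] = 0.15
            group = short_frac if src in short_frac else long_frac
            for g in group:
                if g in idx:
                    w[idx[g]] = max(w[idx[g]], 0.08)
            if "rec" in idx:
                w[idx["rec"]] = 0.50
        else:  # peripheral one-long phenotypes
            w[i] = 0.10
            if "rec" in idx:
                w[idx["rec"]] = 0.72
        m[i] = w / w.sum()
    return m


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic population."""

    archetypes: tuple[str, ...] = ("rec", "1-a", "1-b", "1-c", "c2", "c3", "c4")
    n_individuals: int = 100
    n_nights: int = 90
    truth_transition_matrix: np.ndarray | None = None
    initial_distribution: np.ndarray | None = None
    missing_night_prob: float = 0.0
    nonwear: NonwearSpec = field(default_factory=NonwearSpec)
    condition_effects: tuple[ConditionEffect, ...] = ()
    block_nights: int = 6
    start_date: dt.date = dt.date(2020, 1, 1)
    onset_jitter_h: float = 0.5
    sd_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [a for a in self.archetypes if a not in ARCHETYPES]
        if unknown:
            raise ConfigError(f"unknown archetypes {unknown}")
        k = len(self.archetypes)
        if self.truth_transition_matrix is None:
            self.truth_transition_matrix = default_transition_matrix(self.archetypes)
        self.truth_transition_matrix = _check_stochastic(self.truth_transition_matrix)
        if self.truth_transition_matrix.shape[0] != k:
            raise ConfigError("transition matrix size must match archetype count")
        if self.initial_distribution is None:
            pi = np.full(k, 0.15 / max(k - 1, 1))
            pi[0] = 1.0 - pi[1:].sum() if k > 1 else 1.0
            self.initial_distribution = pi
        self.initial_distribution = np.asarray(self.initial_distribution, float)
        if self.initial_distribution.shape != (k,) or np.any(self.initial_distribution < 0):
            raise ConfigError("initial distribution must be a length-K simplex vector")
        if abs(self.initial_distribution.sum() - 1.0) > 1e-9:
            raise ConfigError("initial distribution must sum to 1")
        if not 0.0 <= self.missing_night_prob < 1.0:
            raise ConfigError("missing_night_prob must lie in [0, 1)")
        for eff in self.condition_effects:
            if eff.transition_matrix.shape[0] != k:
                raise ConfigError(
                    f"effect {eff.condition!r}: matrix size must match archetype count"
                )

    @property
    def n_blocks(self) -> int:
        return -(-self.n_nights // self.block_nights)

    def block_start_day(self, block: int) -> int:
        return block * self.block_nights


@dataclass
class SyntheticTruth:
    """Ground truth of a generated population.

    ``block_labels`` holds the latent chain (one state per 6-night block);
    ``night_labels`` its per-night expansion.  Night *i* of an individual is
    assigned to calendar date ``start_date + i + 1`` (sleep onset near 23:00
    on day *i*, nearest midnight the following date).
    """

    archetype_names: tuple[str, ...]
    start_date: dt.date
    block_nights: int
    block_labels: dict[str, np.ndarray]
    night_labels: dict[str, np.ndarray]
    missing: dict[str, np.ndarray]
    chronic_positive: dict[str, set[str]] = field(default_factory=dict)
    acute_reports: dict[str, dict[str, dt.date]] = field(default_factory=dict)
    base_matrix: np.ndarray | None = None
    effect_matrices: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.block_labels)

    def night_index(self, night_date: dt.date) -> int:
        return (night_date - self.start_date).days - 1

    def night_label(self, individual_id: str, night_date: dt.date) -> str:
        i = self.night_index(night_date)
        return self.archetype_names[self.night_labels[individual_id][i]]

    def period_label(self, individual_id: str, night_dates) -> str:
        """Majority latent archetype over a period's nights (ties: earliest)."""
        idx = [self.night_index(d) for d in night_dates]
        labels = self.night_labels[individual_id][idx]
        values, counts = np.unique(labels, return_counts=True)
        return self.archetype_names[int(values[np.argmax(counts)])]

    def switch_frequency(self) -> float:
        """Fraction of latent chain steps that change state."""
        switches = total = 0
        for seq in self.block_labels.values():
            if seq.size > 1:
                switches += int(np.count_nonzero(np.diff(seq)))
                total += seq.size - 1
        return switches / total if total else float("nan")


# ---------------------------------------------------------------------------
# night emission


def _wake_bout_sizes(n_wake: int, rng: np.random.Generator) -> list[int]:
    # every bout < 20 epochs (10 min) so smoothing rule (a) absorbs it
    sizes = []
    rem = int(n_wake)
    while rem > 0:
        s = int(rng.integers(8, 20)) if rem > 19 else rem
        sizes.append(min(s, rem))
        rem -= sizes[-1]
    return sizes


def _window_sleep_mask(n_ep: int, n_wake: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean sleep mask for one window: wake in sub-10-min interior bouts."""
    if n_wake <= 0:
        return np.ones(n_ep, dtype=bool)
    sizes = _wake_bout_sizes(n_wake, rng)
    nb = len(sizes)
    n_sleep = n_ep - n_wake
    if n_sleep < nb + 1:
        raise GenerationError("window too small for its planned wake time")
    extra = rng.multinomial(n_sleep - (nb + 1), np.full(nb + 1, 1.0 / (nb + 1)))
    gaps = extra + 1
    parts = []
    for g, w in zip(gaps[:-1], sizes):
        parts.append(np.ones(int(g), dtype=bool))
        parts.append(np.zeros(int(w), dtype=bool))
    parts.append(np.ones(int(gaps[-1]), dtype=bool))
    return np.concatenate(parts)


def _stages_from_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    stages = np.zeros(mask.size, dtype=np.int8)
    n_sleep = int(np.count_nonzero(mask))
    stages[mask] = rng.choice(
        np.array([1, 2, 3], dtype=np.int8), size=n_sleep, p=_STAGE_PROPORTIONS
    )
    return stages


def _draw(pair: tuple[float, float], rng: np.random.Generator, lo: float, hi: float) -> float:
    mean, sd = pair
    return float(np.clip(mean if sd == 0 else rng.normal(mean, sd), lo, hi))


def sample_night_type(archetype: PhenotypeArchetype, rng: np.random.Generator) -> str:
    types = list(archetype.night_type_probs)
    probs = np.array([archetype.night_type_probs[t] for t in types])
    return types[int(rng.choice(len(types), p=probs / probs.sum()))]


def _night_windows(
    archetype: PhenotypeArchetype, night_type: str, rng: np.random.Generator
) -> list[tuple[str, float]]:
    """Planned (kind, length_h) list for one night."""
    lw_sd = archetype.lw_length_h[1] if archetype.lw_length_h else 0.0
    if night_type == "one_long":
        return [("long", _draw((archetype.single_long_mean_h, lw_sd), rng, 3.05, 14.0))]
    if night_type == "short_only":
        return [("short", _draw(archetype.sw_length_h, rng, 0.175, 2.9))]
    if night_type == "double_short":
        return [
            ("short", _draw(archetype.sw_length_h, rng, 0.175, 2.9)),
            ("short", _draw(archetype.sw_length_h, rng, 0.175, 2.9)),
        ]
    if night_type == "long_short":
        return [
            ("long", _draw((archetype.single_long_mean_h, lw_sd), rng, 3.05, 14.0)),
            ("short", _draw(archetype.sw_length_h, rng, 0.175, 2.9)),
        ]
    if night_type == "double_long":
        f = _draw((1.0, lw_sd / 8.0), rng, 0.96, 1.25)
        return [("long", _DOUBLE_LONG_WINDOWS[0] * f), ("long", _DOUBLE_LONG_WINDOWS[1] * f)]
    raise GenerationError(f"unknown night type {night_type!r}")


def generate_night(
    archetype: PhenotypeArchetype,
    rng: np.random.Generator,
    *,
    individual_id: str = "ind",
    date: dt.date = dt.date(2020, 1, 1),
    night_type: str | None = None,
    onset_jitter_h: float = 0.5,
    nonwear_hours: float = 0.0,
) -> EpochSeries:
    """Emit one night's hypnogram for an archetype.

    ``date`` is the evening the night starts (sleep onset near 23:00 local);
    the emitted ``night_date`` is the nearest-midnight calendar day, i.e. the
    following date.  Raises :class:`GenerationError` when the archetype's
    sleep percentage is incompatible with the >60-min wake gaps a
    multi-window night requires.
    """
    if night_type is None:
        night_type = sample_night_type(archetype, rng)
    windows = _night_windows(archetype, night_type, rng)
    p = _draw(archetype.target_sleep_percent, rng, 0.15, 0.995)

    n_gaps = len(windows) - 1
    min_gap_h = 61.0 / 60.0
    gap_h = []
    if n_gaps:
        if archetype.target_sleep_percent[0] >= 0.999:
            raise GenerationError(
                f"{archetype.name}: sleep percent "
                f"{archetype.target_sleep_percent[0]} incompatible with the "
                f">60 min wake gap a {night_type} night requires"
            )
        jitter = 0.35 if archetype.target_sleep_percent[1] == 0 else float(
            abs(rng.normal(0.35, 0.2))
        )
        gap_h = [min(min_gap_h + jitter, 2.0)] * n_gaps

    win_ep = [max(int(round(length * 3600 / EPOCH_SECONDS)), 21) for _, length in windows]
    gap_ep = [max(int(round(g * 3600 / EPOCH_SECONDS)), 122) for g in gap_h]
    total_ep = sum(win_ep) + sum(gap_ep)
    # In-window wake targets the night-level sleep percentage; when the
    # mandatory between-window gaps already exceed the wake budget, the
    # windows are emitted as pure sleep and the night's sleep percentage
    # lands below target (multi-window nights are intrinsically less
    # efficient than the archetype's single-window nights).
    target_sleep_ep = int(round(p * total_ep))
    wake_in = sum(win_ep) - target_sleep_ep
    wake_in = int(np.clip(wake_in, 0, sum(win_ep)))

    # distribute in-window wake proportionally to window size
    alloc = [int(round(wake_in * w / sum(win_ep))) for w in win_ep]
    alloc[-1] = wake_in - sum(alloc[:-1])
    parts = []
    for i, (w_ep, a) in enumerate(zip(win_ep, alloc)):
        a = int(np.clip(a, 0, max(w_ep - (a // 19 + 2), 0)))
        parts.append(_window_sleep_mask(w_ep, a, rng))
        if i < n_gaps:
            parts.append(np.zeros(gap_ep[i], dtype=bool))
    mask = np.concatenate(parts)
    stages = _stages_from_mask(mask, rng)

    jitter_s = float(rng.normal(0.0, onset_jitter_h * 3600)) if onset_jitter_h else 0.0
    jitter_s = float(np.clip(jitter_s, -3 * 3600, 3 * 3600))
    onset = np.datetime64(
        dt.datetime(date.year, date.month, date.day, 23, 0), "s"
    ) + np.timedelta64(int(jitter_s), "s")
    wake = onset + np.timedelta64(int(stages.size * EPOCH_SECONDS), "s")
    return EpochSeries(
        individual_id=individual_id,
        night_date=assign_day(onset),
        sleep_onset=onset,
        wake_onset=wake,
        stages=stages,
        nonwear_hours=nonwear_hours,
    )


# ---------------------------------------------------------------------------
# population generation


def simulate_phenotype_sequences(
    n_sequences: int,
    length: int,
    transition_matrix,
    initial_distribution,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate label-level Markov chains; returns (n_sequences, length) ints."""
    t = _check_stochastic(transition_matrix)
    pi = np.asarray(initial_distribution, float)
    k = t.shape[0]
    out = np.empty((n_sequences, length), dtype=np.int64)
    out[:, 0] = rng.choice(k, size=n_sequences, p=pi / pi.sum())
    cum = np.cumsum(t, axis=1)
    for step in range(1, length):
        u = rng.random(n_sequences)
        out[:, step] = (u[:, None] > cum[out[:, step - 1]]).sum(axis=1)
    return out


def _individual_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, index, stream])


def _simulate_chain(
    config: GeneratorConfig,
    matrix_for_step,
    rng: np.random.Generator,
) -> np.ndarray:
    k = len(config.archetypes)
    chain = np.empty(config.n_blocks, dtype=np.int64)
    chain[0] = rng.choice(k, p=config.initial_distribution)
    for b in range(1, config.n_blocks):
        m = matrix_for_step(b)
        chain[b] = rng.choice(k, p=m[chain[b - 1]])
    return chain


def _assign_conditions(
    config: GeneratorConfig, ids: list[str], rng: np.random.Generator
) -> tuple[dict[str, set[str]], dict[str, dict[str, dt.date]]]:
    """Sample disjoint positive sets (and acute report dates) per effect."""
    chronic: dict[str, set[str]] = {}
    acute: dict[str, dict[str, dt.date]] = {}
    pool = list(ids)
    for eff in config.condition_effects:
        n_pos = int(round(eff.prevalence * len(ids)))
        n_pos = min(n_pos, len(pool))
        chosen = [pool[i] for i in rng.choice(len(pool), size=n_pos, replace=False)]
        pool = [p for p in pool if p not in set(chosen)]
        if eff.kind == "chronic":
            chronic[eff.condition] = set(chosen)
        else:
            lo = 51 + abs(eff.window_days[0]) + config.block_nights
            hi = max(config.n_nights - eff.window_days[1], lo + 1)
            reports = {}
            for ind in chosen:
                day = eff.report_day if eff.report_day is not None else int(
                    rng.integers(lo, hi)
                )
                reports[ind] = config.start_date + dt.timedelta(days=day)
            acute[eff.condition] = reports
    return chronic, acute


def apply_condition_effects(
    truth: SyntheticTruth,
    config: GeneratorConfig,
) -> SyntheticTruth:
    """Re-simulate latent chains of condition-positive individuals.

    Chronic positives use the effect's matrix on every chain step; acute
    positives use it only on steps into blocks starting within the effect's
    day window around their report date.  With no effects configured the
    truth is returned unchanged.  Explicit acute reports closer than 50 days
    apart for one individual are rejected, mirroring the cohort clean rule.
    """
    if not config.condition_effects:
        return truth

    # reject overlapping acute events (cohort clean rule)
    per_ind: dict[str, list[dt.date]] = {}
    for reports in truth.acute_reports.values():
        for ind, d in reports.items():
            per_ind.setdefault(ind, []).append(d)
    for ind, dates in per_ind.items():
        dates = sorted(dates)
        for a, b in zip(dates, dates[1:]):
            if (b - a).days < 50:
                raise ConfigError(
                    f"{ind}: acute reports {a} and {b} overlap within 50 days"
                )

    effects = {e.condition: e for e in config.condition_effects}
    for i, ind in enumerate(truth.individual_ids):
        active: list[tuple[ConditionEffect, dt.date | None]] = []
        for cond, members in truth.chronic_positive.items():
            if ind in members:
                active.append((effects[cond], None))
        for cond, reports in truth.acute_reports.items():
            if ind in reports:
                active.append((effects[cond], reports[ind]))
        if not active:
            continue

        def matrix_for_step(b: int) -> np.ndarray:
            day = config.start_date + dt.timedelta(days=config.block_start_day(b))
            for eff, report in active:
                if eff.kind == "chronic":
                    return eff.transition_matrix
                offset = (day - report).days
                if eff.window_days[0] <= offset <= eff.window_days[1]:
                    return eff.transition_matrix
            return config.truth_transition_matrix

        rng = _individual_rng(config.seed, i, 4)
        truth.block_labels[ind] = _simulate_chain(config, matrix_for_step, rng)
    _expand_nights(truth, config)
    return truth


def _expand_nights(truth: SyntheticTruth, config: GeneratorConfig) -> None:
    for ind, chain in truth.block_labels.items():
        nights = np.repeat(chain, config.block_nights)[: config.n_nights]
        truth.night_labels[ind] = nights


def generate_population(
    config: GeneratorConfig,
) -> tuple[list[EpochSeries], pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a full synthetic population.

    Returns ``(nights, survey, symptoms, truth)``: one
    :class:`~sleepscape.preprocess.EpochSeries` per non-missing
    (individual, night); a survey table (``individual_id``, ``condition``,
    ``response``); a symptom table (``individual_id``, ``condition``,
    ``report_date``); and the :class:`SyntheticTruth` actually used.
    Identical config and seed give byte-identical output.
    """
    ids = [f"ind{i:05d}" for i in range(config.n_individuals)]
    rng_pop = np.random.default_rng([config.seed, 0xA5])
    chronic, acute = _assign_conditions(config, ids, rng_pop)

    truth = SyntheticTruth(
        archetype_names=config.archetypes,
        start_date=config.start_date,
        block_nights=config.block_nights,
        block_labels={},
        night_labels={},
        missing={},
        chronic_positive=chronic,
        acute_reports=acute,
        base_matrix=config.truth_transition_matrix,
        effect_matrices={e.condition: e.transition_matrix for e in config.condition_effects},
    )
    for i, ind in enumerate(ids):
        rng = _individual_rng(config.seed, i, 1)
        truth.block_labels[ind] = _simulate_chain(
            config, lambda b: config.truth_transition_matrix, rng
        )
    _expand_nights(truth, config)
    truth = apply_condition_effects(truth, config)

    archetype_objs = [ARCHETYPES[name].with_sd(config.sd_scale) for name in config.archetypes]
    nights: list[EpochSeries] = []
    for i, ind in enumerate(ids):
        rng_aux = _individual_rng(config.seed, i, 3)
        missing = rng_aux.random(config.n_nights) < config.missing_night_prob
        truth.missing[ind] = missing
        nonwear = np.where(
            rng_aux.random(config.n_nights) < config.nonwear.p_nonzero,
            np.clip(
                rng_aux.exponential(config.nonwear.mean_h, config.n_nights),
                0.0,
                config.nonwear.max_h,
            ),
            0.0,
        )

        rng_n = _individual_rng(config.seed, i, 2)
        labels = truth.night_labels[ind]
        for b in range(config.n_blocks):
            lo = config.block_start_day(b)
            hi = min(lo + config.block_nights, config.n_nights)
            block_nights = list(range(lo, hi))
            arch = archetype_objs[labels[lo]]
            types = [sample_night_type(arch, rng_n) for _ in block_nights]
            # guarantee each defining night type at least once per block
            free = list(range(len(types)))
            for d_type in arch.defining_types:
                if d_type in types:
                    free = [j for j in free if types[j] != d_type]
                    continue
                if not free:
                    break
                j = free.pop(int(rng_n.integers(len(free))))
                types[j] = d_type
            for j, night_idx in enumerate(block_nights):
                if missing[night_idx]:
                    continue
                nights.append(
                    generate_night(
                        arch,
                        rng_n,
                        individual_id=ind,
                        date=config.start_date + dt.timedelta(days=night_idx),
                        night_type=types[j],
                        onset_jitter_h=config.onset_jitter_h,
                        nonwear_hours=float(nonwear[night_idx]),
                    )
                )

    survey_rows = []
    for eff in config.condition_effects:
        if eff.kind != "chronic":
            continue
        positives = chronic[eff.condition]
        for ind in ids:
            if ind in positives:
                response = "positive"
            else:
                response = (
                    "no_answer" if rng_pop.random() < eff.no_answer_rate else "negative"
                )
            survey_rows.append(
                {"individual_id": ind, "condition": eff.condition, "response": response}
            )
    survey = pd.DataFrame(survey_rows, columns=["individual_id", "condition", "response"])

    symptom_rows = [
        {"individual_id": ind, "condition": cond, "report_date": d}
        for cond, reports in acute.items()
        for ind, d in reports.items()
    ]
    symptoms = pd.DataFrame(
        symptom_rows, columns=["individual_id", "condition", "report_date"]
    )
    return nights, survey, symptoms, truth
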