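"""Condition cohorts, contingency tables, chi-square and information gain.

Two cohort designs are supported.  *Chronic*: sleep periods (or transition
pairs) from survey-positive vs survey-negative individuals; no-answer
individuals are excluded.  *Acute*: within the same individuals, units whose
start date falls within 14 days either side of a symptom report ("during")
vs units starting strictly more than 50 days before the report ("baseline");
the gap zone between -50 and -14 days belongs to neither group, and
individuals with another report in the 50 days before are excluded.
Transition pairs are dated by the *from* period's start date.

The chi-square statistic follows the goodness-of-fit convention of the
source analysis: the positive (or during) group is the observed
distribution, the negative (baseline) group's category proportions scaled
to the observed total are the expected, and dof = categories - 1.
Information gain is the mutual information between group membership P and
the categorical variable C in bits: IG = H[P] - H[P|C].
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortDesign:
    """How units are split into the two compared groups.

    Acute windows are day-granular and inclusive; ``during_window`` is
    relative to the report date and ``baseline_before_days`` means units
    strictly earlier than that many days before the report.
    """

    mode: str  # "chronic" | "acute"
    condition: str
    during_window: tuple[int, int] = (-14, 14)
    baseline_before_days: int = 50
    clean_days: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("chronic", "acute"):
            raise ConfigError(f"unknown cohort mode {self.mode!r}")
        if self.mode == "acute" and self.baseline_before_days <= -self.during_window[0]:
            raise ConfigError("baseline and during windows must be disjoint")

    @property
    def group_names(self) -> tuple[str, str]:
        # (observed, expected/reference)
        return ("pos", "neg") if self.mode == "chronic" else ("during", "baseline")


@dataclass
class ContingencyTable:
    """Category-by-group counts with the expected distribution derived.

    ``counts`` has one row per group in ``groups`` order; categories zero in
    both groups are dropped at construction (recorded in
    ``dropped_categories``), and dof = kept categories - 1.
    """

    categories: tuple[str, ...]
    groups: tuple[str, str]
    counts: np.ndarray  # (2, K) ints
    dropped_categories: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise DataError("contingency counts must be non-negative")

    @property
    def dof(self) -> int:
        return len(self.categories) - 1


def build_contingency_table(
    units: pd.DataFrame,
    category_col: str,
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate units into a 2 x K table, dropping empty categories."""
    if groups is None:
        observed_groups = tuple(pd.unique(units[group_col]))
        if len(observed_groups) != 2:
            raise DataError(f"need exactly 2 groups, got {observed_groups}")
        groups = observed_groups  # type: ignore[assignment]
    tab = pd.crosstab(units[group_col], units[category_col].astype(str))
    for g in groups:
        if g not in tab.index:
            tab.loc[g] = 0
    tab = tab.loc[list(groups)]
    keep = tab.sum(axis=0) > 0
    dropped = tuple(tab.columns[~keep].astype(str))
    tab = tab.loc[:, keep]
    return ContingencyTable(
        categories=tuple(tab.columns.astype(str)),
        groups=groups,
        counts=tab.to_numpy(),
        dropped_categories=dropped,
    )


def assign_cohort(
    units: pd.DataFrame,
    design: CohortDesign,
    *,
    survey: pd.DataFrame | None = None,
    symptoms: pd.DataFrame | None = None,
    date_col: str = "start_date",
) -> pd.DataFrame:
    """Attach a ``group`` column to units; units in neither group are dropped.

    Chronic mode groups by the individual's survey response (no-answer
    excluded); acute mode groups each unit by its start date relative to the
    individual's report.  Pure: identical inputs give identical groups.
    """
    units = units.copy()
    if design.mode == "chronic":
        if survey is None:
            raise DataError("chronic design requires a survey table")
        resp = survey[survey["condition"] == design.condition].set_index("individual_id")[
            "response"
        ]
        mapped = units["individual_id"].map(resp)
        units["group"] = mapped.map({"positive": "pos", "negative": "neg"})
        return units[units["group"].notna()].reset_index(drop=True)

    if symptoms is None:
        raise DataError("acute design requires a symptom table")
    units = units.reset_index(drop=True)
    cond = symptoms[symptoms["condition"] == design.condition]
    all_reports = symptoms.groupby("individual_id")["report_date"].apply(list)

    groups = np.full(len(units), None, dtype=object)
    lo, hi = design.during_window
    for ind, grp in units.groupby("individual_id").groups.items():
        mine = cond[cond["individual_id"] == ind]["report_date"]
        if mine.empty:
            continue
        report = min(mine)
        # clean rule: no other acute report in the clean_days before
        others = [
            d
            for d in all_reports.get(ind, [])
            if d != report and 0 < (report - d).days <= design.clean_days
        ]
        if others:
            logger.info("excluding %s: another report within %d days", ind, design.clean_days)
            continue
        offsets = np.array(
            [(d - report).days for d in units.loc[grp, date_col]], dtype=int
        )
        g = np.full(len(offsets), None, dtype=object)
        g[(offsets >= lo) & (offsets <= hi)] = "during"
        g[offsets < -design.baseline_before_days] = "baseline"
        if not np.any(g == "baseline"):
            logger.info("dropping %s: no baseline data before report %s", ind, report)
            continue
        groups[np.asarray(grp)] = g
    units["group"] = groups
    return units[units["group"].notna()].reset_index(drop=True)


def chi_square_test(
    table: ContingencyTable,
    *,
    pseudocount: float = 0.0,
) -> tuple[float, int, float]:
    """Pearson chi-square of the observed group against the reference group.

    Expected counts are the reference (second) group's category proportions
    scaled to the observed (first) group's total; the statistic is
    sum((O - E)^2 / E) with dof = K - 1 and an upper-tail p-value.  A zero
    expected count with nonzero observed raises unless ``pseudocount`` > 0
    (added to every cell of both groups) -- a silent infinity is worse than
    a loud failure.
    """
    if len(table.categories) < 2:
        raise DataError("chi-square needs at least 2 categories")
    obs = table.counts[0].astype(float) + pseudocount
    ref = table.counts[1].astype(float) + pseudocount
    if ref.sum() == 0:
        raise DataError("reference group is empty")
    bad = (ref == 0) & (obs > 0)
    if bad.any():
        raise DataError(
            f"zero expected count with nonzero observed in categories "
            f"{[table.categories[i] for i in np.flatnonzero(bad)]}; "
            "enable a pseudocount to proceed"
        )
    expected = ref / ref.sum() * obs.sum()
    mask = expected > 0
    stat = float(np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask]))
    dof = table.dof
    p = float(stats.chi2.sf(stat, dof))
    return stat, dof, p


def information_gain(table: ContingencyTable) -> float:
    """IG(P, C) = H[P] - H[P|C] in bits over the joint counts.

    Empty categories contribute nothing; the result is non-negative and
    bounded by min(H[P], H[C]).
    """
    counts = table.counts.astype(float)
    if counts.shape[0] < 2 or counts.sum() == 0:
        raise DataError("information gain needs two non-empty groups")
    total = counts.sum()

    def _entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p)))

    h_p = _entropy(counts.sum(axis=1) / total)
    col_tot = counts.sum(axis=0)
    h_p_given_c = 0.0
    for j in range(counts.shape[1]):
        if col_tot[j] == 0:
            continue
        h_p_given_c += (col_tot[j] / total) * _entropy(counts[:, j] / col_tot[j])
    return h_p - h_p_given_c


def static_vs_dynamic(
    labelled_periods: pd.DataFrame,
    pairs: pd.DataFrame,
    design: CohortDesign,
    *,
    survey: pd.DataFrame | None = None,
    symptoms: pd.DataFrame | None = None,
    pseudocount: float = 0.0,
) -> dict:
    """Compare the static (phenotype membership) and dynamic (transition)
    categorizations of one condition.

    The static table counts periods per subcluster and group; the dynamic
    table counts transition pairs per ordered subcluster pair ("A>B") and
    group, with pairs dated by the from-period's start date.  Returns the
    chi-square results, both information gains (bits) and their ratio
    IG_dynamic / IG_static (NaN when IG_static is 0).
    """
    static_units = assign_cohort(
        labelled_periods, design, survey=survey, symptoms=symptoms
    )
    pairs = pairs.copy()
    pairs["transition"] = (
        pairs["from_label"].astype(str) + ">" + pairs["to_label"].astype(str)
    )
    date_col = "from_start_date" if "from_start_date" in pairs.columns else "start_date"
    dynamic_units = assign_cohort(
        pairs, design, survey=survey, symptoms=symptoms, date_col=date_col
    )
    static_tab = build_contingency_table(
        static_units, "subcluster", groups=design.group_names
    )
    dynamic_tab = build_contingency_table(
        dynamic_units, "transition", groups=design.group_names
    )
    chi_s, dof_s, p_s = chi_square_test(static_tab, pseudocount=pseudocount)
    chi_d, dof_d, p_d = chi_square_test(dynamic_tab, pseudocount=pseudocount)
    ig_s = information_gain(static_tab)
    ig_d = information_gain(dynamic_tab)
    return {
        "condition": design.condition,
        "mode": design.mode,
        "n_static_units": int(static_tab.counts.sum()),
        "n_dynamic_units": int(dynamic_tab.counts.sum()),
        "group_sizes_static": dict(
            zip(static_tab.groups, static_tab.counts.sum(axis=1).tolist())
        ),
        "chi2_static": chi_s,
        "dof_static": dof_s,
        "p_static": p_s,
        "chi2_dynamic": chi_d,
        "dof_dynamic": dof_d,
        "p_dynamic": p_d,
        "ig_static_bits": ig_s,
        "ig_dynamic_bits": ig_d,
        "ig_ratio": (ig_d / ig_s) if ig_s > 0 else float("nan"),
        "dropped_categories_static": list(static_tab.dropped_categories),
        "dropped_categories_dynamic": list(dynamic_tab.dropped_categories),
    }
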