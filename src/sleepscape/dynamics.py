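"""Directed transition graph over phenotypes and conditional probabilities.

Every pair of successive retained sleep periods from one individual is a
transition; the conditional transition probability CTP(A, B) is the count of
A-to-B transitions divided by the count of transitions leaving A, so each
row of the CTP matrix with any outgoing transition sums to one.  Successive
means successive among retained periods regardless of calendar gap;
``require_adjacent`` optionally restricts pairs to calendar-adjacent 6-day
blocks.  Rows with no outgoing transitions are left all-zero (no smoothing:
uniform fill would silently bias the estimates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DataError
from .phenotypes import LONG_FRACTURED, SHORT_FRACTURED, SUBCLUSTERS


@dataclass
class TransitionGraph:
    """Counts and row-normalized conditional transition probabilities."""

    nodes: tuple[str, ...]
    count_matrix: np.ndarray  # (K, K) ints
    ctp_matrix: np.ndarray  # (K, K) floats in [0, 1]
    zero_rows: tuple[str, ...] = field(default_factory=tuple)

    def ctp(self, a: str, b: str) -> float:
        return float(self.ctp_matrix[self.nodes.index(a), self.nodes.index(b)])

    def to_frame(self, which: str = "ctp") -> pd.DataFrame:
        m = self.ctp_matrix if which == "ctp" else self.count_matrix
        return pd.DataFrame(m, index=list(self.nodes), columns=list(self.nodes))

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {
                "from": a,
                "to": b,
                "count": int(self.count_matrix[i, j]),
                "ctp": float(self.ctp_matrix[i, j]),
            }
            for i, a in enumerate(self.nodes)
            for j, b in enumerate(self.nodes)
            if self.count_matrix[i, j] > 0
        ]
        return pd.DataFrame(rows, columns=["from", "to", "count", "ctp"])

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, row in self.to_edge_list().iterrows():
            g.add_edge(row["from"], row["to"], count=int(row["count"]), ctp=row["ctp"])
        return g


def extract_transition_pairs(
    labelled_periods: pd.DataFrame,
    *,
    label_col: str = "subcluster",
    require_adjacent: bool = False,
    block_days: int = 6,
) -> pd.DataFrame:
    """Pairs of successive retained periods per individual.

    Individuals with fewer than two periods contribute no pairs.  Duplicate
    (individual, period_index) keys are a data error.
    """
    df = labelled_periods.sort_values(
        ["individual_id", "period_index"], kind="stable"
    )
    if df.duplicated(subset=["individual_id", "period_index"]).any():
        raise DataError("duplicate period keys in input")
    same_ind = df["individual_id"].to_numpy()[1:] == df["individual_id"].to_numpy()[:-1]
    if require_adjacent:
        gap = df["period_index"].to_numpy()[1:] - df["period_index"].to_numpy()[:-1]
        same_ind &= gap == 1
    idx_from = np.flatnonzero(same_ind)
    idx_to = idx_from + 1
    pairs = pd.DataFrame(
        {
            "individual_id": df["individual_id"].to_numpy()[idx_from],
            "from_period": df["period_index"].to_numpy()[idx_from],
            "to_period": df["period_index"].to_numpy()[idx_to],
            "from_label": df[label_col].to_numpy()[idx_from],
            "to_label": df[label_col].to_numpy()[idx_to],
        }
    )
    if "start_date" in df.columns:
        pairs["from_start_date"] = df["start_date"].to_numpy()[idx_from]
        pairs["to_start_date"] = df["start_date"].to_numpy()[idx_to]
    return pairs


def build_ctp(pairs: pd.DataFrame, nodes: tuple[str, ...] | None = None) -> TransitionGraph:
    """Count transitions and row-normalize into CTPs.

    ``nodes`` fixes the matrix order (defaults to the 13 subclusters when
    all labels are known subclusters, else sorted observed labels).  Labels
    outside ``nodes`` raise.  Rows with zero outgoing transitions stay
    all-zero and are flagged in ``zero_rows``.
    """
    if len(pairs) == 0:
        raise DataError("no transition pairs")
    observed = set(pairs["from_label"]) | set(pairs["to_label"])
    if nodes is None:
        nodes = (
            SUBCLUSTERS
            if observed <= set(SUBCLUSTERS)
            else tuple(sorted(observed, key=str))
        )
    unknown = observed - set(nodes)
    if unknown:
        raise DataError(f"labels {sorted(map(str, unknown))} not in node order")
    index = {n: i for i, n in enumerate(nodes)}
    k = len(nodes)
    counts = np.zeros((k, k), dtype=np.int64)
    i = pairs["from_label"].map(index).to_numpy()
    j = pairs["to_label"].map(index).to_numpy()
    np.add.at(counts, (i, j), 1)
    row_sums = counts.sum(axis=1)
    ctp = np.divide(
        counts,
        row_sums[:, None],
        out=np.zeros((k, k), dtype=float),
        where=row_sums[:, None] > 0,
    )
    zero = tuple(n for n, s in zip(nodes, row_sums) if s == 0)
    return TransitionGraph(tuple(nodes), counts, ctp, zero)


def relative_reduction(p_same: float, p_other: float) -> float:
    """(p_same - p_other) / p_same, as a fraction; NaN when p_same is 0."""
    if p_same == 0:
        return float("nan")
    return (p_same - p_other) / p_same


def transition_summaries(graph: TransitionGraph) -> pd.DataFrame:
    """Grouped outgoing probabilities per source subcluster.

    For each source: summed CTP into the recommended, short-fractured,
    long-fractured and other groups, plus, for insomnia-like sources, the
    relative reduction from the same-sleep-length group to the opposite
    group (as a percentage).
    """
    groups = {
        "recommended": {"0-center"},
        "short_fractured": set(SHORT_FRACTURED),
        "long_fractured": set(LONG_FRACTURED),
    }
    groups["other"] = set(graph.nodes) - set().union(*groups.values())
    rows = []
    for i, src in enumerate(graph.nodes):
        row = {"from": src}
        for gname, members in groups.items():
            row[f"p_{gname}"] = float(
                sum(graph.ctp_matrix[i, graph.nodes.index(m)] for m in members if m in graph.nodes)
            )
        if src in SHORT_FRACTURED:
            same, other = row["p_short_fractured"], row["p_long_fractured"]
        elif src in LONG_FRACTURED:
            same, other = row["p_long_fractured"], row["p_short_fractured"]
        else:
            same = other = None
        row["relative_reduction_pct"] = (
            100.0 * relative_reduction(same, other) if same is not None else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows)
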