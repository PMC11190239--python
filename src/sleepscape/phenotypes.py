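"""The 13 sleep phenotypes: subdividing Clusters 0 and 1.

Cluster 1 is split by rules on per-night window counts: periods with any
night holding more than one long window become 1-c; of the remainder, any
night with more than one short window gives 1-b; the rest are 1-a.

Cluster 0 (every night one long window) is split geometrically in embedding
space: periods whose radial distance from the Cluster-0 centroid reaches the
(1 - periphery_fraction) quantile form the periphery, carved into six
60-degree sectors counter-clockwise from -180 degrees (0-A..0-F); the rest
is 0-center, the recommended 8-h monophasic phenotype.  How the original
analysis delimited the periphery is unreported; the default
``periphery_fraction`` of 0.084 is derived from the published subcluster
sizes (54,628 peripheral of 650,339 Cluster-0 periods) and is the single
largest reproducibility gap, hence a prominent knob.

Clusters 2, 3, 4 pass through unchanged.  Insomnia-like phenotypes
(DSM-5-TR-motivated: nights with >60-min wake blocks or <6.5 h sleep) are
grouped by total sleep time into short-fractured {1-a, 1-b, 4} and
long-fractured {1-c, 2, 3}; 0-E and 0-F are tagged insomnia-like as well,
an admittedly subjective call that is config-overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ConfigError, DataError

#: The 13 phenotype labels.
SUBCLUSTERS = (
    "0-center",
    "0-A",
    "0-B",
    "0-C",
    "0-D",
    "0-E",
    "0-F",
    "1-a",
    "1-b",
    "1-c",
    "2",
    "3",
    "4",
)
SECTOR_NAMES = ("0-A", "0-B", "0-C", "0-D", "0-E", "0-F")
SHORT_FRACTURED = frozenset({"1-a", "1-b", "4"})
LONG_FRACTURED = frozenset({"1-c", "2", "3"})
DEFAULT_INSOMNIA_LIKE = frozenset(SHORT_FRACTURED | LONG_FRACTURED | {"0-E", "0-F"})


@dataclass(frozen=True)
class PhenotypeLabel:
    cluster: int
    subcluster: str
    is_recommended: bool
    is_insomnia_like: bool

    def __post_init__(self) -> None:
        if self.subcluster not in SUBCLUSTERS:
            raise DataError(f"unknown subcluster {self.subcluster!r}")


def make_label(
    subcluster: str, insomnia_like: frozenset = DEFAULT_INSOMNIA_LIKE
) -> PhenotypeLabel:
    cluster = 0 if subcluster.startswith("0") else int(subcluster[0])
    return PhenotypeLabel(
        cluster=cluster,
        subcluster=subcluster,
        is_recommended=subcluster == "0-center",
        is_insomnia_like=subcluster in insomnia_like,
    )


def subdivide_cluster1(periods: pd.DataFrame) -> np.ndarray:
    """Split Cluster-1 periods into 1-a / 1-b / 1-c by window-count rules.

    Precedence: any night with >1 long window -> 1-c; else any night with
    >1 short window -> 1-b; else 1-a.
    """
    out = np.full(len(periods), "1-a", dtype=object)
    out[periods["max_sw_count"].to_numpy() > 1] = "1-b"
    out[periods["max_lw_count"].to_numpy() > 1] = "1-c"
    return out


def sector_of_angle(theta_deg: np.ndarray) -> np.ndarray:
    """Sector index 0-5 for angles in degrees, sectors [-180 + 60k, -120 + 60k)."""
    theta = np.asarray(theta_deg, dtype=float)
    theta = np.where(theta >= 180.0, theta - 360.0, theta)
    return np.clip(((theta + 180.0) // 60.0).astype(int), 0, 5)


def subdivide_cluster0(
    embedding_xy: np.ndarray, periphery_fraction: float = 0.084
) -> np.ndarray:
    """Split Cluster-0 periods into 0-center and six peripheral sectors.

    The centroid is the mean (x, y) of the Cluster-0 periods; points whose
    radial distance is at or above the ``1 - periphery_fraction`` quantile
    form the periphery, labelled 0-A..0-F by 60-degree sectors
    counter-clockwise from -180 degrees (half-open ``[lo, hi)``).
    """
    if not 0.0 < periphery_fraction < 0.5:
        raise ConfigError("periphery_fraction must lie in (0, 0.5)")
    xy = np.asarray(embedding_xy, dtype=float)
    centroid = xy.mean(axis=0)
    delta = xy - centroid
    r = np.hypot(delta[:, 0], delta[:, 1])
    threshold = np.quantile(r, 1.0 - periphery_fraction)
    theta = np.degrees(np.arctan2(delta[:, 1], delta[:, 0]))
    labels = np.full(len(xy), "0-center", dtype=object)
    peripheral = r >= threshold
    sectors = sector_of_angle(theta[peripheral])
    labels[peripheral] = np.array(SECTOR_NAMES, dtype=object)[sectors]
    return labels


def assign_phenotypes(
    periods: pd.DataFrame,
    semantic_cluster: np.ndarray,
    embedding: np.ndarray | None = None,
    *,
    periphery_fraction: float = 0.084,
    insomnia_like: frozenset = DEFAULT_INSOMNIA_LIKE,
) -> pd.DataFrame:
    """Assign one of the 13 subcluster labels to every period.

    ``semantic_cluster`` holds high-level labels 0-4 (from the landscape
    mapping or the rule-based classifier).  ``embedding`` is required when
    any period is in Cluster 0; without it Cluster-0 periods all become
    0-center (rule-only pipelines).  Returns a copy of ``periods`` with
    ``cluster``, ``subcluster``, ``is_recommended`` and ``is_insomnia_like``.
    """
    semantic_cluster = np.asarray(semantic_cluster)
    sub = semantic_cluster.astype(object).copy()
    in0 = semantic_cluster == 0
    if embedding is not None and in0.any():
        sub[in0] = subdivide_cluster0(
            np.asarray(embedding)[in0], periphery_fraction=periphery_fraction
        )
    else:
        sub[in0] = "0-center"
    in1 = semantic_cluster == 1
    if in1.any():
        sub[in1] = subdivide_cluster1(periods.loc[in1])
    for c in (2, 3, 4):
        sub[semantic_cluster == c] = str(c)

    out = periods.copy()
    out["cluster"] = semantic_cluster
    out["subcluster"] = sub
    out["is_recommended"] = out["subcluster"] == "0-center"
    out["is_insomnia_like"] = out["subcluster"].isin(insomnia_like)
    return out


def phenotype_report(
    labelled_periods: pd.DataFrame, nights: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-subcluster feature summary in the published table layout.

    Period-level columns give mean (sd) of the per-night feature means over
    member periods; when the nightly table is supplied (with a
    ``subcluster`` merge possible through individual/period keys), window
    lengths are reported conditionally over nights that contain the window
    kind, NaN when the kind never occurs, matching the dash convention of
    the source tables.  Empty subclusters are omitted with a warning.
    """
    rows = []
    groups = {
        **{s: "recommended" for s in ("0-center",)},
        **{s: "short-fractured" for s in SHORT_FRACTURED},
        **{s: "long-fractured" for s in LONG_FRACTURED},
    }
    for sub in SUBCLUSTERS:
        members = labelled_periods[labelled_periods["subcluster"] == sub]
        if members.empty:
            warnings.warn(f"subcluster {sub} is empty; omitted from report", stacklevel=2)
            continue
        row = {
            "subcluster": sub,
            "n_periods": len(members),
            "group": groups.get(sub, "other"),
            "lw_count": members["lw_count_mean"].mean(),
            "sw_count": members["sw_count_mean"].mean(),
            "sleep_percent": members["sleep_percent_mean"].mean(),
            "sleep_percent_sd": members["sleep_percent_mean"].std(ddof=0),
            "st_long_h": members["st_long_h_mean"].mean(),
            "wt_long_h": members["wt_long_h_mean"].mean(),
        }
        if nights is not None:
            night_sub = nights.merge(
                members[["individual_id", "period_index"]],
                on=["individual_id", "period_index"],
            )
            with_lw = night_sub[night_sub["lw_count"] > 0]
            with_sw = night_sub[night_sub["sw_count"] > 0]
            row["lw_length_h"] = with_lw["lw_length_h"].mean() if len(with_lw) else np.nan
            row["sw_length_h"] = with_sw["sw_length_h"].mean() if len(with_sw) else np.nan
        else:
            row["lw_length_h"] = members["lw_length_h_mean"].mean()
            row["sw_length_h"] = members["sw_length_h_mean"].mean()
        rows.append(row)
    return pd.DataFrame(rows)
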