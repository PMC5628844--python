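"""Trend-by-trait contingency tables and the two-tailed Fisher exact test.

The question: are species whose larvae feed on trees or vines (where the
introduced parasitoid fly *Compsilura concinnata* forages most effectively)
more likely to have declined than shrub/herb feeders?  Rows of the 2x2 table
are host-plant habit (tree/vine vs shrub/herb), columns are declined vs not.

The two-tailed p-value follows the small-p-values convention: the sum of the
hypergeometric probabilities of every table with the observed margins whose
point probability does not exceed that of the observed table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "fisher_exact_two_tailed",
    "odds_ratio",
    "build_table",
]


@dataclass
class ContingencyTable:
    """2x2 nonnegative integer counts with row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("tree/vine", "shrub/herb")
    col_labels: tuple[str, str] = ("declined", "not declined")

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(c < 0):
            raise ValueError("negative cell count")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("cell counts must be integers")
            c = c.astype(int)
        self.counts = c

    def __str__(self) -> str:
        c = self.counts
        w = max(len(l) for l in self.row_labels)
        header = " " * (w + 2) + "  ".join(f"{l:>12}" for l in self.col_labels)
        rows = [
            f"{self.row_labels[i]:<{w + 2}}" + "  ".join(f"{c[i, j]:>12d}" for j in range(2))
            for i in range(2)
        ]
        return "\n".join([header, *rows])


def fisher_exact_two_tailed(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 table (small-p-values method)."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2) or np.any(counts < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise ValueError("test undefined: a margin is zero")
    return float(stats.fisher_exact(counts, alternative="two-sided").pvalue)


def odds_ratio(table) -> float:
    """Cross-product (sample) odds ratio a*d / (b*c); inf if b*c == 0."""
    c = np.asarray(table.counts if isinstance(table, ContingencyTable) else table, dtype=float)
    denom = c[0, 1] * c[1, 0]
    if denom == 0:
        return np.inf
    return float(c[0, 0] * c[1, 1] / denom)


def build_table(
    trend_calls,
    traits,
    activity: str | None = "nocturnal",
    exclude_pests: bool = True,
    summer_only: bool = False,
    spring_end_month: int = 6,
) -> ContingencyTable:
    """Host-plant-habit x declined table from per-species trend calls and traits.

    Parameters
    ----------
    trend_calls : DataFrame with columns ``species`` and either ``declined``
        (bool) or ``call`` (decline/increase/no_trend/insufficient).
    traits : DataFrame with columns ``species``, ``host_habit``
        ("tree/vine" or "shrub/herb"), ``activity`` ("diurnal"/"nocturnal"),
        ``pest`` (bool) and ``flight_end_month`` (int, last month of adult
        flight).
    activity : keep only this activity class (None = keep all).
    exclude_pests : drop crop-pest species (their trends track farming, not
        natural host availability).
    summer_only : drop species whose flight ends by ``spring_end_month``
        (spring fliers develop before the parasitoid's seasonal build-up).

    Species with call == "insufficient" (or missing calls) are excluded.
    Every exclusion is logged.
    """
    traits = traits.drop(columns=["declined", "call"], errors="ignore")
    merged = traits.merge(trend_calls, on="species", how="left", validate="1:1")
    if len(merged) == 0:
        raise ValueError("empty species roster")
    missing_trait = set(trend_calls["species"]) - set(traits["species"])
    if missing_trait:
        raise KeyError(f"species missing from trait table: {sorted(missing_trait)}")

    if "declined" in merged.columns:
        declined = merged["declined"].astype("boolean")
    else:
        declined = merged["call"].map(
            {"decline": True, "increase": False, "no_trend": False}
        ).astype("boolean")

    keep = declined.notna()
    _log_excluded(merged, ~keep, "no usable trend call")
    if activity is not None:
        drop = merged["activity"] != activity
        _log_excluded(merged, keep & drop, f"not {activity}")
        keep &= ~drop
    if exclude_pests:
        drop = merged["pest"].astype(bool)
        _log_excluded(merged, keep & drop, "crop pest")
        keep &= ~drop
    if summer_only:
        drop = merged["flight_end_month"] <= spring_end_month
        _log_excluded(merged, keep & drop, "spring-only flight")
        keep &= ~drop

    sub = merged[keep]
    if len(sub) == 0:
        raise ValueError("no species remain after filtering")
    bad_habit = set(sub["host_habit"]) - {"tree/vine", "shrub/herb"}
    if bad_habit:
        raise ValueError(f"unknown host_habit values: {sorted(bad_habit)}")

    d = declined[keep].astype(bool)
    tv = sub["host_habit"] == "tree/vine"
    counts = np.array(
        [
            [int((tv & d).sum()), int((tv & ~d).sum())],
            [int((~tv & d).sum()), int((~tv & ~d).sum())],
        ]
    )
    return ContingencyTable(counts)


def _log_excluded(frame, mask, reason: str) -> None:
    if mask.any():
        logger.info(
            "excluded (%s): %s", reason, ", ".join(sorted(frame.loc[mask, "species"]))
        )
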