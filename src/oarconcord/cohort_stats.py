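"""Cohort-level summarization and group comparison of agreement results.

Builds a long-format table with one row per (patient, observer, organ) slot —
including not-delineated slots — then computes per-organ medians and ranges of
DSC / MSD / HD95 over the valid comparisons, per-group delineation rates, and
a two-group significance test (Welch's t by default) of guideline users (ICG)
against other observers.

Undefined metrics (empty or missing structures) are excluded from statistics
rather than imputed; delineation counts are reported alongside so the two
facts stay separate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .grid_io import CohortBundle
from .metrics import AgreementResult, Status, compare

__all__ = [
    "METRIC_COLUMNS",
    "OrganSummary",
    "GroupComparison",
    "build_table",
    "table_from_cohort",
    "summarize_per_organ",
    "summaries_to_frame",
    "delineation_rate",
    "group_ttest",
]

#: Mapping from metric name to its column in the cohort table.
METRIC_COLUMNS = {"DSC": "dsc", "MSD": "msd_mm", "HD95": "hd95_mm"}

_TABLE_COLUMNS = [
    "patient", "observer", "organ", "group", "status",
    "dsc", "msd_mm", "hd95_mm", "volume_ref_cc", "volume_test_cc",
]


@dataclass(frozen=True)
class OrganSummary:
    """Median and (min, max) of each metric for one organ, over OK rows only,
    plus delineated-count / slot-count per observer group."""

    organ: str
    n_ok: int
    dsc_median: float
    dsc_range: tuple[float, float]
    msd_median: float
    msd_range: tuple[float, float]
    hd95_median: float
    hd95_range: tuple[float, float]
    delineated_by_group: dict[str, int]
    slots_by_group: dict[str, int]


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided independent t-test of one metric between observer groups."""

    metric: str
    unit: str  # PER_DELINEATION or PER_OBSERVER
    test: str  # welch or student
    mean_icg: float
    mean_other: float
    t_statistic: float
    dof: float
    p_value: float
    n_icg: int
    n_other: int


def build_table(
    bundles: Mapping[tuple[str, str], CohortBundle] | Iterable[CohortBundle],
    compare_fn=compare,
) -> pd.DataFrame:
    """Score every (patient, observer, organ) slot of a loaded cohort.

    One row per slot, including NOT_DELINEATED ones, in deterministic
    (patient, observer, organ) order.  ``compare_fn`` defaults to
    :func:`oarconcord.metrics.compare` and may be swapped (e.g. for a
    different HD percentile).
    """
    if isinstance(bundles, Mapping):
        bundle_list = [bundles[k] for k in sorted(bundles)]
    else:
        bundle_list = sorted(bundles, key=lambda b: (b.patient, b.organ))
    rows: list[dict] = []
    for bundle in bundle_list:
        for observer in sorted(bundle.observations):
            result: AgreementResult = compare_fn(
                bundle.reference, bundle.observations[observer]
            )
            rows.append(
                {
                    "patient": bundle.patient,
                    "observer": observer,
                    "organ": bundle.organ,
                    "group": bundle.groups.get(observer, "OTHER"),
                    "status": result.status.value,
                    "dsc": result.dsc,
                    "msd_mm": result.msd_mm,
                    "hd95_mm": result.hd95_mm,
                    "volume_ref_cc": result.volume_ref_cc,
                    "volume_test_cc": result.volume_test_cc,
                }
            )
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return table.sort_values(["patient", "observer", "organ"], ignore_index=True)


def table_from_cohort(dataset, compare_fn=compare) -> pd.DataFrame:
    """Score an in-memory synthetic :class:`~oarconcord.synthetic.CohortDataset`."""
    groups = dataset.groups()
    rows: list[dict] = []
    for (patient, organ), reference in sorted(dataset.references.items()):
        for profile in dataset.profiles:
            observer = profile.observer
            test = dataset.observations.get((patient, observer, organ))
            result = compare_fn(reference, test)
            rows.append(
                {
                    "patient": patient,
                    "observer": observer,
                    "organ": organ,
                    "group": groups[observer],
                    "status": result.status.value,
                    "dsc": result.dsc,
                    "msd_mm": result.msd_mm,
                    "hd95_mm": result.hd95_mm,
                    "volume_ref_cc": result.volume_ref_cc,
                    "volume_test_cc": result.volume_test_cc,
                }
            )
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return table.sort_values(["patient", "observer", "organ"], ignore_index=True)


def _median_range(values: np.ndarray) -> tuple[float, float, float]:
    if values.size == 0:
        return (math.nan, math.nan, math.nan)
    return (float(np.median(values)), float(values.min()), float(values.max()))


def summarize_per_organ(table: pd.DataFrame) -> list[OrganSummary]:
    """Per-organ median and range of each metric over status-OK rows.

    The median of an even-count sample is the midpoint of the two central
    order statistics.  Organs with zero OK rows get NaN metrics but their
    delineation counts are still reported.  Row order never matters.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty cohort table")
    summaries: list[OrganSummary] = []
    for organ in sorted(table["organ"].unique()):
        sub = table[table["organ"] == organ]
        ok = sub[sub["status"] == Status.OK.value]
        dsc_med, dsc_lo, dsc_hi = _median_range(ok["dsc"].to_numpy(dtype=float))
        msd_med, msd_lo, msd_hi = _median_range(ok["msd_mm"].to_numpy(dtype=float))
        hd_med, hd_lo, hd_hi = _median_range(ok["hd95_mm"].to_numpy(dtype=float))
        delineated = sub["status"] != Status.NOT_DELINEATED.value
        groups = sorted(sub["group"].unique())
        summaries.append(
            OrganSummary(
                organ=organ,
                n_ok=int(len(ok)),
                dsc_median=dsc_med, dsc_range=(dsc_lo, dsc_hi),
                msd_median=msd_med, msd_range=(msd_lo, msd_hi),
                hd95_median=hd_med, hd95_range=(hd_lo, hd_hi),
                delineated_by_group={
                    g: int(delineated[sub["group"] == g].sum()) for g in groups
                },
                slots_by_group={g: int((sub["group"] == g).sum()) for g in groups},
            )
        )
    return summaries


def summaries_to_frame(summaries: list[OrganSummary]) -> pd.DataFrame:
    """Flatten organ summaries to a report table (one row per organ)."""
    rows = []
    for s in summaries:
        row = {
            "organ": s.organ,
            "n_ok": s.n_ok,
            "dsc_median": s.dsc_median,
            "dsc_min": s.dsc_range[0], "dsc_max": s.dsc_range[1],
            "msd_median_mm": s.msd_median,
            "msd_min_mm": s.msd_range[0], "msd_max_mm": s.msd_range[1],
            "hd95_median_mm": s.hd95_median,
            "hd95_min_mm": s.hd95_range[0], "hd95_max_mm": s.hd95_range[1],
        }
        for g in sorted(s.slots_by_group):
            row[f"n_delineated_{g}"] = s.delineated_by_group.get(g, 0)
            row[f"n_slots_{g}"] = s.slots_by_group[g]
        rows.append(row)
    return pd.DataFrame(rows)


def delineation_rate(table: pd.DataFrame, organ: str, group: str) -> float:
    """Fraction of (patient, observer) slots for ``organ`` in ``group`` that
    were delineated at all (an empty delineation still counts as delineated;
    an absent record does not)."""
    sub = table[(table["organ"] == organ) & (table["group"] == group)]
    if len(sub) == 0:
        raise ValueError(f"no slots for organ {organ!r} in group {group!r}")
    delineated = (sub["status"] != Status.NOT_DELINEATED.value).sum()
    return float(delineated) / float(len(sub))


def group_ttest(
    table: pd.DataFrame,
    metric: str = "MSD",
    unit: str = "PER_DELINEATION",
    *,
    test: str = "welch",
    groups: tuple[str, str] = ("ICG", "OTHER"),
) -> GroupComparison:
    """Two-sided independent t-test of one metric between observer groups.

    ``unit='PER_DELINEATION'`` pools every OK row of a group (every contour is
    one sample); ``unit='PER_OBSERVER'`` first averages each observer's rows
    and tests the observer means, removing the pseudo-replication of observers
    contributing many contours.  ``test`` selects Welch (unequal variances,
    default) or Student (pooled variance).
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(f"metric must be one of {sorted(METRIC_COLUMNS)}, got {metric!r}")
    if unit not in ("PER_DELINEATION", "PER_OBSERVER"):
        raise ValueError(f"unit must be PER_DELINEATION or PER_OBSERVER, got {unit!r}")
    if test not in ("welch", "student"):
        raise ValueError(f"test must be 'welch' or 'student', got {test!r}")
    column = METRIC_COLUMNS[metric]
    ok = table[table["status"] == Status.OK.value]

    samples: list[np.ndarray] = []
    for g in groups:
        sub = ok[ok["group"] == g]
        if unit == "PER_OBSERVER":
            values = sub.groupby("observer")[column].mean().to_numpy(dtype=float)
        else:
            values = sub[column].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        if values.size < 2:
            raise ValueError(
                f"group {g!r} has {values.size} defined {metric} value(s); >=2 required"
            )
        samples.append(values)

    a, b = samples
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    dof = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    return GroupComparison(
        metric=metric,
        unit=unit,
        test=test,
        mean_icg=float(a.mean()),
        mean_other=float(b.mean()),
        t_statistic=float(res.statistic),
        dof=dof,
        p_value=float(res.pvalue),
        n_icg=int(len(a)),
        n_other=int(len(b)),
    )
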