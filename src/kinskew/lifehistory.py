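"""Observational life-history computations.

Daily group-size interpolation, group-season mean-of-means summaries (each
group contributes one value regardless of how many seasons it was watched),
group-switch/dispersal tallies, pup survival proportions, and the equal-
opportunity null expectations for reproductive skew.

Dates are whole-day ISO dates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "interpolate_sizes",
    "weighted_group_size",
    "season_summaries",
    "switch_summary",
    "expected_skew",
    "survival_summary",
]


def interpolate_sizes(series: pd.DataFrame, method: str = "flank-mean") -> pd.DataFrame:
    """Fill unobserved days between observations of group size.

    ``series`` columns: group, date, size (dates strictly increasing within a
    group).  ``method='flank-mean'`` (default) fills each gap with the mean of
    the two flanking observations — constant across the gap; ``'linear'``
    ramps linearly instead.  Days outside the observed range are never
    imputed, and a single observation yields itself only.

    Returns columns group, date, size, interpolated.
    """
    if method not in ("flank-mean", "linear"):
        raise ValueError(f"unknown method {method!r}")
    out = []
    for group, sub in series.groupby("group", sort=False):
        sub = sub.copy()
        sub["date"] = pd.to_datetime(sub["date"])
        sub = sub.sort_values("date")
        if sub["date"].duplicated().any():
            raise ValueError(f"duplicate dates for group {group}")
        dates = sub["date"].to_numpy()
        sizes = sub["size"].to_numpy(dtype=float)
        for k in range(len(sub)):
            out.append((group, dates[k], sizes[k], False))
            if k + 1 < len(sub):
                gap = pd.date_range(dates[k], dates[k + 1], freq="D")[1:-1]
                if len(gap) == 0:
                    continue
                if method == "flank-mean":
                    fill = np.full(len(gap), (sizes[k] + sizes[k + 1]) / 2.0)
                else:
                    fill = np.linspace(sizes[k], sizes[k + 1], len(gap) + 2)[1:-1]
                out.extend((group, d, v, True) for d, v in zip(gap, fill))
    return pd.DataFrame(out, columns=["group", "date", "size", "interpolated"])


def weighted_group_size(daily: pd.DataFrame, start, end,
                        group: str | None = None) -> float:
    """Arithmetic mean of daily sizes over [start, end] (inclusive)."""
    sub = daily
    if group is not None:
        sub = sub[sub["group"] == group]
    dates = pd.to_datetime(sub["date"])
    mask = (dates >= pd.Timestamp(start)) & (dates <= pd.Timestamp(end))
    if not mask.any():
        raise ValueError("period does not overlap the daily series")
    return float(sub.loc[mask, "size"].mean())


def season_summaries(values: pd.DataFrame,
                     metric_col: str = "value") -> pd.DataFrame:
    """Mean-of-means debiasing: group-season value -> group mean -> grand mean.

    ``values`` columns: group, season, <metric_col> (optionally a ``metric``
    column for several metrics at once).  Each group contributes exactly one
    value to the grand mean, so a heavily observed group cannot dominate.
    Returns per metric: mean_of_means, se (across group means), n_groups.
    """
    frame = values.copy()
    if "metric" not in frame.columns:
        frame["metric"] = metric_col
    rows = []
    for metric, sub in frame.groupby("metric", sort=False):
        gmeans = sub.groupby("group")[metric_col].mean()
        gmeans = gmeans.dropna()
        n = len(gmeans)
        mean = float(gmeans.mean())
        se = float(gmeans.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append((metric, mean, se, n))
    return pd.DataFrame(rows, columns=["metric", "mean_of_means", "se", "n_groups"])


def switch_summary(events: pd.DataFrame) -> dict:
    """Dispersal report from a long-format switch table.

    ``events`` columns: event_id, individual_id, sex, date (optional),
    from_group, to_group.  An event with more than one individual is a
    coalition.  Returns counts by sex, coalition composition classes, monthly
    counts when dates are present, and the male fraction.
    """
    ev = events.copy()
    n_ind = len(ev)
    males = int((ev["sex"] == "M").sum())
    females = int((ev["sex"] == "F").sum())
    sizes = ev.groupby("event_id").size()
    coalition_events = sizes[sizes > 1]
    comp = {"all_male": 0, "all_female": 0, "mixed": 0}
    for event_id in coalition_events.index:
        sexes = set(ev.loc[ev["event_id"] == event_id, "sex"])
        if sexes == {"M"}:
            comp["all_male"] += 1
        elif sexes == {"F"}:
            comp["all_female"] += 1
        else:
            comp["mixed"] += 1
    report = {
        "n_individuals": n_ind,
        "n_events": int(sizes.size),
        "n_males": males,
        "n_females": females,
        "male_fraction": males / n_ind if n_ind else float("nan"),
        "n_single_events": int((sizes == 1).sum()),
        "n_coalition_events": int((sizes > 1).sum()),
        "coalition_composition": comp,
    }
    if "date" in ev.columns and ev["date"].notna().any():
        months = pd.to_datetime(ev["date"]).dt.month
        report["by_month"] = {int(mth): int(cnt)
                              for mth, cnt in months.value_counts().sort_index().items()}
    return report


@dataclass
class SkewExpectation:
    expected_dominant_maternity_pct: float
    expected_subordinate_paternity_pct: float
    expected_dominant_maternity_pct_truncated: int
    expected_subordinate_paternity_pct_truncated: int


def expected_skew(mean_pregnant_females: float,
                  mean_mating_males: float) -> SkewExpectation:
    """Null skew expectations if all breeders contribute equally.

    With exactly one dominant among the mean count of pregnant females, her
    expected offspring share is 1/mean; subordinate males' expected siring
    share is (mean - 1)/mean.  Truncated integer percentages are reported
    alongside the exact values.
    """
    if mean_pregnant_females < 1 or mean_mating_males < 1:
        raise ValueError("means must be >= 1 (the dominant is always counted)")
    dom = 100.0 / mean_pregnant_females
    sub = 100.0 * (mean_mating_males - 1.0) / mean_mating_males
    return SkewExpectation(dom, sub, int(dom), int(sub))


def survival_summary(pups: pd.DataFrame, survival_days: int = 365) -> dict:
    """Proportion of emerged pups surviving to ``survival_days``.

    ``pups`` columns: birth_date, emerged (bool), last_alive_date, emigrated
    (bool).  Reported both ways per the censoring caveat: ``uncensored``
    counts early emigrants as non-survivors; ``censored`` drops pups that
    emigrated before the cutoff from the denominator.
    """
    emerged = pups[pups["emerged"].astype(bool)].copy()
    n = len(emerged)
    if n == 0:
        return {"n_emerged": 0, "n_survived": 0,
                "pct_uncensored": float("nan"), "pct_censored": float("nan"),
                "note": "no emerged pups"}
    days = (pd.to_datetime(emerged["last_alive_date"])
            - pd.to_datetime(emerged["birth_date"])).dt.days
    survived = days >= survival_days
    emigrated_early = emerged["emigrated"].astype(bool) & ~survived
    n_surv = int(survived.sum())
    n_cens = int(emigrated_early.sum())
    return {
        "n_emerged": n,
        "n_survived": n_surv,
        "n_censored": n_cens,
        "pct_uncensored": 100.0 * n_surv / n,
        "pct_censored": 100.0 * n_surv / (n - n_cens) if n > n_cens else float("nan"),
    }
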