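"""Lifestyle-change features from daily diet and activity diaries.

Deltas are observation-period minus baseline-period means of daily totals:
carbohydrate g/day, fat g/day, exercise kcal/day. A participant's activity
class is a median split of the delta matched to their modification group,
'active' meaning the guidance-adherent side.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from grslife.synthetic import DIET_GROUPS, EXERCISE_GROUPS

DateWindow = tuple  # (start, end), inclusive


def _normalize_window(window: DateWindow) -> tuple[pd.Timestamp, pd.Timestamp]:
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if start > end:
        raise ValueError(f"window start {start} after end {end}")
    return start, end


def _daily_totals(df: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"])
    return (
        out.groupby(["participant_id", "date"], sort=True)[value_cols]
        .sum()
        .reset_index()
    )


def _window_stats(
    daily: pd.DataFrame, window: tuple[pd.Timestamp, pd.Timestamp], value_cols
) -> pd.DataFrame:
    start, end = window
    sel = daily[(daily["date"] >= start) & (daily["date"] <= end)]
    agg = sel.groupby("participant_id").agg(
        **{c: (c, "mean") for c in value_cols}, n_days=("date", "nunique")
    )
    return agg


def compute_lifestyle_delta(
    diet: pd.DataFrame,
    activity: pd.DataFrame,
    baseline_window: DateWindow,
    observation_window: DateWindow,
    min_days: int = 7,
    participants: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-participant lifestyle deltas with per-diary coverage flags.

    Parameters
    ----------
    diet, activity
        Diary tables (``participant_id, date, meal, carb_g, fat_g,
        protein_g, kcal`` and ``participant_id, date, kcal_expended,
        minutes, intensity_frac``).
    baseline_window, observation_window
        Inclusive ``(start, end)`` date pairs; must be disjoint with the
        baseline first.
    min_days
        Minimum distinct diary days required in *each* window for the
        corresponding deltas to count as covered.
    participants
        Optional id list; any listed participant absent from both diaries
        raises.

    Returns
    -------
    pandas.DataFrame
        Columns ``participant_id, delta_c, delta_f, delta_e,
        n_baseline_days, n_observation_days, n_baseline_days_activity,
        n_observation_days_activity, diet_ok, activity_ok, included``.
        Day-count columns without a suffix refer to the diet diary.
    """
    base = _normalize_window(baseline_window)
    obs = _normalize_window(observation_window)
    if base[1] >= obs[0]:
        raise ValueError("baseline window must end before the observation window")
    if min_days < 1:
        raise ValueError("min_days must be >= 1")

    diet_daily = _daily_totals(diet, ["carb_g", "fat_g"])
    act_daily = _daily_totals(activity, ["kcal_expended"])

    ids = sorted(
        set(diet_daily["participant_id"]) | set(act_daily["participant_id"])
    )
    if participants is not None:
        requested = list(participants)
        absent = sorted(set(requested) - set(ids))
        if absent:
            raise ValueError(
                f"participants absent from both diaries: {absent[:10]}"
            )
        ids = requested

    db = _window_stats(diet_daily, base, ["carb_g", "fat_g"]).reindex(ids)
    do = _window_stats(diet_daily, obs, ["carb_g", "fat_g"]).reindex(ids)
    ab = _window_stats(act_daily, base, ["kcal_expended"]).reindex(ids)
    ao = _window_stats(act_daily, obs, ["kcal_expended"]).reindex(ids)

    n_db = db["n_days"].fillna(0).astype(int)
    n_do = do["n_days"].fillna(0).astype(int)
    n_ab = ab["n_days"].fillna(0).astype(int)
    n_ao = ao["n_days"].fillna(0).astype(int)
    out = pd.DataFrame(
        {
            "participant_id": ids,
            "delta_c": (do["carb_g"] - db["carb_g"]).to_numpy(),
            "delta_f": (do["fat_g"] - db["fat_g"]).to_numpy(),
            "delta_e": (ao["kcal_expended"] - ab["kcal_expended"]).to_numpy(),
            "n_baseline_days": n_db.to_numpy(),
            "n_observation_days": n_do.to_numpy(),
            "n_baseline_days_activity": n_ab.to_numpy(),
            "n_observation_days_activity": n_ao.to_numpy(),
        }
    )
    out["diet_ok"] = (out["n_baseline_days"] >= min_days) & (
        out["n_observation_days"] >= min_days
    )
    out["activity_ok"] = (out["n_baseline_days_activity"] >= min_days) & (
        out["n_observation_days_activity"] >= min_days
    )
    out["included"] = out["diet_ok"] & out["activity_ok"]
    return out


def classify_activity(
    deltas: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> pd.Series:
    """Active/inactive label per participant by within-group median split.

    Low-carb splits on delta_c, low-fat on delta_f (active = at or below the
    median, i.e. the larger decrease); exercise groups split on delta_e
    (active = at or above the median). Exact-median ties go to 'active'.
    A group whose deltas are all identical is labelled all-'inactive' with a
    warning. Participants with a missing group-matched delta get NaN.
    """
    groups = pd.Series(groups)
    labels = pd.Series(
        np.nan, index=deltas["participant_id"], dtype=object, name="activity_class"
    )
    metric_col = {
        "low_carb": "delta_c",
        "low_fat": "delta_f",
        "moderate_exercise": "delta_e",
        "intense_exercise": "delta_e",
    }
    d = deltas.set_index("participant_id")
    for grp, members in groups.groupby(groups):
        ids = members.index.intersection(d.index)
        if grp not in metric_col:
            raise ValueError(f"unknown modification group: {grp!r}")
        vals = d.loc[ids, metric_col[grp]]
        obs = vals.dropna()
        if len(obs) < 2:
            raise ValueError(f"group {grp!r} needs >= 2 participants with deltas")
        if obs.nunique() == 1:
            warnings.warn(
                f"group {grp!r}: all deltas identical; labelling all inactive",
                stacklevel=2,
            )
            labels.loc[obs.index] = "inactive"
            continue
        med = float(np.median(obs))
        if grp in DIET_GROUPS:
            active = obs <= med
        else:
            active = obs >= med
        labels.loc[obs.index] = np.where(active, "active", "inactive")
    return labels


def weekly_pppw(
    diet: pd.DataFrame,
    activity: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_baseline_weeks: int = 0,
    start_date=None,
) -> pd.DataFrame:
    """Per-person-per-week group means for carb g, fat g, kcal expended.

    Weeks are contiguous 7-day blocks anchored at the first study date
    (``start_date`` or the earliest date in either diary). Each week's value
    is the mean over participants of their within-week daily-total mean;
    participants contribute only to weeks where they have records.

    Returns a long table ``group, week, measure, pppw, n_participants,
    is_baseline``; weeks with index < n_baseline_weeks are flagged baseline.
    """
    groups = pd.Series(groups, name="group")
    diet_daily = _daily_totals(diet, ["carb_g", "fat_g"])
    act_daily = _daily_totals(activity, ["kcal_expended"])
    if start_date is None:
        candidates = []
        if len(diet_daily):
            candidates.append(diet_daily["date"].min())
        if len(act_daily):
            candidates.append(act_daily["date"].min())
        if not candidates:
            return pd.DataFrame(
                columns=["group", "week", "measure", "pppw", "n_participants", "is_baseline"]
            )
        start = min(candidates)
    else:
        start = pd.Timestamp(start_date)

    frames = []
    for daily, measures in ((diet_daily, ["carb_g", "fat_g"]), (act_daily, ["kcal_expended"])):
        if not len(daily):
            continue
        daily = daily.copy()
        daily["week"] = (daily["date"] - start).dt.days // 7
        daily = daily.merge(
            groups.rename_axis("participant_id").reset_index(),
            on="participant_id",
            how="inner",
        )
        person_week = daily.groupby(["group", "week", "participant_id"], sort=True)[
            measures
        ].mean()
        for mcol in measures:
            agg = person_week[mcol].groupby(["group", "week"]).agg(["mean", "count"])
            frames.append(
                pd.DataFrame(
                    {
                        "group": agg.index.get_level_values("group"),
                        "week": agg.index.get_level_values("week"),
                        "measure": mcol,
                        "pppw": agg["mean"].to_numpy(),
                        "n_participants": agg["count"].to_numpy(),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out["is_baseline"] = out["week"] < n_baseline_weeks
    return out.sort_values(["measure", "group", "week"]).reset_index(drop=True)
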