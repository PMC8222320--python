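"""GRS stratification, multiple-testing adjustment, and the testing layer.

The cutoff search scans midpoints between consecutive distinct scores and
keeps the split maximizing the between-class difference in mean BFM change
(or the Welch |t|), subject to a minimum class size; the three high/low
comparisons are then adjusted with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_CLASS_FLOOR = 10


def default_min_class_size(n: int) -> int:
    """max(10, 10% of the cohort), the stratification floor."""
    return max(MIN_CLASS_FLOOR, int(np.ceil(0.10 * n)))


@dataclass
class StratificationResult:
    """One high/low split of a GRS with its two-sample comparison."""

    grs_type: str
    cutoff: float
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    t_stat: float
    p_value: float
    q_value: float = np.nan
    criterion: str = "mean_diff"
    labels: pd.Series = field(default=None, repr=False)  # 'high'/'low' per pid


@dataclass
class FourGroupResult:
    """One-way ANOVA of BFM change over GRS class x activity class cells."""

    grs_type: str
    cell_means: dict[str, float]
    cell_sizes: dict[str, int]
    f_stat: float
    p_value: float


def _as_series(values) -> pd.Series:
    """Float Series preserving an existing index (participant ids)."""
    if isinstance(values, pd.Series):
        return values.astype(float)
    return pd.Series(np.asarray(values, dtype=float))


def _align(scores: pd.Series, dbfm: pd.Series) -> tuple[pd.Series, pd.Series]:
    if not scores.index.equals(dbfm.index):
        if len(scores) != len(dbfm):
            raise ValueError("scores and delta_bfm lengths differ")
        dbfm = pd.Series(dbfm.to_numpy(), index=scores.index)
    return scores, dbfm


def _welch(high: np.ndarray, low: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(high, low, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def find_cutoff(
    scores: Sequence[float],
    delta_bfm: Sequence[float],
    min_class_size: int | None = None,
    criterion: str = "mean_diff",
    grs_type: str = "",
) -> StratificationResult:
    """Data-driven high/low split maximizing the between-class BFM contrast.

    Candidate cutoffs are midpoints between consecutive distinct sorted
    scores; 'high' means score > cutoff. Among candidates leaving both
    classes at least ``min_class_size`` strong, the one maximizing
    |mean(high) - mean(low)| (``mean_diff``) or the Welch |t| (``t_stat``)
    wins; exact ties go to the cutoff nearest the score median, then to the
    smaller cutoff. The Welch t-test for the chosen split is reported.
    """
    if criterion not in ("mean_diff", "t_stat"):
        raise ValueError(f"criterion must be 'mean_diff' or 't_stat', got {criterion!r}")
    scores, dbfm = _align(_as_series(scores), _as_series(delta_bfm))
    ok = scores.notna() & dbfm.notna()
    s = scores[ok].to_numpy()
    y = dbfm[ok].to_numpy()
    n = len(s)
    if min_class_size is None:
        min_class_size = default_min_class_size(n)
    if min_class_size < 1:
        raise ValueError("min_class_size must be >= 1")
    if n < 2 * min_class_size:
        raise ValueError(
            f"need >= {2 * min_class_size} participants, got {n}"
        )
    distinct = np.unique(s)
    if len(distinct) < 2:
        raise ValueError("fewer than 2 distinct scores; cannot stratify")

    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    median = float(np.median(s))
    best = None  # (objective, -|cutoff-median| handled explicitly)
    for cut in candidates:
        hi = s > cut
        n_hi = int(hi.sum())
        n_lo = n - n_hi
        if n_hi < min_class_size or n_lo < min_class_size:
            continue
        if criterion == "mean_diff":
            obj = abs(y[hi].mean() - y[~hi].mean())
        else:
            t, _ = _welch(y[hi], y[~hi])
            obj = abs(t)
        if not np.isfinite(obj):
            obj = 0.0
        cand = (obj, cut)
        if best is None:
            best = cand
            continue
        if cand[0] > best[0] + 1e-12:
            best = cand
        elif abs(cand[0] - best[0]) <= 1e-12:
            d_new = abs(cut - median)
            d_old = abs(best[1] - median)
            if d_new < d_old - 1e-12 or (
                abs(d_new - d_old) <= 1e-12 and cut < best[1]
            ):
                best = cand
    if best is None:
        raise ValueError(
            f"no candidate cutoff satisfies min_class_size={min_class_size}"
        )
    return stratify_at(
        scores, dbfm, best[1], grs_type=grs_type, criterion=criterion
    )


def stratify_at(
    scores: Sequence[float],
    delta_bfm: Sequence[float],
    cutoff: float,
    grs_type: str = "",
    criterion: str = "fixed",
) -> StratificationResult:
    """Split at a fixed cutoff (high = score > cutoff) and run the Welch test."""
    scores, dbfm = _align(_as_series(scores), _as_series(delta_bfm))
    ok = scores.notna() & dbfm.notna()
    s, y = scores[ok].to_numpy(), dbfm[ok].to_numpy()
    hi = s > cutoff
    if hi.sum() == 0 or (~hi).sum() == 0:
        raise ValueError(f"cutoff {cutoff} leaves an empty class")
    t, p = _welch(y[hi], y[~hi])
    labels = pd.Series(np.nan, index=scores.index, dtype=object, name="grs_class")
    labels[ok] = np.where(hi, "high", "low")
    return StratificationResult(
        grs_type=grs_type,
        cutoff=float(cutoff),
        n_high=int(hi.sum()),
        n_low=int((~hi).sum()),
        mean_high=float(y[hi].mean()),
        mean_low=float(y[~hi].mean()),
        t_stat=t,
        p_value=p,
        criterion=criterion,
        labels=labels,
    )


def stratify_at_median(scores, delta_bfm, grs_type: str = "") -> StratificationResult:
    """Median split (selection-free reference for the optimized cutoff).

    Uses the candidate midpoint nearest the score median so both classes are
    guaranteed non-empty even when scores tie heavily at the median.
    """
    s = pd.Series(np.asarray(scores, dtype=float)).dropna().to_numpy()
    distinct = np.unique(s)
    if len(distinct) < 2:
        raise ValueError("fewer than 2 distinct scores; cannot stratify")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    cutoff = candidates[np.argmin(np.abs(candidates - np.median(s)))]
    return stratify_at(
        scores, delta_bfm, float(cutoff), grs_type=grs_type, criterion="median"
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def stratify_all(
    scores: pd.DataFrame,
    delta_bfm: pd.Series,
    min_class_size: int | None = None,
    criterion: str = "mean_diff",
    method: str = "optimize",
) -> list[StratificationResult]:
    """Stratify GRS-C/F/E and BH-adjust the three comparisons jointly.

    ``scores`` carries participant_id plus grs_c/grs_f/grs_e columns;
    ``delta_bfm`` is indexed by participant_id. ``method='median'`` replaces
    the cutoff search with a fixed median split.
    """
    if method not in ("optimize", "median"):
        raise ValueError(f"method must be 'optimize' or 'median', got {method!r}")
    sc = scores.set_index("participant_id") if "participant_id" in scores.columns else scores
    results = []
    for grs_type in ("C", "F", "E"):
        col = f"grs_{grs_type.lower()}"
        aligned = pd.concat(
            [sc[col], delta_bfm.rename("delta_bfm")], axis=1, join="inner"
        )
        if method == "optimize":
            res = find_cutoff(
                aligned[col],
                aligned["delta_bfm"],
                min_class_size=min_class_size,
                criterion=criterion,
                grs_type=grs_type,
            )
        else:
            res = stratify_at_median(
                aligned[col], aligned["delta_bfm"], grs_type=grs_type
            )
        results.append(res)
    qvals = fdr_adjust([r.p_value for r in results])
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    return results


CELL_ORDER = ("high-active", "high-inactive", "low-active", "low-inactive")


def four_group_anova(
    grs_labels: Mapping[str, str] | pd.Series,
    activity_labels: Mapping[str, str] | pd.Series,
    delta_bfm: Mapping[str, float] | pd.Series,
    grs_type: str = "",
) -> FourGroupResult:
    """One-way fixed-effects ANOVA of BFM change over the four combination cells."""
    df = pd.concat(
        [
            pd.Series(grs_labels, name="grs_class"),
            pd.Series(activity_labels, name="activity_class"),
            pd.Series(delta_bfm, name="delta_bfm"),
        ],
        axis=1,
        join="inner",
    ).dropna()
    df["cell"] = df["grs_class"].astype(str) + "-" + df["activity_class"].astype(str)
    groups = {c: df.loc[df["cell"] == c, "delta_bfm"].to_numpy() for c in CELL_ORDER}
    empty = [c for c, v in groups.items() if len(v) == 0]
    if empty:
        raise ValueError(f"empty cell(s): {empty}")

    values = [groups[c] for c in CELL_ORDER]
    n = sum(len(v) for v in values)
    k = len(values)
    grand = np.concatenate(values).mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in values)
    dfb, dfw = k - 1, n - k
    if ssw == 0.0:
        f_stat, p = (0.0, 1.0) if ssb == 0.0 else (np.inf, 0.0)
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f_stat, dfb, dfw))
    return FourGroupResult(
        grs_type=grs_type,
        cell_means={c: float(v.mean()) for c, v in groups.items()},
        cell_sizes={c: int(len(v)) for c, v in groups.items()},
        f_stat=float(f_stat),
        p_value=float(p),
    )


# variable name -> (pre column, post column), in report order
PREPOST_VARIABLES = {
    "weight_kg": ("weight_pre", "weight_post"),
    "body_fat_mass_kg": ("bfm_pre", "bfm_post"),
    "body_fat_pct": ("bfp_pre", "bfp_post"),
    "bmi": ("bmi_pre", "bmi_post"),
    "skeletal_muscle_mass_kg": ("smm_pre", "smm_post"),
    "waist_hip_ratio": ("whr_pre", "whr_post"),
    "triglycerides_mg_dl": ("tg_pre", "tg_post"),
    "ldl_mg_dl": ("ldl_pre", "ldl_post"),
    "hdl_mg_dl": ("hdl_pre", "hdl_post"),
}


def paired_prepost_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Pre/post summary with two-sided paired t-tests, one row per variable.

    A variable with fewer than 2 complete pairs is reported as NA (with a
    warning); identical pre/post vectors give t = 0, p = 1.
    """
    rows = []
    for var, (pre_col, post_col) in PREPOST_VARIABLES.items():
        if pre_col not in pheno.columns or post_col not in pheno.columns:
            continue
        pair = pheno[[pre_col, post_col]].dropna()
        pre = pair[pre_col].to_numpy(dtype=float)
        post = pair[post_col].to_numpy(dtype=float)
        diff = post - pre
        n = len(diff)
        if n < 2:
            warnings.warn(f"{var}: fewer than 2 complete pairs, reporting NA",
                          stacklevel=2)
            rows.append(
                dict(variable=var, n=n, mean_pre=np.nan, sd_pre=np.nan,
                     mean_post=np.nan, sd_post=np.nan, mean_diff=np.nan,
                     sd_diff=np.nan, t_stat=np.nan, p_value=np.nan)
            )
            continue
        sd_diff = diff.std(ddof=1)
        if sd_diff == 0.0:
            t = 0.0 if diff.mean() == 0.0 else np.inf * np.sign(diff.mean())
            p = 1.0 if diff.mean() == 0.0 else 0.0
        else:
            res = stats.ttest_rel(post, pre)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            dict(
                variable=var,
                n=n,
                mean_pre=pre.mean(),
                sd_pre=pre.std(ddof=1),
                mean_post=post.mean(),
                sd_post=post.std(ddof=1),
                mean_diff=diff.mean(),
                sd_diff=sd_diff,
                t_stat=t,
                p_value=p,
            )
        )
    return pd.DataFrame(rows)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t-test (continuous group comparisons)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std(ddof=0) == 0.0 and y.std(ddof=0) == 0.0:
        raise ValueError("zero-variance continuous input in both groups")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def chi2_test(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared test without continuity correction."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("contingency table has an all-zero row or column")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
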