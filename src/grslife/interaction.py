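"""Per-SNP gene-environment interaction regressions and GRS panel building.

Two OLS model families per SNP, both with gender, age, age^2 covariates:

* diet:     dBFM ~ 1 + gender + age + age^2 + g + dC + dF + g*dC + g*dF
* exercise: dBFM ~ 1 + gender + age + age^2 + g + dE + g*dE

where ``g`` is the minor-allele dosage. The interaction coefficients (with
standard errors and two-sided p-values) become the GRS weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from grslife.qc import GenotypeMatrix

MIN_COMPLETE_CASES = 10

COVARIATE_BASE = ["gender", "age"]


@dataclass
class InteractionWeight:
    """Fitted interaction coefficients for one SNP under one model family."""

    snp_id: str
    model: str  # 'diet' or 'exercise'
    beta_c: float = np.nan
    beta_f: float = np.nan
    beta_e: float = np.nan
    se_c: float = np.nan
    se_f: float = np.nan
    se_e: float = np.nan
    p_c: float = np.nan
    p_f: float = np.nan
    p_e: float = np.nan
    n_used: int = 0
    skipped: bool = False
    reason: str | None = None


@dataclass
class PanelEntry:
    snp_id: str
    weight: float
    risk_allele: str


@dataclass
class GrsPanel:
    """Ordered SNP panel for one GRS type; weight = signed interaction beta."""

    grs_type: str  # 'C', 'F', or 'E'
    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.snp_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate snp_ids in panel {self.grs_type}")

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    def to_records(self) -> list[dict]:
        return [
            {"snp_id": e.snp_id, "weight": e.weight, "risk_allele": e.risk_allele}
            for e in self.entries
        ]


def build_covariates(
    phenotypes: pd.DataFrame, deltas: pd.DataFrame
) -> pd.DataFrame:
    """Model covariate table indexed by participant_id.

    Combines sex/age from the phenotype table with lifestyle deltas and
    derives ``delta_bfm = bfm_post - bfm_pre``.
    """
    pheno = phenotypes
    if "participant_id" in pheno.columns:
        pheno = pheno.set_index("participant_id")
    d = deltas
    if "participant_id" in d.columns:
        d = d.set_index("participant_id")
    cov = d[["delta_c", "delta_f", "delta_e"]].copy()
    cov["gender"] = pheno["sex"]
    cov["age"] = pheno["age"].astype(float)
    cov["delta_bfm"] = pheno["bfm_post"] - pheno["bfm_pre"]
    return cov


def _design(
    dosage: np.ndarray, covariates: pd.DataFrame, delta_cols: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Complete-case design matrix; returns (X, y, n_used)."""
    g = np.asarray(dosage, dtype=float)
    if g.shape[0] != len(covariates):
        raise ValueError(
            f"dosage length {g.shape[0]} != covariate rows {len(covariates)}"
        )
    cols = {"gender": covariates["gender"].to_numpy(dtype=float)}
    age = covariates["age"].to_numpy(dtype=float)
    cols["age"] = age
    cols["age_sq"] = age**2
    for c in delta_cols:
        cols[c] = covariates[c].to_numpy(dtype=float)
    y = covariates["delta_bfm"].to_numpy(dtype=float)

    X_parts = [np.ones_like(g), cols["gender"], cols["age"], cols["age_sq"], g]
    names = ["const", "gender", "age", "age_sq", "dosage"]
    for c in delta_cols:
        X_parts.append(cols[c])
        names.append(c)
    for c in delta_cols:
        X_parts.append(g * cols[c])
        names.append(f"dosage:{c}")
    X = np.column_stack(X_parts)

    ok = np.isfinite(X).all(axis=1) & np.isfinite(y)
    return X[ok], y[ok], int(ok.sum())


def _fit(
    snp_id: str,
    model: str,
    dosage: np.ndarray,
    covariates: pd.DataFrame,
    delta_cols: Sequence[str],
) -> InteractionWeight:
    X, y, n_used = _design(dosage, covariates, delta_cols)
    if n_used < MIN_COMPLETE_CASES:
        raise ValueError(
            f"{snp_id}: {n_used} complete cases < required {MIN_COMPLETE_CASES}"
        )
    g_col = X[:, 4]
    if np.ptp(g_col) == 0:
        return InteractionWeight(
            snp_id=snp_id, model=model, n_used=n_used, skipped=True,
            reason="constant dosage",
        )
    # a demographic covariate constant in this sub-cohort is absorbed by the
    # intercept; drop it instead of declaring the fit rank-deficient
    keep = [
        j
        for j in range(X.shape[1])
        if j not in (1, 2, 3) or np.ptp(X[:, j]) > 0
    ]
    X = X[:, keep]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return InteractionWeight(
            snp_id=snp_id, model=model, n_used=n_used, skipped=True,
            reason="rank-deficient design",
        )
    res = sm.OLS(y, X).fit()
    k = len(delta_cols)
    betas = res.params[-k:]
    ses = res.bse[-k:]
    ps = res.pvalues[-k:]
    w = InteractionWeight(snp_id=snp_id, model=model, n_used=n_used)
    for name, b, s, p in zip(delta_cols, betas, ses, ps):
        suffix = {"delta_c": "c", "delta_f": "f", "delta_e": "e"}[name]
        setattr(w, f"beta_{suffix}", float(b))
        setattr(w, f"se_{suffix}", float(s))
        setattr(w, f"p_{suffix}", float(p))
    return w


def fit_diet_model(
    dosage: np.ndarray, covariates: pd.DataFrame, snp_id: str = "snp"
) -> InteractionWeight:
    """OLS of dBFM on covariates, dosage, dC, dF and both interactions.

    ``covariates`` needs columns gender, age, delta_c, delta_f, delta_bfm
    (age^2 is derived). Rows with any missing value are dropped; fewer than
    10 complete cases raises; a constant-dosage or rank-deficient design is
    returned skipped with a reason.
    """
    return _fit(snp_id, "diet", dosage, covariates, ["delta_c", "delta_f"])


def fit_exercise_model(
    dosage: np.ndarray, covariates: pd.DataFrame, snp_id: str = "snp"
) -> InteractionWeight:
    """OLS of dBFM on covariates, dosage, dE and the dosage x dE interaction."""
    return _fit(snp_id, "exercise", dosage, covariates, ["delta_e"])


def fit_panel_models(
    gm: GenotypeMatrix,
    covariates: pd.DataFrame,
    model: str,
    participant_ids: Iterable[str] | None = None,
) -> list[InteractionWeight]:
    """Fit one model family for every SNP in ``gm``.

    ``covariates`` is indexed by participant_id (or carries that column);
    ``participant_ids`` optionally restricts fitting to a sub-cohort (e.g.
    the modification groups whose BFM the model describes). SNPs violating
    the complete-case floor are returned skipped rather than raising, so one
    bad SNP cannot abort a panel fit.
    """
    if model not in ("diet", "exercise"):
        raise ValueError(f"model must be 'diet' or 'exercise', got {model!r}")
    cov = covariates
    if "participant_id" in cov.columns:
        cov = cov.set_index("participant_id")
    if participant_ids is not None:
        cov = cov.loc[[p for p in participant_ids if p in cov.index]]
    dframe = gm.dosage_frame().reindex(cov.index)
    fitter = fit_diet_model if model == "diet" else fit_exercise_model
    out = []
    for snp_id in dframe.columns:
        try:
            out.append(fitter(dframe[snp_id].to_numpy(), cov, snp_id=snp_id))
        except ValueError as exc:
            out.append(
                InteractionWeight(
                    snp_id=snp_id, model=model, skipped=True, reason=str(exc)
                )
            )
    return out


def weights_frame(weights: Iterable[InteractionWeight]) -> pd.DataFrame:
    """Tabular view of fitted weights (one row per SNP x model)."""
    return pd.DataFrame([vars(w) for w in weights])


_PANEL_FIELDS = {
    "C": ("diet", "beta_c", "p_c"),
    "F": ("diet", "beta_f", "p_f"),
    "E": ("exercise", "beta_e", "p_e"),
}


def build_panels(
    weights: Iterable[InteractionWeight],
    panel_sizes: tuple[int, int, int] = (37, 19, 25),
    selection_rule: str = "min_p",
    risk_alleles: Mapping[str, str] | None = None,
) -> dict[str, GrsPanel]:
    """Select the C/F/E scoring panels from fitted interaction weights.

    Default (and only) rule: smallest interaction p-value first, ties broken
    by lexical snp_id. Panel sizes are exact; insufficient usable SNPs raise.
    ``risk_alleles`` maps snp_id to the reported risk (minor) allele.
    """
    if selection_rule != "min_p":
        raise ValueError(f"unknown selection_rule: {selection_rule!r}")
    if len(panel_sizes) != 3 or any(s < 0 for s in panel_sizes):
        raise ValueError("panel_sizes must be three non-negative counts")
    weights = list(weights)
    risk_alleles = risk_alleles or {}
    panels: dict[str, GrsPanel] = {}
    for grs_type, size in zip(("C", "F", "E"), panel_sizes):
        model, beta_attr, p_attr = _PANEL_FIELDS[grs_type]
        usable = [
            w
            for w in weights
            if w.model == model and not w.skipped and np.isfinite(getattr(w, p_attr))
        ]
        if len(usable) < size:
            raise ValueError(
                f"panel {grs_type}: need {size} SNPs, only {len(usable)} usable"
            )
        usable.sort(key=lambda w: (getattr(w, p_attr), w.snp_id))
        panels[grs_type] = GrsPanel(
            grs_type=grs_type,
            entries=[
                PanelEntry(
                    snp_id=w.snp_id,
                    weight=float(getattr(w, beta_attr)),
                    risk_allele=risk_alleles.get(w.snp_id, "NA"),
                )
                for w in usable[:size]
            ],
        )
    return panels
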