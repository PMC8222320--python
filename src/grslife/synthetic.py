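"""Synthetic cohort generator with planted gene-environment interactions.

Produces genotypes (bi-allelic autosomal SNPs near HWE), daily diet and
activity diaries over a baseline + observation period with group-specific
lifestyle shifts, and pre/post phenotypes whose body-fat-mass change is the
forward run of the two per-SNP interaction models plus Gaussian noise.
A truth channel records planted coefficients and noise-free signals so
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from grslife import qc
from grslife.qc import GenotypeMatrix, SNP_META_COLUMNS

GROUPS = ("low_carb", "low_fat", "moderate_exercise", "intense_exercise")
DIET_GROUPS = ("low_carb", "low_fat")
EXERCISE_GROUPS = ("moderate_exercise", "intense_exercise")

#: fixed generative coefficients for the non-genetic part of the BFM model
COVARIATE_COEF = {
    "intercept": 0.0,
    "gender": 0.3,
    "age": 0.02,
    "age_sq": -2.0e-4,
    "delta_c": 0.01,
    "delta_f": 0.01,
    "delta_e": -0.005,
}

PHENOTYPE_COLUMNS = [
    "participant_id",
    "sex",
    "age",
    "group",
    "weight_pre",
    "weight_post",
    "bfm_pre",
    "bfm_post",
    "bfp_pre",
    "bfp_post",
    "bmi_pre",
    "bmi_post",
    "smm_pre",
    "smm_post",
    "whr_pre",
    "whr_post",
    "tg_pre",
    "tg_post",
    "ldl_pre",
    "ldl_post",
    "hdl_pre",
    "hdl_post",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Group proportions default to the 35/34/99/83 split over the four
    modification arms; lifestyle shift means default to the observed
    magnitudes (carbohydrate -24.1 g/day, fat -16.87 g/day, exercise
    +22.75 / +31.21 kcal/day).
    """

    n_participants: int = 259
    n_snps: int = 90
    panel_sizes: tuple[int, int, int] = (37, 19, 25)
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.002
    group_proportions: tuple[float, float, float, float] = (
        35 / 251,
        34 / 251,
        99 / 251,
        83 / 251,
    )
    baseline_weeks: int = 2
    observation_weeks: int = 12
    # per-allele interaction effects (kg BFM per unit delta per minor allele);
    # positive diet betas make intake cuts shrink BFM in carriers, the
    # negative exercise beta makes extra expenditure shrink it
    beta_c: float = 0.01
    beta_f: float = 0.01
    beta_e: float = -0.005
    noise_sd: float = 1.0
    seed: int = 0
    # dispersion / realism knobs (free parameters; not pinned by the study)
    shift_carb: float = -24.1
    shift_fat: float = -16.87
    shift_kcal_moderate: float = 22.75
    shift_kcal_intense: float = 31.21
    shift_sd: float = 10.0
    meal_sd: float = 8.0
    activity_sd: float = 60.0
    female_fraction: float = 0.224
    age_range: tuple[int, int] = (23, 67)
    inbreeding: float = 0.0  # test hook: >0 plants excess homozygosity
    start_date: str = "2016-06-06"

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_snps < 1:
            raise ValueError("n_participants and n_snps must be >= 1")
        if self.baseline_weeks < 1 or self.observation_weeks < 1:
            raise ValueError("baseline_weeks and observation_weeks must be >= 1")
        if len(self.panel_sizes) != 3 or any(s < 0 for s in self.panel_sizes):
            raise ValueError("panel_sizes must be three non-negative counts")
        if sum(self.panel_sizes) > self.n_snps:
            raise ValueError(
                f"panel sizes {self.panel_sizes} exceed n_snps={self.n_snps}"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.group_proportions) != len(GROUPS):
            raise ValueError("group_proportions must have four entries")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"group_proportions must sum to 1, got {sum(self.group_proportions)}"
            )
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding must be in [0, 1]")


@dataclass
class SyntheticCohort:
    """Bundle of generated data plus the planted truth channel."""

    config: CohortConfig
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    diet_log: pd.DataFrame
    activity_log: pd.DataFrame
    truth_panel: pd.DataFrame  # snp_id, grs_type, beta (stored orientation)
    truth_participants: pd.DataFrame  # participant_id, true deltas, signal
    truth_allele_freq: pd.Series = field(default=None)  # drawn minor-allele p
    baseline_window: tuple[pd.Timestamp, pd.Timestamp] = field(default=None)
    observation_window: tuple[pd.Timestamp, pd.Timestamp] = field(default=None)

    def save(self, out_dir: str | Path) -> dict[str, str]:
        """Write all components in the pipeline's input formats."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes_vcf": out_dir / "genotypes.vcf",
            "genotypes_traw": out_dir / "genotypes.traw",
            "phenotypes": out_dir / "phenotypes.csv",
            "diet": out_dir / "diet.csv",
            "activity": out_dir / "activity.csv",
            "truth_panel": out_dir / "truth_panel.tsv",
            "truth_participants": out_dir / "truth_participants.tsv",
        }
        qc.write_vcf(self.genotypes, paths["genotypes_vcf"])
        qc.write_traw(self.genotypes, paths["genotypes_traw"])
        self.phenotypes.to_csv(paths["phenotypes"], index=False)
        self.diet_log.to_csv(paths["diet"], index=False)
        self.activity_log.to_csv(paths["activity"], index=False)
        self.truth_panel.to_csv(paths["truth_panel"], sep="\t", index=False)
        self.truth_participants.to_csv(
            paths["truth_participants"], sep="\t", index=False
        )
        return {k: str(v) for k, v in paths.items()}


def _group_assignment(n: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Deterministic largest-remainder allocation of n participants to groups."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return np.repeat(np.arange(len(proportions)), counts)


def _draw_genotypes(
    rng: np.random.Generator, n: int, m: int, p: np.ndarray, inbreeding: float
) -> np.ndarray:
    """ALT-count genotypes; inbreeding > 0 shifts mass from hets to homozygotes."""
    if inbreeding == 0.0:
        return rng.binomial(2, p[None, :], size=(n, m)).astype(float)
    f = inbreeding
    p_hom_ref = (1 - p) ** 2 + f * p * (1 - p)
    p_het = 2 * p * (1 - p) * (1 - f)
    u = rng.random((n, m))
    g = np.full((n, m), 2.0)
    g[u < p_hom_ref + p_het] = 1.0
    g[u < p_hom_ref] = 0.0
    return g


def synthesize_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full cohort under ``config``; identical seed, identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pids = [f"P{i + 1:05d}" for i in range(n)]

    # --- genotypes ------------------------------------------------------
    m = config.n_snps
    p_alt = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    g_alt = _draw_genotypes(rng, n, m, p_alt, config.inbreeding)

    ref_alt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:05d}" for i in range(m)],
            "chrom": [str(i % 22 + 1) for i in range(m)],
            "pos": [1_000_000 + 137 * i for i in range(m)],
            "ref": [ref_alt[i % 4][0] for i in range(m)],
            "alt": [ref_alt[i % 4][1] for i in range(m)],
            "is_indel": False,
        }
    )
    # orient each column to the sample minor allele (complete data)
    f_alt = g_alt.mean(axis=0) / 2.0
    flip = f_alt > 0.5
    g = np.where(flip[None, :], 2.0 - g_alt, g_alt)
    meta["minor_allele"] = np.where(flip, meta["ref"], meta["alt"])
    meta["major_allele"] = np.where(flip, meta["alt"], meta["ref"])
    meta = meta[SNP_META_COLUMNS]
    truth_allele_freq = pd.Series(
        np.where(flip, 1.0 - p_alt, p_alt),
        index=meta["snp_id"].tolist(),
        name="p_minor",
    )

    # --- participants ---------------------------------------------------
    group_idx = _group_assignment(n, config.group_proportions)
    group = np.array(GROUPS)[group_idx]
    sex = (rng.random(n) < config.female_fraction).astype(int)  # 1 = female
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n).astype(
        float
    )

    # --- diaries --------------------------------------------------------
    start = pd.Timestamp(config.start_date)
    n_base_days = config.baseline_weeks * 7
    n_obs_days = config.observation_weeks * 7
    n_days = n_base_days + n_obs_days
    dates = pd.date_range(start, periods=n_days, freq="D")
    is_obs_day = np.arange(n_days) >= n_base_days
    baseline_window = (dates[0], dates[n_base_days - 1])
    observation_window = (dates[n_base_days], dates[-1])

    carb_base = np.clip(rng.normal(300.0, 40.0, size=n), 50.0, None)
    fat_base = np.clip(rng.normal(60.0, 12.0, size=n), 10.0, None)
    prot_base = np.clip(rng.normal(70.0, 10.0, size=n), 10.0, None)
    act_base = np.clip(rng.normal(250.0, 60.0, size=n), 0.0, None)

    shift_c = rng.normal(0.0, config.shift_sd / 2.0, size=n)
    shift_f = rng.normal(0.0, config.shift_sd / 2.0, size=n)
    shift_e = rng.normal(0.0, config.shift_sd / 2.0, size=n)
    lc = group == "low_carb"
    lf = group == "low_fat"
    me = group == "moderate_exercise"
    ie = group == "intense_exercise"
    shift_c[lc] = rng.normal(config.shift_carb, config.shift_sd, size=lc.sum())
    shift_f[lf] = rng.normal(config.shift_fat, config.shift_sd, size=lf.sum())
    shift_e[me] = rng.normal(
        config.shift_kcal_moderate, config.shift_sd, size=me.sum()
    )
    shift_e[ie] = rng.normal(config.shift_kcal_intense, config.shift_sd, size=ie.sum())

    # daily nutrient targets: (n, n_days); three meals per day with noise
    day_carb_target = carb_base[:, None] + shift_c[:, None] * is_obs_day[None, :]
    day_fat_target = fat_base[:, None] + shift_f[:, None] * is_obs_day[None, :]
    day_prot_target = np.broadcast_to(prot_base[:, None], (n, n_days))

    meal_carb = np.clip(
        day_carb_target[:, :, None] / 3.0 + rng.normal(0, config.meal_sd, (n, n_days, 3)),
        0.0,
        None,
    )
    meal_fat = np.clip(
        day_fat_target[:, :, None] / 3.0
        + rng.normal(0, config.meal_sd / 2.0, (n, n_days, 3)),
        0.0,
        None,
    )
    meal_prot = np.clip(
        day_prot_target[:, :, None] / 3.0
        + rng.normal(0, config.meal_sd / 2.0, (n, n_days, 3)),
        0.0,
        None,
    )
    meal_kcal = 4.0 * (meal_carb + meal_prot) + 9.0 * meal_fat

    act_kcal = np.clip(
        act_base[:, None]
        + shift_e[:, None] * is_obs_day[None, :]
        + rng.normal(0, config.activity_sd, (n, n_days)),
        0.0,
        None,
    )
    act_minutes = np.clip(act_kcal / 7.0 + rng.normal(0, 5.0, (n, n_days)), 0.0, None)
    act_intensity = rng.uniform(0.4, 0.9, (n, n_days))

    # realized lifestyle deltas (exact diary arithmetic; the truth channel)
    day_carb = meal_carb.sum(axis=2)
    day_fat = meal_fat.sum(axis=2)
    true_dc = day_carb[:, is_obs_day].mean(axis=1) - day_carb[:, ~is_obs_day].mean(
        axis=1
    )
    true_df = day_fat[:, is_obs_day].mean(axis=1) - day_fat[:, ~is_obs_day].mean(axis=1)
    true_de = act_kcal[:, is_obs_day].mean(axis=1) - act_kcal[:, ~is_obs_day].mean(
        axis=1
    )

    # --- planted interaction panels and the BFM signal ------------------
    n_c, n_f, n_e = config.panel_sizes
    idx_c = np.arange(0, n_c)
    idx_f = np.arange(n_c, n_c + n_f)
    idx_e = np.arange(n_c + n_f, n_c + n_f + n_e)
    truth_panel = pd.DataFrame(
        {
            "snp_id": meta["snp_id"].to_numpy()[np.r_[idx_c, idx_f, idx_e]],
            "grs_type": ["C"] * n_c + ["F"] * n_f + ["E"] * n_e,
            "beta": [config.beta_c] * n_c
            + [config.beta_f] * n_f
            + [config.beta_e] * n_e,
        }
    )

    cc = COVARIATE_COEF
    base_pred = (
        cc["intercept"] + cc["gender"] * sex + cc["age"] * age + cc["age_sq"] * age**2
    )
    g_c_sum = g[:, idx_c].sum(axis=1) if n_c else np.zeros(n)
    g_f_sum = g[:, idx_f].sum(axis=1) if n_f else np.zeros(n)
    g_e_sum = g[:, idx_e].sum(axis=1) if n_e else np.zeros(n)

    signal_diet = (
        base_pred
        + cc["delta_c"] * true_dc
        + cc["delta_f"] * true_df
        + config.beta_c * true_dc * g_c_sum
        + config.beta_f * true_df * g_f_sum
    )
    signal_ex = base_pred + cc["delta_e"] * true_de + config.beta_e * true_de * g_e_sum
    is_diet = np.isin(group, DIET_GROUPS)
    signal = np.where(is_diet, signal_diet, signal_ex)
    delta_bfm = signal + rng.normal(0.0, config.noise_sd, size=n)

    truth_participants = pd.DataFrame(
        {
            "participant_id": pids,
            "group": group,
            "true_delta_c": true_dc,
            "true_delta_f": true_df,
            "true_delta_e": true_de,
            "signal": signal,
            "delta_bfm": delta_bfm,
        }
    )

    # --- phenotypes consistent with delta_bfm ---------------------------
    bfm_pre = np.clip(rng.normal(19.11, 6.08, size=n), 5.0, None)
    bfm_post = bfm_pre + delta_bfm
    weight_pre = np.clip(bfm_pre + rng.normal(54.0, 9.0, size=n), 40.0, None)
    weight_post = weight_pre + delta_bfm
    height = np.clip(rng.normal(1.70, 0.08, size=n), 1.45, 2.05)
    smm_pre = np.clip(0.42 * weight_pre + rng.normal(0, 2.0, size=n), 10.0, None)
    smm_post = smm_pre + rng.normal(0.04, 0.3, size=n)
    whr_pre = np.clip(rng.normal(0.87, 0.06, size=n), 0.6, 1.2)
    whr_post = np.clip(whr_pre + rng.normal(0.0, 0.02, size=n), 0.6, 1.2)
    tg_pre = np.clip(rng.normal(128.5, 87.6, size=n), 30.0, None)
    tg_post = np.clip(tg_pre + rng.normal(4.2, 40.0, size=n), 30.0, None)
    ldl_pre = np.clip(rng.normal(125.2, 30.5, size=n), 40.0, None)
    ldl_post = np.clip(ldl_pre + rng.normal(-4.7, 15.0, size=n), 40.0, None)
    hdl_pre = np.clip(rng.normal(51.9, 13.8, size=n), 20.0, None)
    hdl_post = np.clip(hdl_pre + rng.normal(-1.4, 6.0, size=n), 20.0, None)

    phenotypes = pd.DataFrame(
        {
            "participant_id": pids,
            "sex": sex,
            "age": age.astype(int),
            "group": group,
            "weight_pre": weight_pre,
            "weight_post": weight_post,
            "bfm_pre": bfm_pre,
            "bfm_post": bfm_post,
            "bfp_pre": 100.0 * bfm_pre / weight_pre,
            "bfp_post": 100.0 * bfm_post / weight_post,
            "bmi_pre": weight_pre / height**2,
            "bmi_post": weight_post / height**2,
            "smm_pre": smm_pre,
            "smm_post": smm_post,
            "whr_pre": whr_pre,
            "whr_post": whr_post,
            "tg_pre": tg_pre,
            "tg_post": tg_post,
            "ldl_pre": ldl_pre,
            "ldl_post": ldl_post,
            "hdl_pre": hdl_pre,
            "hdl_post": hdl_post,
        }
    )[PHENOTYPE_COLUMNS]

    # --- long-form diaries ----------------------------------------------
    meals = ("breakfast", "lunch", "dinner")
    diet_log = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, n_days * 3),
            "date": np.tile(np.repeat(dates.strftime("%Y-%m-%d"), 3), n),
            "meal": np.tile(meals, n * n_days),
            "carb_g": meal_carb.reshape(-1),
            "fat_g": meal_fat.reshape(-1),
            "protein_g": meal_prot.reshape(-1),
            "kcal": meal_kcal.reshape(-1),
        }
    )
    activity_log = pd.DataFrame(
        {
            "participant_id": np.repeat(pids, n_days),
            "date": np.tile(dates.strftime("%Y-%m-%d"), n),
            "kcal_expended": act_kcal.reshape(-1),
            "minutes": act_minutes.reshape(-1),
            "intensity_frac": act_intensity.reshape(-1),
        }
    )

    # --- missingness mask (after the signal is computed) ----------------
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        g = g.copy()
        g[mask] = np.nan

    genotypes = GenotypeMatrix(pids, meta, g)
    return SyntheticCohort(
        config=config,
        genotypes=genotypes,
        phenotypes=phenotypes,
        diet_log=diet_log,
        activity_log=activity_log,
        truth_panel=truth_panel,
        truth_participants=truth_participants,
        truth_allele_freq=truth_allele_freq,
        baseline_window=baseline_window,
        observation_window=observation_window,
    )


def hwe_consistency_check(cohort: SyntheticCohort) -> pd.Series:
    """Exact-test HWE p-value per generated SNP (generator self-check)."""
    gm = cohort.genotypes
    pvals = [qc.hwe_exact_test(*gm.genotype_counts(j)) for j in range(gm.n_snps)]
    return pd.Series(pvals, index=gm.snps["snp_id"].tolist(), name="hwe_p")
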