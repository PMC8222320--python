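"""Shared builders for the test suite."""

from __future__ import annotations

import pandas as pd

from grslife import interaction, scoring, synthetic
from grslife.synthetic import DIET_GROUPS, EXERCISE_GROUPS, CohortConfig


def make_cohort(seed: int, **overrides) -> synthetic.SyntheticCohort:
    """Small fast cohort: 120 participants, 12 SNPs, 3 weeks of diaries."""
    params = dict(
        n_participants=120,
        n_snps=12,
        panel_sizes=(4, 3, 3),
        noise_sd=1.0,
        missing_rate=0.0,
        baseline_weeks=1,
        observation_weeks=2,
        seed=seed,
    )
    params.update(overrides)
    return synthetic.synthesize_cohort(CohortConfig(**params))


def truth_covariates(cohort: synthetic.SyntheticCohort) -> pd.DataFrame:
    """Covariate table built from the generator's exact delta truth channel."""
    tp = cohort.truth_participants.set_index("participant_id")
    deltas = tp[["true_delta_c", "true_delta_f", "true_delta_e"]].rename(
        columns={
            "true_delta_c": "delta_c",
            "true_delta_f": "delta_f",
            "true_delta_e": "delta_e",
        }
    )
    return interaction.build_covariates(cohort.phenotypes, deltas)


def group_ids(cohort: synthetic.SyntheticCohort, kind: str) -> list[str]:
    pheno = cohort.phenotypes.set_index("participant_id")
    groups = DIET_GROUPS if kind == "diet" else EXERCISE_GROUPS
    return list(pheno.index[pheno["group"].isin(groups)])


def fit_cohort_panels(
    cohort: synthetic.SyntheticCohort, panel_sizes=(4, 3, 3)
) -> dict[str, interaction.GrsPanel]:
    """Fit both model families on the cohort and build scoring panels."""
    cov = truth_covariates(cohort)
    weights = interaction.fit_panel_models(
        cohort.genotypes, cov, "diet", participant_ids=group_ids(cohort, "diet")
    ) + interaction.fit_panel_models(
        cohort.genotypes, cov, "exercise", participant_ids=group_ids(cohort, "exercise")
    )
    return interaction.build_panels(weights, panel_sizes=panel_sizes)


def score_cohort(
    cohort: synthetic.SyntheticCohort, panels: dict[str, interaction.GrsPanel]
) -> pd.DataFrame:
    return scoring.score_all(cohort.genotypes, panels)
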