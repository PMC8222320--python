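import numpy as np
import pytest
from scipy import stats

import helpers
from grslife import analysis, interaction, scoring


def _null_replicate(seed: int):
    """Weights trained on one null cohort, evaluated on an independent one."""
    train = helpers.make_cohort(2 * seed, beta_c=0.0, beta_f=0.0, beta_e=0.0)
    evalc = helpers.make_cohort(2 * seed + 1, beta_c=0.0, beta_f=0.0, beta_e=0.0)
    cov_t = helpers.truth_covariates(train)
    weights = interaction.fit_panel_models(
        train.genotypes, cov_t, "diet", participant_ids=helpers.group_ids(train, "diet")
    ) + interaction.fit_panel_models(
        train.genotypes,
        cov_t,
        "exercise",
        participant_ids=helpers.group_ids(train, "exercise"),
    )
    panels = interaction.build_panels(weights, panel_sizes=(4, 3, 3))
    sc = scoring.score_all(evalc.genotypes, panels)
    dbfm = helpers.truth_covariates(evalc)["delta_bfm"]
    med = analysis.stratify_all(sc, dbfm, method="median")
    opt = analysis.stratify_all(sc, dbfm, min_class_size=12, method="optimize")
    corr_p = [
        stats.pearsonr(sc[f"grs_{t.lower()}"], dbfm.loc[sc["participant_id"]]).pvalue
        for t in ("C", "F", "E")
    ]
    return {
        "median_p": [r.p_value for r in med],
        "median_q": [r.q_value for r in med],
        "opt_p": [r.p_value for r in opt],
        "opt_q": [r.q_value for r in opt],
        "corr_p": corr_p,
    }


@pytest.fixture(scope="session")
def null_calibration():
    """500 independent global-null replicates (shared across test modules)."""
    reps = [_null_replicate(s) for s in range(500)]
    return {
        "median_p": np.array([p for r in reps for p in r["median_p"]]),
        "opt_p": np.array([p for r in reps for p in r["opt_p"]]),
        "median_min_q": np.array([min(r["median_q"]) for r in reps]),
        "opt_min_q": np.array([min(r["opt_q"]) for r in reps]),
        "corr_p_first50": np.array([p for r in reps[:50] for p in r["corr_p"]]),
    }
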