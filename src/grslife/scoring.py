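"""Weighted genetic risk scores: GRS = sum_i weight_i * dosage_i."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from grslife.interaction import GrsPanel
from grslife.qc import GenotypeMatrix

MISSING_POLICIES = ("mean_impute", "drop_snp")


def score(
    gm: GenotypeMatrix, panel: GrsPanel, missing_policy: str = "mean_impute"
) -> pd.Series:
    """Score every participant against one panel.

    Missing dosages are replaced by the SNP's sample mean dosage
    (``mean_impute``, default) or contribute 0 (``drop_snp``), so every
    participant receives a finite score. Panel SNPs absent from the
    genotype matrix raise with the missing ids listed.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(
            f"missing_policy must be one of {MISSING_POLICIES}, got {missing_policy!r}"
        )
    index = pd.Index(gm.participant_ids, name="participant_id")
    name = f"grs_{panel.grs_type.lower()}"
    if not panel.entries:
        return pd.Series(0.0, index=index, name=name)

    col_of = {s: j for j, s in enumerate(gm.snps["snp_id"])}
    absent = [e.snp_id for e in panel.entries if e.snp_id not in col_of]
    if absent:
        raise ValueError(f"panel {panel.grs_type} SNPs absent from genotypes: {absent}")

    cols = [col_of[e.snp_id] for e in panel.entries]
    weights = np.array([e.weight for e in panel.entries])
    d = gm.dosage[:, cols].copy()
    nan = np.isnan(d)
    if missing_policy == "mean_impute":
        with np.errstate(invalid="ignore"):
            means = np.nanmean(np.where(nan, np.nan, d), axis=0)
        means = np.where(np.isnan(means), 0.0, means)  # all-missing SNP -> 0
        d = np.where(nan, means[None, :], d)
    else:
        d = np.where(nan, 0.0, d)
    return pd.Series(d @ weights, index=index, name=name)


def score_all(
    gm: GenotypeMatrix,
    panels: Mapping[str, GrsPanel],
    missing_policy: str = "mean_impute",
) -> pd.DataFrame:
    """GRS-C/F/E per participant as a ``grs_c, grs_f, grs_e`` frame."""
    series = [
        score(gm, panels[t], missing_policy=missing_policy)
        for t in ("C", "F", "E")
        if t in panels
    ]
    out = pd.concat(series, axis=1)
    return out.reset_index()
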