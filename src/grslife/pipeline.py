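"""End-to-end pipeline: simulate/load -> QC -> features -> fit -> score -> analyze.

A run is described by a single :class:`RunConfig` (optionally loaded from
TOML or JSON) and leaves every intermediate artifact plus a deterministic
JSON manifest in the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import grslife
from grslife import analysis, interaction, lifelog, qc, scoring, synthetic
from grslife.synthetic import DIET_GROUPS, EXERCISE_GROUPS, CohortConfig

log = logging.getLogger("grslife")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    out_dir: str = "grslife_out"
    seed: int = 0
    # either simulate a cohort ...
    simulate: bool = True
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    # ... or point at existing inputs
    genotypes: str | None = None
    genotype_format: str = "vcf"
    phenotypes: str | None = None
    diet: str | None = None
    activity: str | None = None
    baseline_start: str | None = None
    baseline_end: str | None = None
    observation_start: str | None = None
    observation_end: str | None = None
    # stage thresholds
    call_rate_min: float = 0.99
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    min_days: int = 7
    panel_sizes: tuple[int, int, int] = (37, 19, 25)
    criterion: str = "mean_diff"
    missing_policy: str = "mean_impute"
    min_class_frac: float = 0.10

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.panel_sizes, list):
            cfg.panel_sizes = tuple(cfg.panel_sizes)
        return cfg

    def validate(self) -> None:
        for name in ("call_rate_min", "maf_min", "min_class_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min must be in [0, 1]")
        if self.min_days < 1:
            raise ValueError("min_days must be >= 1")
        if not self.simulate:
            for name in ("genotypes", "phenotypes", "diet", "activity"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"simulate=false requires input path {name!r}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} input not found: {p}")
            for name in (
                "baseline_start",
                "baseline_end",
                "observation_start",
                "observation_end",
            ):
                if getattr(self, name) is None:
                    raise ValueError(f"simulate=false requires {name}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, t0: float) -> None:
    log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": grslife.__version__,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "inputs": {},
        "stages": {},
    }

    # --- inputs ---------------------------------------------------------
    t0 = time.perf_counter()
    if config.simulate:
        cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
        cohort = synthetic.synthesize_cohort(cohort_cfg)
        paths = cohort.save(out / "cohort")
        manifest["inputs"] = {k: _sha256(Path(v)) for k, v in paths.items()}
        gm = cohort.genotypes
        pheno = cohort.phenotypes
        diet, activity = cohort.diet_log, cohort.activity_log
        base_win, obs_win = cohort.baseline_window, cohort.observation_window
    else:
        for name in ("genotypes", "phenotypes", "diet", "activity"):
            manifest["inputs"][name] = _sha256(Path(getattr(config, name)))
        gm = qc.read_genotypes(config.genotypes, format=config.genotype_format)
        pheno = pd.read_csv(config.phenotypes)
        diet = pd.read_csv(config.diet)
        activity = pd.read_csv(config.activity)
        base_win = (config.baseline_start, config.baseline_end)
        obs_win = (config.observation_start, config.observation_end)
    manifest["stages"]["inputs"] = {
        "n_participants": gm.n_participants,
        "n_snps": gm.n_snps,
    }
    _stage("inputs", t0)

    # --- genotype QC ----------------------------------------------------
    t0 = time.perf_counter()
    gm_qc, report = qc.apply_qc(
        gm,
        call_rate_min=config.call_rate_min,
        maf_min=config.maf_min,
        hwe_p_min=config.hwe_p_min,
    )
    report.write(out / "qc")
    qc.write_traw(gm_qc, out / "qc" / "genotypes_qc.traw")
    manifest["stages"]["qc"] = report.summary()
    _stage("qc", t0)

    # --- lifelog features ----------------------------------------------
    t0 = time.perf_counter()
    deltas = lifelog.compute_lifestyle_delta(
        diet,
        activity,
        base_win,
        obs_win,
        min_days=config.min_days,
        participants=pheno["participant_id"].tolist(),
    )
    groups = pheno.set_index("participant_id")["group"]
    activity_class = lifelog.classify_activity(deltas, groups)
    feat = deltas.merge(
        activity_class.rename("activity_class").reset_index(), on="participant_id"
    )
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    feat.to_csv(feat_dir / "deltas.tsv", sep="\t", index=False)
    weekly = lifelog.weekly_pppw(
        diet,
        activity,
        groups,
        n_baseline_weeks=int(
            np.ceil(((pd.Timestamp(base_win[1]) - pd.Timestamp(base_win[0])).days + 1) / 7)
        ),
        start_date=base_win[0],
    )
    weekly.to_csv(feat_dir / "weekly_pppw.tsv", sep="\t", index=False)
    manifest["stages"]["lifelog"] = {
        "n_participants": int(len(feat)),
        "n_diet_ok": int(feat["diet_ok"].sum()),
        "n_activity_ok": int(feat["activity_ok"].sum()),
    }
    _stage("lifelog", t0)

    # --- interaction fitting -------------------------------------------
    t0 = time.perf_counter()
    pheno_i = pheno.set_index("participant_id")
    cov = interaction.build_covariates(pheno, feat)
    ok = feat.set_index("participant_id")[["diet_ok", "activity_ok"]]

    diet_ids = pheno_i.index[pheno_i["group"].isin(DIET_GROUPS)]
    diet_ids = [p for p in diet_ids if p in ok.index and ok.loc[p, "diet_ok"]]
    ex_ids = pheno_i.index[pheno_i["group"].isin(EXERCISE_GROUPS)]
    ex_ids = [p for p in ex_ids if p in ok.index and ok.loc[p, "activity_ok"]]

    weights = interaction.fit_panel_models(
        gm_qc, cov, "diet", participant_ids=diet_ids
    ) + interaction.fit_panel_models(gm_qc, cov, "exercise", participant_ids=ex_ids)
    risk_alleles = dict(zip(gm_qc.snps["snp_id"], gm_qc.snps["minor_allele"]))
    panels = interaction.build_panels(
        weights, panel_sizes=tuple(config.panel_sizes), risk_alleles=risk_alleles
    )
    wdir = out / "weights"
    wdir.mkdir(exist_ok=True)
    interaction.weights_frame(weights).to_csv(
        wdir / "weights.tsv", sep="\t", index=False
    )
    (wdir / "panels.json").write_text(
        json.dumps({t: p.to_records() for t, p in panels.items()}, indent=2) + "\n"
    )
    manifest["stages"]["fit"] = {
        "n_fitted": int(sum(not w.skipped for w in weights)),
        "n_skipped": int(sum(w.skipped for w in weights)),
        "panel_sizes": {t: len(p.entries) for t, p in panels.items()},
    }
    _stage("fit", t0)

    # --- scoring --------------------------------------------------------
    t0 = time.perf_counter()
    scores = scoring.score_all(gm_qc, panels, missing_policy=config.missing_policy)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    manifest["stages"]["score"] = {"n_scored": int(len(scores))}
    _stage("score", t0)

    # --- stratified analysis -------------------------------------------
    t0 = time.perf_counter()
    res_dir = out / "results"
    res_dir.mkdir(exist_ok=True)
    delta_bfm = (pheno_i["bfm_post"] - pheno_i["bfm_pre"]).rename("delta_bfm")
    min_class = max(
        analysis.MIN_CLASS_FLOOR, int(np.ceil(config.min_class_frac * len(scores)))
    )
    strata = analysis.stratify_all(
        scores, delta_bfm, min_class_size=min_class, criterion=config.criterion
    )
    strat_rows, four_rows, box_rows = [], [], []
    relevant = {
        "C": list(DIET_GROUPS[:1]),
        "F": list(DIET_GROUPS[1:]),
        "E": list(EXERCISE_GROUPS),
    }
    for r in strata:
        strat_rows.append(
            dict(
                grs_type=r.grs_type,
                cutoff=r.cutoff,
                n_high=r.n_high,
                n_low=r.n_low,
                mean_delta_bfm_high=r.mean_high,
                mean_delta_bfm_low=r.mean_low,
                t_stat=r.t_stat,
                p_value=r.p_value,
                q_value=r.q_value,
            )
        )
        for pid, lab in r.labels.dropna().items():
            box_rows.append(
                dict(
                    grs_type=r.grs_type,
                    participant_id=pid,
                    grs_class=lab,
                    delta_bfm=float(delta_bfm.get(pid, np.nan)),
                )
            )
        ids = pheno_i.index[pheno_i["group"].isin(relevant[r.grs_type])]
        act = activity_class.reindex(ids).dropna()
        try:
            fg = analysis.four_group_anova(
                r.labels.reindex(act.index),
                act,
                delta_bfm.reindex(act.index),
                grs_type=r.grs_type,
            )
        except ValueError as exc:
            log.warning("four-group ANOVA skipped for GRS-%s: %s", r.grs_type, exc)
            continue
        row = dict(grs_type=fg.grs_type, f_stat=fg.f_stat, p_value=fg.p_value)
        for cell in analysis.CELL_ORDER:
            row[f"mean_{cell}"] = fg.cell_means[cell]
            row[f"n_{cell}"] = fg.cell_sizes[cell]
        four_rows.append(row)
    strat_df = pd.DataFrame(strat_rows)
    strat_df.to_csv(res_dir / "stratification.tsv", sep="\t", index=False)
    pd.DataFrame(four_rows).to_csv(res_dir / "four_group.tsv", sep="\t", index=False)
    pd.DataFrame(box_rows).to_csv(res_dir / "boxplot_data.tsv", sep="\t", index=False)
    table1 = analysis.paired_prepost_table(pheno)
    table1.to_csv(res_dir / "prepost_table.tsv", sep="\t", index=False)
    manifest["stages"]["analyze"] = {
        "stratification": strat_rows,
        "four_group": four_rows,
    }
    (res_dir / "summary.json").write_text(
        json.dumps(manifest["stages"]["analyze"], indent=2, default=float) + "\n"
    )
    _stage("analyze", t0)

    # --- manifest -------------------------------------------------------
    payload = json.dumps(manifest, sort_keys=True, default=float)
    manifest["manifest_hash"] = hashlib.sha256(payload.encode()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float) + "\n"
    )
    return manifest
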