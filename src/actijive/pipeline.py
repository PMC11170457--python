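"""Pipeline orchestration: simulate -> features -> jive -> associate.

A :class:`RunConfig` (YAML-loadable) drives the stages; every stage writes
its outputs under the run directory and the run ends with a JSON manifest
recording the seed, a parameter hash, and per-stage row counts, so an
identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, blocks, epoch, jive, simulate


@dataclass
class RunConfig:
    out_dir: str = "actijive_run"
    seed: int = 0
    # inputs: either simulate a cohort or read epoch/covariate CSVs
    simulate_tier: str | None = "epoch"  # "epoch", "feature" or None
    n_subjects: int = 150
    n_days: int = 14
    epochs_csv: str | None = None
    covariates_csv: str | None = None
    sleep_annotations_csv: str | None = None
    # extraction thresholds
    min_valid_days: int = 7
    theta_sleep: float = 10.0
    theta_sed: float = 50.0
    theta_mvpa: float = 1000.0
    # JIVE settings
    ranks: tuple[int, int, int, int] | None = None  # joint, SL, PA, CR; None=auto
    alpha: float = 0.05
    n_perm: int = 99
    tol: float = 1e-8
    # regression settings
    contrasts: tuple[str, ...] = ("lifetime", "current", "remitted")
    with_medication: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("ranks"), list):
            raw["ranks"] = tuple(raw["ranks"])
        if isinstance(raw.get("contrasts"), list):
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)

    def param_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _feature_config(cfg: RunConfig) -> blocks.FeatureConfig:
    return blocks.FeatureConfig(
        min_valid_days=cfg.min_valid_days, theta_sleep=cfg.theta_sleep,
        theta_sed=cfg.theta_sed, theta_mvpa=cfg.theta_mvpa)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "param_hash": cfg.param_hash(),
                      "stages": {}}
    # ---- stage: inputs
    if cfg.simulate_tier == "feature":
        plan = simulate.FeaturePlan(n_subjects=cfg.n_subjects)
        feats, covariates, _ = simulate.generate_feature_cohort(plan, cfg.seed)
        manifest["stages"]["simulate"] = {"tier": "feature",
                                          "n_subjects": len(feats.subjects)}
    else:
        if cfg.simulate_tier == "epoch":
            plan = simulate.EpochPlan(n_subjects=cfg.n_subjects, n_days=cfg.n_days)
            series, annotations, truth = simulate.generate_epoch_cohort(
                plan, cfg.seed)
            rng = np.random.default_rng(cfg.seed + 1)
            n = len(series)
            covariates = pd.DataFrame({
                "age": np.clip(rng.normal(61.79, 9.97, n), 35, 90),
                "sex": np.where(rng.random(n) < 0.5442, "female", "male"),
                "bmi": np.clip(rng.normal(26.35, 4.75, n), 15, 50),
                "group": rng.choice(["none", "remitted", "current"], n,
                                    p=[0.5024, 0.4178, 0.0798]),
                "anxiety": rng.random(n) < 0.048,
                "sud": rng.random(n) < 0.006,
                "medication": rng.random(n) < 0.097,
            }, index=pd.Index([s.subject_id for s in series], name="subject"))
            manifest["stages"]["simulate"] = {"tier": "epoch", "n_subjects": n,
                                              "n_days": cfg.n_days}
        elif cfg.epochs_csv:
            series = epoch.read_epochs(cfg.epochs_csv)
            covariates = epoch.read_covariates(cfg.covariates_csv)
            annotations = None
            if cfg.sleep_annotations_csv:
                from .sleep import read_sleep_annotations
                annotations = read_sleep_annotations(cfg.sleep_annotations_csv)
            manifest["stages"]["load"] = {"n_subjects": len(series)}
        else:
            raise ValueError("config must either simulate or point at input CSVs")
        feats, meta = blocks.extract_features(series, _feature_config(cfg))
        manifest["stages"]["features"] = {
            "n_included": len(feats.subjects),
            "n_excluded": len(meta["excluded"]),
            "valid_days": {k: int(v) for k, v in sorted(meta["n_valid_days"].items())},
        }
        covariates = covariates.loc[feats.subjects]
    blocks.write_features(feats, out / "features.csv")
    covariates.to_csv(out / "covariates.csv")
    # ---- stage: JIVE
    scaled = jive.preprocess(feats)
    if cfg.ranks is not None:
        r_joint, r_indiv = cfg.ranks[0], dict(zip(["SL", "PA", "CR"], cfg.ranks[1:]))
        stable = True
    else:
        r_joint, r_indiv, stable = jive.select_ranks(
            scaled, alpha=cfg.alpha, n_perm=cfg.n_perm, seed=cfg.seed)
        r_joint = max(r_joint, 1)
        r_indiv = {k: max(v, 1) for k, v in r_indiv.items()}
    model = jive.fit_jive(scaled, r_joint, r_indiv, tol=cfg.tol)
    scores = jive.extract_scores(model)
    scores.to_csv(out / "scores.csv")
    jive.loading_table(model).to_csv(out / "loadings.csv", index=False)
    jive.varexp_table(model).to_csv(out / "varexp.csv")
    with open(out / "jive.json", "w") as fh:
        json.dump({"r_joint": model.r_joint, "r_indiv": model.r_indiv,
                   "converged": model.converged, "n_iter": model.n_iter,
                   "rank_selection_stable": stable,
                   "varexp": model.varexp}, fh, indent=2)
    manifest["stages"]["jive"] = {"r_joint": model.r_joint,
                                  "r_indiv": model.r_indiv,
                                  "converged": model.converged}
    # ---- stage: descriptive + regressions
    desc_data = pd.concat([covariates, feats.data], axis=1)
    desc = association.descriptive_table(
        desc_data, "group", categorical=["sex"],
        continuous=["age", "bmi"] + list(feats.data.columns))
    desc.to_csv(out / "descriptive.csv", index=False)
    assoc_meta = {}
    for contrast in cfg.contrasts:
        res = association.jive_logistic(
            scores, covariates, contrast, with_medication=cfg.with_medication)
        res.table.to_csv(out / f"association_{contrast}.csv", index=False)
        assoc_meta[contrast] = {"n_case": res.n_case, "n_control": res.n_control,
                                "converged": res.converged,
                                "warnings": res.warnings}
    manifest["stages"]["associate"] = assoc_meta
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
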