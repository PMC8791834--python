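"""Stage orchestration: simulate -> featurize -> associate -> train ->
validate -> importance -> impact, with provenance manifests.

Each stage reads the previous stage's artefacts from the run directory and
writes its own, together with a JSON manifest recording input checksums and
the master seed, so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .features import FeatureMatrix, build_feature_matrix, load_feature_definitions
from .mlcore import (
    clean_training_data,
    clinical_impact,
    evaluate,
    feature_importance,
    run_nested_models,
    score_rcb_monotonicity,
    train_model,
)
from .stats import association_table, encode_rcb, fdr_adjust, ordinal_trend
from .synth import SimulationConfig, simulate_cohort

log = logging.getLogger("neoresponse")

STAGES = ["simulate", "featurize", "associate", "train", "validate",
          "importance", "impact"]


@dataclass
class RunConfig:
    """Run configuration: stages, output directory, seed, sizes."""

    outdir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    n_train: int = 200
    n_validation: int = 75
    n_iter: int = 100
    cv_seeds: list[int] = field(default_factory=lambda: [101, 202, 303, 404, 505])
    nested: bool = True
    fn_budgets: tuple[int, ...] = (0, 2)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def _load_features(outdir: Path, split: str) -> FeatureMatrix:
    X = pd.read_csv(outdir / f"features_{split}.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(outdir / f"features_{split}_meta.tsv", sep="\t",
                       index_col=0)
    defs = load_feature_definitions().set_index("name")
    return FeatureMatrix(
        X=X,
        modality=defs["modality"].reindex(X.columns),
        y=meta["pcr"],
        rcb=meta["rcb_class"],
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages in dependency order."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")
    log.info("run seed=%d stages=%s", config.seed, config.stages)

    if "simulate" in config.stages:
        for split, n, off in [("train", config.n_train, 0),
                              ("validation", config.n_validation, 1)]:
            cfg = SimulationConfig(n_patients=n, seed=config.seed * 2 + off)
            bundle = simulate_cohort(cfg)
            paths = nio.write_bundle(bundle, outdir / split)
            nio.write_manifest(
                nio.provenance_manifest({}, cfg.seed, f"simulate:{split}"),
                outdir / split / "manifest.json",
            )
            log.info("simulate %s: %d patients, %d mutations", split, n,
                     len(bundle.mutations))

    if "featurize" in config.stages:
        for split in ("train", "validation"):
            indir = outdir / split
            if not indir.exists():
                raise FileNotFoundError(
                    f"featurize needs simulate artefacts at {indir}"
                )
            cfg = SimulationConfig(
                n_patients=1000, seed=config.seed
            )  # genome model/reference carrier only
            bundle = nio.read_bundle(indir, config=cfg)
            fm = build_feature_matrix(bundle)
            fm.validate()
            fm.X.to_csv(outdir / f"features_{split}.tsv", sep="\t")
            pd.DataFrame(
                {"pcr": fm.y, "rcb_class": fm.rcb}
            ).to_csv(outdir / f"features_{split}_meta.tsv", sep="\t")
            nio.write_manifest(
                nio.provenance_manifest(
                    {"clinical": indir / "clinical.tsv"}, config.seed,
                    f"featurize:{split}",
                ),
                outdir / f"features_{split}_manifest.json",
            )
            log.info("featurize %s: %s", split, fm.X.shape)

    if "associate" in config.stages:
        fm = _load_features(outdir, "train")
        assoc = association_table(fm.X, fm.y)
        trends = []
        codes = encode_rcb(fm.rcb)
        for col in fm.X.columns:
            try:
                r = ordinal_trend(fm.X[col], codes, name=col)
                trends.append({"feature": col, "coefficient": r.coefficient,
                               "p_value": r.p_value})
            except RuntimeError:
                trends.append({"feature": col, "coefficient": np.nan,
                               "p_value": np.nan})
        tr = pd.DataFrame(trends)
        ok = tr["p_value"].notna()
        tr.loc[ok, "q_value"] = fdr_adjust(tr.loc[ok, "p_value"].to_numpy())
        assoc.to_csv(outdir / "associations_logistic.tsv", sep="\t", index=False)
        tr.to_csv(outdir / "associations_ordinal.tsv", sep="\t", index=False)
        log.info("associate: %d features", fm.X.shape[1])

    models = None
    if "train" in config.stages:
        import joblib

        fm = clean_training_data(_load_features(outdir, "train"))
        if config.nested:
            models = run_nested_models(fm, seeds=config.cv_seeds,
                                       n_iter=config.n_iter)
        else:
            name = "+".join(["clinical", "DNA", "RNA", "DigPath", "treatment"])
            models = {name: train_model(fm.X, fm.y, seeds=config.cv_seeds,
                                        n_iter=config.n_iter)}
        (outdir / "models").mkdir(exist_ok=True)
        for name, model in models.items():
            safe = name.replace("+", "_")
            joblib.dump(model, outdir / "models" / f"{safe}.joblib")
            model.save_manifest(outdir / "models" / f"{safe}.manifest.json")
        log.info("train: %d models", len(models))

    if "validate" in config.stages:
        import joblib

        if models is None:
            models = {
                p.stem.replace("_", "+"): joblib.load(p)
                for p in sorted((outdir / "models").glob("*.joblib"))
            }
        fm_val = clean_training_data(_load_features(outdir, "validation"),
                                     validation=True)
        rows = {}
        for name, model in models.items():
            scores = model.predict_scores(fm_val.X)
            rep = evaluate(scores, fm_val.y.to_numpy(), seed=config.seed)
            rows[name] = rep.to_dict()
            rows[name]["rcb_trend_p"] = score_rcb_monotonicity(
                scores, fm_val.rcb
            )
            pd.DataFrame({"patient": fm_val.X.index, "score": scores,
                          "pcr": fm_val.y}).to_csv(
                outdir / f"scores_{name.replace('+', '_')}.tsv", sep="\t",
                index=False)
        with open(outdir / "validation_report.json", "w") as fh:
            json.dump(rows, fh, indent=1)
        log.info("validate: %s", {k: round(v["auc"], 3) for k, v in rows.items()})

    if "importance" in config.stages:
        fm = clean_training_data(_load_features(outdir, "train"))
        rep = feature_importance(fm.X, fm.y)
        out = rep.per_algorithm.copy()
        out["signed_z"] = rep.signed_z
        out["unsigned_z"] = rep.unsigned_z
        out.sort_values("unsigned_z", ascending=False).to_csv(
            outdir / "feature_importance.tsv", sep="\t")
        log.info("importance: top feature %s", rep.unsigned_z.idxmax())

    if "impact" in config.stages:
        import joblib

        if models is None:
            models = {
                p.stem.replace("_", "+"): joblib.load(p)
                for p in sorted((outdir / "models").glob("*.joblib"))
            }
        fm_val = clean_training_data(_load_features(outdir, "validation"),
                                     validation=True)
        report = {}
        for name, model in models.items():
            scores = model.predict_scores(fm_val.X)
            report[name] = {
                f"fn_budget_{b}": clinical_impact(scores,
                                                  fm_val.y.to_numpy(), b)
                for b in config.fn_budgets
            }
        with open(outdir / "clinical_impact.json", "w") as fh:
            json.dump(report, fh, indent=1)
        log.info("impact written")

    return outdir
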