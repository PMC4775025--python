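"""End-to-end runs: configuration, orchestration and result files.

A run reads a dataset (expression table + sequences), assembles the
configured feature blocks, repeats nested cross-validation with re-drawn
fold groupings, ensemble-averages the out-of-fold predictions, and fits
the final all-data model. Everything is deterministic given the
configuration including the base seed; result files are JSON/CSV with a
schema version header and no timestamps, so identical runs produce
identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ensemble import EnsembleResult, ensemble_average
from .features import FeatureBlockSpec, FeatureMatrix, assemble_feature_matrix
from .nested_cv import fit_final_model, repeat_nested_cv, summarize_repetitions
from .regression import FittedModel, ModelSpec, predict
from .sequences import CodingSequence, ExpressionRecord, read_dataset

__all__ = ["RunConfig", "run_pipeline", "predict_sequences", "load_final_model"]

log = logging.getLogger("codonexpress")

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: data, feature blocks, model grid, CV shape, seed."""

    table_path: str
    fasta_path: str | None
    feature_spec: FeatureBlockSpec
    model_spec: ModelSpec
    m_outer: int
    n_inner: int
    n_reps: int
    base_seed: int
    out_dir: str

    @classmethod
    def from_yaml(cls, path: str | Path, base_seed: int | None = None, out_dir: str | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        feats = raw.get("features", {})
        fspec = FeatureBlockSpec(
            use_mfe=feats.get("use_mfe", "off"),
            use_bias=feats.get("use_bias", "all"),
            drop_absent_bias_columns=feats.get("drop_absent_bias_columns", False),
            use_count=feats.get("use_count", True),
            use_id=feats.get("use_id", True),
        )
        mspec = ModelSpec.from_dict(raw["model"])
        cv = raw.get("cv", {})
        return cls(
            table_path=raw["dataset"]["table"],
            fasta_path=raw["dataset"].get("fasta"),
            feature_spec=fspec,
            model_spec=mspec,
            m_outer=int(cv.get("m_outer", 7)),
            n_inner=int(cv.get("n_inner", 6)),
            n_reps=int(cv.get("n_reps", 100)),
            base_seed=int(base_seed if base_seed is not None else cv.get("base_seed", 0)),
            out_dir=str(out_dir if out_dir is not None else raw.get("output", "results")),
        )

    def digest(self) -> str:
        payload = {
            "table": self.table_path,
            "fasta": self.fasta_path,
            "features": _feature_spec_dict(self.feature_spec),
            "model": {
                "algorithm": self.model_spec.algorithm,
                "grid": self.model_spec.grid_points(),
            },
            "cv": {
                "m_outer": self.m_outer,
                "n_inner": self.n_inner,
                "n_reps": self.n_reps,
                "base_seed": self.base_seed,
            },
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _feature_spec_dict(spec: FeatureBlockSpec) -> dict:
    return {
        "use_mfe": spec.use_mfe,
        "use_bias": spec.use_bias if isinstance(spec.use_bias, str) else list(spec.use_bias),
        "drop_absent_bias_columns": spec.drop_absent_bias_columns,
        "use_count": spec.use_count,
        "use_id": spec.use_id,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a full run and write the results bundle to ``cfg.out_dir``.

    Files written: ``repetitions.jsonl`` (header line + one JSON record per
    repetition), ``ensemble.csv`` / ``ensemble_summary.json``,
    ``final_model.json`` (model + feature configuration), ``run_summary.json``.
    Returns the in-memory bundle.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run config digest %s, base seed %d", cfg.digest(), cfg.base_seed)

    t0 = time.perf_counter()
    seqs, records = read_dataset(cfg.table_path, cfg.fasta_path)
    X = assemble_feature_matrix(records, seqs, cfg.feature_spec)
    y = np.array([r.expression for r in records])
    log.info(
        "featurized %d patterns x %d features in %.2fs",
        X.n_patterns, X.n_features, time.perf_counter() - t0,
    )

    t1 = time.perf_counter()
    reps, summary = repeat_nested_cv(
        X, y, cfg.model_spec, cfg.m_outer, cfg.n_inner, cfg.n_reps, cfg.base_seed
    )
    for rep in reps:
        for fold, hp in rep.fold_hyperparams.items():
            log.info("rep seed %d outer fold %d chose %s", rep.seed, fold, hp)
    log.info("%d nested-CV repetitions in %.2fs", cfg.n_reps, time.perf_counter() - t1)

    ens = ensemble_average(reps, y, pattern_ids=X.pattern_ids)

    t2 = time.perf_counter()
    final = fit_final_model(X, y, cfg.model_spec, cfg.n_inner, cfg.base_seed + cfg.n_reps)
    log.info("final model (%s) in %.2fs", final.hyperparams, time.perf_counter() - t2)

    with open(out / "repetitions.jsonl", "w") as fh:
        header = {
            "schema": "codonexpress.repetitions",
            "version": _SCHEMA_VERSION,
            "config_digest": cfg.digest(),
            "base_seed": cfg.base_seed,
        }
        fh.write(json.dumps(header) + "\n")
        for rep in reps:
            fh.write(json.dumps(rep.to_dict()) + "\n")
    ens.save(out / "ensemble.csv", out / "ensemble_summary.json")
    model_doc = final.to_dict()
    model_doc["feature_spec"] = _feature_spec_dict(cfg.feature_spec)
    model_doc["schema"] = "codonexpress.model"
    with open(out / "final_model.json", "w") as fh:
        json.dump(model_doc, fh)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(
            {
                "schema": "codonexpress.run_summary",
                "version": _SCHEMA_VERSION,
                "config_digest": cfg.digest(),
                "n_patterns": X.n_patterns,
                "n_features": X.n_features,
                "repetition_summary": summary,
                "ensemble": ens.summary(),
                "final_hyperparams": final.hyperparams,
            },
            fh,
            indent=2,
        )
    return {"repetitions": reps, "summary": summary, "ensemble": ens, "final_model": final}


def load_final_model(path: str | Path) -> tuple[FittedModel, FeatureBlockSpec]:
    """Load a saved final model together with its feature configuration."""
    with open(path) as fh:
        doc = json.load(fh)
    fspec_d = doc.pop("feature_spec", None)
    doc.pop("schema", None)
    model = FittedModel.from_dict(doc)
    if fspec_d is None:
        raise ValueError(f"{path}: model file carries no feature_spec")
    use_bias = fspec_d["use_bias"]
    fspec = FeatureBlockSpec(
        use_mfe=fspec_d["use_mfe"],
        use_bias=use_bias if isinstance(use_bias, str) else tuple(use_bias),
        drop_absent_bias_columns=fspec_d["drop_absent_bias_columns"],
        use_count=fspec_d["use_count"],
        use_id=fspec_d["use_id"],
    )
    return model, fspec


def predict_sequences(
    model: FittedModel,
    fspec: FeatureBlockSpec,
    seqs: list[CodingSequence],
    records: list[ExpressionRecord] | None = None,
) -> np.ndarray:
    """Score new synonymous encodings with a saved model.

    The model is protein specific: sequences must have the codon length the
    model was trained on, and any required MFE covariate must be supplied
    via ``records``. When the training run dropped absent bias columns, the
    bias block is pinned to the model's own column list rather than
    re-dropped on the new data.
    """
    if records is None:
        if fspec.use_mfe != "off":
            raise ValueError("model uses an MFE feature; supply records with MFE values")
        records = [ExpressionRecord(s.identifier, 1.0) for s in seqs]

    pin = fspec
    if model.columns is not None and fspec.use_bias != "off":
        bias_codons = tuple(c[5:] for c in model.columns if c.startswith("bias_"))
        pin = FeatureBlockSpec(
            use_mfe=fspec.use_mfe,
            use_bias=bias_codons,
            drop_absent_bias_columns=False,
            use_count=fspec.use_count,
            use_id=fspec.use_id,
        )
    try:
        X = assemble_feature_matrix(records, seqs, pin)
    except ValueError as exc:
        raise ValueError(f"sequences incompatible with this model ({exc})") from exc
    if model.columns is not None and X.columns != model.columns:
        raise ValueError(
            "feature schema mismatch: the model is protein specific "
            f"(trained on {len(model.columns)} features, these sequences give {X.n_features})"
        )
    return predict(model, X)
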