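"""End-to-end orchestration: preprocess -> featurize -> per-assay
resample/train/evaluate -> top-k selection -> pathway enrichment.

Every stage is a pure function of (inputs, config, seed); the run
manifest records parameters, seeds, package versions, and SHA-256
checksums of all inputs and outputs so a run can be audited and
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import (
    build_assay_datasets,
    imbalance_ratio,
    read_label_csv,
    resolve_duplicate_labels,
    standardize_compound,
    write_label_csv,
)
from .enrichment import enrich_pathways, read_gmt, restrict_to_universe, results_to_frame
from .forest import ForestConfig, gini_importance, select_top_features, train_with_cv
from .metrics import evaluate_predictions
from .resampling import ResampleConfig
from .signatures import (
    InteractionMatrix,
    build_interaction_matrix,
    ecfp4_fingerprint,
    filter_solved,
    load_protein_library,
)

logger = logging.getLogger("toxsig")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    labels_csv: str
    protein_library: str
    pathways_gmt: str
    out_dir: str
    matrix_tsv: Optional[str] = None  # precomputed; else featurized from SMILES
    seed: int = 0
    fingerprint_width: int = 1024
    top_k: int = 100
    solved_only: bool = True
    resample: dict = field(default_factory=dict)
    forest: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=lambda: {"min_overlap": 2, "stat": "tail"})

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def resample_config(self) -> ResampleConfig:
        return ResampleConfig(**{"seed": self.seed, **self.resample})

    def forest_config(self) -> ForestConfig:
        return ForestConfig(**{"seed": self.seed, **self.forest})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _featurize(cfg: PipelineConfig, smiles: dict[str, str], compound_ids, proteins,
               rejections: list[tuple[str, str]]) -> InteractionMatrix:
    fps, kept = [], []
    for cid in compound_ids:
        smi = smiles.get(cid)
        if smi is None:
            rejections.append((cid, "no-structure"))
            continue
        res = standardize_compound(smi)
        if not res.accepted:
            rejections.append((cid, res.reason))
            continue
        fps.append(ecfp4_fingerprint(res.canonical_smiles, width=cfg.fingerprint_width))
        kept.append(cid)
    return build_interaction_matrix(kept, fps, proteins)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    # validate inputs before any compute
    required = [cfg.labels_csv, cfg.protein_library, cfg.pathways_gmt]
    if cfg.matrix_tsv:
        required.append(cfg.matrix_tsv)
    missing = [p for p in required if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "toxsig_version": __version__,
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "inputs": {p: _sha256(Path(p)) for p in required},
        "stages": {},
        "outputs": {},
        "final": False,
    }

    try:
        table, smiles, split = read_label_csv(cfg.labels_csv)
        proteins = load_protein_library(cfg.protein_library)
        pmap_raw = read_gmt(cfg.pathways_gmt)
    except Exception as e:  # noqa: BLE001
        raise StageError("load", e) from e

    try:
        resolved = resolve_duplicate_labels(table)
        n_dropped = len({(c, a) for c, a, _ in table.rows}) - len(resolved.rows)
        manifest["stages"]["preprocess"] = {
            "label_rows_in": len(table.rows),
            "pairs_out": len(resolved.rows),
            "ambiguous_pairs_dropped": n_dropped,
        }
        logger.info("preprocess: %d rows -> %d pairs (%d ambiguous dropped)",
                    len(table.rows), len(resolved.rows), n_dropped)
        write_label_csv(resolved, out / "labels_resolved.csv", smiles=smiles, split=split)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("preprocess", e) from e

    try:
        rejections: list[tuple[str, str]] = []
        if cfg.matrix_tsv:
            matrix = InteractionMatrix.from_tsv(cfg.matrix_tsv)
        else:
            cids = sorted({c for c, _, _ in resolved.rows})
            matrix = _featurize(cfg, smiles, cids, proteins, rejections)
        pd.DataFrame(rejections, columns=["compound_id", "reason"]).to_csv(
            out / "rejections.tsv", sep="\t", index=False
        )
        if rejections:  # rejected compounds lose their labels too
            bad = {c for c, _ in rejections}
            resolved = type(resolved)(
                rows=[r for r in resolved.rows if r[0] not in bad],
                assay_ids=resolved.assay_ids,
            )
        if cfg.solved_only:
            matrix = filter_solved(matrix, proteins)
        if not matrix.protein_ids:
            raise ValueError("feature space is empty after the solved-structure filter")
        manifest["stages"]["featurize"] = {
            "compounds": len(matrix.compound_ids),
            "proteins": len(matrix.protein_ids),
            "rejections": len(rejections),
        }
        logger.info("featurize: %d x %d matrix (%d rejections)",
                    len(matrix.compound_ids), len(matrix.protein_ids), len(rejections))
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("featurize", e) from e

    try:
        datasets = build_assay_datasets(resolved, matrix, split)
    except Exception as e:  # noqa: BLE001
        raise StageError("assemble", e) from e

    solved_ids = {p.protein_id for p in proteins if p.solved} if cfg.solved_only else {
        p.protein_id for p in proteins
    }
    pmap = restrict_to_universe(pmap_raw, solved_ids)

    metric_rows = []
    for ds in datasets:
        aid = ds.assay_id
        try:
            model, best, cv_table = train_with_cv(ds, cfg.resample_config(), cfg.forest_config())
            cv_table.to_csv(out / f"{aid}_cv_scores.tsv", sep="\t", index=False)
            with open(out / f"{aid}_best_params.json", "w") as fh:
                json.dump(best, fh, indent=1, sort_keys=True)

            proba = model.predict_proba(ds.X_test)[:, list(model.classes_).index(1)]
            report = evaluate_predictions(ds.y_test, (proba >= 0.5).astype(int), proba)
            metric_rows.append({
                "assay": aid,
                "train_ir": imbalance_ratio(ds.y_train),
                "f1": report.f1, "precision": report.precision, "recall": report.recall,
                "auc_roc": report.auc_roc, "auc_pr": report.auc_pr,
                "balanced_accuracy": report.balanced_accuracy, "mcc": report.mcc,
                "specificity": report.specificity, "accuracy": report.accuracy,
            })

            imp = gini_importance(model, ds.feature_ids)
            imp.to_frame().to_csv(out / f"{aid}_importances.tsv", sep="\t", index=False)
            top = select_top_features(imp, k=min(cfg.top_k, len(ds.feature_ids)))
            pd.DataFrame({"rank": range(1, len(top) + 1), "protein_id": top}).to_csv(
                out / f"{aid}_top_features.tsv", sep="\t", index=False
            )

            results = enrich_pathways(top, pmap, **cfg.enrichment)
            results_to_frame(results).to_csv(out / f"{aid}_enrichment.tsv", sep="\t", index=False)
            logger.info("assay %s: best=%s BA=%.3f AUCROC=%.3f, %d enriched pathways",
                        aid, best, report.balanced_accuracy, report.auc_roc, len(results))
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError(f"assay:{aid}", e) from e

    pd.DataFrame(metric_rows).to_csv(out / "metrics.tsv", sep="\t", index=False)

    for f in sorted(out.glob("*")):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    manifest["final"] = True
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
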