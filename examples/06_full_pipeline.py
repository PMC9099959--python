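"""Run the whole pipeline end to end on generated files.

generate -> preprocess (duplicate resolution) -> featurize (precomputed
matrix) -> per-assay resample/train/evaluate -> top features ->
enrichment, with a manifest recording checksums of all inputs/outputs.
"""

from pathlib import Path

import pandas as pd

from toxsig.pipeline import PipelineConfig, run_pipeline
from toxsig.synthetic import SyntheticConfig, generate_bundle

bundle_dir = Path("scratch/pipeline_bundle")
run_dir = Path("scratch/pipeline_run")
cfg = SyntheticConfig(
    n_compounds=500, n_proteins=100, n_assays=3, n_pathways=15,
    pathway_size_range=(8, 18), n_causal_proteins=10, n_causal_pathways=2,
    seed=11,
)
generate_bundle(cfg, out_dir=bundle_dir)

manifest = run_pipeline(
    PipelineConfig(
        labels_csv=str(bundle_dir / "labels.csv"),
        protein_library=str(bundle_dir / "protein_library.json"),
        pathways_gmt=str(bundle_dir / "pathways.gmt"),
        matrix_tsv=str(bundle_dir / "interaction_matrix.tsv"),
        out_dir=str(run_dir),
        seed=0,
        top_k=20,  # a fifth of the feature space, as in the full-scale setup
        forest={"grid": {"max_depth": [8], "n_estimators": [60]},
                "cv_folds": 3, "cv_repeats": 1},
    )
)
print("stages:", manifest["stages"])
metrics = pd.read_csv(run_dir / "metrics.tsv", sep="\t")
cols = ["assay", "train_ir", "f1", "recall", "specificity", "balanced_accuracy", "auc_roc"]
print(metrics[cols].round(3).to_string(index=False))
enr = pd.read_csv(run_dir / "TOX-01_enrichment.tsv", sep="\t")
print("top enriched pathways for TOX-01:")
print(enr.head(3)[["pathway_id", "pathway_size", "overlap", "p_value"]].to_string(index=False))
# Balanced accuracy well above 0.5 on every assay shows the resampled
# forest detects the planted signal; the causal pathways head the
# enrichment table.
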