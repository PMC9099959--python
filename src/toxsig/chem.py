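"""Compound standardization and per-assay dataset assembly.

qHTS toxicity panels label each compound 0 (inactive) or 1 (active/toxic)
per assay; the same compound can be assayed repeatedly with conflicting
outcomes, and raw SMILES may contain salts or be unparsable.  This module
standardizes structures, resolves replicate labels by per-(compound, assay)
majority vote (ties are dropped), and joins the resolved labels with an
interaction-score matrix into one train/test dataset per assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .signatures import Fingerprint, InteractionMatrix

__all__ = [
    "CompoundRecord",
    "AssayLabelTable",
    "AssayDataset",
    "StandardizationResult",
    "standardize_compound",
    "resolve_duplicate_labels",
    "imbalance_ratio",
    "build_assay_datasets",
    "read_label_csv",
    "write_label_csv",
]

REJECT_UNPARSABLE = "unparsable"
REJECT_MULTI_FRAGMENT = "multi-fragment/salt"


@dataclass(frozen=True)
class StandardizationResult:
    accepted: bool
    canonical_smiles: Optional[str] = None
    reason: Optional[str] = None


@dataclass
class CompoundRecord:
    """One compound: structure (SMILES and/or fingerprint) plus assay labels."""

    compound_id: str
    smiles: Optional[str] = None
    fingerprint: Optional[Fingerprint] = None
    labels: dict[str, int] = field(default_factory=dict)  # assay_id -> 0/1

    def __post_init__(self) -> None:
        if self.smiles is None and self.fingerprint is None:
            raise ValueError(f"{self.compound_id}: need smiles or fingerprint")
        bad = {a: v for a, v in self.labels.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"{self.compound_id}: non-binary labels {bad}")


@dataclass
class AssayLabelTable:
    """Long-format label rows; (compound_id, assay_id) pairs may repeat."""

    rows: list[tuple[str, str, int]]
    assay_ids: list[str]

    def __post_init__(self) -> None:
        declared = set(self.assay_ids)
        for cid, aid, lab in self.rows:
            if lab not in (0, 1):
                raise ValueError(f"non-binary label {lab!r} for ({cid}, {aid})")
            if aid not in declared:
                raise ValueError(f"assay {aid!r} not in declared assay set")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["compound_id", "assay_id", "label"])


@dataclass
class AssayDataset:
    """Feature matrix + binary labels for one assay, fixed train/test split."""

    assay_id: str
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    feature_ids: list[str]
    train_compounds: list[str] = field(default_factory=list)
    test_compounds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X_train.shape[0] != self.y_train.shape[0]:
            raise ValueError("train rows != train labels")
        if self.X_test.shape[0] != self.y_test.shape[0]:
            raise ValueError("test rows != test labels")
        if self.X_train.shape[1] != len(self.feature_ids) or (
            self.X_test.size and self.X_test.shape[1] != len(self.feature_ids)
        ):
            raise ValueError("feature count mismatch")


def standardize_compound(smiles: str) -> StandardizationResult:
    """Canonicalize a single-fragment SMILES, or reject it.

    Multi-fragment inputs (salts, mixtures) are rejected rather than
    salt-stripped; tautomer/resonance normalization is whatever the
    toolkit's canonical form provides.  Idempotent on accepted output.
    """
    if not smiles or not smiles.strip():
        return StandardizationResult(False, reason=REJECT_UNPARSABLE)
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return StandardizationResult(False, reason=REJECT_UNPARSABLE)
    if len(Chem.GetMolFrags(mol)) > 1:
        return StandardizationResult(False, reason=REJECT_MULTI_FRAGMENT)
    return StandardizationResult(True, canonical_smiles=Chem.MolToSmiles(mol))


def resolve_duplicate_labels(table: AssayLabelTable) -> AssayLabelTable:
    """Majority-vote replicate labels per (compound, assay); drop exact ties.

    A pair with equally many active and inactive replicates is ambiguous
    and emitted nowhere; otherwise the strictly more frequent label wins.
    Idempotent, and the output never repeats a (compound, assay) pair.
    """
    out: list[tuple[str, str, int]] = []
    df = table.to_frame()
    if len(df):
        grouped = df.groupby(["compound_id", "assay_id"], sort=False)["label"]
        for (cid, aid), labels in grouped:
            ones = int((labels == 1).sum())
            zeros = int((labels == 0).sum())
            if ones == zeros:
                continue
            out.append((cid, aid, 1 if ones > zeros else 0))
    return AssayLabelTable(rows=out, assay_ids=list(table.assay_ids))


def imbalance_ratio(labels: Sequence[int] | np.ndarray) -> float:
    """(# inactive) / (# active); undefined without at least one active."""
    y = np.asarray(labels)
    active = int((y == 1).sum())
    inactive = int((y == 0).sum())
    if active == 0:
        raise ZeroDivisionError("imbalance ratio undefined: no active compounds")
    return inactive / active


def build_assay_datasets(
    table: AssayLabelTable,
    matrix: InteractionMatrix,
    split: Mapping[str, str],
) -> list[AssayDataset]:
    """One dataset per declared assay from a resolved label table.

    ``split`` maps compound_id -> ``"train"`` or ``"test"`` (the panel's
    fixed partition; never re-randomized here).  Compounds lacking a label
    for an assay are simply absent from that assay's dataset.
    """
    resolved = resolve_duplicate_labels(table)
    row_index = {cid: i for i, cid in enumerate(matrix.compound_ids)}
    for cid, _, _ in resolved.rows:
        if cid not in row_index:
            raise KeyError(f"labeled compound {cid!r} missing from interaction matrix")
        if cid not in split:
            raise KeyError(f"labeled compound {cid!r} has no train/test assignment")

    by_assay: dict[str, list[tuple[str, int]]] = {a: [] for a in resolved.assay_ids}
    for cid, aid, lab in resolved.rows:
        by_assay[aid].append((cid, lab))

    datasets = []
    for aid in resolved.assay_ids:
        pairs = by_assay[aid]
        tr = [(c, l) for c, l in pairs if split[c] == "train"]
        te = [(c, l) for c, l in pairs if split[c] == "test"]
        datasets.append(
            AssayDataset(
                assay_id=aid,
                X_train=matrix.scores[[row_index[c] for c, _ in tr], :]
                if tr else np.zeros((0, len(matrix.protein_ids))),
                y_train=np.array([l for _, l in tr], dtype=np.int64),
                X_test=matrix.scores[[row_index[c] for c, _ in te], :]
                if te else np.zeros((0, len(matrix.protein_ids))),
                y_test=np.array([l for _, l in te], dtype=np.int64),
                feature_ids=list(matrix.protein_ids),
                train_compounds=[c for c, _ in tr],
                test_compounds=[c for c, _ in te],
            )
        )
    return datasets


def read_label_csv(path) -> tuple[AssayLabelTable, dict[str, str], dict[str, str]]:
    """Read the wide label CSV: compound_id, smiles, split, one column per assay.

    Repeated compound rows are legitimate (replicate measurements).
    Returns (long label table, compound->smiles, compound->split).
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    fixed = ["compound_id", "smiles", "split"]
    assays = [c for c in df.columns if c not in fixed]
    rows: list[tuple[str, str, int]] = []
    smiles: dict[str, str] = {}
    split: dict[str, str] = {}
    for _, rec in df.iterrows():
        cid = str(rec["compound_id"])
        if "smiles" in df.columns and isinstance(rec.get("smiles"), str):
            smiles[cid] = rec["smiles"]
        if "split" in df.columns and isinstance(rec.get("split"), str):
            split[cid] = rec["split"]
        for aid in assays:
            v = rec[aid]
            if pd.isna(v):
                continue
            rows.append((cid, aid, int(v)))
    return AssayLabelTable(rows=rows, assay_ids=assays), smiles, split


def write_label_csv(
    table: AssayLabelTable,
    path,
    smiles: Mapping[str, str] | None = None,
    split: Mapping[str, str] | None = None,
) -> None:
    """Write one wide row per replicate-group occurrence of a compound.

    Replicates of the same (compound, assay) pair become additional rows
    so that a read-back round-trips the long table exactly.
    """
    df = table.to_frame()
    df["occurrence"] = df.groupby(["compound_id", "assay_id"]).cumcount()
    wide = df.pivot_table(
        index=["compound_id", "occurrence"],
        columns="assay_id",
        values="label",
        aggfunc="first",
    ).reindex(columns=table.assay_ids)
    wide = wide.reset_index().drop(columns="occurrence")
    wide.insert(1, "smiles", wide["compound_id"].map(smiles or {}))
    wide.insert(2, "split", wide["compound_id"].map(split or {}))
    for aid in table.assay_ids:
        wide[aid] = wide[aid].astype("Int64")
    wide.to_csv(path, index=False)
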