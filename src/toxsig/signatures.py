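"""Compound-protein interaction signatures.

The feature space of the whole pipeline is a dense compounds x proteins
matrix of interaction scores in [0, 1].  Each protein carries a set of
predicted binding sites; a site has a prediction-confidence score
(*BScore*, pre-normalized to [0, 1]) and the ECFP4 fingerprint of its
co-crystallized ligand.  The chemical similarity between a query compound
and a site ligand (*CScore*) is the Sorenson-Dice coefficient of their
fingerprints, and the compound-protein interaction score is

    score(c, p) = max over sites s of p of  BScore(s) * Dice(fp_c, fp_s)

i.e. the best-supported site-level match, a proxy for binding likelihood.
Proteins expose a ``solved`` flag (at least one X-ray structure); the
feature space is conventionally restricted to solved proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fingerprint",
    "BindingSite",
    "ProteinEntry",
    "InteractionMatrix",
    "ecfp4_fingerprint",
    "dice_similarity",
    "interaction_score",
    "build_interaction_matrix",
    "filter_solved",
    "load_protein_library",
    "save_protein_library",
]


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-width bitset representing a molecule's circular substructures."""

    bits: np.ndarray  # uint8 0/1 vector of length width
    width: int

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("fingerprint width must be positive")
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.shape != (self.width,):
            raise ValueError(
                f"bit vector shape {arr.shape} does not match width {self.width}"
            )
        if np.any(arr > 1):
            raise ValueError("bits must be 0/1")
        object.__setattr__(self, "bits", arr)

    @classmethod
    def from_indices(cls, on_bits: Iterable[int], width: int = 1024) -> "Fingerprint":
        arr = np.zeros(width, dtype=np.uint8)
        idx = np.asarray(sorted(set(int(i) for i in on_bits)), dtype=np.int64)
        if idx.size:
            if idx.min() < 0 or idx.max() >= width:
                raise ValueError("bit index out of range for width")
            arr[idx] = 1
        return cls(bits=arr, width=width)

    @property
    def cardinality(self) -> int:
        return int(self.bits.sum())

    @property
    def on_bits(self) -> list[int]:
        return np.flatnonzero(self.bits).tolist()


@dataclass(frozen=True)
class BindingSite:
    """Predicted binding site: confidence score plus co-crystallized ligand."""

    bscore: float
    ligand_fp: Fingerprint

    def __post_init__(self) -> None:
        if not (0.0 <= self.bscore <= 1.0):
            raise ValueError(f"bscore {self.bscore} outside [0, 1]")


@dataclass
class ProteinEntry:
    protein_id: str
    solved: bool = True
    sites: list[BindingSite] = field(default_factory=list)
    pathways: set[str] = field(default_factory=set)


@dataclass
class InteractionMatrix:
    """Dense compounds x proteins score table, all values in [0, 1]."""

    compound_ids: list[str]
    protein_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.compound_ids), len(self.protein_ids)):
            raise ValueError("score shape inconsistent with id lists")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("interaction scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=self.compound_ids, columns=self.protein_ids
        )

    def to_tsv(self, path) -> None:
        # full precision internally; 6 decimals on disk (documented contract)
        df = self.to_frame().round(6)
        df.index.name = "compound_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            compound_ids=[str(i) for i in df.index],
            protein_ids=[str(c) for c in df.columns],
            scores=df.to_numpy(dtype=np.float64),
        )


def ecfp4_fingerprint(smiles: str, width: int = 1024) -> Fingerprint:
    """Extended-connectivity fingerprint of radius 2 folded to ``width`` bits.

    Requires RDKit; raises ValueError for unparsable SMILES.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=width)
    bv = gen.GetFingerprint(mol)
    return Fingerprint.from_indices(bv.GetOnBits(), width=width)


def dice_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Sorenson-Dice coefficient 2|a&b| / (|a|+|b|).

    Two empty fingerprints score 0: absence of features is treated as no
    evidence of similarity, not as identity.
    """
    if a.width != b.width:
        raise ValueError(f"fingerprint width mismatch: {a.width} vs {b.width}")
    denom = a.cardinality + b.cardinality
    if denom == 0:
        return 0.0
    inter = int(np.dot(a.bits.astype(np.int64), b.bits.astype(np.int64)))
    return 2.0 * inter / denom


def interaction_score(compound_fp: Fingerprint, protein: ProteinEntry) -> float:
    """Best site-level BScore x Dice product; 0 for site-less proteins."""
    best = 0.0
    for site in protein.sites:
        s = site.bscore * dice_similarity(compound_fp, site.ligand_fp)
        if s > best:
            best = s
    return best


def build_interaction_matrix(
    compound_ids: Sequence[str],
    fingerprints: Sequence[Fingerprint],
    proteins: Sequence[ProteinEntry],
) -> InteractionMatrix:
    """Score every compound against every protein.

    Vectorized over sites: for each protein the per-site Dice values are
    computed for all compounds at once and the BScore-weighted maximum is
    taken, matching the scalar ``interaction_score`` cell-for-cell.
    """
    if len(compound_ids) != len(fingerprints):
        raise ValueError("compound_ids and fingerprints length mismatch")
    n, m = len(fingerprints), len(proteins)
    scores = np.zeros((n, m), dtype=np.float64)
    if n == 0 or m == 0:
        return InteractionMatrix(list(compound_ids), [p.protein_id for p in proteins], scores)

    width = fingerprints[0].width
    C = np.stack([fp.bits for fp in fingerprints]).astype(np.float64)  # n x width
    card_c = C.sum(axis=1)  # n
    for j, prot in enumerate(proteins):
        col = np.zeros(n)
        for site in prot.sites:
            if site.ligand_fp.width != width:
                raise ValueError("fingerprint width mismatch between compounds and sites")
            lig = site.ligand_fp.bits.astype(np.float64)
            denom = card_c + lig.sum()
            with np.errstate(invalid="ignore", divide="ignore"):
                dice = np.where(denom > 0, 2.0 * (C @ lig) / np.maximum(denom, 1e-300), 0.0)
            np.maximum(col, site.bscore * dice, out=col)
        scores[:, j] = col
    return InteractionMatrix(list(compound_ids), [p.protein_id for p in proteins], scores)


def filter_solved(
    matrix: InteractionMatrix, proteins: Sequence[ProteinEntry]
) -> InteractionMatrix:
    """Restrict the feature space to structure-solved proteins, order kept."""
    solved = {p.protein_id for p in proteins if p.solved}
    unknown = set(matrix.protein_ids) - {p.protein_id for p in proteins}
    if unknown:
        raise ValueError(f"matrix columns absent from protein library: {sorted(unknown)[:5]}")
    keep = [j for j, pid in enumerate(matrix.protein_ids) if pid in solved]
    return InteractionMatrix(
        compound_ids=list(matrix.compound_ids),
        protein_ids=[matrix.protein_ids[j] for j in keep],
        scores=matrix.scores[:, keep] if keep else np.zeros((len(matrix.compound_ids), 0)),
    )


def save_protein_library(proteins: Sequence[ProteinEntry], path) -> None:
    payload = [
        {
            "protein_id": p.protein_id,
            "solved": bool(p.solved),
            "pathways": sorted(p.pathways),
            "sites": [
                {"bscore": round(float(s.bscore), 10), "ligand_bits": s.ligand_fp.on_bits,
                 "width": s.ligand_fp.width}
                for s in p.sites
            ],
        }
        for p in proteins
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_protein_library(path) -> list[ProteinEntry]:
    with open(path) as fh:
        payload = json.load(fh)
    proteins = []
    seen: set[str] = set()
    for rec in payload:
        pid = str(rec["protein_id"])
        if pid in seen:
            raise ValueError(f"duplicate protein_id {pid}")
        seen.add(pid)
        sites = [
            BindingSite(
                bscore=float(s["bscore"]),
                ligand_fp=Fingerprint.from_indices(s["ligand_bits"], width=int(s.get("width", 1024))),
            )
            for s in rec.get("sites", [])
        ]
        proteins.append(
            ProteinEntry(
                protein_id=pid,
                solved=bool(rec.get("solved", True)),
                sites=sites,
                pathways=set(rec.get("pathways", [])),
            )
        )
    return proteins
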