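"""Synthetic qHTS-like benchmark with a planted causal mechanism.

Real multi-assay toxicity panels (a dozen binary endpoints over ~10k
compounds, inactive:active ratios of 5-70, replicate measurements with
occasional conflicts) cannot be bundled with a package, so this module
generates structurally faithful stand-ins in which the ground truth is
known by construction:

* a protein library whose members carry 1-5 predicted binding sites
  (confidence scores + sparse ligand fingerprints) and pathway
  annotations, with a small *causal* subset drawn from a few causal
  pathways;
* compounds, a fraction of which are mutated copies of causal-site
  ligands and therefore score highly against causal proteins;
* per-assay binary labels drawn from a logistic model on the causal
  interaction scores, with the intercept calibrated by bisection so the
  realized imbalance ratio hits its target, plus label noise, replicate
  rows, and injected 50/50 label conflicts.

Everything is deterministic under the config seed, and the emitted files
are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from .chem import AssayLabelTable, CompoundRecord, write_label_csv
from .enrichment import PathwayMap, write_gmt
from .signatures import (
    BindingSite,
    Fingerprint,
    InteractionMatrix,
    ProteinEntry,
    build_interaction_matrix,
    save_protein_library,
)

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticBundle",
           "generate_protein_library", "generate_compounds_and_labels",
           "generate_bundle"]


@dataclass
class SyntheticConfig:
    """Benchmark shape and signal strength.

    The defaults define the package's standard study conditions: 2000
    compounds x 500 proteins, 12 assays at imbalance ratio 8, 20 causal
    proteins drawn from 4 causal pathways, logistic effect size 8.
    """

    n_compounds: int = 2000
    n_proteins: int = 500
    n_assays: int = 12
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (20, 50)
    n_causal_proteins: int = 20
    n_causal_pathways: int = 4
    fingerprint_width: int = 1024
    sites_per_protein_range: tuple[int, int] = (1, 5)
    bscore_alpha: float = 5.0  # Beta distribution of site confidence scores
    bscore_beta: float = 2.0
    effect_size: float = 8.0  # logistic weight scale; 0 = null model
    target_imbalance_ratio: float = 8.0
    assay_imbalance_ratios: tuple[float, ...] | None = None  # per-assay override
    label_noise: float = 0.02
    duplicate_fraction: float = 0.05
    conflict_fraction: float = 0.2  # fraction of duplicated compounds made conflicting
    test_fraction: float = 0.2
    seed: int = 0
    # planted-mechanism internals (see the fingerprint model in docs)
    causal_like_fraction: float = 0.15  # compounds built from causal-site ligands
    ligand_bits_range: tuple[int, int] = (30, 60)  # fingerprint cardinality
    mutation_rate: float = 0.15  # fraction of a causal-like compound's bits
    #   drawn from ordinary chemistry instead of the toxicophore pool
    causal_bscore_min: float = 0.7  # confidence floor for the causal site
    weight_range: tuple[float, float] = (0.5, 1.5)
    solved_fraction: float = 0.9
    # shared-substructure vocabulary: all fingerprints draw their bits from
    # a popularity-weighted pool (compounds share substructures, so score
    # vectors are correlated / low-rank, as in real chemistry), and every
    # non-causal compound is a mutated copy of one of a limited number of
    # scaffolds (chemical series)
    bit_pool_size: int = 256
    causal_pool_size: int = 80  # disjoint toxicophore bit vocabulary
    n_scaffolds: int = 50
    scaffold_mutation_rate: float = 0.2
    causal_mix: int = 3  # causal ligands blended per causal-like compound

    def __post_init__(self) -> None:
        if self.n_causal_proteins > self.n_proteins:
            raise ValueError("more causal proteins than proteins")
        if self.n_causal_pathways > self.n_pathways:
            raise ValueError("more causal pathways than pathways")
        if self.target_imbalance_ratio < 1:
            raise ValueError("target imbalance ratio must be >= 1")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")

    def imbalance_targets(self) -> list[float]:
        if self.assay_imbalance_ratios is not None:
            if len(self.assay_imbalance_ratios) != self.n_assays:
                raise ValueError("assay_imbalance_ratios length != n_assays")
            return list(self.assay_imbalance_ratios)
        return [self.target_imbalance_ratio] * self.n_assays

    def assay_ids(self) -> list[str]:
        return [f"TOX-{i + 1:02d}" for i in range(self.n_assays)]


@dataclass
class GroundTruth:
    causal_protein_ids: list[str]
    causal_pathway_ids: list[str]
    weights: dict[str, float]  # nonzero exactly on causal proteins
    realized_imbalance_ratios: dict[str, float]
    injected_conflicts: list[tuple[str, str]]  # (compound_id, assay_id)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["injected_conflicts"] = [list(t) for t in self.injected_conflicts]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    proteins: list[ProteinEntry]
    pathway_map: PathwayMap
    compounds: list[CompoundRecord]
    labels: AssayLabelTable
    matrix: InteractionMatrix
    truth: GroundTruth
    split: dict[str, str] = field(default_factory=dict)


@dataclass
class _BitVocabulary:
    """Shared substructure vocabulary for all generated fingerprints.

    ``general`` bits model ordinary chemistry, drawn with popularity
    weights so fingerprints overlap the way related molecules do;
    ``causal`` bits are a disjoint toxicophore vocabulary used by the
    causal binding-site ligands and causal-like compounds.
    """

    general: np.ndarray
    general_p: np.ndarray
    causal: np.ndarray


def _make_vocabulary(cfg: SyntheticConfig, rng: np.random.Generator) -> _BitVocabulary:
    total = cfg.bit_pool_size + cfg.causal_pool_size
    if total > cfg.fingerprint_width:
        raise ValueError("bit pools exceed fingerprint width")
    chosen = rng.choice(cfg.fingerprint_width, size=total, replace=False)
    # gentle popularity gradient (2:1 most- to least-common substructure):
    # strong enough to correlate fingerprints, weak enough that baseline
    # Dice stays well below the toxicophore signal
    weights = 1.0 / (np.arange(1, cfg.bit_pool_size + 1) + float(cfg.bit_pool_size))
    return _BitVocabulary(
        general=chosen[: cfg.bit_pool_size],
        general_p=weights / weights.sum(),
        causal=chosen[cfg.bit_pool_size:],
    )


def _pool_fingerprint(
    rng: np.random.Generator, vocab: _BitVocabulary, width: int, lo: int, hi: int
) -> Fingerprint:
    card = int(rng.integers(lo, hi + 1))
    idx = rng.choice(vocab.general, size=card, replace=False, p=vocab.general_p)
    return Fingerprint.from_indices(idx, width=width)


def generate_protein_library(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    vocab: _BitVocabulary | None = None,
) -> tuple[list[ProteinEntry], PathwayMap, list[str], list[str]]:
    """Proteins with sites + pathway map; returns causal pathway/protein ids.

    Pathway memberships may overlap.  Causal pathways share most of the
    causal protein set — toxicity mechanisms in real pathway databases
    are interconnected modules whose member pathways recruit the same
    core proteins — so over-representation of the causal set is
    detectable even when the selection covers a sizeable slice of the
    universe.  Causal proteins are always structure-solved, and their
    first site (the planted binding site) gets a high confidence score.
    """
    protein_ids = [f"P{i:04d}" for i in range(cfg.n_proteins)]
    pathway_ids = [f"PW{i:03d}" for i in range(cfg.n_pathways)]
    lo, hi = cfg.pathway_size_range
    if lo < 1 or hi > cfg.n_proteins:
        raise ValueError("infeasible pathway_size_range")

    causal_pathways = sorted(
        str(p) for p in rng.choice(pathway_ids, size=cfg.n_causal_pathways, replace=False)
    )
    causal_proteins = sorted(
        str(p) for p in rng.choice(protein_ids, size=cfg.n_causal_proteins, replace=False)
    )
    causal_set = set(causal_proteins)
    others = [p for p in protein_ids if p not in causal_set]

    members: dict[str, set[str]] = {}
    for pw in pathway_ids:
        size = int(rng.integers(lo, hi + 1))
        if pw in causal_pathways:
            core = {p for p in causal_proteins if rng.uniform() < 0.75}
            fill = rng.choice(others, size=max(0, size - len(core)), replace=False)
            members[pw] = core | set(fill)
        else:
            members[pw] = set(rng.choice(protein_ids, size=size, replace=False))
    # every causal protein belongs to at least one causal pathway
    for p in causal_proteins:
        if not any(p in members[pw] for pw in causal_pathways):
            members[causal_pathways[int(rng.integers(len(causal_pathways)))]].add(p)

    vocab = vocab or _make_vocabulary(cfg, np.random.default_rng(cfg.seed))
    s_lo, s_hi = cfg.sites_per_protein_range
    proteins = []
    for pid in protein_ids:
        n_sites = int(rng.integers(s_lo, s_hi + 1))
        sites = []
        for s in range(n_sites):
            if pid in causal_set and s == 0:
                # the planted site: confident prediction, toxicophore ligand
                bscore = float(rng.uniform(cfg.causal_bscore_min, 1.0))
                # full-size ligands so every planted site carries comparable
                # signal (a tiny co-crystallized fragment would mute it)
                lo_l, hi_l = cfg.ligand_bits_range
                card = min(int(rng.integers((lo_l + hi_l) // 2, hi_l + 1)), len(vocab.causal))
                lig = Fingerprint.from_indices(
                    rng.choice(vocab.causal, size=card, replace=False),
                    width=cfg.fingerprint_width,
                )
            else:
                bscore = float(rng.beta(cfg.bscore_alpha, cfg.bscore_beta))
                lig = _pool_fingerprint(
                    rng, vocab, cfg.fingerprint_width, *cfg.ligand_bits_range
                )
            sites.append(BindingSite(bscore=round(bscore, 10), ligand_fp=lig))
        solved = bool(rng.uniform() < cfg.solved_fraction) or pid in causal_set
        pathways = {pw for pw in pathway_ids if pid in members[pw]}
        proteins.append(ProteinEntry(protein_id=pid, solved=solved, sites=sites, pathways=pathways))

    pmap = PathwayMap(
        pathways=members,
        universe_size=len(set().union(*members.values())),
        descriptions={pw: f"synthetic pathway {pw}" for pw in pathway_ids},
    )
    return proteins, pmap, causal_pathways, causal_proteins


def _mutate_scaffold(
    fp: Fingerprint, rate: float, vocab: _BitVocabulary, rng: np.random.Generator
) -> Fingerprint:
    """Drop each on-bit with probability ``rate``; refill from the vocabulary."""
    on = np.array(fp.on_bits)
    keep = on[rng.uniform(size=on.size) >= rate]
    lost = on.size - keep.size
    if lost:
        mask = ~np.isin(vocab.general, keep)
        cand, p = vocab.general[mask], vocab.general_p[mask]
        extra = rng.choice(cand, size=lost, replace=False, p=p / p.sum())
        keep = np.concatenate([keep, extra])
    return Fingerprint.from_indices(keep, width=fp.width)


def _calibrate_intercept(
    logits: np.ndarray, u: np.ndarray, n_target: int, max_steps: int = 50
) -> float:
    """Bisect the intercept b so that #(u < sigmoid(logits - b)) == n_target.

    The active count is monotone non-increasing in b; with continuous u
    the target count is reached exactly in well under ``max_steps``.
    """

    def count(b: float) -> int:
        return int((u < expit(logits - b)).sum())

    lo_b = float(np.min(logits)) - 40.0
    hi_b = float(np.max(logits)) + 40.0
    if not (count(hi_b) <= n_target <= count(lo_b)):
        raise RuntimeError("calibration target outside the bracketable range")
    for _ in range(max_steps):
        mid = 0.5 * (lo_b + hi_b)
        c = count(mid)
        if c > n_target:
            lo_b = mid
        elif c < n_target:
            hi_b = mid
        else:
            return mid
    raise RuntimeError(
        f"intercept calibration failed to reach target count {n_target} "
        f"within {max_steps} bisection steps"
    )


def generate_compounds_and_labels(
    cfg: SyntheticConfig,
    proteins: list[ProteinEntry],
    causal_proteins: list[str],
    rng: np.random.Generator,
    vocab: _BitVocabulary | None = None,
) -> tuple[list[CompoundRecord], AssayLabelTable, GroundTruth, InteractionMatrix,
           dict[str, str]]:
    """Compound fingerprints, per-assay labels, ground truth, score matrix.

    A ``causal_like_fraction`` of compounds are mutated copies of a causal
    site's ligand (high Dice similarity at that protein); labels follow a
    logistic model on the weighted causal score sum with the intercept
    calibrated so the *post-noise* expected imbalance ratio matches each
    assay's target.
    """
    vocab = vocab or _make_vocabulary(cfg, np.random.default_rng(cfg.seed))
    compound_ids = [f"C{i:05d}" for i in range(cfg.n_compounds)]
    by_id = {p.protein_id: p for p in proteins}
    causal_sites = {pid: by_id[pid].sites[0].ligand_fp for pid in causal_proteins}

    scaffolds = [
        _pool_fingerprint(rng, vocab, cfg.fingerprint_width, *cfg.ligand_bits_range)
        for _ in range(cfg.n_scaffolds)
    ]
    is_causal_like = rng.uniform(size=cfg.n_compounds) < cfg.causal_like_fraction
    scaffold_of = rng.integers(0, cfg.n_scaffolds, size=cfg.n_compounds)
    lo, hi = cfg.ligand_bits_range
    fingerprints = []
    for i in range(cfg.n_compounds):
        if is_causal_like[i] and cfg.effect_size != 0:
            # blend toxicophore bits from a few causal-site ligands with
            # ordinary chemistry (the "mutation" of the causal ligands)
            card = int(rng.integers(lo, hi + 1))
            picks = rng.choice(
                len(causal_proteins),
                size=min(cfg.causal_mix, len(causal_proteins)),
                replace=False,
            )
            union = np.unique(
                np.concatenate(
                    [causal_sites[causal_proteins[k]].on_bits for k in picks]
                )
            )
            n_caus = min(int(round((1.0 - cfg.mutation_rate) * card)), union.size)
            caus_bits = rng.choice(union, size=n_caus, replace=False)
            gen_bits = rng.choice(
                vocab.general, size=card - n_caus, replace=False, p=vocab.general_p
            )
            fingerprints.append(
                Fingerprint.from_indices(
                    np.concatenate([caus_bits, gen_bits]), width=cfg.fingerprint_width
                )
            )
        else:
            fingerprints.append(
                _mutate_scaffold(
                    scaffolds[scaffold_of[i]], cfg.scaffold_mutation_rate, vocab, rng
                )
            )

    matrix = build_interaction_matrix(compound_ids, fingerprints, proteins)
    col = {pid: j for j, pid in enumerate(matrix.protein_ids)}
    weights = {pid: float(rng.uniform(*cfg.weight_range)) for pid in causal_proteins}
    w = np.zeros(len(matrix.protein_ids))
    for pid, wt in weights.items():
        w[col[pid]] = wt
    z = cfg.effect_size * (matrix.scores @ w)

    nu = cfg.label_noise
    assay_ids = cfg.assay_ids()
    labels_by_assay: dict[str, np.ndarray] = {}
    realized: dict[str, float] = {}
    for aid, ir in zip(assay_ids, cfg.imbalance_targets()):
        m_target = cfg.n_compounds / (1.0 + ir)
        m_pre = (m_target - cfg.n_compounds * nu) / (1.0 - 2.0 * nu)
        if m_pre < 0:
            raise RuntimeError(
                f"assay {aid}: imbalance ratio {ir} unreachable at label noise {nu} "
                f"(noise alone caps the ratio at {(1 - nu) / nu:.1f})"
            )
        u = rng.uniform(size=cfg.n_compounds)
        flip = rng.uniform(size=cfg.n_compounds) < nu
        # re-bisect with a corrected pre-noise target until the realized
        # (post-noise) ratio lands inside the 10% band; the flip mask is
        # fixed, so each correction is an exact count adjustment
        target_pre = int(round(m_pre))
        y = None
        for _ in range(10):
            b = _calibrate_intercept(z, u, target_pre)
            y = np.where(flip, 1 - (u < expit(z - b)), (u < expit(z - b))).astype(np.int64)
            actives = int(y.sum())
            if actives > 0 and abs((cfg.n_compounds - actives) / actives - ir) / ir <= 0.10:
                break
            target_pre = min(cfg.n_compounds, max(0, target_pre + int(round(m_target - actives))))
        else:
            raise RuntimeError(
                f"assay {aid}: could not calibrate the realized imbalance ratio "
                f"to within 10% of {ir}"
            )
        labels_by_assay[aid] = y
        realized[aid] = round(float((y == 0).sum() / (y == 1).sum()), 6)

    rows: list[tuple[str, str, int]] = []
    for i, cid in enumerate(compound_ids):
        for aid in assay_ids:
            rows.append((cid, aid, int(labels_by_assay[aid][i])))

    n_dup = int(round(cfg.duplicate_fraction * cfg.n_compounds))
    dup_idx = sorted(rng.choice(cfg.n_compounds, size=n_dup, replace=False)) if n_dup else []
    n_conf = int(round(cfg.conflict_fraction * n_dup))
    conflict_idx = set(dup_idx[:n_conf])  # dup_idx already randomly chosen
    injected: list[tuple[str, str]] = []
    for i in dup_idx:
        cid = compound_ids[i]
        for aid in assay_ids:
            lab = int(labels_by_assay[aid][i])
            if i in conflict_idx:
                rows.append((cid, aid, 1 - lab))
                injected.append((cid, aid))
            else:
                rows.append((cid, aid, lab))

    n_test = int(round(cfg.test_fraction * cfg.n_compounds))
    test_ids = set(rng.choice(compound_ids, size=n_test, replace=False))
    split = {cid: ("test" if cid in test_ids else "train") for cid in compound_ids}

    compounds = [
        CompoundRecord(
            compound_id=cid,
            fingerprint=fingerprints[i],
            labels={aid: int(labels_by_assay[aid][i]) for aid in assay_ids},
        )
        for i, cid in enumerate(compound_ids)
    ]
    truth = GroundTruth(
        causal_protein_ids=list(causal_proteins),
        causal_pathway_ids=[],  # filled by generate_bundle
        weights={pid: round(wt, 10) for pid, wt in weights.items()},
        realized_imbalance_ratios=realized,
        injected_conflicts=injected,
    )
    table = AssayLabelTable(rows=rows, assay_ids=assay_ids)
    return compounds, table, truth, matrix, split


def generate_bundle(cfg: SyntheticConfig, out_dir: str | Path | None = None) -> SyntheticBundle:
    """Full benchmark bundle; optionally written to disk.

    Files emitted: ``labels.csv`` (wide, with split column),
    ``protein_library.json``, ``pathways.gmt``, ``interaction_matrix.tsv``,
    ``ground_truth.json``.  Byte-identical for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    vocab = _make_vocabulary(cfg, rng)
    proteins, pmap, causal_pathways, causal_proteins = generate_protein_library(cfg, rng, vocab)
    compounds, table, truth, matrix, split = generate_compounds_and_labels(
        cfg, proteins, causal_proteins, rng, vocab=vocab
    )
    truth.causal_pathway_ids = list(causal_pathways)
    bundle = SyntheticBundle(
        config=cfg, proteins=proteins, pathway_map=pmap, compounds=compounds,
        labels=table, matrix=matrix, truth=truth, split=split,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_label_csv(table, out / "labels.csv", split=split)
        save_protein_library(proteins, out / "protein_library.json")
        write_gmt(pmap, out / "pathways.gmt")
        matrix.to_tsv(out / "interaction_matrix.tsv")
        truth.to_json(out / "ground_truth.json")
    return bundle
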