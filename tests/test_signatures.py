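"""Fingerprints, Dice similarity, and interaction-score matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxsig.signatures import (
    BindingSite,
    Fingerprint,
    InteractionMatrix,
    ProteinEntry,
    build_interaction_matrix,
    dice_similarity,
    ecfp4_fingerprint,
    filter_solved,
    interaction_score,
    load_protein_library,
    save_protein_library,
)

WIDTH = 64


def fp(*bits, width=WIDTH):
    return Fingerprint.from_indices(bits, width=width)


bitsets = st.sets(st.integers(min_value=0, max_value=WIDTH - 1), max_size=WIDTH)


class TestDice:
    def test_textbook_example(self):
        assert dice_similarity(fp(1, 2, 3), fp(2, 3, 4)) == pytest.approx(2 * 2 / 6)

    def test_identity_and_disjoint(self):
        assert dice_similarity(fp(1, 5, 9), fp(1, 5, 9)) == 1.0
        assert dice_similarity(fp(1, 2), fp(3, 4)) == 0.0

    def test_both_empty_score_zero(self):
        assert dice_similarity(fp(), fp()) == 0.0

    def test_width_mismatch_raises(self):
        with pytest.raises(ValueError, match="width"):
            dice_similarity(fp(1), Fingerprint.from_indices([1], width=32))

    @settings(max_examples=100, derandomize=True)
    @given(a=bitsets, b=bitsets)
    def test_symmetric_bounded_and_identity_only_when_equal(self, a, b):
        d = dice_similarity(fp(*a), fp(*b))
        assert d == dice_similarity(fp(*b), fp(*a))
        assert 0.0 <= d <= 1.0
        if a or b:
            assert (d == 1.0) == (a == b and bool(a))


class TestEcfp4:
    def test_deterministic(self):
        a = ecfp4_fingerprint("CC(=O)Oc1ccccc1C(=O)O")
        b = ecfp4_fingerprint("CC(=O)Oc1ccccc1C(=O)O")
        assert np.array_equal(a.bits, b.bits)
        assert a.width == 1024 and a.cardinality > 0

    def test_self_similarity_is_one(self):
        benz = ecfp4_fingerprint("c1ccccc1")
        assert dice_similarity(benz, benz) == 1.0

    def test_dissimilar_molecules_have_low_dice(self):
        # methane shares essentially no circular environments with a
        # 20-atom heteroaromatic
        methane = ecfp4_fingerprint("C")
        heteroaromatic = ecfp4_fingerprint("n1c2ccccc2c3ccccc13CCNC(=O)c1ccco1")
        assert dice_similarity(methane, heteroaromatic) < 0.2

    def test_unparsable_raises(self):
        with pytest.raises(ValueError):
            ecfp4_fingerprint("not_a_smiles")


class TestInteractionScore:
    def test_max_of_bscore_times_dice(self):
        compound = fp(0, 1, 2, 3)
        protein = ProteinEntry(
            "p",
            sites=[
                BindingSite(0.8, fp(0, 1, 2, 3, 4, 5, 6, 7)),  # dice 8/12 = 0.667
                BindingSite(0.5, fp(0, 1, 2, 3)),  # dice 1.0
            ],
        )
        assert interaction_score(compound, protein) == pytest.approx(
            max(0.8 * (2 * 4 / 12), 0.5 * 1.0)
        )

    def test_no_sites_scores_zero(self):
        assert interaction_score(fp(1), ProteinEntry("p", sites=[])) == 0.0

    def test_perfect_match_returns_bscore(self):
        assert interaction_score(
            fp(3, 4), ProteinEntry("p", sites=[BindingSite(0.63, fp(3, 4))])
        ) == pytest.approx(0.63)

    def test_monotone_in_sites_and_bscore(self, rng):
        compound = fp(*rng.choice(WIDTH, 10, replace=False))
        sites = [
            BindingSite(float(rng.uniform()), fp(*rng.choice(WIDTH, 8, replace=False)))
            for _ in range(4)
        ]
        for k in range(1, 5):
            less = interaction_score(compound, ProteinEntry("p", sites=sites[: k - 1]))
            more = interaction_score(compound, ProteinEntry("p", sites=sites[:k]))
            assert more >= less
        boosted = [BindingSite(min(1.0, s.bscore + 0.2), s.ligand_fp) for s in sites]
        assert interaction_score(
            compound, ProteinEntry("p", sites=boosted)
        ) >= interaction_score(compound, ProteinEntry("p", sites=sites))


class TestMatrix:
    @staticmethod
    def _random_setup(rng, n=12, m=15):
        fps = [
            Fingerprint.from_indices(rng.choice(WIDTH, rng.integers(0, 12), replace=False),
                                     width=WIDTH)
            for _ in range(n)
        ]
        prots = [
            ProteinEntry(
                f"p{j:02d}",
                solved=bool(rng.uniform() < 0.7),
                sites=[
                    BindingSite(
                        float(rng.uniform()),
                        Fingerprint.from_indices(
                            rng.choice(WIDTH, rng.integers(1, 10), replace=False), width=WIDTH
                        ),
                    )
                    for _ in range(rng.integers(0, 4))
                ],
            )
            for j in range(m)
        ]
        return [f"c{i:02d}" for i in range(n)], fps, prots

    def test_matches_scalar_double_loop_oracle(self, rng):
        cids, fps, prots = self._random_setup(rng)
        mat = build_interaction_matrix(cids, fps, prots)
        for i, cfp in enumerate(fps):
            for j, prot in enumerate(prots):
                assert mat.scores[i, j] == pytest.approx(
                    interaction_score(cfp, prot), abs=1e-12
                )

    def test_protein_permutation_permutes_columns(self, rng):
        cids, fps, prots = self._random_setup(rng)
        mat = build_interaction_matrix(cids, fps, prots)
        perm = rng.permutation(len(prots))
        mat_p = build_interaction_matrix(cids, fps, [prots[j] for j in perm])
        assert np.allclose(mat_p.scores, mat.scores[:, perm])

    def test_filter_solved_keeps_order(self, rng):
        cids, fps, prots = self._random_setup(rng)
        mat = build_interaction_matrix(cids, fps, prots)
        kept = filter_solved(mat, prots)
        expected = [p.protein_id for p in prots if p.solved]
        assert kept.protein_ids == expected
        all_solved = [ProteinEntry(p.protein_id, True, p.sites) for p in prots]
        assert filter_solved(mat, all_solved).protein_ids == mat.protein_ids
        none_solved = [ProteinEntry(p.protein_id, False, p.sites) for p in prots]
        assert filter_solved(mat, none_solved).protein_ids == []

    def test_causal_compounds_score_higher_at_causal_proteins(self, small_bundle):
        truth = small_bundle.truth
        cols = [small_bundle.matrix.protein_ids.index(p) for p in truth.causal_protein_ids]
        causal_scores = small_bundle.matrix.scores[:, cols].mean(axis=1)
        # compounds the generator built from causal ligands have weights-driven
        # high label propensity; compare labeled actives vs inactives instead
        y = np.array([c.labels["TOX-01"] for c in small_bundle.compounds])
        assert causal_scores[y == 1].mean() > causal_scores[y == 0].mean()

    def test_tsv_round_trip(self, tmp_path, rng):
        cids, fps, prots = self._random_setup(rng, n=5, m=4)
        mat = build_interaction_matrix(cids, fps, prots)
        mat.to_tsv(tmp_path / "m.tsv")
        back = InteractionMatrix.from_tsv(tmp_path / "m.tsv")
        assert back.compound_ids == mat.compound_ids
        assert back.protein_ids == mat.protein_ids
        assert np.allclose(back.scores, mat.scores, atol=1e-6)


def test_protein_library_json_round_trip(tmp_path, small_bundle):
    path = tmp_path / "lib.json"
    save_protein_library(small_bundle.proteins, path)
    back = load_protein_library(path)
    assert len(back) == len(small_bundle.proteins)
    for a, b in zip(back, small_bundle.proteins):
        assert a.protein_id == b.protein_id
        assert a.solved == b.solved
        assert a.pathways == b.pathways
        assert len(a.sites) == len(b.sites)
        assert a.sites[0].bscore == pytest.approx(b.sites[0].bscore)
        assert np.array_equal(a.sites[0].ligand_fp.bits, b.sites[0].ligand_fp.bits)
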