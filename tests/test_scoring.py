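"""piTM/pIS scores, clash detection and the ranking score.

The derived expected values are computed by hand arithmetic and
cross-checked against the naive triple-loop oracles in oracles.py.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import two_residue_interface
from oracles import allpairs_clash_count, naive_pis, naive_pitm
from pisrank import (
    FixtureRecipe,
    InterfaceSet,
    PaeMatrix,
    ScoringError,
    Token,
    TokenMappingError,
    UniformPae,
    ZeroPae,
    d0,
    detect_clashes,
    find_interface,
    make_complex,
    make_decoys,
    make_pae,
    make_random_complex,
    native_style_ranking,
    pis,
    pitm,
    ranking_score,
    score_model,
)


class TestD0:
    def test_linear_branch(self):
        assert d0(21) == pytest.approx(0.02 * 21)
        assert d0(1) == pytest.approx(0.02)

    def test_cubic_branch_at_boundary(self):
        assert d0(22) == pytest.approx(1.24 * 7 ** (1 / 3) - 1.8)

    @pytest.mark.parametrize("n", [1, 5, 21, 22, 50, 500])
    def test_positive_everywhere(self, n):
        assert d0(n) > 0

    def test_rejects_nonpositive_size(self):
        with pytest.raises(ValueError):
            d0(0)


class TestPitm:
    def test_zero_pae_gives_one(self, dimer_structure):
        iface = find_interface(dimer_structure)
        bundle = make_pae(dimer_structure, ZeroPae())
        assert pitm(bundle.pae, iface) == 1.0

    def test_hand_evaluated_two_residue_case(self):
        # |I| = 2, d0 = 0.04, e = 4 off-diagonal:
        # max_i (1/2)(1 + 1/(1 + (4/0.04)^2)) = 0.5 + 0.5/10001
        pae, iface = two_residue_interface(4.0)
        expected = 0.5 * (1 + 1 / (1 + (4 / 0.04) ** 2))
        assert pitm(pae, iface) == pytest.approx(expected, abs=1e-15)
        assert pitm(pae, iface) == pytest.approx(0.50005, abs=1e-5)

    def test_huge_errors_tend_to_self_term(self):
        pae, iface = two_residue_interface(1e6)
        # only the i = j term survives: value -> 1/|I|
        assert pitm(pae, iface) == pytest.approx(0.5, abs=1e-6)

    def test_asymmetric_pae_uses_row_alignment(self):
        # row A has small errors, row B large: the max picks row A's frame
        pae, iface = two_residue_interface(0.0)
        pae.values[1, 0] = 100.0
        expected = 1.0  # aligning on A: both terms are 1
        assert pitm(pae, iface) == pytest.approx(expected)

    def test_missing_token_raises(self, dimer_structure):
        iface = find_interface(dimer_structure)
        tokens = [Token("A", i) for i in range(1, 6)]  # chain B missing
        pae = PaeMatrix(values=np.zeros((5, 5)), token_map=tokens)
        with pytest.raises(TokenMappingError, match="B/"):
            pitm(pae, iface)

    def test_empty_interface_rejected(self):
        pae = PaeMatrix(values=np.zeros((1, 1)), token_map=[Token("A", 1)])
        empty = InterfaceSet(residues=(), by_chain={}, cutoff_used=4.5)
        with pytest.raises(ScoringError):
            pitm(pae, empty)


class TestPis:
    def test_zero_pae_gives_one(self, dimer_structure):
        iface = find_interface(dimer_structure)
        bundle = make_pae(dimer_structure, ZeroPae())
        assert pis(bundle.pae, iface) == 1.0

    def test_hand_evaluated_symmetric_case(self):
        # e_ab = e_ba = d0(2): each chain contributes (1/2)(1/2)
        pae, iface = two_residue_interface(0.04)
        assert pis(pae, iface) == pytest.approx(0.5, abs=1e-12)

    def test_chain_with_empty_subset_contributes_zero(self, dimer_structure):
        """A 3-chain complex whose chain C is far away scores like the dimer."""
        trimer_atoms = list(dimer_structure.atoms)
        from pisrank import AtomRecord

        for r in range(1, 6):
            trimer_atoms.append(
                AtomRecord("C", r, "ALA", "CA", "C", (r * 4.5, 500.0, 0.0))
            )
        from pisrank import ComplexStructure

        trimer = ComplexStructure(model_id="trimer", atoms=trimer_atoms)
        iface2 = find_interface(dimer_structure)
        iface3 = find_interface(trimer)
        assert iface3.residues == iface2.residues  # chain C not interfacial
        bundle = make_pae(trimer, UniformPae(1.0, 6.0), seed=5)
        # dimer-restricted PAE: select the tokens of chains A and B
        keep = [i for i, t in enumerate(bundle.pae.token_map) if t.chain_id != "C"]
        sub = PaeMatrix(
            values=bundle.pae.values[np.ix_(keep, keep)],
            token_map=[bundle.pae.token_map[i] for i in keep],
        )
        assert pis(bundle.pae, iface3) == pytest.approx(pis(sub, iface2), abs=1e-12)

    def test_two_chain_reduction(self):
        """For C = 2 with symmetric PAE, pIS is the mean of the two per-chain maxima."""
        rng = np.random.default_rng(11)
        tokens = [Token("A", i) for i in range(1, 4)] + [Token("B", i) for i in range(1, 4)]
        raw = rng.uniform(0, 8, size=(6, 6))
        sym = (raw + raw.T) / 2
        np.fill_diagonal(sym, 0)
        pae = PaeMatrix(values=sym, token_map=tokens)
        residues = tuple((t.chain_id, t.residue_index) for t in tokens)
        iface = InterfaceSet(
            residues=residues,
            by_chain={"A": residues[:3], "B": residues[3:]},
            cutoff_used=4.5,
        )
        norm = d0(6)
        terms = 1 / (1 + (sym / norm) ** 2)
        term_a = terms[3:, :3].sum(axis=1).max() / 6  # align on B, sum over I_A
        term_b = terms[:3, 3:].sum(axis=1).max() / 6
        assert pis(pae, iface) == pytest.approx(term_a + term_b, abs=1e-12)
        assert pis(pae, iface) == pytest.approx(2 * (term_a + term_b) / 2, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_loops(self, seed):
        structure = make_random_complex(seed, n_chains=3, residues_per_chain=6)
        iface = find_interface(structure, cutoff=8.0)
        if not 1 <= iface.size <= 30:
            pytest.skip("geometry gave no scorable interface")
        bundle = make_pae(structure, UniformPae(0.2, 15.0), seed=seed)
        token_index = bundle.pae.token_index()
        assert pitm(bundle.pae, iface) == pytest.approx(
            naive_pitm(bundle.pae.values, token_index, list(iface.residues)), abs=1e-12
        )
        assert pis(bundle.pae, iface) == pytest.approx(
            naive_pis(
                bundle.pae.values, token_index, list(iface.residues), iface.by_chain
            ),
            abs=1e-12,
        )


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    scale=st.floats(0.1, 30.0),
    n_res=st.integers(2, 8),
)
def test_score_bounds_property(seed, scale, n_res):
    """0 <= piTM, pIS <= 1 for arbitrary nonnegative PAE matrices."""
    structure, _ = make_complex(FixtureRecipe(seed=0, residues_per_chain=n_res))
    iface = find_interface(structure)
    bundle = make_pae(structure, UniformPae(0.0, scale), seed=seed)
    p1 = pitm(bundle.pae, iface)
    p2 = pis(bundle.pae, iface)
    assert 0.0 < p1 <= 1.0
    assert 0.0 <= p2 <= 1.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 10_000), lam=st.floats(1.0, 20.0))
def test_scaling_pae_never_increases_scores(seed, lam):
    structure, _ = make_complex(FixtureRecipe(seed=0))
    iface = find_interface(structure)
    bundle = make_pae(structure, UniformPae(0.1, 10.0), seed=seed)
    scaled = PaeMatrix(values=bundle.pae.values * lam, token_map=bundle.pae.token_map)
    assert pitm(scaled, iface) <= pitm(bundle.pae, iface) + 1e-12
    assert pis(scaled, iface) <= pis(bundle.pae, iface) + 1e-12


class TestClashes:
    def test_well_separated_dimer_clash_free(self, dimer_structure):
        assert detect_clashes(dimer_structure) == (False, 0)

    def test_overlapping_chains_flagged(self, dimer_structure):
        collided = make_decoys(dimer_structure, [(0.0, -4.4)])[0]
        has_clash, count = detect_clashes(collided)
        assert has_clash and count > 0
        assert count == allpairs_clash_count(collided, 1.1)

    def test_exact_threshold_distance_not_counted(self):
        from pisrank import AtomRecord, ComplexStructure

        atoms = [
            AtomRecord("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            AtomRecord("B", 1, "ALA", "CA", "C", (1.1, 0.0, 0.0)),
        ]
        structure = ComplexStructure(model_id="pair", atoms=atoms)
        assert detect_clashes(structure, clash_distance=1.1) == (False, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_count_matches_allpairs(self, seed):
        structure = make_random_complex(seed, n_chains=2, residues_per_chain=10, box_size=8.0)
        _, count = detect_clashes(structure, clash_distance=2.0, count_threshold=10**9)
        assert count == allpairs_clash_count(structure, 2.0)


class TestRanking:
    def test_plain_score(self):
        assert ranking_score(0.9, has_clash=False) == (0.9, False)

    def test_clash_penalty_dominates(self):
        clashing, _ = ranking_score(1.0, has_clash=True)
        clash_free, _ = ranking_score(0.0, has_clash=False)
        assert clashing < clash_free

    def test_ptm_fallback(self):
        score, fallback = ranking_score(None, has_clash=False, ptm=0.7)
        assert score == 0.7 and fallback

    def test_fallback_without_ptm_errors(self):
        with pytest.raises(ScoringError):
            ranking_score(None, has_clash=False)

    def test_native_style_composite(self):
        assert native_style_ranking(0.5, 1.0, False) == pytest.approx(0.6)
        assert native_style_ranking(0.5, 1.0, True) < -90


class TestScoreModel:
    def test_full_pipeline_zero_pae(self, dimer_structure):
        bundle = make_pae(dimer_structure, ZeroPae())
        report = score_model(dimer_structure, bundle)
        assert report.pis == 1.0 and report.pitm == 1.0
        assert report.ranking_score == 1.0
        assert not report.has_clash and not report.fallback_used
        assert report.interface_size == 10

    def test_empty_interface_uses_fallback(self, separated_dimer):
        bundle = make_pae(separated_dimer, ZeroPae(), ptm=0.66)
        report = score_model(separated_dimer, bundle)
        assert report.fallback_used and report.ranking_score == 0.66

    def test_report_serialization(self, dimer_structure):
        bundle = make_pae(dimer_structure, ZeroPae())
        report = score_model(dimer_structure, bundle)
        row = report.to_tsv_row()
        assert row.startswith(report.model_id)
        assert len(row.split("\t")) == len(report.TSV_HEADER.split("\t"))
        import json

        assert json.loads(report.to_json())["pis"] == 1.0
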