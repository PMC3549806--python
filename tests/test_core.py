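"""Pair PSSM construction and interfacial energies."""

import io
import math

import numpy as np
import pytest

from pairpssm.core import (CandidateAlignmentPair, PairPSSM, build_pairpssm,
                           classify, position_scores, pseudocount_q,
                           specific_energy)
from pairpssm.errors import (BuildError, DegenerateWeights,
                             NormalizationUndefined)
from pairpssm.fixtures import FixtureSpec, build_fixture_pssm, make_toy_dimer
from pairpssm.potential import (AA_INDEX, AMINO_ACIDS, EmpiricalPotential,
                                MODIFIED_SCHEME)
from pairpssm.profile import Msa, MsaRow, column_pair_counts, pair_rows


def uniform_potential(S=None):
    S = np.zeros((20, 20)) if S is None else S
    return EmpiricalPotential(S, np.full(20, 0.05))


def counts_fixture(counts_dict, pos=0):
    from pairpssm.profile import PairColumnCounts
    return PairColumnCounts(position_index=pos, counts=dict(counts_dict))


class TestPseudocountQ:
    def test_alpha_zero_collapses_to_prior(self):
        assert pseudocount_q(0.7, 0.01, alpha=0, beta=5) == pytest.approx(0.01)

    def test_printed_formula_case(self):
        # (3*0.5 + 5*0.01) / 8 = 0.19375
        assert pseudocount_q(0.5, 0.01, alpha=3, beta=5) == pytest.approx(0.19375)

    def test_fixed_point_when_f_equals_g(self):
        for alpha, beta in [(0, 5), (3, 5), (10, 1)]:
            assert pseudocount_q(0.2, 0.2, alpha, beta) == pytest.approx(0.2)

    def test_degenerate_weights_rejected(self):
        with pytest.raises(DegenerateWeights):
            pseudocount_q(0.5, 0.1, alpha=0, beta=0)


class TestPositionScores:
    def test_alpha_zero_degenerates_to_empirical_matrix(self):
        """With a single observed symbol the score table equals S exactly."""
        rng = np.random.default_rng(0)
        S = rng.normal(size=(20, 20))
        S = (S + S.T) / 2
        pot = uniform_potential(S)
        sym = (MODIFIED_SCHEME.group_of("L"), MODIFIED_SCHEME.group_of("D"))
        counts = counts_fixture({sym: 4})  # n_distinct=1 -> alpha=0
        table = position_scores(counts, pot, MODIFIED_SCHEME)
        assert np.allclose(table, S, atol=1e-12)

    def test_q_equals_p_gives_zero_score(self):
        pot = uniform_potential()  # S=0 -> g = P_i P_j -> Q = P_ij
        sym = (MODIFIED_SCHEME.group_of("L"), MODIFIED_SCHEME.group_of("D"))
        counts = counts_fixture({sym: 1})
        table = position_scores(counts, pot, MODIFIED_SCHEME)
        assert np.allclose(table, 0.0, atol=1e-12)

    def test_matches_direct_formula_oracle(self):
        """Independent per-pair evaluation of Q=(af+bg)/(a+b), score=ln(Q/P)."""
        ii_viii = (MODIFIED_SCHEME.group_of("L"), MODIFIED_SCHEME.group_of("D"))
        i_viii = (MODIFIED_SCHEME.group_of("A"), MODIFIED_SCHEME.group_of("D"))
        counts = counts_fixture({ii_viii: 3, i_viii: 1})
        rng = np.random.default_rng(1)
        S = rng.normal(scale=0.5, size=(20, 20))
        S = (S + S.T) / 2
        P = rng.dirichlet(np.full(20, 5.0))
        pot = EmpiricalPotential(S, P)
        beta = 5.0
        table = position_scores(counts, pot, MODIFIED_SCHEME, beta=beta)
        alpha = counts.n_distinct - 1
        for ai, a in enumerate(AMINO_ACIDS):
            for bi, b in enumerate(AMINO_ACIDS):
                sym = (MODIFIED_SCHEME.group_of(a), MODIFIED_SCHEME.group_of(b))
                f = counts.counts.get(sym, 0) / counts.n_effective
                g = P[ai] * P[bi] * math.exp(S[ai, bi])
                q = (alpha * f + beta * g) / (alpha + beta)
                expected = math.log(q / (P[ai] * P[bi]))
                assert table[ai, bi] == pytest.approx(expected, abs=1e-12)

    def test_empty_counts_fall_back_to_prior_with_warning(self):
        pot = uniform_potential()
        with pytest.warns(UserWarning, match="pseudocount"):
            table = position_scores(counts_fixture({}), pot, MODIFIED_SCHEME)
        assert np.allclose(table, pot.S, atol=1e-12)

    def test_observing_template_pair_raises_its_score(self):
        """More observations of a symbol raise its score once f exceeds g."""
        rng = np.random.default_rng(2)
        S = rng.normal(scale=0.3, size=(20, 20))
        S = (S + S.T) / 2
        pot = uniform_potential(S)
        sym = (MODIFIED_SCHEME.group_of("L"), MODIFIED_SCHEME.group_of("D"))
        other = (MODIFIED_SCHEME.group_of("K"), MODIFIED_SCHEME.group_of("F"))
        li, di = AA_INDEX["L"], AA_INDEX["D"]
        weak = position_scores(counts_fixture({sym: 1, other: 3}), pot,
                               MODIFIED_SCHEME)
        strong = position_scores(counts_fixture({sym: 3, other: 1}), pot,
                                 MODIFIED_SCHEME)
        assert strong[li, di] > weak[li, di]


def tiny_template(seq_a="LKDE" * 10, seq_b="DFAG" * 10, n_contacts=8):
    spec = FixtureSpec(seed=5, n_residues_per_chain=40, n_contacts=n_contacts,
                       n_profile_rows=20)
    return make_toy_dimer(spec), spec


class TestBuildPairPssm:
    def test_one_table_per_contact_position(self):
        toy, spec = tiny_template()
        dimer, pssm = build_fixture_pssm(toy, spec)
        assert pssm.R == dimer.contact_map.R == spec.n_contacts

    def test_self_energy_sums_template_scores(self):
        toy, spec = tiny_template()
        dimer, pssm = build_fixture_pssm(toy, spec)
        expected = sum(
            p.scores[AA_INDEX[p.template_pair[0]], AA_INDEX[p.template_pair[1]]]
            for p in pssm.positions
        )
        assert pssm.self_energy == pytest.approx(expected)
        assert np.isfinite(pssm.self_energy)

    def test_empty_profile_scores_equal_empirical_matrix(self):
        """Prior-only profile: every position table is exactly S."""
        import warnings

        import gemmi

        from pairpssm.geometry import dimer_from_structure
        toy, spec = tiny_template()
        st = gemmi.read_pdb_string(toy.pdb_text)
        st.setup_entities()
        dimer = dimer_from_structure(st, "A", "B")
        msa_a = Msa(rows=[MsaRow("tA", "template", toy.seq_a)])
        msa_b = Msa(rows=[MsaRow("tB", "template", toy.seq_b)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = pair_rows(msa_a, msa_b)
        rng = np.random.default_rng(3)
        S = rng.normal(size=(20, 20))
        pot = EmpiricalPotential((S + S.T) / 2, np.full(20, 0.05))
        pssm = build_pairpssm(dimer, prof, pot, scheme=MODIFIED_SCHEME)
        for p in pssm.positions:
            assert np.allclose(p.scores, pot.S, atol=1e-12)

    def test_unmappable_contact_position_raises(self):
        import warnings

        import gemmi

        from pairpssm.geometry import dimer_from_structure
        toy, spec = tiny_template()
        st = gemmi.read_pdb_string(toy.pdb_text)
        st.setup_entities()
        dimer = dimer_from_structure(st, "A", "B")
        msa_a = Msa(rows=[MsaRow("tA", "template", toy.seq_a[:5])])  # too short
        msa_b = Msa(rows=[MsaRow("tB", "template", toy.seq_b)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = pair_rows(msa_a, msa_b)
        with pytest.raises(BuildError):
            build_pairpssm(dimer, prof, uniform_potential(), MODIFIED_SCHEME)

    def test_json_round_trip_bit_exact(self):
        toy, spec = tiny_template()
        _, pssm = build_fixture_pssm(toy, spec)
        back = PairPSSM.from_json(pssm.to_json())
        assert back.self_energy == pssm.self_energy
        assert back.beta == pssm.beta
        for p, q in zip(pssm.positions, back.positions):
            assert p.template_pair == q.template_pair
            assert np.array_equal(p.scores, q.scores)
        assert np.array_equal(back.S, pssm.S)


def template_candidate(dimer):
    """The template aligned to itself over its full chains."""
    return CandidateAlignmentPair(
        id_a="self_A", id_b="self_B",
        aln_a={i: (i, aa) for i, aa in enumerate(dimer.chain_a_seq)},
        aln_b={i: (i, aa) for i, aa in enumerate(dimer.chain_b_seq)},
    )


class TestSpecificEnergy:
    def test_template_self_normalizes_to_one(self):
        toy, spec = tiny_template()
        dimer, pssm = build_fixture_pssm(toy, spec)
        res = specific_energy(pssm, template_candidate(dimer), dimer=dimer)
        assert res.normalized_energy == pytest.approx(1.0)
        assert res.covered_positions == pssm.R

    def test_unaligned_candidate_scores_zero(self):
        toy, spec = tiny_template()
        dimer, pssm = build_fixture_pssm(toy, spec)
        cand = CandidateAlignmentPair("x", "y", {}, {})
        res = specific_energy(pssm, cand, dimer=dimer)
        assert res.specific_energy == 0.0
        assert res.normalized_energy == 0.0
        assert res.covered_positions == 0

    def test_half_coverage_matches_per_position_oracle(self):
        toy, spec = tiny_template()
        dimer, pssm = build_fixture_pssm(toy, spec)
        rng = np.random.default_rng(4)
        positions = dimer.contact_positions()
        keep = set(rng.choice(len(positions), size=len(positions) // 2,
                              replace=False))
        cand = template_candidate(dimer)
        for r, (pa, pb) in enumerate(positions):
            if r not in keep:
                cand.aln_a.pop(pa, None)
        res = specific_energy(pssm, cand, dimer=dimer)
        # brute-force per-position summation
        expected = 0.0
        for r, (pa, pb) in enumerate(positions):
            if r in keep:
                expected += pssm.score(r, dimer.chain_a_seq[pa],
                                       dimer.chain_b_seq[pb])
        assert res.specific_energy == pytest.approx(expected, abs=1e-9)
        assert res.normalized_energy == pytest.approx(expected / pssm.self_energy)

    def test_general_energy_sums_empirical_matrix(self):
        toy, spec = tiny_template()
        dimer, pssm = build_fixture_pssm(toy, spec)
        res = specific_energy(pssm, template_candidate(dimer), dimer=dimer)
        expected = sum(
            pssm.general(dimer.chain_a_seq[pa], dimer.chain_b_seq[pb])
            for pa, pb in dimer.contact_positions()
        )
        assert res.general_energy == pytest.approx(expected)

    def test_nonpositive_self_energy_rejected(self):
        entry_scores = np.full((20, 20), -1.0)
        from pairpssm.core import PositionEntry
        pssm = PairPSSM("t", [PositionEntry(("A", "A"), entry_scores)],
                        beta=5.0, scheme_name="modified", S=np.zeros((20, 20)))
        with pytest.raises(NormalizationUndefined):
            specific_energy(pssm, CandidateAlignmentPair("x", "y", {}, {}))


class TestClassify:
    @pytest.mark.parametrize("norm,threshold,expected", [
        (0.84, 0.5, True),   # strong candidate at the stricter threshold
        (0.08, 0.4, False),  # mutated-interface candidate
        (0.4, 0.4, True),    # boundary is inclusive
        (0.399999, 0.4, False),
    ])
    def test_threshold_rule(self, norm, threshold, expected):
        from pairpssm.core import EnergyResult
        res = EnergyResult(specific_energy=1.0, normalized_energy=norm,
                           general_energy=0.0, covered_positions=1)
        assert classify(res, threshold=threshold) is expected
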