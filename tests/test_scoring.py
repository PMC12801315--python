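"""Answer extraction, equivalence rules, and evaluation statistics."""

import itertools
import math

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chemquiz import core, scoring

from test_core import mol_to_nx


class TestExtractAnswer:
    def test_final_answer_line(self):
        assert scoring.extract_answer("thinking...\nAnswer: 7", "strict") == "7"

    def test_last_answer_line_wins(self):
        text = "Answer: 3\nwait\nAnswer: 7"
        assert scoring.extract_answer(text, "strict") == "7"

    def test_strict_requires_pattern(self):
        assert scoring.extract_answer("the distance is 7 bonds", "strict") is None

    def test_lenient_number_fallback(self):
        got = scoring.extract_answer(
            "the distance is 7 bonds", "lenient", "shortest_path"
        )
        assert got == "7"

    @pytest.mark.parametrize(
        "category,response,expected",
        [
            ("carbon_count", "I count 5 then 6 carbons total", "6"),
            ("free_wilson", "score should be about 23", "23"),
            ("shortest_path", "path: 3 rings, so 9", "9"),
            ("reaction", "the product is CCO probably", "CCO"),
            ("nmr_1d", "structure: c1ccccc1 fits all peaks", "c1ccccc1"),
            ("atom_map", "so 1->2 and 2 -> 1 I think", "1->2, 2->1"),
            ("iupac_fg", "I believe it is\n1,2-dichlorobenzene", "1,2-dichlorobenzene"),
        ],
    )
    def test_lenient_grammar_suite(self, category, response, expected):
        assert scoring.extract_answer(response, "lenient", category) == expected

    def test_empty_response(self):
        assert scoring.extract_answer("", "lenient", "carbon_count") is None


class TestNumbersEqual:
    @pytest.mark.parametrize("text", ["7", " 7 ", "7.0", "+7", "7."])
    def test_format_tolerant(self, text):
        assert scoring.numbers_equal(text, 7)

    @pytest.mark.parametrize("text", ["8", "seven", "", "7.5"])
    def test_rejects(self, text):
        assert not scoring.numbers_equal(text, 7)


class TestSmilesEquivalent:
    def test_spelling_variants(self):
        assert scoring.smiles_equivalent("OCC", "CCO")

    def test_different_molecules(self):
        assert not scoring.smiles_equivalent("CCO", "CCN")

    def test_unparseable_is_false(self):
        assert not scoring.smiles_equivalent("C1CC", "CCO")

    def test_randomized_vs_canonical_fixture_pairs(self, druglike):
        for i, mol in enumerate(druglike[:100]):
            variant = core.randomized_smiles(mol, seed=i)
            assert scoring.smiles_equivalent(variant.text, core.canonical_smiles(mol))

    def test_mismatched_fixture_pairs(self, druglike):
        canon = [core.canonical_smiles(m) for m in druglike[:101]]
        for a, b in zip(canon, canon[1:]):
            assert not scoring.smiles_equivalent(a, b)


class TestCheckMapping:
    def _truth(self, smiles):
        mol = core.parse_smiles(smiles)
        n = mol.GetNumAtoms()
        return {
            "mapping": {str(i): i for i in range(1, n + 1)},
            "order_map_a": list(range(n)),
            "order_map_b": list(range(n)),
            "source_smiles": core.canonical_smiles(mol),
        }

    def test_stored_truth_accepted(self, default_benchmark):
        for q in default_benchmark:
            if q.category != "atom_map":
                continue
            assert scoring.check_mapping(q.truth["mapping"], q.truth)

    def test_ring_flip_automorphism_accepted(self):
        # para-disubstituted benzene: Clc1ccc(Cl)cc1, written identically on
        # both sides; flipping the ring is an equally correct mapping
        truth = self._truth("Clc1ccc(Cl)cc1")
        mol = core.parse_smiles(truth["source_smiles"])
        n = mol.GetNumAtoms()
        identity = {i: i for i in range(1, n + 1)}
        assert scoring.check_mapping(identity, truth)
        g = mol_to_nx(mol)
        gm = nx.algorithms.isomorphism.GraphMatcher(
            g, g, node_match=lambda a, b: a["symbol"] == b["symbol"]
        )
        autos = list(gm.isomorphisms_iter())
        assert len(autos) > 1
        for auto in autos:
            mapping = {i + 1: auto[i] + 1 for i in range(n)}
            assert scoring.check_mapping(mapping, truth)

    def test_transposition_of_inequivalent_atoms_rejected(self):
        truth = self._truth("Clc1ccc(Br)cc1")
        n = len(truth["order_map_a"])
        bad = {i: i for i in range(1, n + 1)}
        bad[1], bad[5] = bad[5], bad[1]  # swap Cl and Br images
        assert not scoring.check_mapping(bad, truth)

    def test_incomplete_or_nonbijective_rejected(self):
        truth = self._truth("CCO")
        assert not scoring.check_mapping({1: 1, 2: 2}, truth)
        assert not scoring.check_mapping({1: 1, 2: 1, 3: 3}, truth)
        assert not scoring.check_mapping("no pairs here", truth)

    @pytest.mark.parametrize("smiles", ["ClCCCl", "c1cnccn1", "CC(C)O"])
    def test_accepts_exactly_aut_g_mappings(self, smiles):
        # exhaustive check over all position bijections of small fixtures:
        # the number accepted equals |Aut(G)| from an independent enumerator
        truth = self._truth(smiles)
        mol = core.parse_smiles(truth["source_smiles"])
        n = mol.GetNumAtoms()
        g = nx.Graph()
        for atom in mol.GetAtoms():
            g.add_node(atom.GetIdx(), sym=atom.GetSymbol(), h=atom.GetTotalNumHs())
        for bond in mol.GetBonds():
            g.add_edge(
                bond.GetBeginAtomIdx(),
                bond.GetEndAtomIdx(),
                order=str(bond.GetBondType()),
            )
        gm = nx.algorithms.isomorphism.GraphMatcher(
            g,
            g,
            node_match=lambda a, b: (a["sym"], a["h"]) == (b["sym"], b["h"]),
            edge_match=lambda a, b: a["order"] == b["order"],
        )
        n_aut = sum(1 for _ in gm.isomorphisms_iter())
        accepted = sum(
            scoring.check_mapping(
                {i + 1: perm[i] + 1 for i in range(n)}, truth
            )
            for perm in itertools.permutations(range(n))
        )
        assert accepted == n_aut


class TestStatistics:
    def test_binomial_ci_closed_form(self):
        low, high = scoring.binomial_ci(50, 100)
        assert low == pytest.approx(0.402, abs=1e-3)
        assert high == pytest.approx(0.598, abs=1e-3)

    def test_degenerate_wald(self):
        assert scoring.binomial_ci(0, 20) == (0.0, 0.0)
        assert scoring.binomial_ci(20, 20) == (1.0, 1.0)

    def test_ci_clipped(self):
        low, high = scoring.binomial_ci(1, 10)
        assert 0.0 <= low <= high <= 1.0

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            scoring.binomial_ci(0, 0)

    def test_mcnemar_closed_forms(self):
        assert scoring.mcnemar_one_tailed(0, 0) == 1.0
        assert scoring.mcnemar_one_tailed(0, 5) == pytest.approx(0.03125)
        assert scoring.mcnemar_one_tailed(5, 0) == pytest.approx(0.03125)

    @given(st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=100, derandomize=True)
    def test_mcnemar_matches_brute_force_tail(self, b, c):
        n = b + c
        if n == 0:
            assert scoring.mcnemar_one_tailed(b, c) == 1.0
            return
        brute = sum(
            math.comb(n, k) * 0.5**n for k in range(max(b, c), n + 1)
        )
        assert scoring.mcnemar_one_tailed(b, c) == pytest.approx(brute)


class TestScoreBenchmark:
    def test_truths_score_perfectly(self, default_benchmark):
        subset = default_benchmark[::13]
        responses = {q.id: scoring.truth_as_response(q) for q in subset}
        report = scoring.score_benchmark(subset, responses, "strict")
        assert report.overall.accuracy == 1.0

    def test_empty_responses_score_zero(self, default_benchmark):
        subset = default_benchmark[:20]
        report = scoring.score_benchmark(subset, {}, "strict")
        assert report.overall.accuracy == 0.0
        assert all(j.detail == "no response" for j in report.judgments)

    def test_known_fraction(self, default_benchmark):
        subset = [q for q in default_benchmark if q.category == "carbon_count"][:10]
        responses = {
            q.id: scoring.truth_as_response(q) if i < 7 else "Answer: -1"
            for i, q in enumerate(subset)
        }
        report = scoring.score_benchmark(subset, responses, "strict")
        assert report.overall.k == 7 and report.overall.n == 10
        assert report.overall.accuracy == pytest.approx(0.7)

    def test_lenient_never_below_strict(self, default_benchmark):
        subset = default_benchmark[::19]
        responses = {}
        for i, q in enumerate(subset):
            body = scoring.truth_as_response(q).removeprefix("Answer: ")
            if i % 2:
                responses[q.id] = f"I conclude the result is {body}"
            else:
                responses[q.id] = f"Answer: {body}"
        strict = scoring.score_benchmark(subset, responses, "strict")
        lenient = scoring.score_benchmark(subset, responses, "lenient")
        assert lenient.overall.k >= strict.overall.k

    def test_duplicate_ids_hard_error(self, default_benchmark):
        dup = [default_benchmark[0], default_benchmark[0]]
        with pytest.raises(ValueError):
            scoring.score_benchmark(dup, {}, "strict")

    def test_unknown_response_ids_hard_error(self, default_benchmark):
        subset = default_benchmark[:3]
        with pytest.raises(ValueError):
            scoring.score_benchmark(subset, {"nope": "Answer: 1"}, "strict")


class TestCompareReports:
    def test_equal_reports_p_one(self, default_benchmark):
        subset = default_benchmark[:30]
        responses = {q.id: scoring.truth_as_response(q) for q in subset}
        a = scoring.score_benchmark(subset, responses, "strict")
        b = scoring.score_benchmark(subset, responses, "strict")
        rows = scoring.compare_reports(subset, a, b)
        assert all(r.p_value == 1.0 for r in rows.values())

    def test_five_improvements_closed_form(self, default_benchmark):
        subset = [q for q in default_benchmark if q.category == "ring_count"][:10]
        truths = {q.id: scoring.truth_as_response(q) for q in subset}
        worse = dict(truths)
        for q in subset[:5]:
            worse[q.id] = "Answer: -1"
        a = scoring.score_benchmark(subset, worse, "strict")
        b = scoring.score_benchmark(subset, truths, "strict")
        rows = scoring.compare_reports(subset, a, b)
        assert rows["overall"].b == 0 and rows["overall"].c == 5
        assert rows["overall"].p_value == pytest.approx(0.03125)

    def test_mismatched_benchmarks_error(self, default_benchmark):
        sub_a = default_benchmark[:10]
        sub_b = default_benchmark[10:20]
        responses_a = {q.id: "x" for q in sub_a}
        responses_b = {q.id: "x" for q in sub_b}
        ra = scoring.score_benchmark(sub_a, responses_a, "strict")
        rb = scoring.score_benchmark(sub_b, responses_b, "strict")
        with pytest.raises(ValueError):
            scoring.compare_reports(sub_a, ra, rb)
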