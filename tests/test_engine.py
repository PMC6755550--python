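"""Enumeration engine: length pairs, combinations, templates, skip stream,
assembly, standardization and the orchestrated run."""

import collections
import itertools

import pytest
from rdkit import Chem
from rdkit.Chem import Descriptors

import macroenum as me
from macroenum.engine import _template_stream, permute_with_skip
from macroenum.motifs import COMMON, RARE, MotifRegistry, StructuralMotif

from conftest import brute_force_scaffolds, run_quietly

# atomic masses for the independent formula-mass oracle
_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}


def formula_mass(formula: dict[str, int]) -> float:
    return sum(_MASS[el] * n for el, n in formula.items())


class TestLengthPairs:
    def test_v1m_single_pair(self, v1m):
        assert me.generate_length_pairs(v1m, 12) == [(12, 0)]

    def test_common_priority_sorts_ascending_rare(self):
        rules = me.BuildingRules(
            csm_min=1, csm_max=2, rsm_min=1, rsm_max=2, total_min=3, total_max=3,
            library_size=1,
        )
        assert me.generate_length_pairs(rules, 3) == [(2, 1), (1, 2)]
        rare_first = me.BuildingRules(
            csm_min=1, csm_max=2, rsm_min=1, rsm_max=2, total_min=3, total_max=3,
            priority="rare", library_size=1,
        )
        assert me.generate_length_pairs(rare_first, 3) == [(1, 2), (2, 1)]

    def test_unreachable_ring_size_yields_no_pairs(self):
        rules = me.BuildingRules(
            csm_min=1, csm_max=2, rsm_min=1, rsm_max=2, total_min=3, total_max=5,
            library_size=1,
        )
        assert me.generate_length_pairs(rules, 5) == []


class TestCombinations:
    def test_multiset_dedup(self):
        combos = me.generate_combinations(["A", "A", "B"], 2)
        assert {frozenset(c) for c in combos} == {
            frozenset({("A", 2)}),
            frozenset({("A", 1), ("B", 1)}),
        }

    def test_length_zero_is_single_empty(self):
        assert me.generate_combinations(["A", "B"], 0) == [()]

    def test_length_beyond_pool_is_empty(self):
        assert me.generate_combinations(["A"], 2) == []

    def test_v1m_combination_count_matches_generating_function(self, common_registry, v1m):
        from macroenum.census import count_compositions

        caps = v1m.resolve_caps(common_registry)
        units = common_registry.expand_units(caps, category=COMMON)
        combos = me.generate_combinations(units, 12)
        assert len(combos) == count_compositions(caps, 12)
        assert len(combos) == len({tuple(sorted(c)) for c in combos})  # no duplicates


class TestTemplates:
    def test_trivial_product(self):
        out = list(me.make_templates([(("A", 1), ("B", 1))], [()], ring_size=2))
        assert len(out) == 1 and out[0].key == ("A", "B")

    def test_product_and_dedup(self):
        common = [(("A", 2),), (("A", 1), ("B", 1))]
        rare = [(("C", 1),)]
        out = list(me.make_templates(common, rare, ring_size=3))
        assert [t.key for t in out] == [("A", "A", "C"), ("A", "B", "C")]

    def test_duplicate_template_emitted_once(self):
        seen: set = set()
        first = list(me.make_templates([(("A", 1),)], [()], 1, seen))
        second = list(me.make_templates([(("A", 1),)], [()], 1, seen))
        assert len(first) == 1 and second == []


class TestSkipStream:
    def test_two_units_skip_zero_gives_both_orders(self, toy_ab_registry):
        rules = me.BuildingRules(
            csm_min=2, csm_max=2, total_min=2, total_max=2, skip=0,
            library_size=10, repeat_caps={"A": 1, "B": 1},
        )
        caps = rules.resolve_caps(toy_ab_registry)
        seqs = [
            tuple(s) for _, s in permute_with_skip(
                _template_stream(rules, toy_ab_registry, caps), caps, 0
            )
        ]
        assert sorted(seqs) == [("A", "B"), ("B", "A")]

    def test_duplicated_unit_gives_three_distinct_from_six_raw(self, toy_ab_registry):
        rules = me.BuildingRules(
            csm_min=3, csm_max=3, total_min=3, total_max=3, skip=0,
            library_size=100, repeat_caps={"A": 2, "B": 1},
        )
        caps = rules.resolve_caps(toy_ab_registry)
        raw = list(permute_with_skip(_template_stream(rules, toy_ab_registry, caps), caps, 0))
        assert len(raw) == 6  # instance-level stream: P(3,3)
        result = run_quietly(rules, toy_ab_registry)
        assert len(result) == 3
        oracle = brute_force_scaffolds(toy_ab_registry, caps, 3, add_ester=True)
        assert {r.smiles for r in result} == oracle and len(oracle) == 3

    def test_skip_strides_positions(self, toy_ab_registry):
        rules = me.BuildingRules(
            csm_min=3, csm_max=3, total_min=3, total_max=3, skip=2,
            library_size=100, repeat_caps={"A": 2, "B": 1},
        )
        caps = rules.resolve_caps(toy_ab_registry)
        positions = [
            p for p, _ in permute_with_skip(
                _template_stream(rules, toy_ab_registry, caps), caps, 2
            )
        ]
        assert positions == [0, 2, 4]  # 6-entry stream, stride 2

    def test_skip_carries_over_template_boundaries(self, mixed_registry):
        rules = me.BuildingRules(
            csm_min=0, csm_max=2, rsm_min=0, rsm_max=2, total_min=2, total_max=2,
            skip=3, library_size=10**6,
        )
        caps = rules.resolve_caps(mixed_registry)
        positions = [
            p for p, _ in permute_with_skip(
                _template_stream(rules, mixed_registry, caps), caps, 3
            )
        ]
        assert positions == list(range(0, max(positions) + 1, 3))


class TestAssembly:
    def test_twelve_methylenes_with_ester_is_c13_lactone(self, common_registry):
        mol = me.assemble_macrocycle([common_registry.get("SM001")] * 12, add_ester=True)
        assert Chem.MolToSmiles(mol) == "O=C1CCCCCCCCCCCCO1"
        expected = formula_mass({"C": 13, "H": 24, "O": 2})
        assert Descriptors.MolWt(mol) == pytest.approx(expected, abs=0.01)
        ring = mol.GetRingInfo().AtomRings()
        assert len(ring) == 1 and len(ring[0]) == 14

    def test_no_ester_gives_carbocycle(self, common_registry):
        mol = me.assemble_macrocycle([common_registry.get("SM001")] * 12, add_ester=False)
        assert Chem.MolToSmiles(mol) == "C1CCCCCCCCCCC1"
        assert Descriptors.MolWt(mol) == pytest.approx(formula_mass({"C": 12, "H": 24}), abs=0.01)

    def test_reversal_of_symmetric_sequence_is_identical(self, common_registry):
        # without the directional ester bridge, ring reversal is a graph symmetry
        seq = [common_registry.get(m) for m in ["SM001", "SM004", "SM001", "SM001"]]
        fwd = Chem.MolToSmiles(me.assemble_macrocycle(seq, False))
        rev = Chem.MolToSmiles(me.assemble_macrocycle(seq[::-1], False))
        assert fwd == rev
        # with the ester, a palindromic sequence is reversal-invariant
        pal = [common_registry.get(m) for m in ["SM001", "SM004", "SM001"]]
        assert Chem.MolToSmiles(me.assemble_macrocycle(pal, True)) == Chem.MolToSmiles(
            me.assemble_macrocycle(pal[::-1], True)
        )

    def test_invalid_assemblies_raise_chemistry_error(self, common_registry):
        # valence-broken fragments are rejected before assembly can see them
        with pytest.raises(me.MotifFormatError):
            StructuralMotif("BAD", COMMON, "[*:1]C(F)(F)(F)[*:2]", 1)
        with pytest.raises(me.ChemistryError):
            me.assemble_macrocycle([], add_ester=True)
        with pytest.raises(me.ChemistryError):
            me.assemble_macrocycle([common_registry.get("SM001")], add_ester=False)

    def test_ester_count_matches_flag(self, common_registry):
        ester_smarts = Chem.MolFromSmarts("[CX3](=O)[OX2][#6]")
        seq = [common_registry.get(m) for m in ["SM001", "SM002", "SM005", "SM001"]]
        with_ester = me.assemble_macrocycle(seq, True)
        without = me.assemble_macrocycle(seq, False)
        assert len(with_ester.GetSubstructMatches(ester_smarts)) == 1
        assert len(without.GetSubstructMatches(ester_smarts)) == 0


class TestStandardize:
    def test_explicit_hydrogens_removed_same_heavy_graph(self):
        mol = Chem.MolFromSmiles("[H]C([H])([H])C(=O)O[H]", sanitize=False)
        out = me.standardize(mol)
        assert Chem.MolToSmiles(out) == "CC(=O)O"

    def test_idempotent_on_random_toy_assemblies(self, common_registry):
        import random

        rng = random.Random(3)
        ids = [m.motif_id for m in common_registry]
        for _ in range(25):
            seq = [common_registry.get(rng.choice(ids)) for _ in range(5)]
            mol = me.assemble_macrocycle(seq, add_ester=True)
            once = me.standardize(mol)
            twice = me.standardize(once)
            assert Chem.MolToSmiles(once) == Chem.MolToSmiles(twice)


class TestRunEnumeration:
    def test_skip_zero_matches_brute_force_oracle(self):
        # registries of <= 4 motifs, ring sizes <= 4, with and without ester
        for seed in (0, 1):
            for n_motifs, ring in [(2, 3), (3, 3), (4, 4)]:
                registry, rules = me.make_toy_fixture(n_motifs, ring, seed=seed)
                for ester in (True, False):
                    from dataclasses import replace

                    r = replace(rules, add_ester=ester)
                    result = run_quietly(r, registry)
                    caps = r.resolve_caps(registry)
                    oracle = brute_force_scaffolds(registry, caps, ring, ester)
                    assert {rec.smiles for rec in result.records} == oracle

    def test_constraints_and_uniqueness_on_emitted_records(self, common_registry, v1m):
        from dataclasses import replace

        rules = replace(v1m, library_size=200, skip=10**7)
        result = me.run_enumeration(rules, common_registry, compute_descriptors=False)
        caps = v1m.resolve_caps(common_registry)
        seen = set()
        for rec in result.records:
            assert rec.ring_size == 12 and len(rec.sequence) == 12
            counts = collections.Counter(rec.sequence)
            assert all(counts[mid] <= caps[mid] for mid in counts)
            assert rec.smiles not in seen
            seen.add(rec.smiles)
        assert len(result) == 200

    def test_exhaustion_yields_short_library_and_warning(self, toy_ab_registry):
        rules = me.BuildingRules(
            csm_min=3, csm_max=3, total_min=3, total_max=3, skip=0,
            library_size=10, repeat_caps={"A": 2, "B": 1},
        )
        with pytest.warns(UserWarning, match="exhausted"):
            result = me.run_enumeration(rules, toy_ab_registry)
        assert len(result) == 3 and result.report.exhausted

    def test_determinism_same_seed_same_output(self, common_registry):
        from dataclasses import replace

        rules = replace(me.v1m_rules(), library_size=50, skip=10**8)
        a = me.run_enumeration(rules, common_registry, compute_descriptors=False)
        b = me.run_enumeration(rules, common_registry, compute_descriptors=False)
        assert [r.smiles for r in a.records] == [r.smiles for r in b.records]
        assert [r.sequence for r in a.records] == [r.sequence for r in b.records]

    def test_stream_arithmetic_traversed_equals_emissions_times_skip(self, common_registry):
        from dataclasses import replace

        rules = replace(me.v1m_rules(), library_size=20, skip=10**9)
        result = me.run_enumeration(rules, common_registry, compute_descriptors=False)
        assert result.report.traversed == 20 * 10**9
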