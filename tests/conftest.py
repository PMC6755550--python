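"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import itertools
import warnings

import pytest
from rdkit import Chem
from rdkit import RDLogger

import macroenum as me
from macroenum.motifs import COMMON, RARE, MotifRegistry, StructuralMotif

RDLogger.DisableLog("rdApp.warning")


@pytest.fixture(scope="session")
def common_registry() -> MotifRegistry:
    """The nine default common motifs, deterministic shuffle."""
    return MotifRegistry(me.default_registry(1).common(), shuffle_seed=1)


@pytest.fixture(scope="session")
def v1m() -> me.BuildingRules:
    return me.v1m_rules()


@pytest.fixture()
def toy_ab_registry() -> MotifRegistry:
    """Two simple motifs: A (methylene, cap 2) and B (methyl branch, cap 1)."""
    return MotifRegistry(
        [
            StructuralMotif("A", COMMON, "[*:1]C[*:2]", 2),
            StructuralMotif("B", COMMON, "[*:1]C(C)[*:2]", 1),
        ],
        shuffle_seed=0,
    )


@pytest.fixture()
def mixed_registry() -> MotifRegistry:
    """Common + rare motifs for length-pair and category tests."""
    return MotifRegistry(
        [
            StructuralMotif("A", COMMON, "[*:1]C[*:2]", 2),
            StructuralMotif("B", COMMON, "[*:1]C(C)[*:2]", 2),
            StructuralMotif("X", RARE, "[*:1]C(O)[*:2]", 2),
            StructuralMotif("Y", RARE, "[*:1]C(=O)[*:2]", 2),
        ],
        shuffle_seed=0,
    )


def brute_force_scaffolds(
    registry: MotifRegistry, caps: dict[str, int], ring_size: int, add_ester: bool
) -> set[str]:
    """Independent oracle: every capped sequence, canonicalized and de-duplicated."""
    pool = [mid for mid, cap in caps.items() for _ in range(cap)]
    smis: set[str] = set()
    for perm in set(itertools.permutations(pool, ring_size)):
        mol = me.assemble_macrocycle([registry.get(m) for m in perm], add_ester)
        mol = me.standardize(mol)
        smis.add(Chem.MolToSmiles(mol))
    return smis


def run_quietly(rules, registry, **kw):
    """run_enumeration with exhaustion warnings silenced."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return me.run_enumeration(rules, registry, **kw)
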