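"""Structural-motif building blocks for macrocycle enumeration.

A *structural motif* (SM) is a small backbone fragment with two labelled
attachment points, written as SMILES with atom-mapped dummies ``[*:1]`` (the
incoming bond, R1) and ``[*:2]`` (the outgoing bond, R2).  Concatenating a
sequence of motifs R2->R1 and closing the ring — optionally through a lactone
ester bridge — yields a macrocycle scaffold.

Motifs are split into two categories.  *Common* motifs (CSMs) are backbone
units recurring across well-known bioactive macrolides: methylene and
methyl-branch carbons, an ethyl branch, ketone / hydroxyl / methoxy oxygens,
an alpha-hydroxy methyl carbon, an acetaldehyde side chain and an alkene.
*Rare* motifs (RSMs) are everything else a user may want to inject (amines,
epoxides, in-ring esters, ...).  Every common default contributes exactly one
backbone ring atom and at most one oxygen, which keeps oxygen the only
heteroatom of a common-only library.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem

from .errors import MotifConflictError, MotifFormatError, MotifValidityError

COMMON = "common"
RARE = "rare"

#: Default common structural motifs.  Fragment structures are transcriptions
#: of the backbone units recurring in the eighteen reference bioactive
#: macrolide scaffolds; where the available sources under-determine a
#: structure, the choice was calibrated against the published descriptor
#: profile of the V1M reference library (see docs/methods.md).
DEFAULT_COMMON_MOTIFS: tuple[tuple[str, str, int], ...] = (
    ("SM001", "[*:1]C[*:2]", 3),         # methylene
    ("SM002", "[*:1]C(C)[*:2]", 4),      # methyl branch
    ("SM003", "[*:1]C(CC)[*:2]", 1),     # ethyl branch
    ("SM004", "[*:1]C(=O)[*:2]", 1),     # ketone
    ("SM005", "[*:1]C(O)[*:2]", 1),      # hydroxyl
    ("SM006", "[*:1]C(C)(O)[*:2]", 2),   # alpha-hydroxy methyl
    ("SM008", "[*:1]C(CC=O)[*:2]", 1),   # acetaldehyde side chain
    ("SM009", "[*:1]C(OC)[*:2]", 1),     # methoxy
    ("SM013", "[*:1]C(=CC)[*:2]", 2),    # alkene (ethylidene)
)

#: Default rare structural motifs.  The published rare-motif structures are
#: not available in machine-readable form, so these entries are synthetic
#: stand-ins covering the functional-group families named for the rare
#: category (amines, epoxides, esters, acids); users are expected to edit or
#: replace them.  The V1M reference configuration uses no rare motifs.
DEFAULT_RARE_MOTIFS: tuple[tuple[str, str, int], ...] = (
    ("SM007", "[*:1]C1OC1[*:2]", 1),        # epoxide (two backbone atoms)
    ("SM010", "[*:1]N(C)[*:2]", 1),         # N-methyl ring nitrogen
    ("SM011", "[*:1]C(N)[*:2]", 1),         # amino branch
    ("SM012", "[*:1]C(C(=O)O)[*:2]", 1),    # carboxylic acid branch
    ("SM014", "[*:1]C(=O)O[*:2]", 1),       # in-ring ester
    ("SM015", "[*:1]C(CO)[*:2]", 1),        # hydroxymethyl branch
    ("SM016", "[*:1]C(C)(C)[*:2]", 1),      # gem-dimethyl
)


def _parse_fragment(motif_id: str, fragment: str) -> tuple[Chem.Mol, int, int, int]:
    """Parse a fragment SMILES, returning (mol, r1_idx, r2_idx, ring_atom_count).

    r1_idx / r2_idx are the indices of the heavy atoms bonded to the [*:1] and
    [*:2] dummies.
    """
    mol = Chem.MolFromSmiles(fragment)
    if mol is None:
        raise MotifFormatError(f"motif {motif_id!r}: cannot parse fragment {fragment!r}")
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 2:
        raise MotifValidityError(
            f"motif {motif_id!r}: fragment must contain exactly two attachment "
            f"points, found {len(dummies)}"
        )
    maps = sorted(a.GetAtomMapNum() for a in dummies)
    if maps != [1, 2]:
        raise MotifValidityError(
            f"motif {motif_id!r}: attachment points must be labelled [*:1] and [*:2]"
        )
    attach = {}
    for a in dummies:
        neighbors = a.GetNeighbors()
        if len(neighbors) != 1:
            raise MotifValidityError(
                f"motif {motif_id!r}: attachment point {a.GetAtomMapNum()} must have "
                "exactly one neighbor"
            )
        attach[a.GetAtomMapNum()] = neighbors[0].GetIdx()
    r1, r2 = attach[1], attach[2]
    if r1 == r2:
        ring_atoms = 1
    else:
        ring_atoms = len(Chem.GetShortestPath(mol, r1, r2))
    return mol, r1, r2, ring_atoms


@dataclass(frozen=True)
class StructuralMotif:
    """One backbone building block with two attachment points.

    Parameters
    ----------
    motif_id:
        Short unique label (e.g. ``"SM001"``).
    category:
        ``"common"`` or ``"rare"``.
    fragment:
        SMILES with dummies ``[*:1]`` / ``[*:2]`` marking the incoming and
        outgoing attachment points.
    default_repeat_cap:
        Maximum occurrences of this motif per scaffold unless overridden by
        the building rules.
    """

    motif_id: str
    category: str
    fragment: str
    default_repeat_cap: int = 1
    ring_atom_count: int = field(init=False)

    def __post_init__(self) -> None:
        if self.category not in (COMMON, RARE):
            raise MotifValidityError(
                f"motif {self.motif_id!r}: category must be 'common' or 'rare', "
                f"got {self.category!r}"
            )
        if self.default_repeat_cap < 0:
            raise MotifValidityError(
                f"motif {self.motif_id!r}: repeat cap must be non-negative"
            )
        _, _, _, ring_atoms = _parse_fragment(self.motif_id, self.fragment)
        object.__setattr__(self, "ring_atom_count", ring_atoms)

    @property
    def mol(self) -> Chem.Mol:
        mol, _, _, _ = _parse_fragment(self.motif_id, self.fragment)
        return mol

    def attachment_indices(self) -> tuple[int, int]:
        """Indices of the R1 and R2 heavy atoms in :attr:`mol`."""
        _, r1, r2, _ = _parse_fragment(self.motif_id, self.fragment)
        return r1, r2

    def oxygen_count(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() == 8)


class MotifRegistry:
    """Ordered, validated collection of structural motifs.

    The registry also owns the deterministic shuffle applied to the expanded
    unit pool: repeated units are spread apart before enumeration so that
    identical motifs do not cluster in the permutation stream.  The shuffle is
    a seeded pseudo-random permutation, so the same ``shuffle_seed`` always
    reproduces the same unit order (and hence the same enumeration stream).
    """

    def __init__(self, motifs: Iterable[StructuralMotif], shuffle_seed: int = 0):
        self._motifs: list[StructuralMotif] = []
        self._by_id: dict[str, StructuralMotif] = {}
        self.shuffle_seed = int(shuffle_seed)
        for m in motifs:
            if m.motif_id in self._by_id:
                raise MotifConflictError(f"duplicate motif id {m.motif_id!r}")
            self._motifs.append(m)
            self._by_id[m.motif_id] = m

    def __len__(self) -> int:
        return len(self._motifs)

    def __iter__(self) -> Iterator[StructuralMotif]:
        return iter(self._motifs)

    def __contains__(self, motif_id: str) -> bool:
        return motif_id in self._by_id

    def get(self, motif_id: str) -> StructuralMotif:
        return self._by_id[motif_id]

    @property
    def motif_ids(self) -> tuple[str, ...]:
        return tuple(m.motif_id for m in self._motifs)

    def by_category(self, category: str) -> tuple[StructuralMotif, ...]:
        return tuple(m for m in self._motifs if m.category == category)

    def common(self) -> tuple[StructuralMotif, ...]:
        return self.by_category(COMMON)

    def rare(self) -> tuple[StructuralMotif, ...]:
        return self.by_category(RARE)

    def expand_units(
        self, caps: Mapping[str, int] | None = None, category: str | None = None
    ) -> list[str]:
        """Expand motifs into the shuffled unit pool.

        A motif with repeat cap *k* contributes *k* units.  The expanded list
        is shuffled deterministically with :attr:`shuffle_seed`; the unit
        count always equals the sum of the caps.
        """
        caps = dict(caps or {})
        units: list[str] = []
        for m in self._motifs:
            if category is not None and m.category != category:
                continue
            cap = caps.get(m.motif_id, m.default_repeat_cap)
            if cap < 0:
                raise MotifValidityError(
                    f"motif {m.motif_id!r}: repeat cap must be non-negative"
                )
            units.extend([m.motif_id] * cap)
        rng = random.Random(self.shuffle_seed)
        rng.shuffle(units)
        return units


def load_motifs(
    config: Sequence[Mapping[str, object]] | None = None,
    *,
    include_defaults: bool = True,
    shuffle_seed: int = 0,
) -> MotifRegistry:
    """Build a :class:`MotifRegistry` from a motif definition table.

    ``config`` rows must supply ``motif_id``, ``category``, ``fragment`` and
    ``repeat_cap``.  With ``include_defaults`` the built-in common and rare
    motifs are loaded first; config rows with a fresh ``motif_id`` are
    appended and rows reusing a default id raise a conflict error.
    """
    motifs: list[StructuralMotif] = []
    if include_defaults:
        for mid, frag, cap in DEFAULT_COMMON_MOTIFS:
            motifs.append(StructuralMotif(mid, COMMON, frag, cap))
        for mid, frag, cap in DEFAULT_RARE_MOTIFS:
            motifs.append(StructuralMotif(mid, RARE, frag, cap))
    for row in config or ():
        motifs.append(
            StructuralMotif(
                motif_id=str(row["motif_id"]),
                category=str(row["category"]),
                fragment=str(row["fragment"]),
                default_repeat_cap=int(row.get("repeat_cap", 1)),
            )
        )
    return MotifRegistry(motifs, shuffle_seed=shuffle_seed)


def default_registry(shuffle_seed: int = 0, *, common_only: bool = False) -> MotifRegistry:
    """The built-in sixteen-motif registry (nine common, seven rare)."""
    reg = load_motifs(include_defaults=True, shuffle_seed=shuffle_seed)
    if common_only:
        return MotifRegistry(reg.common(), shuffle_seed=shuffle_seed)
    return reg
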