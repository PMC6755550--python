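"""Core enumeration engine: from building rules to assembled macrocycles.

The generator walks ring sizes, then common/rare length pairs, then motif
combinations whose cartesian products form *templates* (unordered multisets of
motifs).  Each template owns a contiguous block of the global permutation
stream; the stream treats every repeat of a motif as a distinguishable unit,
so a pool of n units taken L at a time yields an n!/(n-L)!-entry stream.  A
skip parameter strides through that stream: after each emitted scaffold the
cursor advances by ``skip`` positions, trading density for diversity.  Emitted
sequences are assembled into macrocycles (optionally closed through a lactone
ester), standardized, and de-duplicated on canonical SMILES.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import ChemistryError
from .motifs import COMMON, RARE, MotifRegistry, StructuralMotif
from .rules import BuildingRules, validate_rules


class LengthPair(NamedTuple):
    """Numbers of common (L_C) and rare (L_R) units in one scaffold."""

    l_common: int
    l_rare: int


def generate_length_pairs(rules: BuildingRules, ring_size: int) -> list[LengthPair]:
    """All (L_C, L_R) with L_C + L_R = ring_size inside the category ranges.

    Ring size takes precedence: category maxima are clamped to it.  With
    common priority the pairs are sorted by ascending rare count, so
    common-only pairs are permuted first; rare priority sorts symmetrically.
    """
    pairs = []
    for l_common in range(rules.csm_min, min(rules.csm_max, ring_size) + 1):
        l_rare = ring_size - l_common
        if rules.rsm_min <= l_rare <= rules.rsm_max:
            pairs.append(LengthPair(l_common, l_rare))
    if rules.priority == COMMON:
        pairs.sort(key=lambda p: p.l_rare)
    else:
        pairs.sort(key=lambda p: p.l_common)
    return pairs


def generate_combinations(
    units: Sequence[str], length: int
) -> list[tuple[tuple[str, int], ...]]:
    """Distinct multisets of ``length`` units drawn from an expanded unit list.

    Each multiset is returned as ``((motif_id, count), ...)`` in the order
    motifs first appear in the (shuffled) unit list.  Generation is
    deterministic: counts of earlier motifs are exhausted from their maximum
    downwards, so a fixed unit list always yields the same combination order.
    A requested length beyond the pool size yields no combinations; length 0
    yields the single empty combination.
    """
    order: list[str] = []
    mult: dict[str, int] = {}
    for u in units:
        if u not in mult:
            order.append(u)
            mult[u] = 0
        mult[u] += 1

    out: list[tuple[tuple[str, int], ...]] = []
    chosen: list[tuple[str, int]] = []

    def rec(idx: int, remaining: int) -> None:
        if remaining == 0:
            out.append(tuple(chosen))
            return
        if idx == len(order):
            return
        capacity = sum(mult[m] for m in order[idx + 1 :])
        mid = order[idx]
        for k in range(min(mult[mid], remaining), -1, -1):
            if remaining - k > capacity:
                continue
            if k:
                chosen.append((mid, k))
            rec(idx + 1, remaining - k)
            if k:
                chosen.pop()

    if 0 <= length <= len(units):
        rec(0, length)
    return out


@dataclass(frozen=True)
class CompositionTemplate:
    """An unordered multiset of motifs of a given ring size."""

    ring_size: int
    counts: tuple[tuple[str, int], ...]

    @property
    def key(self) -> tuple[str, ...]:
        """Canonical identity: the sorted multiset of motif ids."""
        return tuple(sorted(mid for mid, k in self.counts for _ in range(k)))

    @property
    def size(self) -> int:
        return sum(k for _, k in self.counts)


def make_templates(
    common_halves: Iterable[tuple[tuple[str, int], ...]],
    rare_halves: Iterable[tuple[tuple[str, int], ...]],
    ring_size: int,
    seen: set[tuple[str, ...]] | None = None,
) -> Iterator[CompositionTemplate]:
    """Cartesian products of common and rare combination halves, de-duplicated.

    ``seen`` is the per-ring-size template storage; templates whose sorted
    key is already present are suppressed, so each multiset is yielded once
    even when different halves produce it.
    """
    if seen is None:
        seen = set()
    rare_list = list(rare_halves)
    for ch in common_halves:
        for rh in rare_list:
            template = CompositionTemplate(ring_size=ring_size, counts=ch + rh)
            key = template.key
            if key in seen:
                continue
            seen.add(key)
            yield template


# ---------------------------------------------------------------------------
# permutation stream

def _multiset_perm_count(counts: Sequence[int]) -> int:
    total = sum(counts)
    n = math.factorial(total)
    for c in counts:
        n //= math.factorial(c)
    return n


def _unrank_multiset_permutation(
    items: Sequence[str], counts: Sequence[int], rank: int
) -> list[str]:
    """The rank-th distinct sequence of a multiset, lexicographic in ``items`` order."""
    counts = list(counts)
    length = sum(counts)
    seq: list[str] = []
    for _ in range(length):
        for i, item in enumerate(items):
            if counts[i] == 0:
                continue
            counts[i] -= 1
            n = _multiset_perm_count(counts)
            if rank < n:
                seq.append(item)
                break
            counts[i] += 1
            rank -= n
        else:  # pragma: no cover - rank out of range
            raise ValueError("rank exceeds the number of distinct permutations")
    return seq


@dataclass
class _TemplateBlock:
    """A template's contiguous block of the instance-level stream."""

    template: CompositionTemplate
    items: tuple[str, ...]          # type order used for permutation ranking
    counts: tuple[int, ...]
    instance_weight: int            # instance realizations per distinct sequence
    distinct: int                   # distinct sequences

    @property
    def length(self) -> int:
        return self.instance_weight * self.distinct

    def sequence_at(self, offset: int) -> list[str]:
        return _unrank_multiset_permutation(self.items, self.counts, offset // self.instance_weight)


def _block_for(template: CompositionTemplate, pool_counts: Mapping[str, int]) -> _TemplateBlock:
    items = tuple(mid for mid, _ in template.counts)
    counts = tuple(k for _, k in template.counts)
    weight = 1
    for mid, k in template.counts:
        weight *= math.perm(pool_counts[mid], k)
    return _TemplateBlock(
        template=template,
        items=items,
        counts=counts,
        instance_weight=weight,
        distinct=_multiset_perm_count(counts),
    )


def permute_with_skip(
    templates: Iterable[CompositionTemplate],
    pool_counts: Mapping[str, int],
    skip: int,
    library_size: int | None = None,
) -> Iterator[tuple[int, list[str]]]:
    """Skip-strided traversal of the global permutation stream.

    Yields ``(stream_position, motif_sequence)``.  Position 0 is the first
    permutation; after each yield the cursor advances by ``max(skip, 1)``
    positions (skip 0 therefore visits every entry).  The skip counter carries
    over template-block boundaries, forming one contiguous stream.  Stops
    after ``library_size`` yields when given, else on stream exhaustion.
    """
    if skip < 0:
        raise ValueError("skip must be non-negative")
    stride = max(skip, 1)
    cursor = 0
    block_start = 0
    emitted = 0
    for template in templates:
        block = _block_for(template, pool_counts)
        block_end = block_start + block.length
        while cursor < block_end:
            yield cursor, block.sequence_at(cursor - block_start)
            emitted += 1
            if library_size is not None and emitted >= library_size:
                return
            cursor += stride
        block_start = block_end


# ---------------------------------------------------------------------------
# assembly and standardization

def assemble_macrocycle(
    motifs: Sequence[StructuralMotif], add_ester: bool = True
) -> Chem.Mol:
    """Assemble an ordered motif sequence into a macrocycle.

    Bonds R2 of unit i to R1 of unit i+1 and closes the ring either through
    an inserted ester bridge — carbonyl carbon on the last unit's R2 side,
    bridging oxygen on the first unit's R1 side, i.e. a lactone — or through
    a direct single bond.
    """
    if not motifs:
        raise ChemistryError("cannot assemble an empty motif sequence")
    em = Chem.RWMol()
    joins: list[tuple[int, int]] = []
    for motif in motifs:
        frag = motif.mol
        r1, r2 = motif.attachment_indices()
        amap: dict[int, int] = {}
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:
                continue
            new = Chem.Atom(atom.GetAtomicNum())
            new.SetFormalCharge(atom.GetFormalCharge())
            amap[atom.GetIdx()] = em.AddAtom(new)
        for bond in frag.GetBonds():
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            if a.GetAtomicNum() == 0 or b.GetAtomicNum() == 0:
                continue
            em.AddBond(amap[a.GetIdx()], amap[b.GetIdx()], bond.GetBondType())
        joins.append((amap[r1], amap[r2]))
    for i in range(len(joins) - 1):
        em.AddBond(joins[i][1], joins[i + 1][0], Chem.BondType.SINGLE)
    if add_ester:
        carbonyl_c = em.AddAtom(Chem.Atom(6))
        carbonyl_o = em.AddAtom(Chem.Atom(8))
        bridge_o = em.AddAtom(Chem.Atom(8))
        em.AddBond(joins[-1][1], carbonyl_c, Chem.BondType.SINGLE)
        em.AddBond(carbonyl_c, carbonyl_o, Chem.BondType.DOUBLE)
        em.AddBond(carbonyl_c, bridge_o, Chem.BondType.SINGLE)
        em.AddBond(bridge_o, joins[0][0], Chem.BondType.SINGLE)
    else:
        if len(joins) == 1:
            raise ChemistryError(
                "a single unit cannot close a ring without an ester bridge"
            )
        em.AddBond(joins[-1][1], joins[0][0], Chem.BondType.SINGLE)
    mol = em.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        ids = "-".join(m.motif_id for m in motifs)
        raise ChemistryError(f"assembly of sequence {ids} failed: {exc}") from exc
    return mol


_NORMALIZER = rdMolStandardize.Normalizer()
_REIONIZER = rdMolStandardize.Reionizer()
_METAL_DISCONNECTOR = rdMolStandardize.MetalDisconnector()


def standardize(mol: Chem.Mol) -> Chem.Mol:
    """Standardize a molecule: remove hydrogens, sanitize, disconnect metals,
    normalize, reionize, assign stereochemistry — in that order.  Idempotent.
    """
    try:
        mol = Chem.RemoveHs(mol)
        Chem.SanitizeMol(mol)
        mol = _METAL_DISCONNECTOR.Disconnect(mol)
        mol = _NORMALIZER.normalize(mol)
        mol = _REIONIZER.reionize(mol)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    except ChemistryError:
        raise
    except Exception as exc:
        raise ChemistryError(f"standardization failed: {exc}") from exc
    return mol


# ---------------------------------------------------------------------------
# orchestration

@dataclass(frozen=True)
class ScaffoldRecord:
    """One emitted macrocycle scaffold."""

    ordinal: int
    position: int
    ring_size: int
    sequence: tuple[str, ...]
    smiles: str
    descriptors: "DescriptorVector | None" = None
    mol: Chem.Mol | None = field(default=None, compare=False, repr=False)


@dataclass
class EnumerationReport:
    """Run-level metadata: parameters, pools, per-ring-size counts, timing."""

    parameters: dict[str, object]
    common_motifs: tuple[str, ...]
    rare_motifs: tuple[str, ...]
    seed: int
    counts: dict[int, int] = field(default_factory=dict)
    total_arrangements: int = 0
    traversed: int = 0
    emitted: int = 0
    exhausted: bool = False
    elapsed: float = 0.0


@dataclass
class EnumerationResult:
    records: list[ScaffoldRecord]
    report: EnumerationReport

    def __iter__(self) -> Iterator[ScaffoldRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _template_stream(
    rules: BuildingRules, registry: MotifRegistry, caps: Mapping[str, int]
) -> Iterator[CompositionTemplate]:
    common_units = registry.expand_units(caps, category=COMMON)
    rare_units = registry.expand_units(caps, category=RARE)
    for ring_size in range(rules.total_min, rules.total_max + 1):
        seen: set[tuple[str, ...]] = set()
        for pair in generate_length_pairs(rules, ring_size):
            common_halves = generate_combinations(common_units, pair.l_common)
            rare_halves = generate_combinations(rare_units, pair.l_rare)
            yield from make_templates(common_halves, rare_halves, ring_size, seen)


def run_enumeration(
    rules: BuildingRules,
    registry: MotifRegistry,
    *,
    compute_descriptors: bool = True,
    keep_mols: bool = False,
) -> EnumerationResult:
    """Run the full enumeration pipeline for a validated rules/registry pair.

    Emits at most ``rules.library_size`` scaffolds with pairwise-distinct
    canonical structures; a stream exhausted earlier yields a short library
    and a warning.  The emitted records satisfy every constraint by
    construction: ring size, per-category counts, repeat caps, and exactly
    one ring-closing ester when ``add_ester`` is set.
    """
    from .descriptors import compute_descriptors as _compute  # lazy import

    validate_rules(rules, registry)
    t0 = time.monotonic()
    caps = rules.resolve_caps(registry)
    report = EnumerationReport(
        parameters=rules.to_dict(),
        common_motifs=tuple(m.motif_id for m in registry.common()),
        rare_motifs=tuple(m.motif_id for m in registry.rare()),
        seed=registry.shuffle_seed,
    )
    from .census import census as _census

    report.total_arrangements = _census(rules, registry).total_arrangements

    records: list[ScaffoldRecord] = []
    seen_structures: set[str] = set()
    stream = permute_with_skip(
        _template_stream(rules, registry, caps), caps, rules.skip, library_size=None
    )
    last_position = -1
    for position, sequence in stream:
        last_position = position
        mol = assemble_macrocycle([registry.get(mid) for mid in sequence], rules.add_ester)
        mol = standardize(mol)
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen_structures:
            continue
        seen_structures.add(smiles)
        ring_size = len(sequence)
        record = ScaffoldRecord(
            ordinal=len(records),
            position=position,
            ring_size=ring_size,
            sequence=tuple(sequence),
            smiles=smiles,
            descriptors=_compute(mol) if compute_descriptors else None,
            mol=mol if keep_mols else None,
        )
        records.append(record)
        report.counts[ring_size] = report.counts.get(ring_size, 0) + 1
        if len(records) >= rules.library_size:
            break
    else:
        report.exhausted = True
        if len(records) < rules.library_size:
            warnings.warn(
                f"permutation stream exhausted after {len(records)} scaffolds "
                f"(library size {rules.library_size} requested)",
                stacklevel=2,
            )
    report.emitted = len(records)
    report.traversed = (
        report.emitted * rules.skip if rules.skip else last_position + 1
    )
    report.elapsed = time.monotonic() - t0
    return EnumerationResult(records=records, report=report)
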