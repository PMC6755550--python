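"""Exact accounting of the enumeration space, independent of chemistry.

All counting is exact integer arithmetic (Python big ints); floating point
enters only in the final coverage fraction.  Two space sizes are reported:

* ``total_arrangements`` — the instance-level stream length, treating every
  repeat of a motif as a distinguishable unit: the falling factorial
  n!/(n-L)! for a pool of n units taken L at a time.  This is the headline
  space size and the denominator of the coverage convention.
* ``distinct_sequences`` — the multiset-aware count of distinct motif
  sequences, which removes the redundancy among identical repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from .motifs import COMMON, RARE, MotifRegistry
from .rules import BuildingRules, validate_rules


def count_total_arrangements(unit_count: int, length: int) -> int:
    """Ordered arrangements of ``length`` distinguishable units from a pool.

    Exact falling factorial ``unit_count! / (unit_count - length)!``.
    """
    if length < 0 or unit_count < 0:
        raise ValueError("unit_count and length must be non-negative")
    if length > unit_count:
        raise ValueError(f"length {length} exceeds unit count {unit_count}")
    return math.perm(unit_count, length)


def count_distinct_sequences(caps: Mapping[str, int], length: int) -> int:
    """Distinct ordered sequences of ``length`` units from a capped multiset.

    Dynamic programming over motifs: sequences of length j extend to length
    j + k by interleaving k copies of the next motif in C(j + k, k) ways.
    Equivalent to length! times the coefficient extraction from the product
    of truncated exponential series, but in exact integer arithmetic.
    """
    if length < 0:
        raise ValueError("length must be non-negative")
    ways = [0] * (length + 1)
    ways[0] = 1
    for cap in caps.values():
        nxt = [0] * (length + 1)
        for j, w in enumerate(ways):
            if w == 0:
                continue
            for k in range(0, min(cap, length - j) + 1):
                nxt[j + k] += w * math.comb(j + k, k)
        ways = nxt
    return ways[length]


def count_compositions(caps: Mapping[str, int], length: int) -> int:
    """Distinct unordered multisets (templates) of the given size under caps."""
    if length < 0:
        raise ValueError("length must be non-negative")
    coeff = [0] * (length + 1)
    coeff[0] = 1
    for cap in caps.values():
        nxt = [0] * (length + 1)
        for j, w in enumerate(coeff):
            if w == 0:
                continue
            for k in range(0, min(cap, length - j) + 1):
                nxt[j + k] += w
        coeff = nxt
    return coeff[length]


def coverage_fraction(library_size: int, skip: int, total: int) -> float:
    """Fraction of the arrangement space examined: library_size * skip / total."""
    if total <= 0:
        raise ValueError("total arrangement count must be positive")
    return float(Fraction(library_size * skip, total))


@dataclass(frozen=True)
class CensusResult:
    """Exact size and coverage arithmetic for one rules configuration."""

    total_arrangements: int
    distinct_sequences: int
    composition_count: int
    traversed: int
    coverage: float


def census(rules: BuildingRules, registry: MotifRegistry) -> CensusResult:
    """Size the enumeration space of a validated rules/registry pair.

    Sums, over every ring size and admissible common/rare length pair, the
    instance-level arrangements, the distinct sequences and the distinct
    templates.
    """
    from .engine import generate_length_pairs  # local import to avoid a cycle

    validate_rules(rules, registry)
    caps = rules.resolve_caps(registry)
    common_caps = {m.motif_id: caps[m.motif_id] for m in registry.common()}
    rare_caps = {m.motif_id: caps[m.motif_id] for m in registry.rare()}
    n_common = sum(common_caps.values())
    n_rare = sum(rare_caps.values())

    total = 0
    compositions = 0
    for ring_size in range(rules.total_min, rules.total_max + 1):
        for pair in generate_length_pairs(rules, ring_size):
            if pair.l_common > n_common or pair.l_rare > n_rare:
                continue
            # choose the common positions among the ring slots, then order
            # distinguishable units within each category
            total += (
                math.comb(ring_size, pair.l_common)
                * count_total_arrangements(n_common, pair.l_common)
                * count_total_arrangements(n_rare, pair.l_rare)
            )
            compositions += count_compositions(common_caps, pair.l_common) * count_compositions(
                rare_caps, pair.l_rare
            )
    distinct = _distinct_sequences_constrained(rules, common_caps, rare_caps)

    traversed = rules.library_size * rules.skip
    coverage = coverage_fraction(rules.library_size, rules.skip, total) if total else 0.0
    return CensusResult(
        total_arrangements=total,
        distinct_sequences=distinct,
        composition_count=compositions,
        traversed=traversed,
        coverage=min(coverage, 1.0),
    )


def _distinct_sequences_constrained(
    rules: BuildingRules,
    common_caps: Mapping[str, int],
    rare_caps: Mapping[str, int],
) -> int:
    """Distinct sequences summed over ring sizes and admissible length pairs."""
    from .engine import generate_length_pairs

    total = 0
    for ring_size in range(rules.total_min, rules.total_max + 1):
        for pair in generate_length_pairs(rules, ring_size):
            seq_c = count_distinct_sequences(common_caps, pair.l_common)
            seq_r = count_distinct_sequences(rare_caps, pair.l_rare)
            total += math.comb(ring_size, pair.l_common) * seq_c * seq_r
    return total
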