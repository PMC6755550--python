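"""Building rules: the eleven user parameters governing an enumeration run.

The parameters are, in order: the allowed range of common units per macrocycle
(1-2), the allowed range of rare units (3-4), the total ring size range in
motif units (5-6), the priority category (7), the number of permutations to
skip after each emitted scaffold (8), the library size (9), whether to close
the ring through an ester (10, lactone -> macrolide scaffolds; direct bond ->
macrocycle scaffolds), and per-motif repeat caps (11).

Ring size takes precedence over the per-category ranges: category maxima
exceeding the ring size are clamped when length pairs are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

from .errors import RulesInfeasibleError, RulesReferenceError
from .motifs import COMMON, RARE, MotifRegistry

PRIORITIES = (COMMON, RARE)


@dataclass(frozen=True)
class BuildingRules:
    """The eleven enumeration parameters."""

    csm_min: int = 0
    csm_max: int = 0
    rsm_min: int = 0
    rsm_max: int = 0
    total_min: int = 1
    total_max: int = 1
    priority: str = COMMON
    skip: int = 0
    library_size: int = 1
    add_ester: bool = True
    repeat_caps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "repeat_caps", dict(self.repeat_caps))
        if not (0 <= self.csm_min <= self.csm_max):
            raise RulesInfeasibleError("need 0 <= csm_min <= csm_max")
        if not (0 <= self.rsm_min <= self.rsm_max):
            raise RulesInfeasibleError("need 0 <= rsm_min <= rsm_max")
        if not (0 < self.total_min <= self.total_max):
            raise RulesInfeasibleError("need 0 < total_min <= total_max")
        if self.priority not in PRIORITIES:
            raise RulesInfeasibleError(f"priority must be one of {PRIORITIES}")
        if self.skip < 0:
            raise RulesInfeasibleError("skip must be non-negative")
        if self.library_size <= 0:
            raise RulesInfeasibleError("library_size must be positive")
        for mid, cap in self.repeat_caps.items():
            if cap <= 0:
                raise RulesInfeasibleError(f"repeat cap for {mid!r} must be positive")

    def resolve_caps(self, registry: MotifRegistry) -> dict[str, int]:
        """Effective per-motif caps: explicit overrides, else registry defaults."""
        caps = {}
        for m in registry:
            caps[m.motif_id] = int(self.repeat_caps.get(m.motif_id, m.default_repeat_cap))
        return caps

    def to_dict(self) -> dict[str, object]:
        return {
            "csm_min": self.csm_min,
            "csm_max": self.csm_max,
            "rsm_min": self.rsm_min,
            "rsm_max": self.rsm_max,
            "total_min": self.total_min,
            "total_max": self.total_max,
            "priority": self.priority,
            "skip": self.skip,
            "library_size": self.library_size,
            "add_ester": self.add_ester,
            "repeat_caps": dict(self.repeat_caps),
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "BuildingRules":
        return cls(**dict(data))  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str) -> "BuildingRules":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def v1m_rules(**overrides: object) -> BuildingRules:
    """The reference configuration of the one-million-scaffold benchmark run.

    Twelve-unit macrolide scaffolds built from the nine common motifs with
    repeat caps 3/4/2/2 for SM001/SM002/SM006/SM013 and 1 for the rest,
    skip 100,000 and library size 1,000,000, ester closure on.
    """
    params: dict[str, object] = dict(
        csm_min=12,
        csm_max=16,
        rsm_min=0,
        rsm_max=0,
        total_min=12,
        total_max=12,
        priority=COMMON,
        skip=100_000,
        library_size=1_000_000,
        add_ester=True,
        repeat_caps={"SM001": 3, "SM002": 4, "SM006": 2, "SM013": 2},
    )
    params.update(overrides)
    return BuildingRules(**params)  # type: ignore[arg-type]


def validate_rules(rules: BuildingRules, registry: MotifRegistry) -> BuildingRules:
    """Check a rules/registry pair for coherence; returns the rules unchanged.

    Raises :class:`RulesInfeasibleError` when no scaffold can satisfy the
    constraints (minimum ring size beyond the combined category maxima, or
    beyond the total repeat caps) and :class:`RulesReferenceError` for caps
    naming unknown motifs.  Validation is idempotent.
    """
    for mid in rules.repeat_caps:
        if mid not in registry:
            raise RulesReferenceError(f"repeat cap for unknown motif {mid!r}")
    if rules.total_min > rules.csm_max + rules.rsm_max:
        raise RulesInfeasibleError(
            f"minimum ring size {rules.total_min} exceeds the combined category "
            f"maxima {rules.csm_max} + {rules.rsm_max}; no compound can be generated"
        )
    caps = rules.resolve_caps(registry)
    common_pool = sum(caps[m.motif_id] for m in registry.common())
    rare_pool = sum(caps[m.motif_id] for m in registry.rare())
    if rules.csm_min > 0 and common_pool < rules.csm_min:
        raise RulesInfeasibleError(
            f"common repeat caps sum to {common_pool} < csm_min {rules.csm_min}"
        )
    if rules.rsm_min > 0 and rare_pool < rules.rsm_min:
        raise RulesInfeasibleError(
            f"rare repeat caps sum to {rare_pool} < rsm_min {rules.rsm_min}"
        )
    usable_common = min(common_pool, rules.csm_max)
    usable_rare = min(rare_pool, rules.rsm_max)
    if usable_common + usable_rare < rules.total_min:
        raise RulesInfeasibleError(
            f"repeat caps admit at most {usable_common + usable_rare} units per "
            f"scaffold, below the minimum ring size {rules.total_min}"
        )
    return rules


def scaled(rules: BuildingRules, library_size: int, skip: int) -> BuildingRules:
    """A copy of ``rules`` with a different sampling density."""
    return replace(rules, library_size=library_size, skip=skip)
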