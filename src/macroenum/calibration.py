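"""Composition-space descriptor profiles.

Several library descriptors (molecular weight, atom counts, H-bond donor and
acceptor counts) are functions of a scaffold's motif *composition* alone, not
of the arrangement.  Enumerating every admissible composition under a rules
configuration therefore yields exact descriptor extremes for the whole
enumeration space without visiting its billions of arrangements — a few
hundred representative assemblies instead.  This doubles as a calibration
check of the shipped motif structures against a published library profile.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .descriptors import compute_descriptors
from .engine import assemble_macrocycle, standardize
from .motifs import MotifRegistry
from .rules import BuildingRules, validate_rules


def enumerate_compositions(
    caps: dict[str, int], length: int
) -> list[dict[str, int]]:
    """Every multiset of ``length`` motifs with per-motif counts within caps."""
    names = list(caps)
    out = []
    for counts in itertools.product(*(range(caps[n] + 1) for n in names)):
        if sum(counts) == length:
            out.append({n: k for n, k in zip(names, counts) if k})
    return out


def composition_profile(
    rules: BuildingRules, registry: MotifRegistry
) -> pd.DataFrame:
    """Descriptor table with one representative scaffold per composition.

    Only single-ring-size, single-category rules are profiled this way (the
    composition space is the same for every length pair of a ring size).  The
    representative arrangement is the composition in registry order; the
    composition-determined descriptors are arrangement-invariant.
    """
    validate_rules(rules, registry)
    caps = rules.resolve_caps(registry)
    rows = []
    for ring_size in range(rules.total_min, rules.total_max + 1):
        for comp in enumerate_compositions(caps, ring_size):
            seq = [mid for mid in registry.motif_ids for _ in range(comp.get(mid, 0))]
            mol = standardize(
                assemble_macrocycle([registry.get(m) for m in seq], rules.add_ester)
            )
            row: dict[str, object] = {
                "ring_size": ring_size,
                "composition": "-".join(seq),
            }
            row.update(compute_descriptors(mol).as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
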