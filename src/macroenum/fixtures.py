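"""Deterministic toy fixtures for tests and examples.

The fixture generator emits a small, self-consistent motif table (simple
carbon/oxygen fragments) together with feasible building rules, sized so that
exhaustive brute-force oracles remain tractable.
"""

from __future__ import annotations

import random
import warnings

from .motifs import COMMON, MotifRegistry, StructuralMotif
from .rules import BuildingRules, validate_rules

_FRAGMENT_POOL = (
    "[*:1]C[*:2]",
    "[*:1]C(C)[*:2]",
    "[*:1]C(=O)[*:2]",
    "[*:1]C(O)[*:2]",
    "[*:1]O[*:2]",
    "[*:1]C(CC)[*:2]",
    "[*:1]C(C)(O)[*:2]",
    "[*:1]C(OC)[*:2]",
)


def make_toy_fixture(
    n_motifs: int, ring_size: int, seed: int = 0
) -> tuple[MotifRegistry, BuildingRules]:
    """A small registry and matching rules for oracle tests.

    Deterministic per seed.  Repeat caps are drawn in 1..3; if the requested
    ring size exceeds the total caps, caps are raised to make the rules
    feasible (with a warning).
    """
    if n_motifs < 1:
        raise ValueError("need at least one motif")
    rng = random.Random(seed)
    fragments = list(_FRAGMENT_POOL)
    rng.shuffle(fragments)
    caps = {}
    motifs = []
    for i in range(n_motifs):
        mid = f"T{i:03d}"
        frag = fragments[i % len(fragments)]
        cap = rng.randint(1, 3)
        caps[mid] = cap
        motifs.append(StructuralMotif(mid, COMMON, frag, cap))
    total = sum(caps.values())
    if total < ring_size:
        warnings.warn(
            f"toy fixture caps sum to {total} < ring size {ring_size}; raising caps",
            stacklevel=2,
        )
        i = 0
        ids = list(caps)
        while sum(caps.values()) < ring_size:
            caps[ids[i % len(ids)]] += 1
            i += 1
        motifs = [
            StructuralMotif(m.motif_id, COMMON, m.fragment, caps[m.motif_id])
            for m in motifs
        ]
    registry = MotifRegistry(motifs, shuffle_seed=seed)
    rules = BuildingRules(
        csm_min=ring_size,
        csm_max=ring_size,
        rsm_min=0,
        rsm_max=0,
        total_min=ring_size,
        total_max=ring_size,
        priority=COMMON,
        skip=0,
        library_size=1_000_000,
        add_ester=True,
        repeat_caps=dict(caps),
    )
    validate_rules(rules, registry)
    return registry, rules
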