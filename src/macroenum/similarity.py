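"""MACCS-keys fingerprint similarity against probe macrolides.

Library scaffolds are compared with probe molecules via 166-bit MACCS
structural keys and the Tanimoto coefficient.  For each scaffold only the
best probe (maximum aggregation) is reported; a configurable cutoff (default
0.75) counts scaffolds with good similarity to any probe.  MACCS keys are 2D
keys: stereoisomers share identical fingerprints.

Probe preprocessing (:func:`simplify_probe`) reduces a full macrolide to its
comparable core: sugar substituents are excised at the glycosidic oxygen
(capped as hydroxyl), exocyclic ester chains are truncated to hydroxyl, and
substituted exocyclic amines are trimmed to primary amines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .errors import ChemistryError

DEFAULT_CUTOFF = 0.75


def _as_mol(structure: Chem.Mol | str) -> Chem.Mol:
    if isinstance(structure, Chem.Mol):
        return structure
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ChemistryError(f"cannot parse structure {structure!r}")
    return mol


def maccs_fingerprint(structure: Chem.Mol | str) -> np.ndarray:
    """The standard 166-key MACCS bit vector (boolean array of length 167).

    Bit 0 is unused by the MACCS definition and always clear; indices match
    the conventional 1-based key numbering.
    """
    mol = _as_mol(structure)
    bv = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(bv.GetNumBits(), dtype=bool)
    for bit in bv.GetOnBits():
        arr[bit] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a & b| / |a | b|; 0 for two empty vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class SimilarityResult:
    scaffold_id: object
    best_probe: str
    best_score: float
    all_scores: Mapping[str, float] | None = None


def best_probe_similarity(
    structures: Mapping[object, Chem.Mol | str] | Sequence[Chem.Mol | str],
    probes: Mapping[str, Chem.Mol | str],
    *,
    cutoff: float = DEFAULT_CUTOFF,
    keep_all_scores: bool = False,
) -> tuple[list[SimilarityResult], dict[str, object]]:
    """Maximum-aggregation Tanimoto similarity of each scaffold to the probes.

    Ties report the first probe in input order.  The summary carries per-probe
    assignment counts, score quartiles and the count of scaffolds at or above
    the cutoff.
    """
    if not probes:
        raise ValueError("need at least one probe molecule")
    probe_fps = {name: maccs_fingerprint(m) for name, m in probes.items()}
    if isinstance(structures, Mapping):
        items = list(structures.items())
    else:
        items = list(enumerate(structures))

    results: list[SimilarityResult] = []
    for sid, structure in items:
        fp = maccs_fingerprint(structure)
        scores = {name: tanimoto(fp, pfp) for name, pfp in probe_fps.items()}
        best_probe = max(scores, key=lambda n: scores[n])  # first max wins ties
        results.append(
            SimilarityResult(
                scaffold_id=sid,
                best_probe=best_probe,
                best_score=scores[best_probe],
                all_scores=dict(scores) if keep_all_scores else None,
            )
        )
    best = np.array([r.best_score for r in results])
    assignments = pd.Series([r.best_probe for r in results]).value_counts()
    summary = {
        "n_scaffolds": len(results),
        "cutoff": cutoff,
        "above_cutoff": int((best >= cutoff).sum()),
        "mean": float(best.mean()) if len(best) else float("nan"),
        "sd": float(best.std(ddof=1)) if len(best) > 1 else 0.0,
        "quartiles": {
            q: float(np.quantile(best, q)) for q in (0.0, 0.25, 0.5, 0.75, 1.0)
        }
        if len(best)
        else {},
        "assignment_counts": assignments.to_dict(),
    }
    return results, summary


# ---------------------------------------------------------------------------
# probe scaffold simplification

def _macrocycle_atoms(mol: Chem.Mol, min_size: int = 12) -> set[int]:
    rings = mol.GetRingInfo().AtomRings()
    atoms: set[int] = set()
    for ring in rings:
        if len(ring) >= min_size:
            atoms.update(ring)
    return atoms


def _branch_atoms(mol: Chem.Mol, start: int, blocked: set[int]) -> set[int]:
    """Atoms reachable from ``start`` without passing through ``blocked``."""
    seen = {start}
    stack = [start]
    while stack:
        idx = stack.pop()
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            j = nb.GetIdx()
            if j not in seen and j not in blocked:
                seen.add(j)
                stack.append(j)
    return seen


def _is_sugar_carbon(mol: Chem.Mol, idx: int) -> bool:
    """Is this carbon the anomeric-type carbon of a saturated O-heterocycle?"""
    info = mol.GetRingInfo()
    for ring in info.AtomRings():
        if idx not in ring or not (5 <= len(ring) <= 6):
            continue
        has_o = any(mol.GetAtomWithIdx(i).GetAtomicNum() == 8 for i in ring)
        aromatic = any(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
        if has_o and not aromatic:
            return True
    return False


def simplify_probe(structure: Chem.Mol | str, *, min_ring_size: int = 12) -> Chem.Mol:
    """Reduce a macrolide to its core scaffold for comparison with a library.

    Applies, iteratively until a fixed point: (i) excision of O-linked sugar
    rings (the glycosidic oxygen is retained as a hydroxyl); (ii) truncation
    of exocyclic O-acyl ester substituents to hydroxyl; (iii) trimming of
    substituted exocyclic amines to primary amines.  The macrocyclic ring
    framework itself is never modified.
    """
    mol = Chem.Mol(_as_mol(structure))
    if not _macrocycle_atoms(mol, min_ring_size):
        raise ChemistryError(
            f"no macrocyclic ring of >= {min_ring_size} atoms found"
        )
    changed = True
    while changed:
        changed = False
        ring_atoms = _macrocycle_atoms(mol, min_ring_size)
        em = Chem.RWMol(mol)
        to_remove: set[int] = set()

        for atom in mol.GetAtoms():
            idx = atom.GetIdx()
            if idx not in ring_atoms:
                continue
            for nb in atom.GetNeighbors():
                j = nb.GetIdx()
                if j in ring_atoms or j in to_remove:
                    continue
                # (i) glycosidic oxygen -> sugar ring
                if nb.GetAtomicNum() == 8 and nb.GetDegree() == 2:
                    far = next(a for a in nb.GetNeighbors() if a.GetIdx() != idx)
                    if far.GetAtomicNum() == 6 and _is_sugar_carbon(mol, far.GetIdx()):
                        to_remove |= _branch_atoms(mol, far.GetIdx(), {nb.GetIdx()} | ring_atoms)
                        changed = True
                        continue
                    # (ii) O-acyl ester: ring-O-C(=O)R -> ring-OH
                    if far.GetAtomicNum() == 6 and any(
                        b.GetBondTypeAsDouble() == 2.0
                        and b.GetOtherAtom(far).GetAtomicNum() == 8
                        for b in far.GetBonds()
                    ):
                        to_remove |= _branch_atoms(mol, far.GetIdx(), {nb.GetIdx()} | ring_atoms)
                        changed = True
                        continue
                # (iii) substituted exocyclic amine -> NH2
                if nb.GetAtomicNum() == 7 and not nb.GetIsAromatic():
                    subs = [
                        a for a in nb.GetNeighbors() if a.GetIdx() != idx and a.GetAtomicNum() > 1
                    ]
                    if subs and all(a.GetIdx() not in ring_atoms for a in subs):
                        for a in subs:
                            to_remove |= _branch_atoms(
                                mol, a.GetIdx(), {nb.GetIdx()} | ring_atoms
                            )
                        changed = True

        if to_remove:
            for idx in sorted(to_remove, reverse=True):
                em.RemoveAtom(idx)
            mol = em.GetMol()
            Chem.SanitizeMol(mol)
    return mol


def load_probes(path: str) -> dict[str, Chem.Mol]:
    """Read probe molecules from a SMILES (.smi, ``smiles name`` lines) or SDF file."""
    probes: dict[str, Chem.Mol] = {}
    if path.endswith(".sdf"):
        for i, mol in enumerate(Chem.SDMolSupplier(path)):
            if mol is None:
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"probe_{i}"
            probes[name or f"probe_{i}"] = mol
    else:
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                mol = Chem.MolFromSmiles(parts[0])
                if mol is None:
                    raise ChemistryError(f"{path}:{i + 1}: cannot parse SMILES {parts[0]!r}")
                name = parts[1].strip() if len(parts) > 1 else f"probe_{i}"
                probes[name] = mol
    if not probes:
        raise ChemistryError(f"no probe molecules found in {path}")
    return probes
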