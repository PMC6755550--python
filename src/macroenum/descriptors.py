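"""Per-scaffold molecular descriptors and library-level statistics.

Eight descriptors are computed per scaffold: molecular weight (MW, g/mol),
Wildman-Crippen fragment-based octanol/water partition estimate (SlogP),
Ertl topological polar surface area (TPSA, A^2), hydrogen-bond acceptors and
donors (HBA/HBD, Lipinski-style N+O and NH+OH counts), rotatable bonds (NRB),
heteroatom count and heavy-atom count.  The Lipinski-style acceptor count
includes every oxygen — ester oxygens too — which makes HBA coincide with the
heteroatom count on oxygen-only libraries (their correlation is exactly 1).

Drug-likeness flags follow Lipinski's rule of five (MW <= 500, SlogP <= 5,
HBD <= 5, HBA <= 10) and Veber's rules (TPSA <= 140 A^2, NRB <= 10); boundary
values pass.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .errors import ChemistryError

if TYPE_CHECKING:  # pragma: no cover
    from .engine import ScaffoldRecord

DESCRIPTOR_NAMES = ("MW", "SlogP", "TPSA", "HBA", "HBD", "NRB", "heteroatoms", "heavyatoms")


@dataclass(frozen=True)
class DescriptorVector:
    MW: float
    SlogP: float
    TPSA: float
    HBA: int
    HBD: int
    NRB: int
    heteroatoms: int
    heavyatoms: int

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class DruglikenessFlags:
    lipinski_mw: bool
    lipinski_slogp: bool
    lipinski_hbd: bool
    lipinski_hba: bool
    veber_tpsa: bool
    veber_nrb: bool

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_descriptors(mol: Chem.Mol | str) -> DescriptorVector:
    """The eight-descriptor vector of a standardized structure."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ChemistryError(f"cannot parse structure {mol!r}")
        mol = parsed
    return DescriptorVector(
        MW=Descriptors.MolWt(mol),
        SlogP=Crippen.MolLogP(mol),
        TPSA=Descriptors.TPSA(mol),
        HBA=Lipinski.NOCount(mol),
        HBD=Lipinski.NHOHCount(mol),
        NRB=Lipinski.NumRotatableBonds(mol),
        heteroatoms=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6)),
        heavyatoms=mol.GetNumHeavyAtoms(),
    )


def flag_druglikeness(vector: DescriptorVector) -> DruglikenessFlags:
    return DruglikenessFlags(
        lipinski_mw=vector.MW <= 500,
        lipinski_slogp=vector.SlogP <= 5,
        lipinski_hbd=vector.HBD <= 5,
        lipinski_hba=vector.HBA <= 10,
        veber_tpsa=vector.TPSA <= 140,
        veber_nrb=vector.NRB <= 10,
    )


def records_to_frame(records: Iterable["ScaffoldRecord"]) -> pd.DataFrame:
    """Tabulate scaffold records (one row each, descriptor columns appended)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "ordinal": r.ordinal,
            "ring_size": r.ring_size,
            "sequence": "-".join(r.sequence),
            "smiles": r.smiles,
        }
        desc = r.descriptors if r.descriptors is not None else compute_descriptors(r.smiles)
        row.update(desc.as_dict())
        row.update(flag_druglikeness(desc).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


DEFAULT_BINS: Mapping[str, float] = {
    "MW": 15.0,  # g/mol per bin
    "SlogP": 0.5,
    "TPSA": 15.0,
    "HBA": 1.0,
    "HBD": 1.0,
    "NRB": 1.0,
    "heteroatoms": 1.0,
    "heavyatoms": 1.0,
}


def summarize_library(
    frame: pd.DataFrame, bins: Mapping[str, float] | None = None
) -> dict[str, object]:
    """Distribution summary of a scaffold table.

    Returns per-descriptor min/max/mean/sample-SD, binned histograms, and —
    when a ``sequence`` column is present — per-motif occurrence counts
    (scaffolds containing the motif), total compositions, and per-scaffold
    repeat distributions.
    """
    if frame.empty:
        raise ValueError("cannot summarize an empty library")
    bins = dict(DEFAULT_BINS, **(bins or {}))
    present = [c for c in DESCRIPTOR_NAMES if c in frame.columns]
    stats = pd.DataFrame(
        {
            "min": frame[present].min(),
            "max": frame[present].max(),
            "mean": frame[present].mean(),
            "sd": frame[present].std(ddof=1).fillna(0.0),
        }
    )
    histograms: dict[str, pd.Series] = {}
    for col in present:
        width = bins[col]
        edges = np.floor(frame[col] / width) * width
        histograms[col] = edges.value_counts().sort_index()

    summary: dict[str, object] = {"stats": stats, "histograms": histograms}
    if "sequence" in frame.columns:
        seqs = frame["sequence"].str.split("-")
        counts = seqs.apply(lambda s: pd.Series(s).value_counts())
        counts = counts.fillna(0).astype(int)
        summary["motif_scaffold_counts"] = (counts > 0).sum().sort_index()
        summary["motif_total_counts"] = counts.sum().sort_index()
        repeat_dist = {
            mid: counts[mid].value_counts().sort_index() for mid in sorted(counts.columns)
        }
        summary["motif_repeat_distributions"] = repeat_dist
    return summary


def correlation_matrix(
    frame: pd.DataFrame, columns: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix over descriptor columns.

    Constant columns yield missing (NaN) entries rather than zeros; the
    diagonal is unity for non-constant columns.
    """
    cols = list(columns) if columns is not None else [
        c for c in DESCRIPTOR_NAMES if c in frame.columns
    ]
    if len(frame) < 2:
        raise ValueError("need at least two records for a correlation matrix")
    sub = frame[cols].astype(float)
    corr = sub.corr(method="pearson")
    constant = sub.std(ddof=0) == 0
    for c in sub.columns[constant]:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr
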