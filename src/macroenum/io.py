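"""File formats and reports: per-ring-size SDF/CSV, run info, motif tables.

Outputs of an enumeration run, per ring size n: ``RS_<n>.sdf`` (2D structures
with descriptor data fields) and ``RS_<n>.csv`` (one row per scaffold).  Two
run-level files accompany them: ``library_info.txt`` (every input parameter,
the selected motifs, the shuffle seed and the elapsed time — enough to
reproduce the run bit for bit) and ``SM_info.csv`` (motif-type distribution
and per-scaffold repeat counts).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdDepictor

from .descriptors import DESCRIPTOR_NAMES, records_to_frame, summarize_library
from .engine import EnumerationReport, EnumerationResult, ScaffoldRecord
from .errors import MacroenumError
from .motifs import MotifRegistry, load_motifs

CSV_COLUMNS = ["ordinal", "ring_size", "sequence", "smiles", *DESCRIPTOR_NAMES]


def read_motif_table(path: str, *, include_defaults: bool = False, shuffle_seed: int = 0) -> MotifRegistry:
    """Load a motif registry from a delimited table.

    Expected columns: ``motif_id``, ``category``, ``fragment`` (SMILES with
    ``[*:1]``/``[*:2]`` attachment points) and ``repeat_cap``.
    """
    frame = pd.read_csv(path)
    required = {"motif_id", "category", "fragment"}
    missing = required - set(frame.columns)
    if missing:
        raise MacroenumError(f"motif table {path} lacks columns {sorted(missing)}")
    rows = frame.to_dict("records")
    for row in rows:
        row.setdefault("repeat_cap", 1)
    return load_motifs(rows, include_defaults=include_defaults, shuffle_seed=shuffle_seed)


def write_motif_table(registry: MotifRegistry, path: str) -> None:
    pd.DataFrame(
        [
            {
                "motif_id": m.motif_id,
                "category": m.category,
                "fragment": m.fragment,
                "repeat_cap": m.default_repeat_cap,
            }
            for m in registry
        ]
    ).to_csv(path, index=False)


def _mol_with_coords(record: ScaffoldRecord, coords3d: bool) -> Chem.Mol:
    mol = record.mol if record.mol is not None else Chem.MolFromSmiles(record.smiles)
    mol = Chem.Mol(mol)
    if coords3d:
        mol_h = Chem.AddHs(mol)
        if AllChem.EmbedMolecule(mol_h, AllChem.ETKDG()) == 0:
            mol = Chem.RemoveHs(mol_h)
        else:
            rdDepictor.Compute2DCoords(mol)
    else:
        rdDepictor.Compute2DCoords(mol)
    return mol


def write_outputs(
    result: EnumerationResult, out_dir: str | os.PathLike, *, coords3d: bool = False
) -> dict[str, Path]:
    """Write all output files for an enumeration run; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = records_to_frame(result.records) if result.records else pd.DataFrame(
        columns=CSV_COLUMNS
    )
    files: dict[str, Path] = {}

    ring_sizes = sorted(
        set(frame["ring_size"]) if not frame.empty else []
    ) or list(range(result.report.parameters["total_min"], result.report.parameters["total_max"] + 1))
    records_by_rs: dict[int, list[ScaffoldRecord]] = {}
    for rec in result.records:
        records_by_rs.setdefault(rec.ring_size, []).append(rec)

    for rs in ring_sizes:
        csv_path = out / f"RS_{rs}.csv"
        sdf_path = out / f"RS_{rs}.sdf"
        sub = frame[frame["ring_size"] == rs] if not frame.empty else frame
        sub.to_csv(csv_path, index=False)
        writer = Chem.SDWriter(str(sdf_path))
        for rec in records_by_rs.get(rs, []):
            mol = _mol_with_coords(rec, coords3d)
            mol.SetProp("_Name", f"scaffold_{rec.ordinal}")
            mol.SetProp("sequence", "-".join(rec.sequence))
            desc = rec.descriptors
            if desc is not None:
                for name, value in desc.as_dict().items():
                    mol.SetProp(name, f"{value:.4f}" if isinstance(value, float) else str(value))
            writer.write(mol)
        writer.close()
        files[f"RS_{rs}.csv"] = csv_path
        files[f"RS_{rs}.sdf"] = sdf_path

    info_path = out / "library_info.txt"
    info_path.write_text(format_library_info(result.report))
    files["library_info.txt"] = info_path

    sm_path = out / "SM_info.csv"
    write_sm_info(result.records, sm_path)
    files["SM_info.csv"] = sm_path
    return files


def format_library_info(report: EnumerationReport) -> str:
    """Human-readable compilation of every run parameter plus run metadata."""
    lines = ["# library_info", "", "[parameters]"]
    for key, value in report.parameters.items():
        lines.append(f"{key} = {value}")
    lines += [
        "",
        "[motifs]",
        f"common = {', '.join(report.common_motifs) or '(none)'}",
        f"rare = {', '.join(report.rare_motifs) or '(none)'}",
        "",
        "[run]",
        f"shuffle_seed = {report.seed}",
        f"total_arrangements = {report.total_arrangements}",
        f"positions_traversed = {report.traversed}",
        f"emitted = {report.emitted}",
        f"exhausted = {report.exhausted}",
        "counts_per_ring_size = "
        + "; ".join(f"{rs}: {n}" for rs, n in sorted(report.counts.items())),
        f"elapsed_seconds = {report.elapsed:.3f}",
        "",
    ]
    return "\n".join(lines)


def write_sm_info(records: Iterable[ScaffoldRecord], path: str | os.PathLike) -> None:
    """Motif distribution table: scaffold counts, total counts, repeat histogram."""
    records = list(records)
    if not records:
        pd.DataFrame(
            columns=["motif_id", "scaffolds_containing", "total_occurrences"]
        ).to_csv(path, index=False)
        return
    frame = records_to_frame(records)
    summary = summarize_library(frame)
    scaffold_counts = summary["motif_scaffold_counts"]
    total_counts = summary["motif_total_counts"]
    repeat = summary["motif_repeat_distributions"]
    max_rep = max((int(s.index.max()) for s in repeat.values()), default=0)
    rows = []
    for mid in scaffold_counts.index:
        row: dict[str, object] = {
            "motif_id": mid,
            "scaffolds_containing": int(scaffold_counts[mid]),
            "total_occurrences": int(total_counts[mid]),
        }
        for k in range(0, max_rep + 1):
            row[f"repeat_{k}"] = int(repeat[mid].get(k, 0))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scaffold_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def read_scaffold_sdf(path: str) -> pd.DataFrame:
    """Read an ``RS_<n>.sdf`` back into a scaffold table."""
    rows = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        row: dict[str, object] = {"smiles": Chem.MolToSmiles(mol)}
        for prop in mol.GetPropNames():
            row[prop] = mol.GetProp(prop)
        rows.append(row)
    return pd.DataFrame(rows)
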