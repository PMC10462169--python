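"""CSV/JSON readers and writers for datasets, latent vectors, properties and leads.

Schemas
-------
Molecule dataset CSV: required columns ``smiles,id``; optional ``target``
with either ``delta_g`` (kcal/mol) or ``ki`` + ``ki_unit`` (M/mM/uM/nM/pM,
converted to ΔG on read); optional descriptors ``mw,logp,nhd,nha``. One row
per (molecule, target) affinity record; rows sharing an id are merged into
one record.

Latent CSV: ``id`` column plus ``z0..z{d-1}``.

Property CSV: ``id`` plus the ten screened property columns.

All write-then-read round trips are lossless at float precision; malformed
rows raise :class:`~sgnc.exceptions.DataError` naming the file line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from sgnc.codec import MoleculeRecord
from sgnc.exceptions import DataError
from sgnc.screening import PROPERTY_NAMES, PropertyProfile
from sgnc.units import concentration_to_molar, ki_to_delta_g

_DESCRIPTORS = ("mw", "logp", "nhd", "nha")


def _line(row_pos: int) -> int:
    # +2: one for the header, one for 1-based numbering
    return row_pos + 2


def read_dataset(path: str | Path) -> list[MoleculeRecord]:
    """Read a molecule dataset CSV into records, merging rows by molecule id."""
    df = pd.read_csv(path)
    for col in ("smiles", "id"):
        if col not in df.columns:
            raise DataError(f"{path}: dataset CSV lacks required column {col!r}")
    records: dict[str, MoleculeRecord] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        mol_id = str(row["id"])
        smiles = row["smiles"]
        if not isinstance(smiles, str) or not smiles:
            raise DataError(f"{path}:{_line(pos)}: empty or missing SMILES")
        delta_g = None
        if "delta_g" in row and pd.notna(row["delta_g"]):
            delta_g = float(row["delta_g"])
        elif "ki" in row and pd.notna(row["ki"]):
            unit = str(row.get("ki_unit", "M"))
            try:
                delta_g = ki_to_delta_g(concentration_to_molar(float(row["ki"]), unit))
            except Exception as exc:
                raise DataError(f"{path}:{_line(pos)}: bad Ki value/unit: {exc}") from exc
        target = str(row["target"]) if "target" in row and pd.notna(row["target"]) else None
        descriptors = {}
        for name in _DESCRIPTORS:
            if name in row and pd.notna(row[name]):
                descriptors[name] = int(row[name]) if name in ("nhd", "nha") else float(row[name])
        if mol_id in records:
            rec = records[mol_id]
            if rec.smiles != smiles:
                raise DataError(f"{path}:{_line(pos)}: id {mol_id!r} re-used with a different SMILES")
            rec.descriptors.update(descriptors)
        else:
            rec = MoleculeRecord(smiles=smiles, id=mol_id, descriptors=descriptors)
            records[mol_id] = rec
        if delta_g is not None:
            if target is None:
                raise DataError(f"{path}:{_line(pos)}: affinity given without a target name")
            if not np.isfinite(delta_g):
                raise DataError(f"{path}:{_line(pos)}: non-finite affinity")
            rec.affinities[target] = delta_g
    return list(records.values())


def write_dataset(path: str | Path, records: Sequence[MoleculeRecord]) -> None:
    """Write molecule records to CSV, one row per (molecule, target) affinity."""
    rows = []
    for rec in records:
        base = {"smiles": rec.smiles, "id": rec.id}
        base.update({k: rec.descriptors.get(k) for k in _DESCRIPTORS})
        if rec.affinities:
            for target, g in rec.affinities.items():
                rows.append({**base, "target": target, "delta_g": g})
        else:
            rows.append({**base, "target": None, "delta_g": None})
    cols = ["smiles", "id", "target", "delta_g", *_DESCRIPTORS]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_latents(path: str | Path) -> dict[str, np.ndarray]:
    """Read a latent CSV (id, z0..z{d-1}) into an id → vector mapping."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise DataError(f"{path}: latent CSV lacks an 'id' column")
    zcols = [c for c in df.columns if c.startswith("z")]
    expected = [f"z{i}" for i in range(len(zcols))]
    if zcols != expected:
        raise DataError(f"{path}: latent columns must be contiguous z0..z{{d-1}}, got {zcols[:5]}...")
    if not zcols:
        raise DataError(f"{path}: latent CSV has no z columns")
    values = df[zcols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        pos = int(np.argwhere(~np.isfinite(values))[0][0])
        raise DataError(f"{path}:{_line(pos)}: non-finite latent component")
    return {str(i): values[k] for k, i in enumerate(df["id"])}


def write_latents(path: str | Path, latents: dict[str, np.ndarray]) -> None:
    """Write an id → vector mapping to a latent CSV."""
    ids = list(latents)
    Z = np.vstack([latents[i] for i in ids])
    df = pd.DataFrame(Z, columns=[f"z{j}" for j in range(Z.shape[1])])
    df.insert(0, "id", ids)
    df.to_csv(path, index=False)


def read_properties(path: str | Path) -> list[PropertyProfile]:
    """Read a property CSV (id + the ten screened columns) into profiles."""
    df = pd.read_csv(path)
    missing = [c for c in ("id", *PROPERTY_NAMES) if c not in df.columns]
    if missing:
        raise DataError(f"{path}: property CSV lacks column(s) {missing}")
    profiles = []
    for pos, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        try:
            profiles.append(
                PropertyProfile(id=str(row["id"]), **{n: float(row[n]) for n in PROPERTY_NAMES})
            )
        except Exception as exc:
            raise DataError(f"{path}:{_line(pos)}: {exc}") from exc
    return profiles


def write_properties(path: str | Path, profiles: Sequence[PropertyProfile]) -> None:
    """Write property profiles to CSV."""
    rows = [{"id": p.id, **p.as_dict()} for p in profiles]
    pd.DataFrame(rows, columns=["id", *PROPERTY_NAMES]).to_csv(path, index=False)


def write_leads(path: str | Path, leads: pd.DataFrame) -> None:
    """Write the ranked leads table to CSV (deterministic byte output)."""
    leads.to_csv(path, index=False, float_format="%.10g")


def write_json(path: str | Path, payload: dict) -> None:
    """Write a JSON report with sorted keys (deterministic byte output)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
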