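"""Molecular and spectral I/O.

Reads molecules (SMILES / SDF / MOL), per-hydrogen chemical-shift lists
(CSV), and logD label tables (CSV), and prepares structures for the
HOSE-code shift predictor.  Molecules are carried as RDKit ``Mol`` objects
with a stable ``compound_id`` stored in the ``_Name`` property; hydrogen
counts are fixed at parse time so that shift-list lengths can be checked
against them later.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger("nmrlogd")

# Source tags used on ShiftList / spectrum objects throughout the pipeline.
SOURCE_EXPERIMENTAL = "experimental_assigned"
SOURCE_DFT = "dft_style"
SOURCE_HOSE = "hose_predicted"
SOURCE_TRACE = "trace_derived"
VALID_SOURCES = (SOURCE_EXPERIMENTAL, SOURCE_DFT, SOURCE_HOSE, SOURCE_TRACE)

# logD label schema: chromatographic lipophilicity indices at three pHs.
VALID_PARAMETERS = ("CHI", "Chrom")
STANDARD_PHS = (2.6, 7.4, 10.5)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ShiftList:
    """Per-hydrogen chemical shifts (ppm) for one molecule.

    ``h_indices``, when present, maps each shift to the heavy-atom index
    bearing that hydrogen; its length must equal ``len(shifts)``.
    """

    compound_id: str
    shifts: np.ndarray
    h_indices: list[int] | None = None
    source: str = SOURCE_EXPERIMENTAL

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 1:
            raise DataError(f"{self.compound_id}: shifts must be 1-D")
        if not np.all(np.isfinite(self.shifts)):
            raise DataError(f"{self.compound_id}: non-finite chemical shift")
        if self.h_indices is not None and len(self.h_indices) != len(self.shifts):
            raise DataError(
                f"{self.compound_id}: atom mapping length {len(self.h_indices)} "
                f"!= shift count {len(self.shifts)}"
            )

    def __len__(self) -> int:
        return len(self.shifts)


@dataclass
class SpectrumTrace:
    """Dense frequency-intensity array (an experimental-style spectrum)."""

    ppm: np.ndarray
    intensity: np.ndarray
    compound_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise DataError(f"{self.compound_id}: axis/intensity shape mismatch")
        d = np.diff(self.ppm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise DataError(f"{self.compound_id}: ppm axis not strictly monotone")


def compound_id(mol: Chem.Mol) -> str:
    return mol.GetProp("_Name") if mol.HasProp("_Name") else ""


def hydrogen_count(mol: Chem.Mol) -> int:
    """Total hydrogens (implicit + explicit) of the molecule."""
    return sum(a.GetTotalNumHs(includeNeighbors=True)
               for a in mol.GetAtoms() if a.GetAtomicNum() != 1)


def _assign_id(mol: Chem.Mol, fallback: str) -> None:
    if not mol.HasProp("_Name") or not mol.GetProp("_Name").strip():
        mol.SetProp("_Name", fallback)


def read_molecules(path: str) -> list[Chem.Mol]:
    """Read molecules from a SMILES (.smi/.txt) or SDF/MOL file.

    SMILES files hold one record per line: the SMILES string and an
    optional whitespace-separated id.  Compound ids fall back to
    ``cmpd_<index>`` (0-based) when the file provides none.  Implicit
    hydrogens are perceived once here and fixed thereafter.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    mols: list[Chem.Mol] = []
    if ext in (".sdf", ".mol"):
        supplier = Chem.SDMolSupplier(path, removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise DataError(f"{path}: unparsable record #{i}")
            _assign_id(mol, f"cmpd_{i}")
            mols.append(mol)
    else:
        with open(path, encoding="utf-8") as fh:
            idx = 0
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                mol = Chem.MolFromSmiles(parts[0])
                if mol is None:
                    raise DataError(f"{path}:{lineno}: unparsable SMILES {parts[0]!r}")
                mol.SetProp("_Name", parts[1].strip() if len(parts) > 1 else f"cmpd_{idx}")
                mols.append(mol)
                idx += 1
    if not mols:
        logger.warning("%s: no molecules read", path)
    return mols


def embed_and_flatten(mol: Chem.Mol, seed: int = 0) -> Chem.Mol:
    """Generate 3D coordinates, then flatten by zeroing every z-coordinate.

    This mirrors the structure-preparation step that avoids stereochemistry
    assessment problems in HOSE-based predictors: embed in 3D with a fixed
    random seed, then write the conformer back with z = 0 for every atom.
    Idempotent in its z-zeroing effect and deterministic under ``seed``.
    """
    cid = compound_id(mol)
    molh = Chem.AddHs(mol)
    if AllChem.EmbedMolecule(molh, randomSeed=int(seed)) != 0:
        raise DataError(f"embedding failed for compound {cid or '<unnamed>'}")
    flat = Chem.RemoveHs(molh)
    conf = flat.GetConformer()
    for i in range(flat.GetNumAtoms()):
        p = conf.GetAtomPosition(i)
        conf.SetAtomPosition(i, (p.x, p.y, 0.0))
    if cid:
        flat.SetProp("_Name", cid)
    return flat


def read_shift_lists(path: str, source: str = SOURCE_EXPERIMENTAL) -> list[ShiftList]:
    """Read per-hydrogen shift lists from CSV (compound_id, shift_ppm[, h_index])."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"compound_id", "shift_ppm"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    shifts_num = pd.to_numeric(df["shift_ppm"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(shifts_num.to_numpy(dtype=float)))
    if len(bad):
        raise DataError(f"{path}: non-numeric shift_ppm at row {bad[0] + 2}")
    has_map = "h_index" in df.columns and df["h_index"].notna().all()
    out = []
    for cid, grp in df.groupby("compound_id", sort=False):
        out.append(ShiftList(
            compound_id=str(cid),
            shifts=grp["shift_ppm"].to_numpy(dtype=float),
            h_indices=[int(v) for v in grp["h_index"]] if has_map else None,
            source=source,
        ))
    return out


def write_shift_lists(shift_lists: list[ShiftList], path: str) -> None:
    rows = []
    for sl in shift_lists:
        for j, s in enumerate(sl.shifts):
            row = {"compound_id": sl.compound_id, "shift_ppm": s}
            if sl.h_indices is not None:
                row["h_index"] = sl.h_indices[j]
            rows.append(row)
    # %.17g keeps the write->read round trip bit-exact for doubles
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_labels(path: str) -> pd.DataFrame:
    """Read a logD label table: columns compound_id, parameter, pH, value.

    The key (compound_id, parameter, pH) must be unique; a non-standard pH
    is accepted with a warning.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    return validate_labels(df, origin=path)


def validate_labels(df: pd.DataFrame, origin: str = "<labels>") -> pd.DataFrame:
    required = {"compound_id", "parameter", "pH", "value"}
    if not required.issubset(df.columns):
        raise DataError(f"{origin}: missing columns {sorted(required - set(df.columns))}")
    df = df.copy()
    df["compound_id"] = df["compound_id"].astype(str)
    df["pH"] = pd.to_numeric(df["pH"])
    df["value"] = pd.to_numeric(df["value"])
    if not np.all(np.isfinite(df["value"])):
        raise DataError(f"{origin}: non-finite logD value")
    bad_param = set(df["parameter"]) - set(VALID_PARAMETERS)
    if bad_param:
        raise DataError(f"{origin}: unknown parameter(s) {sorted(bad_param)}")
    dup = df.duplicated(subset=["compound_id", "parameter", "pH"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["compound_id", "parameter", "pH"]].tolist()
        raise DataError(f"{origin}: duplicate label key {key}")
    odd = sorted(set(np.round(df["pH"], 6)) - set(STANDARD_PHS))
    if odd:
        logger.warning("%s: non-standard pH value(s) %s", origin, odd)
    return df


def write_labels(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, columns=["compound_id", "parameter", "pH", "value"],
              float_format="%.17g")


def label_slice(labels: pd.DataFrame, parameter: str, ph: float) -> pd.Series:
    """One (parameter, pH) slice as a Series indexed by compound_id."""
    sel = labels[(labels["parameter"] == parameter) & (np.isclose(labels["pH"], ph))]
    return pd.Series(sel["value"].to_numpy(), index=sel["compound_id"].to_numpy())
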