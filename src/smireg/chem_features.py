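"""Small-molecule featurization: 166-key MACCS fingerprints and Tanimoto similarity.

RDKit's MACCS implementation uses the 167-bit convention with bit 0 unused;
bit 0 is dropped here so fingerprints carry exactly the 166 public keys.
Absolute bit patterns are therefore RDKit-specific; the pipeline logic is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

RDLogger.DisableLog("rdApp.*")

N_KEYS = 166


@dataclass(frozen=True)
class SmallMolecule:
    id: str
    smiles: str


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the molecule id."""

    def __init__(self, mol_id: str, smiles: str):
        super().__init__(f"unparseable SMILES for {mol_id!r}: {smiles!r}")
        self.mol_id = mol_id
        self.smiles = smiles


def _parse(mol: SmallMolecule) -> Chem.Mol:
    if not mol.smiles:
        raise SmilesParseError(mol.id, mol.smiles)
    rdmol = Chem.MolFromSmiles(mol.smiles)
    if rdmol is None:
        raise SmilesParseError(mol.id, mol.smiles)
    return rdmol


def canonical_smiles(mol: SmallMolecule) -> str:
    """Canonical form used for duplicate detection (not string equality)."""
    return Chem.MolToSmiles(_parse(mol))


def maccs_fingerprint(mol: SmallMolecule) -> np.ndarray:
    """166-entry 0/1 vector of public MACCS structural keys."""
    bv = MACCSkeys.GenMACCSKeys(_parse(mol))  # 167 bits, bit 0 unused
    arr = np.zeros(167, dtype=np.uint8)
    for b in bv.GetOnBits():
        arr[b] = 1
    return arr[1:]


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|on in both| / |on in either|; 0.0 when both vectors are all-zero."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    return inter / union if union else 0.0


def read_smiles_table(path: str | Path) -> list[SmallMolecule]:
    """Read molecules from TSV with columns (id, smiles), or one SMILES per line.

    A headerless single-column file gets auto-generated ids mol1, mol2, ...
    """
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.lower(): c for c in df.columns}
        if "id" not in cols or "smiles" not in cols:
            raise ValueError(f"{path}: expected columns 'id' and 'smiles', got {list(df.columns)}")
        return [SmallMolecule(r[cols["id"]], r[cols["smiles"]]) for _, r in df.iterrows()]
    mols = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            s = line.strip()
            if s and s.lower() != "smiles":
                mols.append(SmallMolecule(f"mol{i}", s))
    return mols


def fingerprint_table(mols: Iterable[SmallMolecule]) -> pd.DataFrame:
    """One row per molecule (indexed by id), 166 0/1 key columns."""
    mols = list(mols)
    mat = (
        np.vstack([maccs_fingerprint(m) for m in mols])
        if mols
        else np.empty((0, N_KEYS), dtype=np.uint8)
    )
    return pd.DataFrame(mat, index=[m.id for m in mols], columns=fingerprint_columns())


def fingerprint_columns() -> list[str]:
    return [f"maccs_{i}" for i in range(1, N_KEYS + 1)]


def export_fingerprints(fps: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write an id-indexed TSV of 0/1 key columns."""
    df = pd.DataFrame(
        np.vstack(list(fps.values())) if fps else np.empty((0, N_KEYS), dtype=np.uint8),
        index=list(fps.keys()),
        columns=fingerprint_columns(),
    )
    df.to_csv(path, sep="\t", index_label="sm_id")


def import_fingerprints(path: str | Path) -> dict[str, np.ndarray]:
    """Load precomputed fingerprints (the inverse of :func:`export_fingerprints`)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != N_KEYS:
        raise ValueError(f"{path}: expected {N_KEYS} key columns, got {df.shape[1]}")
    bad = df.index[~df.isin([0, 1]).all(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-binary fingerprint entries for {list(bad[:5])}")
    return {str(i): row.to_numpy(dtype=np.uint8) for i, row in df.iterrows()}
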