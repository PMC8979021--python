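"""Query modes: score one pair, or rank a candidate library for a query.

A molecule can be given either as a :class:`SmallMolecule` (SMILES path) or
as an ``(id, fingerprint)`` tuple (precomputed path, used by the synthetic
corpus).  A pair is "worth-studying" when its predicted probability is at
or above the bundle's calibrated suggestion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from smireg.chem_features import N_KEYS, SmallMolecule, maccs_fingerprint
from smireg.model_training import TrainedModelBundle
from smireg.rna_features import MiRNARecord, build_descriptor

MoleculeLike = Union[SmallMolecule, tuple[str, np.ndarray]]

WORTH_STUDYING = "worth-studying"
BELOW_THRESHOLD = "below-threshold"


@dataclass(frozen=True)
class PredictionResult:
    sm_id: str
    mirna_id: str
    direction: str
    probability: float
    call: str


def _mol_id_and_fp(mol: MoleculeLike) -> tuple[str, np.ndarray]:
    if isinstance(mol, SmallMolecule):
        return mol.id, maccs_fingerprint(mol)
    mol_id, fp = mol
    fp = np.asarray(fp)
    if fp.shape != (N_KEYS,):
        raise ValueError(f"fingerprint for {mol_id!r} has shape {fp.shape}, expected ({N_KEYS},)")
    return mol_id, fp


def predict_pair(bundle: TrainedModelBundle, mol: MoleculeLike, mir: MiRNARecord) -> PredictionResult:
    """Probability that ``mol`` regulates ``mir`` in the bundle's direction."""
    mol_id, fp = _mol_id_and_fp(mol)
    row = pd.DataFrame(
        np.concatenate([build_descriptor(mir), fp])[None, :], columns=bundle.feature_columns
    )
    proba = float(bundle.model.predict_proba(row)[0, 1])
    return PredictionResult(
        sm_id=mol_id,
        mirna_id=mir.id,
        direction=bundle.direction,
        probability=proba,
        call=WORTH_STUDYING if proba >= bundle.threshold else BELOW_THRESHOLD,
    )


def rank_candidates(
    bundle: TrainedModelBundle,
    query: Union[MoleculeLike, MiRNARecord],
    library: Sequence,
    top_n: int | None = None,
) -> list[PredictionResult]:
    """Rank a library of the other entity type against the query.

    Sorted by probability descending, ties broken by library-entity id
    ascending; truncated to ``top_n`` if given.
    """
    if len(library) == 0:
        raise ValueError("empty candidate library")
    if isinstance(query, MiRNARecord):
        results = [predict_pair(bundle, mol, query) for mol in library]
        results.sort(key=lambda r: (-r.probability, r.sm_id))
    else:
        results = [predict_pair(bundle, query, mir) for mir in library]
        results.sort(key=lambda r: (-r.probability, r.mirna_id))
    return results if top_n is None else results[:top_n]


def results_table(results: Iterable[PredictionResult]) -> pd.DataFrame:
    rows = [
        (i + 1, r.sm_id, r.mirna_id, r.direction, r.probability, r.call)
        for i, r in enumerate(results)
    ]
    return pd.DataFrame(
        rows, columns=["rank", "sm_id", "mirna_id", "direction", "probability", "call"]
    )
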