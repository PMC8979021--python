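"""Similarity-screened negative pair mining.

A candidate (molecule, miRNA) pair is scored by the mean Tanimoto
coefficient between the candidate molecule's fingerprint and the
fingerprints of the miRNA's known regulators in the same direction.
Candidates scoring strictly below the threshold (default 0.1) form the
negative pool, from which a balanced sample is drawn uniformly without
replacement under an explicit seed.

Rationale for the screen: structurally similar molecules tend to regulate
the same miRNAs, so a molecule very dissimilar from every known regulator
of a miRNA is a credible non-regulator.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from smireg.chem_features import tanimoto
from smireg.pair_data import RegulationDataset, RegulationPair

DEFAULT_THRESHOLD = 0.1


def regulation_score(candidate_fp: np.ndarray, known_regulators: Sequence[np.ndarray]) -> float:
    """Mean Tanimoto between the candidate and each known regulator fingerprint."""
    if len(known_regulators) == 0:
        raise ValueError("regulation score undefined: empty known-regulator set")
    return float(np.mean([tanimoto(candidate_fp, fp) for fp in known_regulators]))


def enumerate_candidates(
    ds: RegulationDataset,
    other_direction_positives: Iterable[tuple[str, str]] = (),
) -> set[tuple[str, str]]:
    """Candidate universe for negative mining.

    Cartesian product of the dataset's molecules and miRNAs, minus its own
    positives, minus (optionally) positives of the opposite direction, minus
    pairs whose miRNA has no known in-direction regulator (score undefined).
    """
    if ds.negatives:
        raise ValueError("candidate enumeration expects a positives-only dataset")
    positives = {(p.sm_id, p.mirna_id) for p in ds.positives}
    sm_ids = {p.sm_id for p in ds.positives}
    regulated = {p.mirna_id for p in ds.positives}  # miRNAs with >= 1 known regulator
    excluded = set(other_direction_positives)
    return {
        (sm, mir)
        for sm in sm_ids
        for mir in regulated
        if (sm, mir) not in positives and (sm, mir) not in excluded
    }


def score_candidates(
    ds: RegulationDataset, candidates: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """Score every candidate; returns columns (sm_id, mirna_id, score)."""
    regulators: dict[str, list[np.ndarray]] = {}
    for p in ds.positives:
        regulators.setdefault(p.mirna_id, []).append(ds.fingerprints[p.sm_id])
    rows = [
        (sm, mir, regulation_score(ds.fingerprints[sm], regulators[mir]))
        for sm, mir in sorted(candidates)
    ]
    return pd.DataFrame(rows, columns=["sm_id", "mirna_id", "score"])


def sample_negatives(
    ds: RegulationDataset,
    threshold: float = DEFAULT_THRESHOLD,
    n: int | None = None,
    seed: int = 0,
    other_direction_positives: Iterable[tuple[str, str]] = (),
    scores_out: str | Path | None = None,
) -> RegulationDataset:
    """Augment a positives-only dataset with n mined negatives (default: balanced).

    Keeps candidates with score strictly below ``threshold``, then draws n
    uniformly without replacement under ``seed``.  Optionally writes a
    scores.tsv audit table (sm_id, mirna_id, score, kept).
    """
    if n is None:
        n = len(ds.positives)
    candidates = enumerate_candidates(ds, other_direction_positives)
    scored = score_candidates(ds, candidates)
    pool = scored[scored["score"] < threshold].reset_index(drop=True)
    if len(pool) < n:
        raise ValueError(
            f"negative pool has {len(pool)} pairs with score < {threshold} "
            f"but {n} are requested; relax the threshold or lower n"
        )
    rng = np.random.default_rng(seed)
    chosen = pool.iloc[np.sort(rng.choice(len(pool), size=n, replace=False))]

    if scores_out is not None:
        kept = set(zip(chosen["sm_id"], chosen["mirna_id"]))
        audit = scored.copy()
        audit["kept"] = [
            (sm, mir) in kept for sm, mir in zip(audit["sm_id"], audit["mirna_id"])
        ]
        audit.to_csv(scores_out, sep="\t", index=False)

    negatives = [
        RegulationPair(r.sm_id, r.mirna_id, ds.direction, label=0) for r in chosen.itertuples()
    ]
    return replace(ds, pairs=ds.pairs + negatives)
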