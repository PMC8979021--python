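"""Regulation-pair corpus: loading, validation and direction-wise splitting.

The input layout is a minimal 4-column TSV (sm_id, smiles, mirna_id,
direction) plus a miRNA FASTA.  Molecules may alternatively be supplied as
precomputed 166-key fingerprints (the synthetic corpus path), in which case
the smiles column may be empty.  Pairs whose miRNA has no sequence are
dropped and logged; duplicates on (sm_id, mirna_id, direction) are
collapsed.  Matching between the pair table and FASTA is by exact id token —
no fuzzy name resolution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from smireg.chem_features import (
    SmallMolecule,
    export_fingerprints,
    import_fingerprints,
    maccs_fingerprint,
)
from smireg.rna_features import MiRNARecord, read_fasta, write_fasta

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")
REQUIRED_COLUMNS = ("sm_id", "smiles", "mirna_id", "direction")


@dataclass(frozen=True)
class RegulationPair:
    sm_id: str
    mirna_id: str
    direction: str  # "up" | "down"
    label: int  # 1 positive, 0 negative

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class RegulationDataset:
    """All pairs of one regulation direction plus the entities they reference."""

    direction: str
    pairs: list[RegulationPair]
    molecules: dict[str, SmallMolecule]
    mirnas: dict[str, MiRNARecord]
    fingerprints: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.pairs:
            if p.direction != self.direction:
                raise ValueError(
                    f"pair ({p.sm_id}, {p.mirna_id}) has direction {p.direction!r} "
                    f"in a {self.direction!r} dataset"
                )
        keys = [(p.sm_id, p.mirna_id, p.direction) for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (sm_id, mirna_id, direction) pairs in dataset")
        # every referenced molecule must be fingerprintable; every miRNA needs a sequence
        for p in self.pairs:
            if p.mirna_id not in self.mirnas:
                raise ValueError(f"pair references unknown miRNA {p.mirna_id!r}")
            if p.sm_id not in self.fingerprints:
                if p.sm_id not in self.molecules:
                    raise ValueError(f"pair references unknown molecule {p.sm_id!r}")
                self.fingerprints[p.sm_id] = maccs_fingerprint(self.molecules[p.sm_id])

    @property
    def positives(self) -> list[RegulationPair]:
        return [p for p in self.pairs if p.label == 1]

    @property
    def negatives(self) -> list[RegulationPair]:
        return [p for p in self.pairs if p.label == 0]

    def summary(self) -> dict:
        return {
            "direction": self.direction,
            "n_pairs": len(self.pairs),
            "n_positive": len(self.positives),
            "n_negative": len(self.negatives),
            "n_molecules": len({p.sm_id for p in self.pairs}),
            "n_mirnas": len({p.mirna_id for p in self.pairs}),
        }


def load_pairs(
    pair_table: str | Path,
    sequences: str | Path,
    fingerprints: str | Path | None = None,
    species_prefix: str | None = None,
) -> dict[str, RegulationDataset]:
    """Load the pair TSV + FASTA into per-direction datasets of positive pairs.

    Parameters
    ----------
    pair_table:
        TSV with columns sm_id, smiles, mirna_id, direction.
    sequences:
        miRNA FASTA; pairs whose mirna_id is absent are dropped (and logged).
    fingerprints:
        optional TSV of precomputed 166-key fingerprints keyed by sm_id.
    species_prefix:
        optional miRNA-id prefix filter, e.g. ``"hsa-"``.
    """
    df = pd.read_csv(pair_table, sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{pair_table}: missing required column(s) {missing}")
    bad_dir = sorted(set(df["direction"]) - set(DIRECTIONS))
    if bad_dir:
        raise ValueError(f"{pair_table}: invalid direction value(s) {bad_dir}")

    mirnas = read_fasta(sequences)
    fps = dict(import_fingerprints(fingerprints)) if fingerprints else {}

    if species_prefix:
        df = df[df["mirna_id"].str.startswith(species_prefix)]

    known = df["mirna_id"].isin(mirnas)
    dropped = df.loc[~known]
    if len(dropped):
        logger.info(
            "dropping %d pair(s) with missing miRNA sequences: %s",
            len(dropped),
            sorted(set(dropped["mirna_id"])),
        )
    df = df.loc[known]

    n_dup = df.duplicated(subset=["sm_id", "mirna_id", "direction"]).sum()
    if n_dup:
        logger.info("collapsing %d duplicate pair(s)", n_dup)
    df = df.drop_duplicates(subset=["sm_id", "mirna_id", "direction"])

    datasets: dict[str, RegulationDataset] = {}
    for direction in DIRECTIONS:
        sub = df[df["direction"] == direction]
        if sub.empty:
            continue
        molecules = {
            r.sm_id: SmallMolecule(r.sm_id, r.smiles)
            for r in sub.itertuples()
            if r.smiles or r.sm_id not in fps
        }
        pairs = [
            RegulationPair(r.sm_id, r.mirna_id, direction, label=1) for r in sub.itertuples()
        ]
        ds = RegulationDataset(
            direction=direction,
            pairs=pairs,
            molecules=molecules,
            mirnas={m: mirnas[m] for m in sub["mirna_id"].unique()},
            fingerprints={k: v for k, v in fps.items() if k in set(sub["sm_id"])},
        )
        logger.info("loaded %s", ds.summary())
        datasets[direction] = ds

    if not datasets:
        raise ValueError(f"{pair_table}: no pairs retained after filtering")
    return datasets


def export_dataset(ds: RegulationDataset, out_dir: str | Path) -> Path:
    """Write pairs.tsv, molecules.tsv, fingerprints.tsv, mirnas.fasta, summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(p.sm_id, p.mirna_id, p.direction, p.label) for p in ds.pairs],
        columns=["sm_id", "mirna_id", "direction", "label"],
    ).to_csv(out / "pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted((m.id, m.smiles) for m in ds.molecules.values()),
        columns=["id", "smiles"],
    ).to_csv(out / "molecules.tsv", sep="\t", index=False)
    export_fingerprints(
        {k: ds.fingerprints[k] for k in sorted(ds.fingerprints)}, out / "fingerprints.tsv"
    )
    write_fasta(sorted(ds.mirnas.values(), key=lambda r: r.id), out / "mirnas.fasta")
    with open(out / "summary.json", "w") as fh:
        json.dump(ds.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def load_dataset(ds_dir: str | Path) -> RegulationDataset:
    """Inverse of :func:`export_dataset`."""
    d = Path(ds_dir)
    pairs_df = pd.read_csv(d / "pairs.tsv", sep="\t", dtype={"sm_id": str, "mirna_id": str})
    mols_df = pd.read_csv(d / "molecules.tsv", sep="\t", dtype=str).fillna("")
    directions = pairs_df["direction"].unique()
    if len(directions) != 1:
        raise ValueError(f"{d}: dataset directory must hold a single direction, got {directions}")
    return RegulationDataset(
        direction=directions[0],
        pairs=[
            RegulationPair(r.sm_id, r.mirna_id, r.direction, int(r.label))
            for r in pairs_df.itertuples()
        ],
        molecules={r.id: SmallMolecule(r.id, r.smiles) for r in mols_df.itertuples()},
        mirnas=read_fasta(d / "mirnas.fasta"),
        fingerprints=import_fingerprints(d / "fingerprints.tsv"),
    )
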