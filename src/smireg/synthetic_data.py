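"""Synthetic regulation corpora with planted, recoverable structure.

Molecules come in fingerprint families: each family has a prototype 166-key
fingerprint and members are noisy copies (independent bit flips).  Each
family is assigned a unique sequence motif and a regulation direction;
miRNAs are random sequences, a subset of which carries a planted family
motif.  Positive pairs are (family member, motif-bearing miRNA); a fraction
``label_noise`` of emitted directions is corrupted, and the uncorrupted rule
is recorded so recovery tests can score against ground truth.

Molecules are emitted at fingerprint level (sampling chemically valid
SMILES with controlled similarity is out of scope); a small fixture of real
SMILES is provided separately for exercising the SMILES code path.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from smireg.chem_features import N_KEYS, SmallMolecule, export_fingerprints
from smireg.rna_features import ALPHABET, MiRNARecord, all_kmers, write_fasta

logger = logging.getLogger(__name__)

#: Real molecules for tests that must pass through SMILES parsing.
REAL_SMILES_FIXTURE = [
    SmallMolecule("ethanol", "CCO"),
    SmallMolecule("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    SmallMolecule("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    SmallMolecule("fluorouracil", "O=c1[nH]cc(F)c(=O)[nH]1"),
    SmallMolecule("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
    SmallMolecule("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    SmallMolecule("nicotine", "CN1CCCC1c1cccnc1"),
    SmallMolecule("glucose", "OCC1OC(O)C(O)C(O)C1O"),
    SmallMolecule("benzene", "c1ccccc1"),
    SmallMolecule("methane", "C"),
]

# prototype on-bit density; kept low so unrelated families usually fall
# below the 0.1 regulation-score screen
_PROTO_DENSITY = 0.12


@dataclass(frozen=True)
class SyntheticConfig:
    n_families: int = 6
    molecules_per_family: int = 8
    n_mirnas: int = 70
    motif_length: int = 4
    fingerprint_noise: float = 0.05
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "molecules_per_family", "n_mirnas", "motif_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("fingerprint_noise", "label_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_families > 4**self.motif_length:
            raise ValueError("more families than distinct motifs; increase motif_length")


@dataclass
class SyntheticCorpus:
    config: SyntheticConfig
    pairs: pd.DataFrame  # sm_id, smiles, mirna_id, direction (possibly corrupted)
    truth: pd.DataFrame  # sm_id, mirna_id, direction_true, corrupted
    fingerprints: dict[str, np.ndarray]
    mirnas: list[MiRNARecord]
    families: dict[str, dict]  # family -> {motif, direction, molecules, mirnas}

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        export_fingerprints(self.fingerprints, out / "fingerprints.tsv")
        write_fasta(self.mirnas, out / "mirnas.fasta")
        with open(out / "families.json", "w") as fh:
            json.dump(
                {"config": asdict(self.config), "families": self.families},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        return out


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def generate_corpus(cfg: SyntheticConfig) -> SyntheticCorpus:
    """Generate a corpus under ``cfg``; byte-identical for identical configs."""
    rng = np.random.default_rng(cfg.seed)

    # unique motif per family (sampling without replacement forbids collisions)
    motif_pool = all_kmers(cfg.motif_length) if cfg.motif_length <= 6 else None
    if motif_pool is not None:
        motifs = list(rng.choice(motif_pool, size=cfg.n_families, replace=False))
    else:  # rejection sampling for long motifs
        motifs = []
        while len(motifs) < cfg.n_families:
            m = _random_sequence(rng, cfg.motif_length)
            if m in motifs:
                logger.info("motif collision on %s; regenerating", m)
                continue
            motifs.append(m)

    families: dict[str, dict] = {}
    fingerprints: dict[str, np.ndarray] = {}
    for f in range(cfg.n_families):
        fam = f"fam{f}"
        proto = (rng.random(N_KEYS) < _PROTO_DENSITY).astype(np.uint8)
        members = []
        for m in range(cfg.molecules_per_family):
            sm_id = f"{fam}_sm{m}"
            flips = rng.random(N_KEYS) < cfg.fingerprint_noise
            fingerprints[sm_id] = (proto ^ flips).astype(np.uint8)
            members.append(sm_id)
        families[fam] = {
            "motif": motifs[f],
            "direction": "up" if f % 2 == 0 else "down",
            "molecules": members,
            "mirnas": [],
        }

    # miRNA i belongs to family i % (n_families + 1); the extra slot is
    # an unregulated remainder so negatives have somewhere to live
    mirnas: list[MiRNARecord] = []
    for i in range(cfg.n_mirnas):
        length = int(rng.integers(18, 26))
        seq = _random_sequence(rng, length)
        fam_idx = i % (cfg.n_families + 1)
        mir_id = f"mir{i:04d}"
        if fam_idx < cfg.n_families:
            fam = f"fam{fam_idx}"
            motif = families[fam]["motif"]
            pos = int(rng.integers(0, length - cfg.motif_length + 1))
            seq = seq[:pos] + motif + seq[pos + cfg.motif_length :]
            families[fam]["mirnas"].append(mir_id)
        mirnas.append(MiRNARecord(mir_id, seq))

    rows = []
    for fam, info in families.items():
        for sm_id in info["molecules"]:
            for mir_id in info["mirnas"]:
                corrupt = bool(rng.random() < cfg.label_noise)
                true_dir = info["direction"]
                emitted = {"up": "down", "down": "up"}[true_dir] if corrupt else true_dir
                rows.append((sm_id, "", mir_id, emitted, true_dir, corrupt))

    emitted_df = pd.DataFrame(
        rows, columns=["sm_id", "smiles", "mirna_id", "direction", "direction_true", "corrupted"]
    )
    pairs = emitted_df[["sm_id", "smiles", "mirna_id", "direction"]]
    truth = emitted_df[["sm_id", "mirna_id", "direction_true", "corrupted"]]
    return SyntheticCorpus(
        config=cfg,
        pairs=pairs,
        truth=truth,
        fingerprints=fingerprints,
        mirnas=mirnas,
        families=families,
    )


def true_regulation(corpus: SyntheticCorpus) -> set[tuple[str, str, str]]:
    """The uncorrupted rule as (sm_id, mirna_id, direction) triples."""
    out = set()
    for info in corpus.families.values():
        for sm in info["molecules"]:
            for mir in info["mirnas"]:
                out.add((sm, mir, info["direction"]))
    return out
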