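"""Seeded synthetic siRNA datasets with planted local sequence similarity.

The removal method rests on one statistical premise: some ineffective siRNAs
are locally similar to each other, so that mini-groups exist that contain no
potent record.  The generator reproduces exactly that structure:

* ineffective records are organized into motif families.  Each family has a
  random 19-nt consensus; members are per-base mutated copies, except for a
  protected motif window of ``motif_length`` nt that is stamped unchanged
  into every member (the shared subsequence);
* all other potent records are independent random sequences, rejected if
  they contain any family motif, so they carry no planted similarity;
* a small number of *decoy* potent records (default 3) emulate the chaotic
  intermixing of potent and ineffective siRNAs seen in real data, where
  sequence features alone cannot separate the classes (merged screens
  contain duplicate or near-identical siRNAs with discordant measured
  efficacies).  Decoy f is an exact copy of family f's consensus, and the
  same consensus also occurs as three extra low-efficacy ineffective twins.
  Identical sequences coincide in every encoding and metric, so the decoy
  deterministically shares its mini-group and mini-cluster with E3 records;
  without this structure no potent training record ever touches a
  low-efficacy neighborhood, the "max over potent" removal thresholds
  collapse to zero and their tie-inclusive conditions fire for every test
  record.  Decoys receive the highest efficacies in the dataset, so after
  the inhibition-sorted every-fifth split they occupy serials 1..4 and are
  always training records;
* efficacies are drawn so the 70% threshold cleanly separates the labels:
  regular potent uniform on [70, 99), decoys on [99, 100), ineffective a
  50/50 mixture of uniform [0, 20) and [20, 70) so both E3-heavy and
  E2-heavy regimes occur across the whole alpha ladder.

Roles are assigned with the canonical every-fifth split.  All randomness
flows from the single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .base_features import BASES
from .data_io import Dataset, SiRNARecord, split_every_fifth
from .neighbor_structures import mg_partition
from .base_features import feature_matrix

__all__ = ["FixtureConfig", "generate_fixture", "plant_pure_groups_check"]

_SEQ_LEN = 19


@dataclass(frozen=True)
class FixtureConfig:
    n_potent: int = 50
    n_ineffective: int = 150
    n_motif_families: int = 6
    motif_length: int = 7
    mutation_rate: float = 0.05
    n_decoy_potent: int = 3  # potent decoys, each duplicated by 3 ineffective twins
    test_fraction: float = 0.2  # realized through the every-fifth split
    potency_threshold: float = 70.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_potent < 1 or self.n_ineffective < 1 or self.n_motif_families < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.n_decoy_potent <= min(4, self.n_potent - 1):
            # at most 4 so the decoys fill serials 1..4 and never reach a
            # test serial (multiples of 5) in the every-fifth split
            raise ValueError("n_decoy_potent must be in 0..min(4, n_potent-1)")
        if self.n_decoy_potent > self.n_motif_families:
            raise ValueError("n_decoy_potent cannot exceed n_motif_families")
        if 3 * self.n_decoy_potent >= self.n_ineffective:
            raise ValueError("n_ineffective too small for the decoy twins")
        if not 0 <= self.motif_length <= _SEQ_LEN:
            raise ValueError(
                f"motif_length must be in 0..{_SEQ_LEN}, got {self.motif_length}"
            )
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")


def _random_seq(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=_SEQ_LEN))


def _mutate(seq: str, protected: slice, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    protected_idx = set(range(*protected.indices(_SEQ_LEN)))
    for pos in range(_SEQ_LEN):
        if pos in protected_idx:
            continue
        if rng.random() < rate:
            chars[pos] = rng.choice([b for b in BASES if b != chars[pos]])
    return "".join(chars)


def generate_fixture(
    cfg: FixtureConfig, return_truth: bool = False
) -> Dataset | tuple[Dataset, pd.DataFrame]:
    """Deterministic synthetic dataset with roles assigned.

    With ``return_truth`` a sidecar table is also returned giving, per record,
    the planted motif family (-1 for potent records) for audits.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    consensus = [_random_seq(rng) for _ in range(cfg.n_motif_families)]
    motif_starts = [
        int(rng.integers(0, _SEQ_LEN - cfg.motif_length + 1))
        for _ in range(cfg.n_motif_families)
    ]
    motifs = [
        consensus[f][motif_starts[f] : motif_starts[f] + cfg.motif_length]
        for f in range(cfg.n_motif_families)
    ]

    records: list[SiRNARecord] = []
    families: dict[str, int] = {}
    width = len(str(max(cfg.n_potent, cfg.n_ineffective)))

    def _motif_free_random() -> str:
        while True:
            seq = _random_seq(rng)
            if cfg.motif_length == 0 or not any(m in seq for m in motifs):
                return seq

    # decoys take the top efficacy band [hi, 100) so the inhibition-sorted
    # split pins them to serials 1..4 (training) for every seed
    hi = cfg.potency_threshold + 0.99 * (100.0 - cfg.potency_threshold)
    for i in range(cfg.n_potent):
        if i < cfg.n_decoy_potent:
            seq = consensus[i]
            eff = float(rng.uniform(hi, 100.0))
            fam = i
        else:
            seq = _motif_free_random()
            eff = float(rng.uniform(cfg.potency_threshold, hi))
            fam = -1
        rid = f"pot-{i + 1:0{width}d}"
        records.append(SiRNARecord(rid, seq, eff))
        families[rid] = fam

    n_twins = 3 * cfg.n_decoy_potent
    for j in range(cfg.n_ineffective):
        if j < n_twins:
            fam = j // 3
            seq = consensus[fam]
            # twins stay in E3 for every cut of the (possibly extended) ladder
            eff = float(rng.uniform(0.0, 10.0))
        else:
            fam = (j - n_twins) % cfg.n_motif_families
            window = slice(motif_starts[fam], motif_starts[fam] + cfg.motif_length)
            seq = _mutate(consensus[fam], window, cfg.mutation_rate, rng)
            if rng.random() < 0.5:
                eff = float(rng.uniform(0.0, 20.0))
            else:
                eff = float(rng.uniform(20.0, cfg.potency_threshold))
        rid = f"ine-{j + 1:0{width}d}"
        records.append(SiRNARecord(rid, seq, eff))
        families[rid] = fam

    ds = split_every_fifth(
        Dataset(records, potency_threshold=cfg.potency_threshold)
    )
    if not return_truth:
        return ds
    truth = pd.DataFrame(
        {
            "id": [r.id for r in ds.records],
            "family": [families[r.id] for r in ds.records],
            "role": [r.role for r in ds.records],
        }
    )
    return ds, truth


def plant_pure_groups_check(ds: Dataset) -> int:
    """Number of MG1 mini-groups (full C_31 encoding) with no potent member.

    Audits that a fixture actually provides the local-similarity structure
    the removal method exploits.
    """
    seqs = [r.sequence for r in ds.records]
    potent = np.array([ds.is_potent(r) for r in ds.records])
    part = mg_partition(feature_matrix(seqs, 31), metric="euclidean")
    count = 0
    for g in range(1, part.n_groups + 1):
        if not potent[part.members(g)].any():
            count += 1
    return count
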