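"""Reading, validation and train/test splitting of siRNA datasets.

An siRNA record is a 19-nt sense-strand sequence over {A,C,G,T} together with
its experimentally observed inhibition of the target gene, on the 0-100
percent scale.  Records at or above the potency threshold (70% knockdown by
default) are called *potent*, the rest *ineffective*.

Supported on-disk dialects:

* TSV/CSV with a header and columns ``id``, ``sequence``, ``inhibition``
  (an optional ``role`` column with values ``train``/``test`` is honoured);
* FASTA, with the observed inhibition carried in the description as
  ``inhibition=<float>``.

The canonical train/test split reorders records by observed inhibition,
assigns serial numbers 1..n and sends every record whose serial is a multiple
of five to the test set (20% of the data); :func:`split_modulus` generalises
this to other strides for cross-validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SiRNARecord",
    "Dataset",
    "ParseError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "split_every_fifth",
    "split_modulus",
    "DEFAULT_POTENCY_THRESHOLD",
]

DEFAULT_POTENCY_THRESHOLD = 70.0

_SEQ_LEN = 19
_VALID_BASES = frozenset("ACGT")
_INHIBITION_RE = re.compile(r"inhibition\s*=\s*([-+0-9.eE]+)")


class ParseError(ValueError):
    """A file could not be parsed into records (names the offending line)."""


class ValidationError(ValueError):
    """A record violates the domain invariants (names the offending id)."""


def canonical_sequence(raw: str, record_id: str = "?") -> str:
    """Canonicalize a sequence: uppercase, U->T; reject anything else.

    Raises :class:`ValidationError` if the result is not exactly 19 nt over
    {A,C,G,T}.
    """
    seq = raw.strip().upper().replace("U", "T")
    if len(seq) != _SEQ_LEN:
        raise ValidationError(
            f"record {record_id!r}: sequence length {len(seq)} != {_SEQ_LEN}"
        )
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValidationError(
            f"record {record_id!r}: invalid characters {sorted(bad)} in sequence"
        )
    return seq


@dataclass(frozen=True)
class SiRNARecord:
    """One siRNA: identifier, canonical 19-nt sequence, observed inhibition %."""

    id: str
    sequence: str
    inhibition: float
    role: str | None = None  # "train" | "test" | None (unassigned)

    def validate(self) -> None:
        canonical_sequence(self.sequence, self.id)
        if not 0.0 <= self.inhibition <= 100.0:
            raise ValidationError(
                f"record {self.id!r}: inhibition {self.inhibition} outside [0, 100]"
            )
        if self.role not in (None, "train", "test"):
            raise ValidationError(f"record {self.id!r}: bad role {self.role!r}")


@dataclass
class Dataset:
    """An ordered collection of validated siRNA records."""

    records: list[SiRNARecord] = field(default_factory=list)
    potency_threshold: float = DEFAULT_POTENCY_THRESHOLD

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            rec.validate()
            if rec.id in seen:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SiRNARecord]:
        return iter(self.records)

    def is_potent(self, rec: SiRNARecord) -> bool:
        return rec.inhibition >= self.potency_threshold

    @property
    def train(self) -> list[SiRNARecord]:
        return [r for r in self.records if r.role == "train"]

    @property
    def test(self) -> list[SiRNARecord]:
        return [r for r in self.records if r.role == "test"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "inhibition": [r.inhibition for r in self.records],
                "role": [r.role for r in self.records],
            }
        )


def _record_from_row(row: dict, lineno: int) -> SiRNARecord:
    try:
        rid = str(row["id"])
        raw_seq = str(row["sequence"])
        inhibition = float(row["inhibition"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"line {lineno}: malformed row ({exc})") from exc
    role = row.get("role")
    if role is not None and (pd.isna(role) or role == ""):
        role = None
    rec = SiRNARecord(rid, canonical_sequence(raw_seq, rid), inhibition, role)
    rec.validate()
    return rec


def _read_table(path: Path, sep: str) -> list[SiRNARecord]:
    try:
        frame = pd.read_csv(path, sep=sep, dtype={"id": str, "sequence": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing = {"id", "sequence", "inhibition"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, row in enumerate(frame.to_dict("records")):
        records.append(_record_from_row(row, lineno=idx + 2))  # +2: header + 1-based
    return records


def _read_fasta(path: Path) -> list[SiRNARecord]:
    records = []
    for i, entry in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        match = _INHIBITION_RE.search(entry.description)
        if match is None:
            raise ParseError(
                f"{path}: entry {i} ({entry.id}): no 'inhibition=<float>' in header"
            )
        rid = entry.id
        rec = SiRNARecord(
            rid, canonical_sequence(str(entry.seq), rid), float(match.group(1))
        )
        rec.validate()
        records.append(rec)
    return records


def read_dataset(
    path: str | Path,
    format: str | None = None,
    potency_threshold: float = DEFAULT_POTENCY_THRESHOLD,
) -> Dataset:
    """Read a dataset from TSV, CSV or FASTA (format inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {
            ".tsv": "tsv",
            ".csv": "csv",
            ".fa": "fasta",
            ".fasta": "fasta",
            ".fna": "fasta",
        }.get(path.suffix.lower(), "tsv")
    if format == "tsv":
        records = _read_table(path, sep="\t")
    elif format == "csv":
        records = _read_table(path, sep=",")
    elif format == "fasta":
        records = _read_fasta(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return Dataset(records, potency_threshold=potency_threshold)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset as canonical TSV (columns id, sequence, inhibition[, role])."""
    path = Path(path)
    frame = ds.to_frame()
    if frame["role"].isna().all():
        frame = frame.drop(columns=["role"])
    frame.to_csv(path, sep="\t", index=False)


def _serial_order(ds: Dataset, descending: bool = True) -> list[SiRNARecord]:
    # Deterministic reorder by observed inhibition; ties broken by id so the
    # split depends only on record content, never on input row order.
    return sorted(
        ds.records,
        key=lambda r: (-r.inhibition if descending else r.inhibition, r.id),
    )


def split_modulus(
    ds: Dataset, modulus: int, offset: int = 0, descending: bool = True
) -> Dataset:
    """Assign roles by serial number: test iff serial = offset (mod modulus).

    Records are reordered by observed inhibition (descending by default, ties
    by id) and given serials 1..n; ``offset=0`` selects the multiples of
    ``modulus``.  A split that would leave the training or test set empty is
    rejected.
    """
    if modulus < 1:
        raise ValueError(f"modulus must be >= 1, got {modulus}")
    if not 0 <= offset < modulus:
        raise ValueError(f"offset must be in [0, {modulus}), got {offset}")
    ordered = _serial_order(ds, descending=descending)
    out = []
    n_test = 0
    for serial, rec in enumerate(ordered, start=1):
        is_test = serial % modulus == offset % modulus
        n_test += is_test
        out.append(replace(rec, role="test" if is_test else "train"))
    if n_test == 0:
        raise ValueError("split produced no test records")
    if n_test == len(out):
        raise ValueError(
            "split selected every record as test (empty training set); "
            "modulus=1 is not a usable partition"
        )
    return Dataset(out, potency_threshold=ds.potency_threshold)


def split_every_fifth(ds: Dataset, descending: bool = True) -> Dataset:
    """The canonical 20% split: serials that are multiples of 5 become test."""
    if len(ds) < 5:
        raise ValueError(f"need at least 5 records to split, got {len(ds)}")
    return split_modulus(ds, modulus=5, offset=0, descending=descending)
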