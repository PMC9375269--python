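"""Raw sequence encodings and the catalogue of 31 composite feature sets.

Two families of raw encodings are computed for a 19-nt siRNA sequence R:

* ``F_m`` (m = 1..4): the frequency vector of all 4^m m-mers counted over the
  circularly extended sequence ``R_m = R r_1 ... r_{m-1}`` (the first m-1
  nucleotides are appended), so every F_m has exactly 19 counting windows and
  its entries always sum to 19.
* ``B``: the 76-entry positional one-hot encoding — 19 positions x 4
  nucleotides (A, C, G, T per position), 19 ones in total.

The 31 composite ``C_k`` feature sets are the non-empty subsets of
{F1, F2, F3, F4, B}, concatenated in that fixed block order.  The index k is
the 5-bit membership mask (bit 0 = F1 ... bit 4 = B), so that C_15 is the
union of the four frequency blocks and C_31 uses all five blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BLOCK_ORDER",
    "BLOCK_DIMS",
    "FeatureBlock",
    "CkFeature",
    "encode_frequency",
    "encode_binary",
    "ck_catalogue",
    "ck_members",
    "ck_dimension",
    "encode_ck",
    "feature_matrix",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

BLOCK_ORDER: tuple[str, ...] = ("F1", "F2", "F3", "F4", "B")
BLOCK_DIMS: dict[str, int] = {"F1": 4, "F2": 16, "F3": 64, "F4": 256, "B": 76}

N_CK = 31


@dataclass(frozen=True)
class FeatureBlock:
    kind: str  # F1 | F2 | F3 | F4 | B
    values: np.ndarray


@dataclass(frozen=True)
class CkFeature:
    k: int
    block_subset: tuple[str, ...]
    values: np.ndarray


def _base_indices(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in sequence") from exc


def encode_frequency(seq: str, m: int) -> FeatureBlock:
    """m-mer frequency vector F_m of the circularly extended sequence.

    The vector is indexed by the 4^m m-mers in lexicographic A<C<G<T order;
    the circular extension guarantees 19 windows, so the entries sum to 19.
    """
    if not 1 <= m <= 4:
        raise ValueError(f"m must be in 1..4, got {m}")
    if len(seq) != 19:
        raise ValueError(f"expected a 19-nt sequence, got length {len(seq)}")
    idx = _base_indices(seq)
    ext = np.concatenate([idx, idx[: m - 1]]) if m > 1 else idx
    # integer code of each m-mer window, base-4, A<C<G<T
    codes = np.zeros(19, dtype=np.int64)
    for j in range(m):
        codes = codes * 4 + ext[j : j + 19]
    values = np.bincount(codes, minlength=4**m).astype(np.int64)
    return FeatureBlock(f"F{m}", values)


def encode_binary(seq: str) -> FeatureBlock:
    """Positional one-hot encoding B: 19 positions x (A,C,G,T) = 76 entries."""
    if len(seq) != 19:
        raise ValueError(f"expected a 19-nt sequence, got length {len(seq)}")
    idx = _base_indices(seq)
    values = np.zeros(76, dtype=np.int64)
    values[np.arange(19) * 4 + idx] = 1
    return FeatureBlock("B", values)


def ck_members(k: int) -> tuple[str, ...]:
    """Member blocks of C_k: the blocks whose bit is set in the mask k."""
    if not 1 <= k <= N_CK:
        raise ValueError(f"k must be in 1..{N_CK}, got {k}")
    return tuple(b for i, b in enumerate(BLOCK_ORDER) if k >> i & 1)


def ck_catalogue() -> list[tuple[str, ...]]:
    """The 31 composite feature sets, ordered by mask index k = 1..31."""
    return [ck_members(k) for k in range(1, N_CK + 1)]


def ck_dimension(k: int) -> int:
    return sum(BLOCK_DIMS[b] for b in ck_members(k))


def _encode_block(seq: str, kind: str) -> FeatureBlock:
    if kind == "B":
        return encode_binary(seq)
    return encode_frequency(seq, int(kind[1]))


def encode_ck(seq: str, k: int) -> CkFeature:
    """Concatenate the member blocks of C_k in fixed F1,F2,F3,F4,B order."""
    members = ck_members(k)
    values = np.concatenate([_encode_block(seq, b).values for b in members])
    return CkFeature(k, members, values)


def feature_matrix(seqs: Sequence[str], k: int) -> np.ndarray:
    """Stack C_k encodings of several sequences into an (n, d_k) matrix."""
    return np.stack([encode_ck(s, k).values for s in seqs]).astype(np.float64)
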