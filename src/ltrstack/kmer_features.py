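"""K-mer vocabulary enumeration and occurrence-count vectorization.

Every sequence is summarized as the vector of overlapping k-mer occurrence
counts for all k in a range (default 1..6, a 5,460-dimensional alignment-free
compositional fingerprint). Counts are raw occurrences, not frequencies —
normalization belongs to the downstream scaling step — and windows containing
an ambiguous (non-ACGT) base contribute to no k-mer.

Counting runs in O(L) per k via a 2-bit base encoding and vectorized window
codes; its correctness contract is exact equality with a naive
position-by-position sliding-window count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocessing import FeatureMatrix
from .sequence_io import Dataset, SequenceRecord

__all__ = [
    "KmerVocabulary",
    "KmerVector",
    "enumerate_kmers",
    "count_kmers",
    "vectorize_dataset",
    "reverse_complement",
]

_BASES = "ACGT"
# A->0, C->1, G->2, T->3; every other byte -> -1 (ambiguous)
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerVocabulary:
    """Ordered universe of k-mers for a k range; positions are feature indices.

    Ordering is ascending k, then lexicographic within k (A < C < G < T), so
    the vocabulary for (1, 6) starts A, C, G, T, AA, ... and has
    sum_{k=1..6} 4^k = 5,460 entries.
    """

    k_min: int
    k_max: int
    kmers: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.kmers)

    def index_of(self, kmer: str) -> int:
        """Feature index of a k-mer, computed from its 2-bit code in O(k)."""
        k = len(kmer)
        if not self.k_min <= k <= self.k_max:
            raise KeyError(f"{kmer!r} outside k range ({self.k_min},{self.k_max})")
        code = 0
        for ch in kmer.upper():
            v = _CODE[ord(ch)]
            if v < 0:
                raise KeyError(f"{kmer!r} contains non-ACGT letters")
            code = code * 4 + int(v)
        return self._offset(k) + code

    def _offset(self, k: int) -> int:
        return sum(4 ** j for j in range(self.k_min, k))

    def __len__(self) -> int:
        return self.size


@dataclass(frozen=True)
class KmerVector:
    """Occurrence counts aligned to a vocabulary, for one source sequence."""

    counts: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", np.asarray(self.counts, dtype=np.int64)
        )


def enumerate_kmers(k_min: int, k_max: int) -> KmerVocabulary:
    """Full cross-product vocabulary over {A,C,G,T} in canonical order."""
    if k_min < 1:
        raise ValueError(f"k_min must be >= 1, got {k_min}")
    if k_min > k_max:
        raise ValueError(f"k_min={k_min} exceeds k_max={k_max}")
    kmers: list[str] = []
    for k in range(k_min, k_max + 1):
        kmers.extend("".join(p) for p in product(_BASES, repeat=k))
    return KmerVocabulary(k_min=k_min, k_max=k_max, kmers=tuple(kmers))


def _count_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts over the 4^k k-mers for one k from 2-bit base codes."""
    if len(codes) < k:
        return np.zeros(4 ** k, dtype=np.int64)
    windows = sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return np.zeros(4 ** k, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    window_codes = windows[valid] @ powers
    return np.bincount(window_codes, minlength=4 ** k).astype(np.int64)


def count_kmers(
    seq: SequenceRecord | str,
    vocab: KmerVocabulary,
    canonical: bool = False,
) -> KmerVector:
    """Overlapping-window k-mer counts of one sequence, case-insensitive.

    Any window containing a non-ACGT letter is skipped; a sequence shorter
    than k contributes zeros for that k. With ``canonical=True`` each
    occurrence is credited to the lexicographic minimum of the k-mer and its
    reverse complement (non-default; plain strand-specific counts are the
    standard feature set).
    """
    if isinstance(seq, SequenceRecord):
        residues, source_id = seq.residues, seq.id
    else:
        residues, source_id = seq, ""
    codes = _CODE[np.frombuffer(residues.upper().encode(), dtype=np.uint8)]
    parts = [
        _count_codes(codes, k) for k in range(vocab.k_min, vocab.k_max + 1)
    ]
    if canonical:
        rc_codes = _CODE[
            np.frombuffer(
                reverse_complement(residues).upper().encode(), dtype=np.uint8
            )
        ]
        for j, k in enumerate(range(vocab.k_min, vocab.k_max + 1)):
            fwd = parts[j]
            rev = _count_codes(rc_codes, k)
            total = fwd + rev
            idx = np.arange(4 ** k)
            rc_idx = _revcomp_index(idx, k)
            keep = idx <= rc_idx
            out = np.zeros_like(total)
            out[idx[keep]] = total[idx[keep]]
            # palindromes were double counted by fwd+rev
            pal = idx[idx == rc_idx]
            out[pal] = total[pal] // 2
            parts[j] = out
    counts = np.concatenate(parts)
    return KmerVector(counts=counts, source_id=source_id)


def _revcomp_index(idx: np.ndarray, k: int) -> np.ndarray:
    """Vectorized index of the reverse complement of each k-mer code."""
    out = np.zeros_like(idx)
    rem = idx.copy()
    for _ in range(k):
        out = out * 4 + (3 - rem % 4)
        rem //= 4
    return out


def vectorize_dataset(
    ds: Dataset,
    vocab: KmerVocabulary,
    normalize_length: bool = False,
    canonical: bool = False,
) -> FeatureMatrix:
    """One count row per record, columns named by the vocabulary's k-mers.

    ``normalize_length=True`` divides each row by sequence length (off by
    default: raw occurrence counts feed the pipeline and scaling happens
    downstream).
    """
    if len(ds) == 0:
        raise ValueError("cannot vectorize an empty dataset")
    rows = np.empty((len(ds), vocab.size), dtype=float)
    ids: list[str] = []
    labels: list[Optional[int]] = []
    for i, rec in enumerate(ds):
        vec = count_kmers(rec, vocab, canonical=canonical)
        row = vec.counts.astype(float)
        if normalize_length:
            row /= len(rec)
        rows[i] = row
        ids.append(rec.id)
        labels.append(rec.label)
    label_arr = (
        np.array(labels) if all(l is not None for l in labels) else None
    )
    return FeatureMatrix(
        values=rows,
        feature_names=list(vocab.kmers),
        sample_ids=ids,
        labels=label_arr,
    )
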