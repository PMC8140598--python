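"""Per-base DNA numeric coding schemes and physicochemical profiles.

Alternative feature representations for the binary task: each sequence becomes
a numeric series under a coding scheme — DAX, EIIP (electron-ion interaction
pseudopotential), Complementary, Enthalpy (dinucleotide nearest-neighbor) or
Galois(4) — or a trio of dinucleotide sliding-window physicochemical profiles
(hydrogen bonding, stacking, and solvation energy per bp). Scheme tables live
in versioned JSON config files under ``ltrstack/data/schemes`` and are
editable; code asserts only their structure (completeness, finiteness), not
specific values, so transcription revisions do not ripple through the API.

Classical estimators need equal-length rows, so series are right-padded with
the scheme's neutral value to a common length before matrix assembly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from itertools import product
from typing import Iterable, Optional

import numpy as np

from .preprocessing import FeatureMatrix
from .sequence_io import Dataset, SequenceRecord

__all__ = [
    "EncodingScheme",
    "PhysChemTable",
    "SCHEME_NAMES",
    "load_scheme",
    "load_physchem",
    "encode_sequence",
    "decode_sequence",
    "physchem_profile",
    "encode_dataset",
    "physchem_dataset",
]

SCHEME_NAMES = ("DAX", "EIIP", "Complementary", "Enthalpy", "Galois4")
_BASES = "ACGT"
_DINUCS = tuple(a + b for a, b in product(_BASES, repeat=2))


class PaddingError(ValueError):
    """Raised when pad_to is shorter than the natural series length."""


@dataclass(frozen=True)
class EncodingScheme:
    """A base- or dinucleotide-level numeric map with a neutral fill value."""

    name: str
    table: dict[str, float]
    arity: int
    neutral: float = 0.0

    def __post_init__(self) -> None:
        if self.arity not in (1, 2):
            raise ValueError(f"arity must be 1 or 2, got {self.arity}")
        required = set(_BASES) if self.arity == 1 else set(_DINUCS)
        missing = required - set(self.table)
        if missing:
            raise ValueError(
                f"scheme {self.name}: incomplete table, missing {sorted(missing)}"
            )
        values = [self.table[k] for k in sorted(required)]
        if not np.all(np.isfinite(values)):
            raise ValueError(f"scheme {self.name}: non-finite table values")

    @property
    def is_injective(self) -> bool:
        keys = _BASES if self.arity == 1 else _DINUCS
        vals = [self.table[k] for k in keys]
        return len(set(vals)) == len(vals)


@dataclass(frozen=True)
class PhysChemTable:
    """Three dinucleotide energy tables (kcal/mol per bp step)."""

    hydrogen_bonding: dict[str, float]
    stacking: dict[str, float]
    solvation: dict[str, float]

    def __post_init__(self) -> None:
        for attr in ("hydrogen_bonding", "stacking", "solvation"):
            table = getattr(self, attr)
            missing = set(_DINUCS) - set(table)
            if missing:
                raise ValueError(
                    f"physchem table {attr}: missing {sorted(missing)}"
                )

    @property
    def properties(self) -> tuple[str, ...]:
        return ("hydrogen_bonding", "stacking", "solvation")


def _scheme_file(stem: str):
    return resources.files("ltrstack.data.schemes").joinpath(f"{stem}.json")


def load_scheme(name: str) -> EncodingScheme:
    """Load a named coding scheme from its config file."""
    if name not in SCHEME_NAMES:
        raise KeyError(f"unknown scheme {name!r}; valid: {SCHEME_NAMES}")
    doc = json.loads(_scheme_file(name.lower()).read_text())
    return EncodingScheme(
        name=doc["name"],
        table={k.upper(): float(v) for k, v in doc["table"].items()},
        arity=int(doc["arity"]),
        neutral=float(doc.get("neutral", 0.0)),
    )


def load_physchem() -> PhysChemTable:
    doc = json.loads(_scheme_file("physchem").read_text())
    return PhysChemTable(
        hydrogen_bonding={k.upper(): float(v) for k, v in doc["hydrogen_bonding"].items()},
        stacking={k.upper(): float(v) for k, v in doc["stacking"].items()},
        solvation={k.upper(): float(v) for k, v in doc["solvation"].items()},
    )


def encode_sequence(
    seq: SequenceRecord | str,
    scheme: EncodingScheme,
    pad_to: Optional[int] = None,
) -> np.ndarray:
    """Encode a sequence as a numeric series under a coding scheme.

    Output length is L for arity-1 schemes and L-1 for arity-2 (dinucleotide)
    schemes. Ambiguous positions map to the scheme's neutral value; ``pad_to``
    right-pads with the neutral value and refuses (raises
    :class:`PaddingError`) to truncate.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    if not residues:
        raise ValueError("cannot encode an empty sequence")
    if scheme.arity == 1:
        out = np.array(
            [scheme.table.get(b, scheme.neutral) for b in residues]
        )
    else:
        if len(residues) < 2:
            raise ValueError("arity-2 scheme needs a sequence of length >= 2")
        out = np.array(
            [
                scheme.table.get(residues[i : i + 2], scheme.neutral)
                for i in range(len(residues) - 1)
            ]
        )
    if pad_to is not None:
        if pad_to < len(out):
            raise PaddingError(
                f"pad_to={pad_to} shorter than natural length {len(out)}"
            )
        out = np.pad(out, (0, pad_to - len(out)),
                     constant_values=scheme.neutral)
    return out


def decode_sequence(series: np.ndarray, scheme: EncodingScheme) -> str:
    """Invert an arity-1 injective scheme (value series back to bases)."""
    if scheme.arity != 1 or not scheme.is_injective:
        raise ValueError(f"scheme {scheme.name} is not invertible")
    inverse = {v: b for b, v in scheme.table.items()}
    return "".join(inverse[float(v)] for v in series)


def physchem_profile(
    seq: SequenceRecord | str, table: Optional[PhysChemTable] = None
) -> dict[str, np.ndarray]:
    """Three dinucleotide sliding-window energy profiles of one sequence.

    Window i covers bases (i, i+1), stepping one base at a time from the first
    dinucleotide, so each series has length L-1. Ambiguous windows contribute
    0 (energetically neutral).
    """
    table = table or load_physchem()
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq.upper()
    if len(residues) < 2:
        raise ValueError(
            f"physicochemical profile needs L >= 2, got L={len(residues)}"
        )
    dinucs = [residues[i : i + 2] for i in range(len(residues) - 1)]
    return {
        prop: np.array([getattr(table, prop).get(d, 0.0) for d in dinucs])
        for prop in table.properties
    }


def encode_dataset(
    ds: Dataset,
    scheme: EncodingScheme,
    pad_to: Optional[int] = None,
) -> FeatureMatrix:
    """Encode every record, right-padded to a common length.

    Default pad length is the dataset's maximum natural series length.
    """
    if len(ds) == 0:
        raise ValueError("cannot encode an empty dataset")
    natural = [len(r) - (scheme.arity - 1) for r in ds]
    width = max(natural) if pad_to is None else pad_to
    rows = np.empty((len(ds), width))
    labels, ids = [], []
    for i, rec in enumerate(ds):
        rows[i] = encode_sequence(rec, scheme, pad_to=width)
        ids.append(rec.id)
        labels.append(rec.label)
    names = [f"{scheme.name.lower()}_{j}" for j in range(width)]
    label_arr = np.array(labels) if all(l is not None for l in labels) else None
    return FeatureMatrix(rows, names, ids, label_arr)


def physchem_dataset(
    ds: Dataset,
    table: Optional[PhysChemTable] = None,
    mode: str = "concat",
    pad_to: Optional[int] = None,
) -> FeatureMatrix:
    """Physicochemical features for every record.

    ``mode="concat"`` (default) concatenates the three padded profiles;
    ``mode="summary"`` reduces each profile to its mean and standard
    deviation (6 features), a compact alternative for long sequences.
    """
    if len(ds) == 0:
        raise ValueError("cannot featurize an empty dataset")
    table = table or load_physchem()
    profiles = [physchem_profile(rec, table) for rec in ds]
    ids = [rec.id for rec in ds]
    labels = [rec.label for rec in ds]
    label_arr = np.array(labels) if all(l is not None for l in labels) else None
    props = table.properties
    if mode == "summary":
        rows = np.array(
            [
                [fn(p[prop]) for prop in props for fn in (np.mean, np.std)]
                for p in profiles
            ]
        )
        names = [f"{prop}_{stat}" for prop in props for stat in ("mean", "std")]
        return FeatureMatrix(rows, names, ids, label_arr)
    if mode != "concat":
        raise ValueError(f"unknown mode {mode!r}")
    width = max(len(p[props[0]]) for p in profiles) if pad_to is None else pad_to
    rows = np.zeros((len(ds), width * 3))
    for i, p in enumerate(profiles):
        for j, prop in enumerate(props):
            series = p[prop]
            if len(series) > width:
                raise PaddingError(
                    f"pad_to={width} shorter than profile length {len(series)}"
                )
            rows[i, j * width : j * width + len(series)] = series
    names = [f"{prop}_{j}" for prop in props for j in range(width)]
    return FeatureMatrix(rows, names, ids, label_arr)
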