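"""FASTA input/output, lineage class registry, and dataset assembly.

DNA sequences arrive as FASTA repeat libraries whose headers optionally carry a
lineage label after a ``#`` separator (``>element_17#ALE/Retrofit``), the
convention used by curated plant LTR retrotransposon libraries such as
InpactorDB. Records parse into :class:`SequenceRecord`; a :class:`ClassRegistry`
maps integer class codes to (superfamily, lineage) names; a :class:`Dataset`
bundles records with the registry and supports the filtering and balanced
sampling rules used to assemble the three classification tasks (binary,
lineage-level multiclass, and the unified binary-plus-multiclass task).
"""

from __future__ import annotations

import random
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional, Sequence

import pandas as pd

IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN")

__all__ = [
    "SequenceRecord",
    "ClassRegistry",
    "Dataset",
    "FastaParseError",
    "UnknownLineageError",
    "default_registry",
    "binary_registry",
    "read_fasta",
    "write_fasta",
    "filter_min_length",
    "balanced_sample",
    "write_manifest",
    "negative_composition",
    "unified_composition",
    "composition_total",
]


class FastaParseError(ValueError):
    """Raised when a FASTA file violates the format."""


class UnknownLineageError(KeyError):
    """Raised when a header lineage name is not in the registry."""


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with identifier, free-text description and optional label.

    ``residues`` is stored uppercased; lowercase (soft-masked) input is accepted
    and uppercased on construction because every downstream feature is
    case-blind. Only IUPAC nucleotide letters are admitted.
    """

    id: str
    residues: str
    description: str = ""
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        seq = self.residues.upper()
        bad = set(seq) - IUPAC_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC letters {sorted(bad)!r}"
            )
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ClassRegistry:
    """Mapping of integer class codes to (superfamily, lineage) names.

    Codes need not be contiguous: the default registry keeps the historical
    gaps of the curated lineage numbering (codes 2, 5, 6, 7, 10, 11 and 15 are
    absent) so confusion matrices line up with published class axes.
    """

    entries: dict[int, tuple[str, str]]
    negative_code: int = 0

    def __post_init__(self) -> None:
        if self.negative_code not in self.entries:
            raise ValueError(
                f"negative code {self.negative_code} missing from entries"
            )

    @property
    def codes(self) -> list[int]:
        return sorted(self.entries)

    @property
    def positive_codes(self) -> list[int]:
        return [c for c in self.codes if c != self.negative_code]

    def superfamily(self, code: int) -> str:
        return self.entries[code][0]

    def lineage(self, code: int) -> str:
        return self.entries[code][1]

    def code_for_lineage(self, name: str) -> int:
        """Resolve a lineage name (header token) to its class code.

        Underscores are accepted in place of spaces so multi-word names survive
        FASTA header tokenisation.
        """
        wanted = name.replace("_", " ")
        for code, (_, lineage) in self.entries.items():
            if lineage == name or lineage == wanted:
                return code
        valid = ", ".join(lin for _, lin in self.entries.values())
        raise UnknownLineageError(
            f"unknown lineage {name!r}; valid names: {valid}"
        )

    def __contains__(self, code: int) -> bool:
        return code in self.entries


#: Lineage composition of the unified classification task: the negative class
#: plus 7 Copia and 6 Gypsy lineages, with their conventional class codes.
_DEFAULT_ENTRIES: dict[int, tuple[str, str]] = {
    0: ("-", "Other genomic features"),
    1: ("Copia", "ALE/Retrofit"),
    3: ("Copia", "Angela"),
    4: ("Copia", "Bianca"),
    8: ("Copia", "Ikeros"),
    9: ("Copia", "Ivana/Oryco"),
    12: ("Copia", "Tork/Tar"),
    13: ("Copia", "SIRE"),
    14: ("Gypsy", "CRM"),
    16: ("Gypsy", "Galadriel"),
    17: ("Gypsy", "Reina"),
    18: ("Gypsy", "Tekay/DEL"),
    19: ("Gypsy", "Athila"),
    20: ("Gypsy", "TAT"),
}


def default_registry() -> ClassRegistry:
    """Registry for the unified task: code 0 negative + 13 lineage classes."""
    return ClassRegistry(entries=dict(_DEFAULT_ENTRIES), negative_code=0)


def binary_registry() -> ClassRegistry:
    """Two-class registry: LTR retrotransposon vs other genomic features."""
    return ClassRegistry(
        entries={
            0: ("-", "Other genomic features"),
            1: ("LTR-RT", "LTR retrotransposon"),
        },
        negative_code=0,
    )


@dataclass
class Dataset:
    """Ordered collection of records plus the registry their labels refer to."""

    records: list[SequenceRecord]
    registry: ClassRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.label is not None and rec.label not in self.registry:
                raise ValueError(
                    f"record {rec.id!r} labeled {rec.label}, "
                    f"not in registry codes {self.registry.codes}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def class_counts(self) -> Counter[Optional[int]]:
        """Per-class record counts; key ``None`` collects unlabeled records."""
        return Counter(rec.label for rec in self.records)

    def labeled(self) -> "Dataset":
        return Dataset(
            [r for r in self.records if r.label is not None], self.registry
        )


LabelParser = Callable[[str, str, ClassRegistry], Optional[int]]


def hash_label_parser(
    name: str, description: str, registry: ClassRegistry
) -> Optional[int]:
    """Default labeling rule: lineage name after ``#`` in the id token."""
    if "#" not in name:
        return None
    lineage = name.split("#", 1)[1]
    return registry.code_for_lineage(lineage)


def read_fasta(
    path: str | Path,
    label_parser: LabelParser = hash_label_parser,
    registry: Optional[ClassRegistry] = None,
) -> Dataset:
    """Read a FASTA file into a labeled :class:`Dataset`.

    Accepts single-line and multi-line sequence dialects. Headers are split at
    the first whitespace; the id token is passed to ``label_parser`` together
    with the remaining description. An empty file yields an empty dataset.

    Raises
    ------
    FastaParseError
        If sequence data precedes the first header, a record is empty, or a
        sequence line contains non-IUPAC characters (the message names the
        offending line number).
    UnknownLineageError
        If a header lineage name is absent from the registry.
    """
    registry = registry or default_registry()
    records: list[SequenceRecord] = []
    header: Optional[tuple[str, str]] = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        name, desc = header
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(
                f"{path}: empty record {name!r} at line {header_line}"
            )
        label = label_parser(name, desc, registry)
        rec_id = name.split("#", 1)[0]
        try:
            records.append(
                SequenceRecord(
                    id=rec_id, residues=seq, description=desc, label=label
                )
            )
        except ValueError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FastaParseError(
                        f"{path}: empty header at line {lineno}"
                    )
                header = (parts[0], parts[1] if len(parts) > 1 else "")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                bad = set(line.upper()) - IUPAC_LETTERS
                if bad:
                    raise FastaParseError(
                        f"{path}: invalid characters {sorted(bad)!r} "
                        f"at line {lineno}"
                    )
                chunks.append(line)
        flush()
    return Dataset(records, registry)


def write_fasta(ds: Dataset, path: str | Path, width: int = 70) -> None:
    """Write a dataset as FASTA, 70-column wrapped.

    Labeled records get ``id#Lineage`` headers (spaces in lineage names become
    underscores so the token survives whitespace splitting); unlabeled records
    get a bare id. Round-tripping through :func:`read_fasta` preserves ids,
    labels and residues exactly.
    """
    with open(path, "w") as fh:
        for rec in ds.records:
            if rec.label is not None:
                lineage = ds.registry.lineage(rec.label).replace(" ", "_")
                name = f"{rec.id}#{lineage}"
            else:
                name = rec.id
            head = f">{name} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def filter_min_length(ds: Dataset, min_len: int) -> Dataset:
    """Keep records strictly longer than ``min_len`` bp, preserving order.

    The unified-task negative pool retains only sequences longer than 6 kb;
    "longer than" is read strictly (``len > min_len``). Idempotent.
    """
    if min_len < 0:
        raise ValueError(f"min_len must be >= 0, got {min_len}")
    return Dataset(
        [r for r in ds.records if len(r) > min_len], ds.registry
    )


def balanced_sample(
    positives: Dataset,
    negatives: Dataset,
    n_per_class: int,
    seed: int,
) -> Dataset:
    """Draw a balanced binary-task dataset: ``n_per_class`` from each pool.

    Sampling is without replacement and reproducible under ``seed``. Positive
    labels collapse to code 1 and negatives to code 0 under the binary
    registry, regardless of the pools' original lineage labels.
    """
    for name, pool in (("positives", positives), ("negatives", negatives)):
        if len(pool) < n_per_class:
            raise ValueError(
                f"{name} pool has {len(pool)} records, "
                f"need {n_per_class} per class"
            )
    rng = random.Random(seed)
    registry = binary_registry()
    out: list[SequenceRecord] = []
    for pool, code in ((positives, 1), (negatives, 0)):
        picked = rng.sample(range(len(pool)), n_per_class)
        for i in sorted(picked):
            out.append(replace(pool.records[i], label=code))
    return Dataset(out, registry)


def write_manifest(ds: Dataset, path: str | Path) -> None:
    """Write a TSV manifest: id, class code, superfamily, lineage, length."""
    rows = []
    for rec in ds.records:
        if rec.label is not None:
            sf = ds.registry.superfamily(rec.label)
            lin = ds.registry.lineage(rec.label)
        else:
            sf, lin = "-", "-"
        rows.append(
            {
                "id": rec.id,
                "class_code": "" if rec.label is None else rec.label,
                "superfamily": sf,
                "lineage": lin,
                "length": len(rec),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Published dataset composition manifests (bookkeeping fixtures)
# ---------------------------------------------------------------------------

def _load_table(name: str) -> pd.DataFrame:
    with resources.files("ltrstack.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def negative_composition() -> pd.DataFrame:
    """Per-row composition of the negative-instance pool (non-LTR features).

    Columns: category (retrotransposon / dna_transposon / non_te), order,
    superfamily, count. Totals are recovered by summation, never stored.
    """
    return _load_table("negative_composition.tsv")


def unified_composition() -> pd.DataFrame:
    """Per-lineage record counts of the unified-task dataset.

    Columns: class_code, superfamily, lineage, count.
    """
    return _load_table("unified_composition.tsv")


def composition_total(table: pd.DataFrame, **filters: object) -> int:
    """Sum the ``count`` column of rows matching the given column filters."""
    mask = pd.Series(True, index=table.index)
    for col, value in filters.items():
        mask &= table[col] == value
    return int(table.loc[mask, "count"].sum())
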