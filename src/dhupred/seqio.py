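"""Reading, validating and writing labelled fixed-length RNA windows.

The on-disk format is plain FASTA with structured headers::

    >record_id|species|label

where ``label`` is ``1`` for a true dihydrouridine (D) site window and ``0``
for a non-modified U window.  Sequences are fixed-length windows (41 nt by
default) centred on the candidate uridine.  DNA-alphabet input is accepted:
``T`` is silently mapped to ``U`` and case is normalised on read.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "DEFAULT_SPECIES",
    "RNA_ALPHABET",
    "SequenceRecord",
    "Dataset",
    "Violation",
    "FastaParseError",
    "EmptyDatasetError",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "validate_dataset",
    "dataset_summary",
]

#: The five species of the benchmark this package emulates.
DEFAULT_SPECIES = (
    "H.sapiens",
    "M.musculus",
    "D.melanogaster",
    "S.cerevisiae",
    "E.coli",
)

RNA_ALPHABET = frozenset("ACGU")

#: id suffix marking oversampling duplicates, e.g. "rec7#dup1".
PROVENANCE_SEP = "#dup"


class FastaParseError(ValueError):
    """A FASTA record could not be parsed under the header convention."""


class EmptyDatasetError(ValueError):
    """The input file contained no records."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map the DNA alphabet onto RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def base_id(record_id: str) -> str:
    """Strip oversampling provenance, returning the ancestral record id."""
    return record_id.split(PROVENANCE_SEP, 1)[0]


@dataclass(frozen=True)
class SequenceRecord:
    """One labelled RNA window.

    Parameters
    ----------
    id:
        Unique record identifier.
    species:
        Species of origin (free string; strictness is applied at read time).
    label:
        1 for a true D-site window, 0 for a negative (unmodified U) window.
    sequence:
        RNA sequence over {A, C, G, U}; normalised on construction.
    """

    id: str
    species: str
    label: int
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    @property
    def is_positive(self) -> bool:
        return self.label == 1


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of equal-length labelled windows."""

    records: tuple[SequenceRecord, ...]
    length: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in collections.Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate record ids: {dup[:5]}")
        if self.records and self.length == 0:
            object.__setattr__(self, "length", len(self.records[0].sequence))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(r.label for r in self.records)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(r.species for r in self.records)

    @property
    def n_positive(self) -> int:
        return sum(r.label for r in self.records)

    @property
    def n_negative(self) -> int:
        return len(self.records) - self.n_positive

    def subset(self, ids: Iterable[str]) -> "Dataset":
        """Records with the given ids, preserving dataset order."""
        wanted = set(ids)
        return Dataset(tuple(r for r in self.records if r.id in wanted), self.length)

    def by_species(self, species: str) -> "Dataset":
        return Dataset(
            tuple(r for r in self.records if r.species == species), self.length
        )

    def species_present(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return tuple(seen)


def read_fasta(
    path: str | Path,
    delimiter: str = "|",
    species_set: Sequence[str] | None = None,
    allow_empty: bool = False,
) -> Dataset:
    """Read a labelled window dataset from FASTA.

    Headers must follow ``id<delimiter>species<delimiter>label`` with label in
    {0, 1}.  Sequences are normalised (uppercase, T mapped to U).  When
    ``species_set`` is given, any species outside it is a parse error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            parts = header.strip().split(delimiter)
            if len(parts) != 3:
                raise FastaParseError(
                    f"header {header!r}: expected id{delimiter}species{delimiter}label"
                )
            rec_id, species, label_str = (p.strip() for p in parts)
            if label_str not in ("0", "1"):
                raise FastaParseError(
                    f"record {rec_id!r}: label must be 0 or 1, got {label_str!r}"
                )
            if species_set is not None and species not in species_set:
                raise FastaParseError(
                    f"record {rec_id!r}: unknown species {species!r} "
                    f"(expected one of {sorted(species_set)})"
                )
            seq = normalize_sequence("".join(seq.split()))
            bad = set(seq) - RNA_ALPHABET
            if bad:
                raise FastaParseError(
                    f"record {rec_id!r}: invalid characters {sorted(bad)}"
                )
            records.append(SequenceRecord(rec_id, species, int(label_str), seq))
    if not records and not allow_empty:
        raise EmptyDatasetError(f"{path}: no FASTA records found")
    return Dataset(tuple(records))


def write_fasta(
    d: Dataset, path: str | Path, delimiter: str = "|", wrap: int | None = None
) -> Path:
    """Write a dataset in the canonical header convention; round-trips exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as out:
        for r in d:
            out.write(f">{r.id}{delimiter}{r.species}{delimiter}{r.label}\n")
            seq = r.sequence
            if wrap:
                for i in range(0, len(seq), wrap):
                    out.write(seq[i : i + wrap] + "\n")
            else:
                out.write(seq + "\n")
    return path


@dataclass(frozen=True)
class Violation:
    """One rule violation found by :func:`validate_dataset`."""

    record_id: str
    rule: str
    message: str
    level: str = "error"  # "error" | "warning"


def validate_dataset(
    d: Dataset,
    expected_length: int = 41,
    require_centre_u: bool = True,
    centre_u_level: str = "warning",
) -> list[Violation]:
    """Check window length, alphabet, and the centre-base convention.

    The centre base of a D-site window is the candidate uridine; a non-U
    centre is reported at warning level by default, because negative windows
    are not guaranteed U-centred by every upstream source.  Positions in
    messages are 1-based (centre of a 41-nt window is position 21).
    """
    out: list[Violation] = []
    centre = expected_length // 2  # 0-based; 1-based position centre + 1
    for r in d:
        if len(r.sequence) != expected_length:
            out.append(
                Violation(
                    r.id,
                    "length",
                    f"length {len(r.sequence)} != expected {expected_length}",
                )
            )
            continue
        bad = set(r.sequence) - RNA_ALPHABET
        if bad:
            out.append(
                Violation(r.id, "alphabet", f"invalid characters {sorted(bad)}")
            )
            continue
        if require_centre_u and r.sequence[centre] != "U":
            out.append(
                Violation(
                    r.id,
                    "centre_base",
                    f"centre base at position {centre + 1} is "
                    f"{r.sequence[centre]!r}, expected 'U'",
                    level=centre_u_level,
                )
            )
    return out


def dataset_summary(d: Dataset) -> pd.DataFrame:
    """Per-species positive/negative counts, one row per species present.

    The layout mirrors the benchmark's published species distribution table.
    """
    rows = {}
    for sp in d.species_present():
        sub = d.by_species(sp)
        rows[sp] = {"positive": sub.n_positive, "negative": sub.n_negative}
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    if df.empty:
        df = pd.DataFrame(columns=["positive", "negative"], dtype=int)
    df.index.name = "species"
    df["total"] = df.sum(axis=1) if len(df) else 0
    return df
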