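"""Readers and writers for the tabular and sequence inputs of the pipeline.

Three kinds of input are handled:

* mating-trial tables — one row per strain pair with the four counts of a
  two-strain multiple-choice test (``n11``: female A x male A, ``n12``:
  female A x male B, ``n21``: female B x male A, ``n22``: female B x male B);
* cross records — offspring sex counts and dissected-male sperm-motility
  counts for one directed cross (mother strain x father strain);
* aligned DNA sequence sets (FASTA) with a strain/group label per record.

The canonical tabular dialect is comma-separated UTF-8 with a header row.
Tab-separated input is rejected rather than silently split, so that printed
tables are transcribed once, deliberately, into CSV fixtures.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "FormatError",
    "ValidationError",
    "AlignmentError",
    "DataQualityWarning",
    "MatingTrialRow",
    "MatingTrialTable",
    "CrossRecord",
    "CrossTable",
    "AlignmentRecord",
    "AlignmentSet",
    "read_mating_trials",
    "write_mating_trials",
    "read_cross_records",
    "write_cross_records",
    "read_fasta_alignment",
    "read_group_map",
    "read_config",
]


class FormatError(ValueError):
    """The file is not in the expected dialect (e.g. tabs, bad characters)."""


class ValidationError(ValueError):
    """The file parsed but violates a domain invariant."""


class AlignmentError(ValueError):
    """Sequence records do not form a valid alignment."""


class DataQualityWarning(UserWarning):
    """A value in the input is kept but looks internally inconsistent."""


# Unambiguous nucleotides + alignment gap + hard missing.
_CANONICAL = set("ACGTN-")
# IUPAC ambiguity codes; collapsed to N on read (missing is the conservative
# reading when no ambiguity policy is given for distance computation).
_AMBIGUOUS = set("RYSWKMBDHV")
_ALLOWED = _CANONICAL | _AMBIGUOUS | {"U"}


@dataclass(frozen=True)
class MatingTrialRow:
    """Counts of one two-strain multiple-choice mating test.

    The first symbol of each count names the female's strain: ``n12`` is
    females of ``strain_a`` mated by males of ``strain_b``.  ``n_reported``
    carries a published total when the table being transcribed printed one;
    the analysis always recomputes the total from the four counts.
    """

    strain_a: str
    strain_b: str
    n11: int
    n12: int
    n21: int
    n22: int
    n_reported: int | None = None

    def __post_init__(self) -> None:
        for name in ("n11", "n12", "n21", "n22"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(
                    f"{self.strain_a}-{self.strain_b}: {name}={v!r} is not a "
                    "non-negative integer"
                )
        if self.strain_a == self.strain_b:
            raise ValidationError(
                f"strain pair uses the same strain twice: {self.strain_a!r}"
            )

    @property
    def n(self) -> int:
        """Total matings, always recomputed as the sum of the four counts."""
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n11, self.n12, self.n21, self.n22)

    @property
    def n_mismatch(self) -> bool:
        """True when a published total disagrees with the count sum."""
        return self.n_reported is not None and self.n_reported != self.n


@dataclass
class MatingTrialTable:
    rows: list[MatingTrialRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        for row in self.rows:
            key = frozenset((row.strain_a, row.strain_b))
            if key in seen:
                raise ValidationError(
                    f"duplicate strain pair {row.strain_a}-{row.strain_b}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


@dataclass(frozen=True)
class CrossRecord:
    """One directed cross: offspring sex counts and sperm-motility scores.

    A dissected F1 male is scored motile if at least one motile sperm was
    seen, so ``males_motile`` counts males with any motile sperm at all.
    """

    mother: str
    father: str
    replicates: int
    females: int
    males: int
    males_dissected: int
    males_motile: int

    def __post_init__(self) -> None:
        for name in ("replicates", "females", "males", "males_dissected", "males_motile"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(
                    f"{self.mother}x{self.father}: {name}={v!r} is not a "
                    "non-negative integer"
                )
        if self.replicates < 1:
            raise ValidationError(
                f"{self.mother}x{self.father}: replicates must be >= 1"
            )
        if self.males_motile > self.males_dissected:
            raise ValidationError(
                f"{self.mother}x{self.father}: males_motile "
                f"({self.males_motile}) exceeds males_dissected "
                f"({self.males_dissected})"
            )

    @property
    def total_offspring(self) -> int:
        return self.females + self.males


@dataclass
class CrossTable:
    rows: list[CrossRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


@dataclass(frozen=True)
class AlignmentRecord:
    id: str
    group: str
    sequence: str


@dataclass
class AlignmentSet:
    """Equal-length DNA sequences with a group (strain/population) label."""

    records: list[AlignmentRecord]
    length: int

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate record ids in alignment")
        for r in self.records:
            if len(r.sequence) != self.length:
                raise AlignmentError(
                    f"record {r.id!r} has length {len(r.sequence)}, "
                    f"expected {self.length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance."""
        out: list[str] = []
        for r in self.records:
            if r.group not in out:
                out.append(r.group)
        return out


def _reject_tabs(path: Path) -> None:
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
    if "\t" in head:
        raise FormatError(
            f"{path}: tab characters in header; the canonical dialect is "
            "comma-separated"
        )


def _int_cell(value: str, column: str, lineno: int, path: Path) -> int:
    value = value.strip()
    try:
        return int(value)
    except ValueError:
        raise FormatError(
            f"{path}, row {lineno}: column {column!r} has malformed "
            f"integer {value!r}"
        ) from None


def read_mating_trials(path: str | Path) -> MatingTrialTable:
    """Read a mating-trial CSV (strain_a,strain_b,n11,n12,n21,n22[,n_reported]).

    Emits a :class:`DataQualityWarning` for any row whose published total
    ``n_reported`` differs from the sum of the four counts; the row is kept.
    """
    path = Path(path)
    _reject_tabs(path)
    required = ["strain_a", "strain_b", "n11", "n12", "n21", "n22"]
    rows: list[MatingTrialRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        for lineno, rec in enumerate(reader, start=2):
            counts = {c: _int_cell(rec[c], c, lineno, path) for c in required[2:]}
            n_reported = None
            if rec.get("n_reported") not in (None, ""):
                n_reported = _int_cell(rec["n_reported"], "n_reported", lineno, path)
            row = MatingTrialRow(
                strain_a=rec["strain_a"].strip(),
                strain_b=rec["strain_b"].strip(),
                n_reported=n_reported,
                **counts,
            )
            if row.n_mismatch:
                warnings.warn(
                    f"{row.strain_a}-{row.strain_b}: reported total "
                    f"{row.n_reported} differs from count sum {row.n}",
                    DataQualityWarning,
                    stacklevel=2,
                )
            rows.append(row)
    return MatingTrialTable(rows)


def write_mating_trials(table: MatingTrialTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["strain_a", "strain_b", "n11", "n12", "n21", "n22", "n_reported"]
        )
        for r in table:
            writer.writerow(
                [r.strain_a, r.strain_b, r.n11, r.n12, r.n21, r.n22,
                 "" if r.n_reported is None else r.n_reported]
            )


def read_cross_records(path: str | Path) -> CrossTable:
    """Read a cross-record CSV
    (mother,father,replicates,females,males,males_dissected,males_motile)."""
    path = Path(path)
    _reject_tabs(path)
    required = [
        "mother", "father", "replicates", "females", "males",
        "males_dissected", "males_motile",
    ]
    rows: list[CrossRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        for lineno, rec in enumerate(reader, start=2):
            ints = {c: _int_cell(rec[c], c, lineno, path) for c in required[2:]}
            rows.append(
                CrossRecord(mother=rec["mother"].strip(),
                            father=rec["father"].strip(), **ints)
            )
    return CrossTable(rows)


def write_cross_records(table: CrossTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["mother", "father", "replicates", "females", "males",
             "males_dissected", "males_motile"]
        )
        for r in table:
            writer.writerow(
                [r.mother, r.father, r.replicates, r.females, r.males,
                 r.males_dissected, r.males_motile]
            )


def read_fasta_alignment(
    path: str | Path,
    group_map: Mapping[str, str] | None = None,
) -> AlignmentSet:
    """Read an aligned FASTA into an :class:`AlignmentSet`.

    Sequences are uppercased.  ``U`` is read as ``T``; IUPAC ambiguity codes
    other than ``N`` are collapsed to ``N`` with a warning.  Group labels come
    from ``group_map`` when given, otherwise from the token before the first
    underscore in the record id.
    """
    path = Path(path)
    records: list[AlignmentRecord] = []
    length: int | None = None
    remapped: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALLOWED
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains characters outside the "
                f"IUPAC nucleotide alphabet: {sorted(bad)}"
            )
        if set(seq) & _AMBIGUOUS:
            remapped.add(rec.id)
            seq = "".join("N" if c in _AMBIGUOUS else c for c in seq)
        seq = seq.replace("U", "T")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"{path}: record {rec.id!r} has length {len(seq)}, "
                f"expected {length}"
            )
        if group_map is not None:
            group = group_map.get(rec.id, rec.id.split("_")[0])
        else:
            group = rec.id.split("_")[0]
        records.append(AlignmentRecord(id=rec.id, group=group, sequence=seq))
    if remapped:
        warnings.warn(
            f"ambiguity codes collapsed to N in records: {sorted(remapped)}",
            DataQualityWarning,
            stacklevel=2,
        )
    if length is None:
        raise FormatError(f"{path}: no FASTA records found")
    return AlignmentSet(records=records, length=length)


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV (id,group) mapping record ids to group labels."""
    path = Path(path)
    _reject_tabs(path)
    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if not reader.fieldnames or reader.fieldnames[:2] != ["id", "group"]:
            raise FormatError(f"{path}: expected header 'id,group'")
        for rec in reader:
            out[rec["id"].strip()] = rec["group"].strip()
    return out


def read_config(path: str | Path) -> dict[str, str]:
    """Read a plain-text ``key=value`` configuration file.

    Blank lines and lines starting with ``#`` are ignored; values keep
    internal whitespace but are stripped at both ends.
    """
    path = Path(path)
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(
                    f"{path}, line {lineno}: expected key=value, got {line!r}"
                )
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
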