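"""Sequence, alignment and domain-table I/O plus the substitution matrix.

Coordinates are 1-based inclusive throughout, matching the residue numbering
used in protein databases (e.g. a domain spanning "positions 2-79" has
``start=2, end=79`` and length 78).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
_ALPHABET = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}

#: Substitution matrices that can be requested by name.
AVAILABLE_MATRICES = ("BLOSUM62", "BLOSUM45", "BLOSUM80", "BLOSUM90", "PAM250")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


class ValidationError(ValueError):
    """Raised when a record, alignment or coordinate table violates an invariant."""


@dataclass
class SequenceRecord:
    """One protein sequence, possibly gapped.

    Residues are case-normalised to upper case; the alphabet is the 20
    standard amino acids plus ``-`` (gap) and ``X`` (unknown).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has no residues")
        self.residues = self.residues.upper()
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)

    def ungapped(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.residues.replace(GAP, ""), self.description)


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped records.

    Column indices are 1-based in all reports.
    """

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("alignment must contain at least one record")
        width = len(self.records[0])
        ragged = [r.id for r in self.records if len(r) != width]
        if ragged:
            raise ValidationError(
                f"ragged alignment: records {ragged!r} differ in length "
                f"from first record ({width} columns)"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sequence ids in alignment: {dupes!r}")

    @property
    def width(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def column(self, index: int) -> list[str]:
        """Residues of 1-based column ``index``, one per record."""
        if not 1 <= index <= self.width:
            raise IndexError(f"column {index} outside 1..{self.width}")
        return [r.residues[index - 1] for r in self.records]

    def columns(self) -> Iterator[list[str]]:
        for i in range(1, self.width + 1):
            yield self.column(i)


@dataclass(frozen=True)
class DomainCoordinates:
    """A labelled 1-based inclusive span within one protein."""

    protein_id: str
    domain_label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"{self.protein_id}/{self.domain_label}: invalid span "
                f"{self.start}-{self.end} (need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 integer substitution matrix.

    Scores are defined only for the 20 standard amino acids; callers decide
    how to treat gaps and 'X'.
    """

    name: str
    scores: dict = field(repr=False)

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(
                f"no {self.name} score for pair ({a!r}, {b!r}); scores are "
                "defined for standard amino acids only"
            ) from None

    def positive_partners(self, residue: str) -> list[str]:
        """Residues other than ``residue`` scoring > 0 against it."""
        return [b for b in AMINO_ACIDS if b != residue and self.scores[(residue, b)] > 0]


def load_substitution_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a named substitution matrix restricted to the 20 standard residues.

    The tables ship with Biopython, so no network access is ever needed.
    """
    key = name.upper()
    if key not in AVAILABLE_MATRICES:
        raise ValueError(
            f"unknown substitution matrix {name!r}; available: {list(AVAILABLE_MATRICES)}"
        )
    table = substitution_matrices.load(key)
    scores: dict[tuple[str, str], float] = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            scores[(a, b)] = float(table[a, b])
    for a in AMINO_ACIDS:
        if scores[(a, a)] <= 0:
            raise ValueError(f"{key} diagonal entry for {a} is not positive")
    return SubstitutionMatrix(name=key, scores=scores)


def _check_fasta_shape(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header '>' "
                        f"before sequence data"
                    )
                return
    raise FastaParseError(f"{path}: line 1: empty FASTA file")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gapped) FASTA file, preserving record order.

    Raises ``FastaParseError`` for an empty file or sequence data before the
    first header, and ``ValidationError`` for duplicate ids.
    """
    path = Path(path)
    _check_fasta_shape(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    if not records:
        raise FastaParseError(f"{path}: no records parsed")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file; all sequences must have equal length."""
    return Msa(read_fasta(path))


def write_msa(msa: Msa, path: str | Path) -> None:
    write_fasta(msa.records, path)


_DOMAIN_COLUMNS = ["protein_id", "domain_label", "start", "end"]


def read_domain_table(path: str | Path) -> list[DomainCoordinates]:
    """Read a 4-column TSV of domain coordinates (1-based inclusive).

    Validates spans row by row and rejects overlapping or duplicate-label
    domains within one protein.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing!r}")
    coords: list[DomainCoordinates] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            coords.append(
                DomainCoordinates(
                    protein_id=str(row.protein_id),
                    domain_label=str(row.domain_label),
                    start=int(row.start),
                    end=int(row.end),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {row_number}: {exc}") from exc
    validate_domain_coordinates(coords)
    return coords


def validate_domain_coordinates(coords: Iterable[DomainCoordinates]) -> None:
    """Check per-protein label uniqueness and non-overlap of spans."""
    by_protein: dict[str, list[DomainCoordinates]] = {}
    for c in coords:
        by_protein.setdefault(c.protein_id, []).append(c)
    for pid, spans in by_protein.items():
        labels = [c.domain_label for c in spans]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"protein {pid!r}: duplicate domain labels {dupes!r}")
        ordered = sorted(spans, key=lambda c: c.start)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.start <= prev.end:
                raise ValidationError(
                    f"protein {pid!r}: domains {prev.domain_label!r} "
                    f"({prev.start}-{prev.end}) and {nxt.domain_label!r} "
                    f"({nxt.start}-{nxt.end}) overlap"
                )


def write_domain_table(coords: Iterable[DomainCoordinates], path: str | Path) -> None:
    df = pd.DataFrame(
        [(c.protein_id, c.domain_label, c.start, c.end) for c in coords],
        columns=_DOMAIN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
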