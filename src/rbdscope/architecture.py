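"""Domain/linker segmentation of multi-domain proteins and linker statistics.

A protein with ordered domains D1..Dk decomposes into an N-terminal segment,
the domains, the inter-domain linkers and a C-terminal extension. Linkers
are numbered after the preceding domain (the region between RBD3 and RBD4
is linker 3, "L3"), so a protein that lacks a domain simply has the flanking
region merged into one linker named after the last preceding domain — e.g.
a five-domain protein without RBD2 has an L1 running from RBD1 to RBD3.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .io import DomainCoordinates, SequenceRecord, ValidationError, validate_domain_coordinates

logger = logging.getLogger(__name__)

#: Conserved decreasing-length order of the linkers in Rbm19/Mrd1 families.
DEFAULT_LINKER_ORDER = ("L1", "L3", "L4", "L2", "L5")


@dataclass(frozen=True)
class Linker:
    label: str
    start: int  # 1-based inclusive; start > end encodes a zero-length linker
    end: int

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)


@dataclass
class Architecture:
    """Ordered segmentation of one protein into termini, domains and linkers."""

    protein_id: str
    protein_length: int
    domains: list[DomainCoordinates]
    linkers: list[Linker]
    n_term_length: int
    c_term_length: int

    def linker_length(self, label: str) -> int | None:
        for l in self.linkers:
            if l.label == label:
                return l.length
        return None

    def check_tiling(self) -> None:
        """Assert that segments tile the protein exactly."""
        total = (
            self.n_term_length
            + sum(d.length for d in self.domains)
            + sum(l.length for l in self.linkers)
            + self.c_term_length
        )
        if total != self.protein_length:
            raise ValidationError(
                f"{self.protein_id}: segments sum to {total}, "
                f"protein length is {self.protein_length}"
            )


def _linker_label(domain_label: str) -> str:
    m = re.search(r"(\d+)$", domain_label)
    return f"L{m.group(1)}" if m else f"L({domain_label})"


def extract_segments(
    protein: SequenceRecord, coords: list[DomainCoordinates]
) -> Architecture:
    """Segment a protein into N-terminus, domains, linkers and C-terminus.

    Coordinates are validated against the (ungapped) protein length; the
    linker after domain i spans end(i)+1 .. start(i+1)-1 and is labelled
    after domain i.
    """
    mine = [c for c in coords if c.protein_id == protein.id]
    if not mine:
        raise ValidationError(f"no domain coordinates for protein {protein.id!r}")
    validate_domain_coordinates(mine)
    length = protein.ungapped_length
    ordered = sorted(mine, key=lambda c: c.start)
    for c in ordered:
        if c.end > length:
            raise ValidationError(
                f"{protein.id}/{c.domain_label}: end {c.end} beyond protein "
                f"length {length}"
            )
    linkers = [
        Linker(label=_linker_label(prev.domain_label), start=prev.end + 1, end=nxt.start - 1)
        for prev, nxt in zip(ordered, ordered[1:])
    ]
    arch = Architecture(
        protein_id=protein.id,
        protein_length=length,
        domains=ordered,
        linkers=linkers,
        n_term_length=ordered[0].start - 1,
        c_term_length=length - ordered[-1].end,
    )
    arch.check_tiling()
    return arch


@dataclass(frozen=True)
class LinkerLabelStats:
    label: str
    n: int
    median: int
    min: int
    max: int


@dataclass
class LinkerStats:
    """Per-label linker length statistics over a set of architectures."""

    per_label: dict[str, LinkerLabelStats]

    def median(self, label: str) -> int:
        return self.per_label[label].median

    @property
    def labels(self) -> list[str]:
        return list(self.per_label)


def _lower_median(values: list[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def linker_stats(architectures: list[Architecture]) -> LinkerStats:
    """Median (lower median for even counts), min and max length per linker.

    Proteins lacking a given linker label are excluded from that label's
    statistics; the exclusion count is logged. The lower median keeps all
    reported medians integral.
    """
    if not architectures:
        raise ValidationError("no architectures supplied")
    lengths: dict[str, list[int]] = {}
    for arch in architectures:
        for linker in arch.linkers:
            lengths.setdefault(linker.label, []).append(linker.length)
    per_label = {}
    n_total = len(architectures)
    for label, values in lengths.items():
        if len(values) < n_total:
            logger.info(
                "linker %s absent from %d of %d proteins; excluded from its stats",
                label, n_total - len(values), n_total,
            )
        per_label[label] = LinkerLabelStats(
            label=label,
            n=len(values),
            median=_lower_median(values),
            min=min(values),
            max=max(values),
        )
    return LinkerStats(per_label=per_label)


def length_order_check(
    stats: LinkerStats, order: tuple[str, ...] = DEFAULT_LINKER_ORDER
) -> tuple[bool, list[tuple[str, str]]]:
    """Do linker medians strictly decrease along the given label order?

    Returns the verdict plus every adjacent pair violating strict decrease.
    The default order is the conserved one: L1 > L3 > L4 > L2 > L5.
    """
    missing = [l for l in order if l not in stats.per_label]
    if missing:
        raise ValidationError(f"labels missing from stats: {missing!r}")
    violations = [
        (a, b)
        for a, b in zip(order, order[1:])
        if not stats.median(a) > stats.median(b)
    ]
    return not violations, violations
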