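"""Consensus-motif calling with a BLOSUM-based conservation rule.

A column of a (non-redundant) domain alignment is *conserved* when at least
85% of the sequences carry a residue scoring above zero against the column's
most common residue in the substitution matrix (BLOSUM62 by default). A
residue is listed in the consensus at a position when at least 10% of the
sequences carry exactly that residue; listed residues are ordered by
descending frequency. A sliding window (default five columns) over the
conserved/not-conserved indicator gives the windowed conservation profile.

Conventions the rule itself does not fix (and which are therefore explicit
choices here): gapped sequences and 'X' count in the denominator and are
never conserved, which can only deflate conservation, never inflate it;
modal-residue ties break alphabetically; edge windows are truncated.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .io import AMINO_ACIDS, GAP, Msa, SubstitutionMatrix, load_substitution_matrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _at_least(x: float, threshold: float) -> bool:
    return x >= threshold - _EPS


@dataclass
class ConsensusConfig:
    """Thresholds of the conservation rule.

    conserve_threshold: minimum fraction of sequences with a positive-scoring
        residue for a column to be called conserved (default 0.85).
    residue_threshold: minimum residue frequency for inclusion in the listed
        consensus residues (default 0.10, inclusive).
    matrix: substitution matrix supplying the similarity rule (BLOSUM62).
    window: odd width of the sliding conservation window (default 5).
    """

    conserve_threshold: float = 0.85
    residue_threshold: float = 0.10
    matrix: SubstitutionMatrix = field(default_factory=load_substitution_matrix)
    window: int = 5

    def __post_init__(self) -> None:
        for name in ("conserve_threshold", "residue_threshold"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")


@dataclass
class ColumnSummary:
    """Per-column conservation call and frequency-ordered residue list."""

    column_index: int  # 1-based
    modal_residue: str | None
    conserved_fraction: float
    is_conserved: bool
    listed_residues: list[tuple[str, float]]


@dataclass
class ConsensusMotif:
    """Consensus over one domain alignment: one ColumnSummary per column."""

    columns: list[ColumnSummary]
    n_sequences: int

    @property
    def width(self) -> int:
        return len(self.columns)

    @property
    def conserved_count(self) -> int:
        return sum(1 for c in self.columns if c.is_conserved)

    @property
    def conserved_indices(self) -> list[int]:
        return [c.column_index for c in self.columns if c.is_conserved]


def column_summary(column: list[str], cfg: ConsensusConfig) -> ColumnSummary:
    """Evaluate the conservation rule on one alignment column.

    The modal residue is the most frequent standard amino acid (alphabetical
    tie-break). A sequence counts as conserved iff its residue is a standard
    amino acid scoring > 0 against the modal residue; the denominator is all
    sequences, gapped or not. A column without any standard residue gets no
    modal residue and is never conserved.
    """
    if not column:
        raise ValueError("column must be non-empty")
    n = len(column)
    counts = Counter(column)
    aa_counts = {r: counts[r] for r in AMINO_ACIDS if counts.get(r)}
    if not aa_counts:
        return ColumnSummary(0, None, 0.0, False, [])
    top = max(aa_counts.values())
    modal = min(r for r, c in aa_counts.items() if c == top)
    conserved = sum(
        c for r, c in aa_counts.items() if cfg.matrix.score(r, modal) > 0
    )
    fraction = conserved / n
    listed = sorted(
        ((r, c / n) for r, c in aa_counts.items() if _at_least(c / n, cfg.residue_threshold)),
        key=lambda item: (-item[1], item[0]),
    )
    if not any(r == modal for r, _ in listed):
        # legal under the literal rule; surfaced via motif_table's modal_listed
        logger.debug(
            "modal residue %s below the %.0f%% listing threshold; excluded "
            "from listed residues",
            modal, 100 * cfg.residue_threshold,
        )
    return ColumnSummary(
        column_index=0,
        modal_residue=modal,
        conserved_fraction=fraction,
        is_conserved=_at_least(fraction, cfg.conserve_threshold),
        listed_residues=listed,
    )


def build_consensus(msa: Msa, cfg: ConsensusConfig | None = None) -> ConsensusMotif:
    """Call the conservation rule on every column of an alignment.

    The alignment is expected to be fragment-cleaned and non-redundant
    already (see the redundancy module); this function does not re-filter.
    """
    cfg = cfg or ConsensusConfig()
    columns = []
    for i, col in enumerate(msa.columns(), start=1):
        summary = column_summary(col, cfg)
        summary.column_index = i
        columns.append(summary)
    return ConsensusMotif(columns=columns, n_sequences=len(msa))


def conservation_profile(
    motif: ConsensusMotif, cfg: ConsensusConfig | None = None
) -> list[tuple[int, float]]:
    """Windowed mean of the conserved indicator, assigned to window centres.

    Windows are truncated at the alignment edges, so the first and last
    ``window // 2`` values average over fewer columns.
    """
    cfg = cfg or ConsensusConfig()
    half = cfg.window // 2
    flags = [1.0 if c.is_conserved else 0.0 for c in motif.columns]
    profile = []
    for i in range(len(flags)):
        lo = max(0, i - half)
        hi = min(len(flags), i + half + 1)
        profile.append((i + 1, sum(flags[lo:hi]) / (hi - lo)))
    return profile


def consensus_agreement(
    motif: ConsensusMotif,
    others: Msa | list,
    min_count: int,
    cfg: ConsensusConfig | None = None,
) -> float:
    """Fraction of conserved motif columns echoed by other aligned sequences.

    A conserved column agrees when at least ``min_count`` of the other
    sequences carry a residue scoring > 0 against the column's modal residue.
    This quantifies how much of a consensus survives in a small outgroup
    (e.g. distant homologues aligned to the same coordinates).
    """
    cfg = cfg or ConsensusConfig()
    records = others.records if isinstance(others, Msa) else list(others)
    if min_count > len(records):
        raise ValueError(
            f"min_count {min_count} exceeds number of other sequences {len(records)}"
        )
    conserved = [c for c in motif.columns if c.is_conserved]
    if not conserved:
        raise ValueError("motif has no conserved columns; agreement undefined")
    for rec in records:
        if len(rec.residues) != motif.width:
            raise ValueError(
                f"sequence {rec.id!r} not aligned to motif coordinates "
                f"({len(rec.residues)} vs {motif.width} columns)"
            )
    hits = 0
    for col in conserved:
        count = 0
        for rec in records:
            r = rec.residues[col.column_index - 1]
            if r in AMINO_ACIDS and cfg.matrix.score(r, col.modal_residue) > 0:
                count += 1
        if count >= min_count:
            hits += 1
    return hits / len(conserved)


def render_motif(motif: ConsensusMotif, non_conserved_mark: str = ".") -> str:
    """Plain-text stacked rendering of a consensus motif.

    Conserved columns show their listed residues stacked by descending
    frequency (most frequent on top); other columns show a placeholder.
    """
    depth = max((len(c.listed_residues) for c in motif.columns if c.is_conserved), default=1)
    lines = []
    for rank in range(depth):
        chars = []
        for col in motif.columns:
            if col.is_conserved and rank < len(col.listed_residues):
                chars.append(col.listed_residues[rank][0])
            elif col.is_conserved:
                chars.append(" ")
            else:
                chars.append(non_conserved_mark if rank == 0 else " ")
        lines.append("".join(chars))
    return "\n".join(lines)


def motif_table(motif: ConsensusMotif) -> "pd.DataFrame":
    """Tabular form of a motif: one row per column, TSV-friendly."""
    import pandas as pd

    rows = []
    for c in motif.columns:
        rows.append(
            {
                "column_index": c.column_index,
                "is_conserved": c.is_conserved,
                "modal": c.modal_residue or "",
                "conserved_fraction": round(c.conserved_fraction, 6),
                "listed": ",".join(f"{r}:{f:.2f}" for r, f in c.listed_residues),
                "modal_listed": c.modal_residue is not None
                and any(r == c.modal_residue for r, _ in c.listed_residues),
            }
        )
    return pd.DataFrame(rows)
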