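"""Fragment cleaning and non-redundancy filtering of domain alignments.

Before consensus motifs are computed, each domain alignment is cleaned of
fragments (records covering too little of the alignment) and reduced to a
set of representatives so that no retained pair of member/representative
exceeds the identity threshold (80% by default). The clustering is greedy
incremental in the style of CD-HIT: records are visited in order of
decreasing non-gap length (ties broken by id) and either join the first
sufficiently similar representative or found a new cluster. This makes the
output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GAP, Msa, SequenceRecord, ValidationError


@dataclass(frozen=True)
class RedundancyConfig:
    """Thresholds for fragment removal and redundancy reduction.

    identity_threshold: records at or above this pairwise identity to an
        existing representative are collapsed into its cluster (default 0.80).
    fragment_min_coverage: minimum fraction of alignment columns a record must
        occupy with non-gap residues to be kept (default 0.50).
    """

    identity_threshold: float = 0.80
    fragment_min_coverage: float = 0.50

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "fragment_min_coverage"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity between two rows of the same alignment.

    The denominator counts only columns where both sequences carry a
    residue (mutually non-gap); identical residues in those columns form
    the numerator. Returns 0.0 when no column is mutually non-gap.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    both = 0
    same = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                same += 1
    return same / both if both else 0.0


def remove_fragments(msa: Msa, cfg: RedundancyConfig = RedundancyConfig()) -> Msa:
    """Drop records whose non-gap coverage of the alignment is below threshold.

    Coverage is ungapped length / alignment width; the threshold is
    inclusive (a record at exactly the minimum coverage is retained).
    Record order is preserved.
    """
    kept = [
        r for r in msa.records
        if r.ungapped_length / msa.width >= cfg.fragment_min_coverage
    ]
    if not kept:
        raise ValidationError(
            "fragment removal discarded every record; lower "
            f"fragment_min_coverage (currently {cfg.fragment_min_coverage})"
        )
    return Msa(kept)


def nonredundant_filter(
    msa: Msa, cfg: RedundancyConfig = RedundancyConfig()
) -> tuple[Msa, dict[str, str]]:
    """Greedy incremental clustering at the configured identity threshold.

    Records are processed sorted by descending non-gap length (ties by id).
    Each record joins the first existing representative with pairwise
    identity >= threshold, else becomes a representative itself. Returns
    the representatives (in processing order) and a member -> representative
    map covering every input record (representatives map to themselves).
    """
    order = sorted(msa.records, key=lambda r: (-r.ungapped_length, r.id))
    representatives: list[SequenceRecord] = []
    cluster_map: dict[str, str] = {}
    for rec in order:
        for rep in representatives:
            if pairwise_identity(rec.residues, rep.residues) >= cfg.identity_threshold:
                cluster_map[rec.id] = rep.id
                break
        else:
            representatives.append(rec)
            cluster_map[rec.id] = rec.id
    return Msa(representatives), cluster_map
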