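"""Profile search: PSSM construction, local scanning, calibration, jack-knife.

This module plays the role that profile HMMs play in large-scale homologue
surveys, at desk scale and fully in-repo: a per-column log-odds matrix
(PSSM) is built from a non-redundant seed alignment, sequences are scored
by affine-gap local dynamic programming against the profile, a score cutoff
is calibrated on a descending grid against decoys ("as many true hits as
possible without admitting any false hit"), per-member stability is checked
by leave-one-out retraining, and a database is searched iteratively, adding
accepted sequences to the profile until convergence.

Scores are log-odds sums in bits. They are not comparable to HMMER bit
scores; cutoffs must always be calibrated with ``calibrate_cutoff`` rather
than copied from an HMM-based analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import AMINO_ACIDS, GAP, Msa, SequenceRecord, ValidationError

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_NEG_INF = float("-inf")


@dataclass
class Pssm:
    """Position-specific scoring matrix with affine gap penalties.

    ``logodds[c, r]`` is the log2-odds (bits) of residue ``r`` at column
    ``c`` relative to the background. Gap penalties are positive costs:
    opening a gap subtracts ``gap_open``, each further gapped position
    subtracts ``gap_extend``.
    """

    logodds: np.ndarray  # (width, 20)
    background: np.ndarray  # (20,)
    pseudocount: float = 1.0
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.logodds.ndim != 2 or self.logodds.shape[1] != 20:
            raise ValueError("logodds must have shape (width, 20)")
        if self.background.shape != (20,) or np.any(self.background <= 0):
            raise ValueError("background must be 20 strictly positive frequencies")
        if not np.all(np.isfinite(self.logodds)):
            raise ValueError("logodds must be finite")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    @property
    def width(self) -> int:
        return self.logodds.shape[0]

    def max_score(self) -> float:
        """Score of the best possible gap-free match (column-wise maxima)."""
        return float(self.logodds.max(axis=1).sum())


@dataclass(frozen=True)
class CalibrationConfig:
    """Descending score grid on which cutoffs are evaluated.

    The grid runs grid_start, grid_start - grid_step, ... down to
    grid_floor (inclusive where it lands on the grid).
    """

    grid_start: float = 90.0
    grid_step: float = 5.0
    grid_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.grid_start <= self.grid_floor:
            raise ValueError("grid_start must exceed grid_floor")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")

    def values(self) -> list[float]:
        grid = []
        v = self.grid_start
        while v >= self.grid_floor - 1e-9:
            grid.append(round(v, 9))
            v -= self.grid_step
        return grid


@dataclass(frozen=True)
class HitResult:
    """Best local match of one sequence against a profile.

    ``start``/``end`` are 1-based inclusive positions in the ungapped
    sequence.
    """

    sequence_id: str
    score: float
    start: int
    end: int


class CalibrationError(ValueError):
    """No grid cutoff excludes every decoy; carries the per-grid report."""

    def __init__(self, message: str, report: list[dict]):
        super().__init__(message)
        self.report = report


def uniform_background() -> np.ndarray:
    return np.full(20, 0.05)


def estimate_background(records: list[SequenceRecord]) -> np.ndarray:
    """Residue composition of the given sequences, floored away from zero."""
    counts = np.zeros(20)
    for rec in records:
        for ch in rec.residues:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    counts += 1.0  # keep every frequency strictly positive
    return counts / counts.sum()


def build_pssm(
    msa: Msa,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Pssm:
    """Log-odds profile from a (non-redundant) alignment.

    Column ``c`` scores residue ``r`` as
    ``log2((count(c, r) + pseudocount * bg[r]) / (n_c + pseudocount)) - log2(bg[r])``
    where counts run over standard residues only and ``n_c`` is the number
    of standard residues in the column. A column with no standard residue
    scores zero for every residue (neutral column).
    """
    bg = uniform_background() if background is None else np.asarray(background, float)
    if bg.shape != (20,) or np.any(bg <= 0):
        raise ValueError("background must be 20 strictly positive frequencies")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    width = msa.width
    logodds = np.zeros((width, 20))
    for c, column in enumerate(msa.columns()):
        counts = np.zeros(20)
        for ch in column:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        n_c = counts.sum()
        if n_c == 0:
            continue  # neutral all-gap column
        logodds[c] = np.log2((counts + pseudocount * bg) / (n_c + pseudocount)) - np.log2(bg)
    return Pssm(
        logodds=logodds,
        background=bg,
        pseudocount=pseudocount,
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


def _score_rows(pssm: Pssm, seq: str) -> np.ndarray:
    """(width, len) match scores; 'X' is neutral (0) at every column."""
    n = len(seq)
    s = np.zeros((pssm.width, n))
    for j, ch in enumerate(seq):
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            s[:, j] = pssm.logodds[:, idx]
    return s


def scan_sequence(
    seq: SequenceRecord, pssm: Pssm, with_path: bool = False
) -> HitResult | tuple[HitResult, list[tuple[int, int | None]]]:
    """Best local alignment of a sequence against the profile (Gotoh DP).

    Gaps in the input sequence are removed before scanning; the reported
    span refers to the ungapped sequence. Ties are broken deterministically:
    smallest start position, then smallest end position. With
    ``with_path=True`` also returns the alignment path as a list of
    ``(profile_column, sequence_position | None)`` pairs (1-based;
    ``None`` marks a profile column aligned to a gap). Sequence residues
    inserted relative to the profile do not appear in the path.
    """
    if pssm.width == 0:
        raise ValueError("cannot scan against an empty profile (width 0)")
    residues = seq.residues.replace(GAP, "")
    if not residues:
        raise ValidationError(f"sequence {seq.id!r} has no residues after degapping")
    m, n = pssm.width, len(residues)
    s = _score_rows(pssm, residues)
    go, ge = pssm.gap_open, pssm.gap_extend

    # DP matrices over (m + 1) x (n + 1); row/col 0 are boundaries.
    M = [[_NEG_INF] * (n + 1) for _ in range(m + 1)]
    X = [[_NEG_INF] * (n + 1) for _ in range(m + 1)]
    Y = [[_NEG_INF] * (n + 1) for _ in range(m + 1)]
    SM = [[0] * (n + 1) for _ in range(m + 1)]  # start column of the local path
    SX = [[0] * (n + 1) for _ in range(m + 1)]
    SY = [[0] * (n + 1) for _ in range(m + 1)]
    PM = [[0] * (n + 1) for _ in range(m + 1)] if with_path else None
    PX = [[0] * (n + 1) for _ in range(m + 1)] if with_path else None
    PY = [[0] * (n + 1) for _ in range(m + 1)] if with_path else None

    best_score = _NEG_INF
    best_start = best_end = best_i = 0

    for i in range(1, m + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mu, Xu, Yu = M[i - 1], X[i - 1], Y[i - 1]
        SMi, SXi, SYi = SM[i], SX[i], SY[i]
        SMu, SXu, SYu = SM[i - 1], SX[i - 1], SY[i - 1]
        si = s[i - 1]
        for j in range(1, n + 1):
            # match state: open a new local path (0) or extend a diagonal
            cand = 0.0
            start = j
            ptr = 0
            d = Mu[j - 1]
            if d > cand or (d == cand and SMu[j - 1] < start):
                cand, start, ptr = d, SMu[j - 1], 1
            d = Xu[j - 1]
            if d > cand or (d == cand and SXu[j - 1] < start):
                cand, start, ptr = d, SXu[j - 1], 2
            d = Yu[j - 1]
            if d > cand or (d == cand and SYu[j - 1] < start):
                cand, start, ptr = d, SYu[j - 1], 3
            Mi[j] = si[j - 1] + cand
            SMi[j] = start
            if PM is not None:
                PM[i][j] = ptr

            # gap in the sequence (profile column i unmatched)
            a = Mu[j] - go
            b = Xu[j] - ge
            if a > b or (a == b and SMu[j] <= SXu[j]):
                Xi[j] = a
                SXi[j] = SMu[j]
                if PX is not None:
                    PX[i][j] = 1
            else:
                Xi[j] = b
                SXi[j] = SXu[j]
                if PX is not None:
                    PX[i][j] = 2

            # gap in the profile (sequence residue j unmatched)
            a = Mi[j - 1] - go
            b = Yi[j - 1] - ge
            if a > b or (a == b and SMi[j - 1] <= SYi[j - 1]):
                Yi[j] = a
                SYi[j] = SMi[j - 1]
                if PY is not None:
                    PY[i][j] = 1
            else:
                Yi[j] = b
                SYi[j] = SYi[j - 1]
                if PY is not None:
                    PY[i][j] = 3

            v = Mi[j]
            if v > best_score or (
                v == best_score and (SMi[j], j) < (best_start, best_end)
            ):
                best_score, best_start, best_end, best_i = v, SMi[j], j, i

    hit = HitResult(sequence_id=seq.id, score=best_score, start=best_start, end=best_end)
    if not with_path:
        return hit

    # traceback from the best match cell
    path: list[tuple[int, int | None]] = []
    state, i, j = "M", best_i, best_end
    while i > 0 and j >= 0:
        if state == "M":
            path.append((i, j))
            ptr = PM[i][j]
            i, j = i - 1, j - 1
            if ptr == 0:
                break
            state = {1: "M", 2: "X", 3: "Y"}[ptr]
        elif state == "X":
            path.append((i, None))
            ptr = PX[i][j]
            i -= 1
            state = "M" if ptr == 1 else "X"
        else:  # Y: sequence residue skipped, not part of the profile mapping
            ptr = PY[i][j]
            j -= 1
            state = "M" if ptr == 1 else "Y"
    path.reverse()
    return hit, path


def align_to_profile(seq: SequenceRecord, pssm: Pssm) -> SequenceRecord:
    """Project a sequence onto profile coordinates via its best local path.

    Profile columns outside the local match, or deleted within it, become
    gaps; sequence residues inserted relative to the profile are dropped
    (the seed alignment is never re-expanded).
    """
    _, path = scan_sequence(seq, pssm, with_path=True)
    residues = seq.residues.replace(GAP, "")
    row = [GAP] * pssm.width
    for col, pos in path:
        if pos is not None:
            row[col - 1] = residues[pos - 1]
    return SequenceRecord(id=seq.id, residues="".join(row), description=seq.description)


def calibrate_cutoff(
    pssm: Pssm,
    positives: list[SequenceRecord],
    decoys: list[SequenceRecord],
    cfg: CalibrationConfig = CalibrationConfig(),
) -> tuple[float, list[dict]]:
    """Pick the lowest grid cutoff that admits zero decoys.

    Cutoffs are evaluated on the descending grid; admitting a sequence
    means its scan score is >= the cutoff. Because lowering the cutoff can
    only admit more sequences, the lowest zero-decoy grid value admits the
    most true hits without any false hit. Returns that cutoff plus a per-grid
    report (cutoff, positives admitted, decoys admitted). Raises
    ``CalibrationError`` when every grid value admits a decoy.
    """
    if not positives or not decoys:
        raise ValueError("need at least one positive and one decoy")
    pos_scores = [scan_sequence(p, pssm).score for p in positives]
    dec_scores = [scan_sequence(d, pssm).score for d in decoys]
    report = []
    for cutoff in cfg.values():
        report.append(
            {
                "cutoff": cutoff,
                "positives_admitted": sum(s >= cutoff for s in pos_scores),
                "decoys_admitted": sum(s >= cutoff for s in dec_scores),
            }
        )
    clean = [row for row in report if row["decoys_admitted"] == 0]
    if not clean:
        best = min(report, key=lambda r: (r["decoys_admitted"], -r["positives_admitted"]))
        raise CalibrationError(
            "no grid cutoff excludes all decoys; best achievable: "
            f"cutoff {best['cutoff']} admits {best['positives_admitted']} "
            f"positives and {best['decoys_admitted']} decoys",
            report,
        )
    chosen = min(clean, key=lambda r: r["cutoff"])
    return chosen["cutoff"], report


@dataclass(frozen=True)
class JackknifeRecord:
    sequence_id: str
    score: float
    max_decoy_score: float
    stable: bool  # strict: left-out score must exceed every decoy score


def jackknife_stability(
    msa: Msa,
    decoys: list[SequenceRecord],
    cutoff: float | None = None,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> list[JackknifeRecord]:
    """Leave-one-out stability of the profile's membership.

    For each member, the profile is rebuilt without it and the member plus
    all decoys are rescanned. A member is stable iff its score strictly
    exceeds every decoy score (ties count as unstable). A stable family
    retains every member under this criterion.
    """
    if len(msa) < 3:
        raise ValidationError("jack-knifing needs at least 3 sequences")
    results = []
    for left_out in msa.records:
        rest = Msa([r for r in msa.records if r.id != left_out.id])
        pssm = build_pssm(rest, pseudocount=pseudocount, background=background)
        score = scan_sequence(left_out, pssm).score
        max_decoy = max(scan_sequence(d, pssm).score for d in decoys)
        results.append(
            JackknifeRecord(
                sequence_id=left_out.id,
                score=score,
                max_decoy_score=max_decoy,
                stable=score > max_decoy,
            )
        )
        if cutoff is not None and score < cutoff:
            logger.info(
                "jack-knife: %s scores %.2f, below cutoff %.2f", left_out.id, score, cutoff
            )
    return results


@dataclass
class SearchRound:
    round_number: int
    n_scanned: int
    accepted_ids: list[str]


@dataclass
class SearchResult:
    accepted: list[str]  # database ids accepted, in order of acceptance
    final_msa: Msa
    rounds: list[SearchRound]
    converged: bool


def iterative_search(
    seed_msa: Msa,
    database: list[SequenceRecord],
    cutoff: float,
    max_rounds: int = 10,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> SearchResult:
    """Iterative profile search with set expansion until convergence.

    Each round builds a profile from the current alignment, scans every
    not-yet-accepted database sequence, accepts those scoring >= cutoff
    (appended to the alignment via their best local alignment to the
    profile), and repeats until a round accepts nothing or ``max_rounds``
    is reached. The accepted set grows monotonically.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    current = Msa(list(seed_msa.records))
    accepted: list[str] = []
    accepted_set: set[str] = set(current.ids)
    rounds: list[SearchRound] = []
    converged = False
    for round_number in range(1, max_rounds + 1):
        pssm = build_pssm(current, pseudocount=pseudocount, background=background)
        pending = [d for d in database if d.id not in accepted_set]
        newly = [d for d in pending if scan_sequence(d, pssm).score >= cutoff]
        rounds.append(
            SearchRound(
                round_number=round_number,
                n_scanned=len(pending),
                accepted_ids=[d.id for d in newly],
            )
        )
        if not newly:
            converged = True
            break
        rows = [align_to_profile(d, pssm) for d in newly]
        current = Msa(current.records + rows)
        accepted.extend(d.id for d in newly)
        accepted_set.update(d.id for d in newly)
    if not converged:
        warnings.warn(
            f"iterative search did not converge within {max_rounds} rounds; "
            "returning partial result",
            stacklevel=2,
        )
    return SearchResult(accepted=accepted, final_msa=current, rounds=rounds, converged=converged)
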