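"""End-to-end orchestration: simulate/load -> NR -> consensus -> profile ->
architecture -> clustering, with a consolidated JSON summary.

The summary mirrors the headline tables of a multi-domain conservation
analysis: conserved/total per domain, calibrated score cutoffs, linker
medians and the decreasing-length order check, and the position-specific
clustering purity. The summary is deterministic for a fixed config and
seed; timings go to the log, never into the summary.
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .architecture import DEFAULT_LINKER_ORDER, extract_segments, length_order_check, linker_stats
from .clustering import DistanceMatrix, domain_distance_matrix, nj_tree, position_cluster_purity
from .consensus import ConsensusConfig, build_consensus, conservation_profile, motif_table
from .io import (
    GAP,
    Msa,
    SequenceRecord,
    ValidationError,
    read_domain_table,
    read_fasta,
    read_msa,
    write_msa,
)
from .profile_search import CalibrationConfig, build_pssm, calibrate_cutoff
from .redundancy import RedundancyConfig, nonredundant_filter, remove_fragments
from .simulate import default_family_spec, generate_decoys, generate_family

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All thresholds and inputs of one pipeline run.

    Either ``simulate`` is true (a synthetic family is generated under the
    run's seed) or ``fasta``/``domains_tsv``/``domain_msas`` point at real
    inputs: full-length sequences, a coordinate table and one precomputed
    alignment per domain.
    """

    outdir: str | Path = "rbdscope_out"
    seed: int = 17
    simulate: bool = True
    n_sequences: int = 60
    match_prob: float = 0.95
    fasta: str | None = None
    domains_tsv: str | None = None
    domain_msas: dict[str, str] = field(default_factory=dict)
    identity_threshold: float = 0.80
    fragment_min_coverage: float = 0.50
    conserve_threshold: float = 0.85
    residue_threshold: float = 0.10
    window: int = 5
    grid_start: float = 90.0
    grid_step: float = 5.0
    grid_floor: float = 0.0
    n_decoys: int = 25
    purity_per_class: int = 12
    linker_order: tuple[str, ...] = DEFAULT_LINKER_ORDER

    def validate(self) -> None:
        if not self.simulate:
            for name in ("fasta", "domains_tsv"):
                path = getattr(self, name)
                if not path or not Path(path).exists():
                    raise ValidationError(f"config {name!r} missing or not found: {path}")
            for label, path in self.domain_msas.items():
                if not Path(path).exists():
                    raise ValidationError(f"domain alignment for {label!r} not found: {path}")
            if not self.domain_msas:
                raise ValidationError("config must list one domain alignment per domain")
        RedundancyConfig(self.identity_threshold, self.fragment_min_coverage)
        ConsensusConfig(self.conserve_threshold, self.residue_threshold, window=self.window)
        CalibrationConfig(self.grid_start, self.grid_step, self.grid_floor)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "linker_order" in data:
        data["linker_order"] = tuple(data["linker_order"])
    return PipelineConfig(**data)


def _position_index(label: str) -> int:
    m = re.search(r"(\d+)$", label)
    if not m:
        raise ValidationError(f"domain label {label!r} has no trailing position digit")
    return int(m.group(1))


def _pad_to(msa_rows: list[SequenceRecord], width: int) -> list[SequenceRecord]:
    return [
        SequenceRecord(r.id, r.residues + GAP * (width - len(r.residues)), r.description)
        for r in msa_rows
    ]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and return the summary dict.

    Outputs written under ``cfg.outdir``: per-domain motif and profile TSVs,
    the NR alignments, the architecture table, the NJ tree (newick) and
    ``summary.json``. Any stage failure raises ``StageError``.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    log_lines: list[str] = []

    def log(stage: str, message: str, t0: float | None = None) -> None:
        suffix = f" ({time.perf_counter() - t0:.2f}s)" if t0 is not None else ""
        line = f"[{stage}] {message}{suffix}"
        log_lines.append(line)
        logger.info(line)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - report stage and cause
            log(name, f"FAILED: {exc}")
            log_path.write_text("\n".join(log_lines) + "\n")
            raise StageError(name, exc) from exc
        log(name, "done", t0)
        return result

    # --- inputs -----------------------------------------------------------
    def stage_inputs():
        if cfg.simulate:
            spec = default_family_spec(
                n_sequences=cfg.n_sequences,
                seed=np.random.default_rng(cfg.seed),
                match_prob=cfg.match_prob,
            )
            family = generate_family(spec, seed=cfg.seed)
            return family.records, family.coordinates, dict(family.domain_msas)
        records = read_fasta(cfg.fasta)
        coords = read_domain_table(cfg.domains_tsv)
        msas = {label: read_msa(path) for label, path in cfg.domain_msas.items()}
        return records, coords, msas

    records, coords, domain_msas = run_stage("inputs", stage_inputs)

    # --- fragment cleaning + non-redundancy -------------------------------
    rcfg = RedundancyConfig(cfg.identity_threshold, cfg.fragment_min_coverage)

    def stage_redundancy():
        nr = {}
        counts = {}
        for label, msa in sorted(domain_msas.items()):
            cleaned = remove_fragments(msa, rcfg)
            reps, clusters = nonredundant_filter(cleaned, rcfg)
            nr[label] = reps
            counts[label] = {"n_input": len(msa), "n_nonredundant": len(reps)}
            write_msa(reps, outdir / f"nr_{label}.fasta")
        return nr, counts

    nr_msas, nr_counts = run_stage("redundancy", stage_redundancy)

    # --- consensus motifs --------------------------------------------------
    ccfg = ConsensusConfig(cfg.conserve_threshold, cfg.residue_threshold, window=cfg.window)

    def stage_consensus():
        motifs = {}
        stats = {}
        for label, msa in sorted(nr_msas.items()):
            motif = build_consensus(msa, ccfg)
            motifs[label] = motif
            stats[label] = {
                "conserved": motif.conserved_count,
                "total": motif.width,
                "pct": round(100.0 * motif.conserved_count / motif.width, 1),
            }
            motif_table(motif).to_csv(outdir / f"motif_{label}.tsv", sep="\t", index=False)
            profile = conservation_profile(motif, ccfg)
            with open(outdir / f"profile_{label}.tsv", "w") as fh:
                fh.write("column_index\tmean_conserved\n")
                for idx, value in profile:
                    fh.write(f"{idx}\t{value:.4f}\n")
        return motifs, stats

    motifs, consensus_stats = run_stage("consensus", stage_consensus)

    # --- profile calibration ----------------------------------------------
    cal_cfg = CalibrationConfig(cfg.grid_start, cfg.grid_step, cfg.grid_floor)

    def stage_profile():
        cutoffs = {}
        decoy_rng = np.random.default_rng(cfg.seed + 104729)  # independent stream
        for label, msa in sorted(nr_msas.items()):
            pssm = build_pssm(msa)
            decoys = generate_decoys(
                cfg.n_decoys,
                (max(10, msa.width - 10), msa.width + 20),
                seed=decoy_rng,
                id_prefix=f"decoy_{label}_",
            )
            positives = [r.ungapped() for r in msa.records]
            cutoff, report = calibrate_cutoff(pssm, positives, decoys, cal_cfg)
            cutoffs[label] = cutoff
        return cutoffs

    cutoffs = run_stage("profile", stage_profile)

    # --- architecture ------------------------------------------------------
    def stage_architecture():
        archs = [extract_segments(rec, coords) for rec in records]
        stats = linker_stats(archs)
        order_ok, violations = length_order_check(stats, cfg.linker_order)
        with open(outdir / "architecture.tsv", "w") as fh:
            fh.write("protein_id\tsegment\tstart\tend\tlength\n")
            for arch in archs:
                fh.write(f"{arch.protein_id}\tN\t1\t{arch.n_term_length}\t{arch.n_term_length}\n")
                for d in arch.domains:
                    fh.write(f"{arch.protein_id}\t{d.domain_label}\t{d.start}\t{d.end}\t{d.length}\n")
                for l in arch.linkers:
                    fh.write(f"{arch.protein_id}\t{l.label}\t{l.start}\t{l.end}\t{l.length}\n")
        return stats, order_ok, violations

    lstats, order_ok, violations = run_stage("architecture", stage_architecture)

    # --- clustering ---------------------------------------------------------
    def stage_clustering():
        width = max(m.width for m in nr_msas.values())
        rows: list[SequenceRecord] = []
        labels: list[tuple[str, int]] = []
        for label, msa in sorted(nr_msas.items()):
            pos = _position_index(label)
            for rec in msa.records[: cfg.purity_per_class]:
                pid = rec.id.split("_")[0]
                rows.append(SequenceRecord(f"{pid}_{label}", rec.residues, rec.description))
                labels.append((pid, pos))
        joint = Msa(_pad_to(rows, width))
        dm = domain_distance_matrix(joint, labels)
        purity = position_cluster_purity(dm)
        tree = nj_tree(dm)
        (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        return purity

    purity = run_stage("clustering", stage_clustering)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "parameters": {
            "seed": cfg.seed,
            "simulate": cfg.simulate,
            "n_sequences": cfg.n_sequences if cfg.simulate else len(records),
            "identity_threshold": cfg.identity_threshold,
            "fragment_min_coverage": cfg.fragment_min_coverage,
            "conserve_threshold": cfg.conserve_threshold,
            "residue_threshold": cfg.residue_threshold,
            "window": cfg.window,
            "grid_start": cfg.grid_start,
            "grid_step": cfg.grid_step,
            "grid_floor": cfg.grid_floor,
            "n_decoys": cfg.n_decoys,
            "purity_per_class": cfg.purity_per_class,
        },
        "domains": {
            label: {**nr_counts[label], **consensus_stats[label]} for label in sorted(nr_msas)
        },
        "cutoffs": cutoffs,
        "linkers": {
            label: {"n": s.n, "median": s.median, "min": s.min, "max": s.max}
            for label, s in sorted(lstats.per_label.items())
        },
        "length_order": {"order": list(cfg.linker_order), "ok": order_ok, "violations": violations},
        "purity": purity,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log_path.write_text("\n".join(log_lines) + "\n")
    return summary
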