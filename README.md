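# rbdscope

Conservation and domain-architecture analysis of multi-domain RNA-binding
proteins.

Proteins such as the ribosome-biogenesis factor Rbm19/Mrd1 are built from
several RNA-binding domains (RBDs, also called RRMs) joined by linkers.
Across a family of homologues, each domain position tends to carry its own
conserved sequence signature, and the linkers keep characteristic length
relationships. `rbdscope` is a library and CLI for quantifying exactly that
on a family of homologues: it reduces per-domain alignments to
non-redundant sets, calls consensus motifs with a BLOSUM62-based
conservation rule, profiles conservation along each domain with a sliding
window, calibrates position-specific scoring matrices (PSSMs) for
homologue search, computes linker-length statistics and the
decreasing-length order check, and tests position-specific clustering of
the individual domains with a neighbor-joining dendrogram and a
nearest-neighbour purity score. A synthetic-family generator with known
ground truth makes every step testable without any external data.

## The rules at the core

**Conservation rule.** For a column of a non-redundant alignment with
*n* sequences, let *m* be the most common amino acid. The column is
*conserved* when at least 85% of the sequences carry a residue *r* with
BLOSUM62 score s(r, m) > 0. A residue is listed in the consensus at that
position when at least 10% of the sequences carry exactly that residue;
listed residues are ordered by descending frequency. Gaps and unknown
residues count in the denominator and never as conserved.

**Windowed profile.** The mean of the conserved indicator over a sliding
window of five columns, assigned to the window centre (truncated at the
edges), gives the conservation profile along a domain.

**Non-redundancy.** Greedy incremental clustering (CD-HIT style): records
sorted by descending non-gap length join the first representative with
pairwise identity >= 80% (identity over mutually non-gap columns), else
found a new cluster.

**Profile search.** Per-column log-odds PSSM,
`log2((count + pc*bg) / (n_c + pc)) - log2(bg)`, scanned by affine-gap
local dynamic programming. Score cutoffs are calibrated on a descending
grid (90 downward in steps of 5): the lowest grid value admitting zero
decoys, i.e. as many true hits as possible without any false hit.
Leave-one-out jack-knifing checks that every member still beats all
decoys; iterative search grows the family until no new sequence passes.

**Domain clustering.** p-distance (1 − fractional identity) between
domains excised from many proteins, a Saitou–Nei neighbor-joining tree
(exact on additive matrices), and nearest-neighbour purity of the
position classes.

## Worked example

Run the bundled end-to-end demo: a synthetic six-domain family (60
sequences; domain widths and planted conserved-column counts mirroring an
Rbm19-like family, linkers drawn around medians 218/32/101/46/19):

```bash
rbdscope run --seed 17 --out-dir demo_out
```

or in Python:

```python
from rbdscope.pipeline import PipelineConfig, run_pipeline
summary = run_pipeline(PipelineConfig(outdir="demo_out", seed=17, n_sequences=60))
```

The summary (also written to `demo_out/summary.json`) contains, among
others:

```
"RBD1": {"n_input": 60, "n_nonredundant": 60, "conserved": 27, "total": 78, "pct": 34.6}
"RBD6": {"n_input": 60, "n_nonredundant": 60, "conserved": 42, "total": 81, "pct": 51.9}
linker medians: L1 211, L3 100, L4 46, L2 32, L5 19   (order check: True)
purity: 1.0
```

Reading: of RBD6's 81 columns, 42 (51.9%) pass the 85% conservation rule —
exactly the planted count, showing the caller recovers the ground truth;
the linker medians recover the generator's targets within sampling error
and strictly decrease in the canonical order L1 > L3 > L4 > L2 > L5; and
purity 1.0 means every domain's nearest neighbour in the p-distance matrix
sits at the same domain position, i.e. the six positions form six clean
clusters. Per-domain motif and profile TSVs, the non-redundant alignments,
the architecture table and the NJ tree (`tree.nwk`) are written next to
the summary.

Individual stages are exposed as subcommands (`rbdscope nr`, `consensus`,
`arch`, `search`, `cluster`, `simulate`) and as plain library functions.

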