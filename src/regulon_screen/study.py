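"""A complete, internally consistent synthetic study for end-to-end runs.

``write_synthetic_study`` lays down every input the pipeline consumes —
two count tables with design files, a qPCR Ct table, a coverage genome
with annotation and stranded bedGraphs, an ORF-scan region, and a small
comparative-genomics panel — all derived from one seed, together with a
ground-truth record of the planted regulon.

The planted cast exercises every branch of the elimination cascade:

- five "known" target genes and the regulator itself;
- three true novel regulon members (DE in both comparisons, qPCR-validated,
  complementation-restored, artifact-free);
- one read-through artifact gene: DE in the count tables and qPCR-positive
  (as unstranded counting and 5'-binding primers would report), but with
  coverage that decays from the upstream neighbor and no signal of its own;
- one complementation-failure gene (qPCR-positive, not restored);
- two genes that fail qPCR validation;
- two production-independent genes (down-regulated in the time course).

The expected final regulon is therefore the five known targets plus the
three true novel members.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CountTable, GeneModel, write_bedgraph, write_fasta, write_gff3
from .synthetic_data import (
    SimulationSpec,
    _nb_sample,
    mutate_to_identity,
    reverse_translate,
    simulate_coverage,
    simulate_ct,
    simulate_genome,
)

__all__ = ["write_synthetic_study"]

KNOWN = [f"eca{i}" for i in range(1, 6)]
REGULATOR = "soxR"
NOVEL_TRUE = ["nov1", "nov2", "nov3"]
ARTIFACT = "art1"
COMP_FAIL = "compfail1"
VAL_FAIL = ["valfail1", "valfail2"]
ACT_INDEP = ["actind1", "actind2"]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _counts_tsv(table: CountTable, counts_path: Path, design_path: Path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": table.samples, "condition": [table.conditions[s] for s in table.samples]}
    ).to_csv(design_path, sep="\t", index=False)


def _make_counts(
    rng: np.random.Generator,
    gene_folds: dict[str, float],
    n_background: int,
    reps: tuple[int, int],
    conditions: tuple[str, str],
    baseline: float = 200.0,
    phi: float = 0.05,
) -> CountTable:
    genes = list(gene_folds) + [f"bg{i:04d}" for i in range(n_background)]
    folds = np.array([gene_folds.get(g, 1.0) for g in genes])
    mu = baseline * rng.lognormal(0.0, 0.5, size=len(genes))
    n1, n2 = reps
    c1, c2 = conditions
    samples = [f"{c1}_{i+1}" for i in range(n1)] + [f"{c2}_{i+1}" for i in range(n2)]
    cond = {s: (c1 if i < n1 else c2) for i, s in enumerate(samples)}
    means = np.empty((len(genes), n1 + n2))
    for j in range(n1 + n2):
        up = folds if j < n1 else np.ones_like(folds)  # condition 1 carries the fold
        means[:, j] = mu * up
    counts = _nb_sample(rng, means, phi)
    return CountTable(
        counts=pd.DataFrame(counts, index=genes, columns=samples, dtype=np.int64),
        conditions=cond,
    )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(_AA20[rng.integers(20)] for _ in range(length - 1))


def write_synthetic_study(seed: int, out_dir: str | Path) -> tuple[dict, dict]:
    """Write all pipeline inputs under ``out_dir``; return (config, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # ---- count tables ----------------------------------------------------
    fold = 16.0
    de_a = {g: fold for g in KNOWN + [REGULATOR] + NOVEL_TRUE
            + [ARTIFACT, COMP_FAIL] + VAL_FAIL + ACT_INDEP}
    de_b = {g: fold for g in KNOWN + NOVEL_TRUE + [ARTIFACT, COMP_FAIL] + VAL_FAIL}
    de_b.update({g: 0.5 for g in ACT_INDEP})   # down in stationary phase
    de_b[REGULATOR] = 1.0                       # constitutively expressed
    table_a = _make_counts(rng, de_a, 200, (3, 3), ("WT", "dsoxr"))
    table_b = _make_counts(rng, de_b, 200, (3, 1), ("day3", "day1"))
    _counts_tsv(table_a, out / "counts_a.tsv", out / "design_a.tsv")
    _counts_tsv(table_b, out / "counts_b.tsv", out / "design_b.tsv")

    # ---- qPCR Ct table ---------------------------------------------------
    spec = SimulationSpec(seed=seed, ct_replicates=2, ct_sigma=0.2)
    true_folds: dict[tuple[str, str], float] = {}
    candidates = NOVEL_TRUE + [ARTIFACT, COMP_FAIL] + VAL_FAIL + ACT_INDEP
    for g in candidates + KNOWN:
        if g in VAL_FAIL or g in ACT_INDEP:
            rel = {"WT": 1.0, "dSoxR": 1.0, "dAct": 1.0, "comp": 1.0}
        elif g == COMP_FAIL:
            rel = {"WT": 1.0, "dSoxR": 1 / fold, "dAct": 1 / fold, "comp": 1.2 / fold}
        else:
            rel = {"WT": 1.0, "dSoxR": 1 / fold, "dAct": 1 / fold, "comp": 0.8}
        for strain, r in rel.items():
            true_folds[(g, strain)] = r
    ct_table, _ = simulate_ct(spec, true_folds, rng=rng)
    ct_table.data.to_csv(out / "ct.tsv", sep="\t", index=False)

    # ---- stranded coverage ----------------------------------------------
    cov_genes = [
        GeneModel("nov1", "synth", 1001, 2000, "+"),
        GeneModel(ARTIFACT, "synth", 2101, 3100, "+"),
        GeneModel("nov2", "synth", 5001, 6000, "-"),
        GeneModel("nov3", "synth", 8001, 9000, "+"),
    ]
    cov_spec = SimulationSpec(seed=seed, readthrough_lambda=100.0, genome_length=10_000)
    expression = {"nov1": 100.0, ARTIFACT: 0.0, "nov2": 80.0, "nov3": 60.0}
    track, cov_truth = simulate_coverage(
        cov_spec, cov_genes, expression, readthrough_pairs=[("nov1", ARTIFACT)]
    )
    cov_genome, _, _ = simulate_genome(
        SimulationSpec(seed=seed + 1, genome_length=track.length), rng=rng
    )
    write_fasta([cov_genome], out / "coverage_genome.fa")
    write_gff3(cov_genes, out / "coverage_genes.gff3")
    write_bedgraph(track, out / "coverage_plus.bedgraph", out / "coverage_minus.bedgraph")

    # ---- ORF-scan region: a planted large ORF spanning two loci ----------
    region_spec = SimulationSpec(seed=seed + 2, genome_length=2500)
    region, _, _ = simulate_genome(region_spec, rng=rng)
    orf_protein = _random_protein(rng, 318)            # 957 bp with stop codon
    coding = reverse_translate(orf_protein, rng)
    residues = list(region.residues)
    orf_start, orf_end = 614, 614 + len(coding) - 1
    residues[orf_start - 4 : orf_start - 1] = list("TAA")  # in-frame stop just upstream
    residues[orf_start - 1 : orf_end] = list(coding)
    region.residues = "".join(residues)
    write_fasta([region], out / "orf_region.fa")
    locus_a, locus_b = (700, 1100), (1200, 1500)

    # ---- conservation panel ---------------------------------------------
    cons_dir = out / "genomes"
    cons_dir.mkdir(exist_ok=True)
    queries = {"q1": _random_protein(rng, 120), "q2": _random_protein(rng, 120)}
    sites_consensus = "GCCTCAAGTTAACTTGAGGC"
    sites = [sites_consensus] * 4 + ["GCTTCAAGTTAACTTGAAGC", "GACTCAAGTTAACTTGAGTC"]
    with open(out / "sites.fa", "w") as fh:
        for i, s in enumerate(sites):
            fh.write(f">site_{i+1} synthetic\n{s}\n")
    with open(out / "queries.fa", "w") as fh:
        for qid, q in queries.items():
            fh.write(f">{qid}\n{q}\n")
    truth_cells = {}
    for gi, (identity, with_motif) in enumerate([(1.0, True), (0.85, False)]):
        g_spec = SimulationSpec(seed=seed + 10 + gi, genome_length=6000)
        motifs = [(1801, "+", sites_consensus)] if with_motif else None
        genome, _, g_truth = simulate_genome(
            g_spec,
            planted_motifs=motifs,
            planted_homologs={"q1": (2001, "+", queries["q1"], identity)},
            rng=rng,
        )
        genome.id = f"genome{gi+1}"
        write_fasta([genome], cons_dir / f"genome{gi+1}.fa")
        truth_cells[genome.id] = {
            "q1": "present_with_soxbox" if with_motif else "present_no_soxbox",
            "q2": "absent",
        }

    config = {
        "seed": seed,
        "known_targets": KNOWN,
        "regulator_id": REGULATOR,
        "screen": {
            "counts_a": str(out / "counts_a.tsv"),
            "design_a": str(out / "design_a.tsv"),
            "counts_b": str(out / "counts_b.tsv"),
            "design_b": str(out / "design_b.tsv"),
            "contrast_a": ["WT", "dsoxr"],
            "contrast_b": ["day3", "day1"],
        },
        "qpcr": {
            "ct_table": str(out / "ct.tsv"),
            "reference": "hrdB",
            "strains": {"wt": "WT", "null": "dSoxR", "act": "dAct", "complemented": "comp"},
        },
        "coverage": {
            "fasta": str(out / "coverage_genome.fa"),
            "gff3": str(out / "coverage_genes.gff3"),
            "plus": str(out / "coverage_plus.bedgraph"),
            "minus": str(out / "coverage_minus.bedgraph"),
        },
        "orf_scan": {
            "fasta": str(out / "orf_region.fa"),
            "locus_a": list(locus_a),
            "locus_b": list(locus_b),
        },
        "conservation": {
            "genomes_dir": str(cons_dir),
            "queries": str(out / "queries.fa"),
            "sites": str(out / "sites.fa"),
        },
    }
    truth = {
        "final_regulon": sorted(KNOWN + NOVEL_TRUE),
        "artifact_genes": [ARTIFACT],
        "eliminated_candidates": sorted(ACT_INDEP),
        "failed_validation": sorted(VAL_FAIL),
        "complementation_failures": [COMP_FAIL],
        "planted_orf": [orf_start, orf_end],
        "readthrough_pairs": cov_truth.readthrough_pairs,
        "conservation_cells": truth_cells,
    }
    return config, truth
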