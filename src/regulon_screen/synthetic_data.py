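"""Synthetic inputs with the statistical structure each analysis stage assumes.

Every generator is deterministic given its seed and returns, alongside the
data, a :class:`GroundTruth` record of what was planted, so recovery can be
checked exactly.  The generators emulate a stationary-phase bacterial
RNA-seq study design: two-condition count tables with replicate structure,
stranded coverage with transcriptional read-through decaying past gene 3'
ends, qPCR quantification cycles with Gaussian noise, and high-GC genomes
with planted protein-coding homologs and planted operator-motif instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import (
    CountTable,
    CtTable,
    GeneModel,
    GenomeSequence,
    StrandedCoverageTrack,
)

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_counts",
    "simulate_genome",
    "simulate_coverage",
    "simulate_ct",
    "reverse_translate",
    "mutate_to_identity",
]

_BASES = np.array(["A", "C", "G", "T"])

# translation table 11 (bacterial); stop codons excluded from the sense map
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in _TABLE11.forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()
_STOP_CODONS = sorted(_TABLE11.stop_codons)


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults encode the study conditions the generators emulate: a
    moderate-sized gene panel with three biological replicates per
    condition, negative-binomial dispersion typical of replicated bulk
    RNA-seq, a high-GC streptomycete-like genome, duplicate qPCR assays
    with sub-cycle noise, and read-through decaying over a few hundred bp.
    """

    seed: int = 0
    genes: int = 1000
    samples_per_condition: tuple[int, int] = (3, 3)
    baseline_mean: float = 100.0
    dispersion: float = 0.05
    n_de: int = 50
    log2_fold: float = 2.0          # planted |log2 FC| for DE genes (fold 4)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    genome_length: int = 20_000
    gc: float = 0.72                # streptomycete-like GC content
    readthrough_lambda: float = 200.0  # bp; exponential decay of read-through
    ct_sigma: float = 0.2           # cycles; replicate noise
    ct_replicates: int = 2
    ct_reference: str = "hrdB"
    ct_reference_ct: float = 18.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("GC fraction must lie in [0, 1]")
        if self.readthrough_lambda <= 0:
            raise ValueError("read-through decay length must be > 0")
        if self.ct_sigma < 0:
            raise ValueError("Ct noise sigma must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline mean must be > 0")


@dataclass
class GroundTruth:
    """What was planted, with coordinates, for recovery checks."""

    true_log2_fold: dict[str, float] = field(default_factory=dict)
    condition_means: pd.DataFrame | None = None
    size_factors: dict[str, float] = field(default_factory=dict)
    motif_instances: list[tuple[int, str]] = field(default_factory=list)  # (1-based start, strand)
    homolog_intervals: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    readthrough_pairs: list[tuple[str, str]] = field(default_factory=list)  # (upstream, downstream)
    expression: dict[str, float] = field(default_factory=dict)
    ct_folds: dict[tuple[str, str], float] = field(default_factory=dict)  # (gene, strain) -> fold vs ref strain


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with variance mean + phi * mean^2; phi == 0 is the Poisson limit."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[CountTable, GroundTruth]:
    """Two-condition negative-binomial count table with planted fold changes.

    Counts are drawn as ``k_ij ~ NB(mean = s_j * mu_i * 2**(beta_i * [j in B]),
    var = mean + phi * mean**2)``.  The first ``n_de`` genes carry
    ``beta = log2_fold`` (condition B up); all others have ``beta = 0``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_a, n_b = spec.samples_per_condition
    gene_ids = [f"g{i:04d}" for i in range(spec.genes)]
    sample_ids = [f"A{i+1}" for i in range(n_a)] + [f"B{i+1}" for i in range(n_b)]
    conditions = {s: ("A" if s.startswith("A") else "B") for s in sample_ids}

    # per-gene baselines spread over ~an order of magnitude around the mean
    mu = spec.baseline_mean * rng.lognormal(mean=0.0, sigma=0.7, size=spec.genes)
    beta = np.zeros(spec.genes)
    beta[: spec.n_de] = spec.log2_fold
    s = rng.uniform(*spec.size_factor_range, size=n_a + n_b)

    means = np.empty((spec.genes, n_a + n_b))
    for j in range(n_a + n_b):
        in_b = j >= n_a
        means[:, j] = s[j] * mu * np.power(2.0, beta * in_b)
    counts = _nb_sample(rng, means, spec.dispersion)

    table = CountTable(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids, dtype=np.int64),
        conditions=conditions,
    )
    cond_means = pd.DataFrame(
        {"A": mu, "B": mu * np.power(2.0, beta)}, index=gene_ids
    )
    truth = GroundTruth(
        true_log2_fold=dict(zip(gene_ids, beta)),
        condition_means=cond_means,
        size_factors=dict(zip(sample_ids, s)),
    )
    return table, truth


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate a protein with uniform synonymous-codon choice
    (bacterial code), appending a uniformly chosen stop codon."""
    codons = []
    for aa in protein:
        if aa not in _CODONS_FOR:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def mutate_to_identity(
    coding: str, identity: float, rng: np.random.Generator
) -> str:
    """Substitute whole codons so the translation has ~``identity`` fraction
    of residues equal to the original; the stop codon is left intact."""
    if not (0.0 < identity <= 1.0):
        raise ValueError("identity fraction must lie in (0, 1]")
    n_codons = len(coding) // 3 - 1  # exclude stop
    n_mut = int(round((1.0 - identity) * n_codons))
    if n_mut == 0:
        return coding
    positions = rng.choice(n_codons, size=n_mut, replace=False)
    codons = [coding[i * 3 : i * 3 + 3] for i in range(len(coding) // 3)]
    aas = sorted(_CODONS_FOR)
    for pos in positions:
        current_aa = _TABLE11.forward_table[codons[pos]]
        new_aa = current_aa
        while new_aa == current_aa:
            new_aa = aas[rng.integers(len(aas))]
        options = _CODONS_FOR[new_aa]
        codons[pos] = options[rng.integers(len(options))]
    return "".join(codons)


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def simulate_genome(
    spec: SimulationSpec,
    planted_motifs: list[tuple[int, str, str]] | None = None,
    planted_homologs: dict[str, tuple[int, str, str, float]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeSequence, list[GeneModel], GroundTruth]:
    """i.i.d.-background genome with planted motifs and coding homologs.

    Background bases are drawn with P(G) = P(C) = GC/2 and
    P(A) = P(T) = (1-GC)/2.

    Parameters
    ----------
    planted_motifs:
        ``(position, strand, site_sequence)`` triples; the site (given in
        motif orientation) is inserted at the 1-based position, reverse
        complemented first when strand is ``-``.
    planted_homologs:
        ``gene_id -> (position, strand, protein, identity_fraction)``; the
        protein is reverse-translated, mutated down to the target identity,
        and inserted (reverse complemented on ``-``).  A :class:`GeneModel`
        covering the insert (including its stop codon) is emitted.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    planted_motifs = planted_motifs or []
    planted_homologs = planted_homologs or {}

    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    residues = rng.choice(_BASES, size=spec.genome_length, p=p)

    occupied: list[tuple[int, int]] = []

    def _claim(start: int, end: int, what: str) -> None:
        if not (1 <= start <= end <= spec.genome_length):
            raise ValueError(f"{what} at {start}-{end} outside genome of length {spec.genome_length}")
        for a, b in occupied:
            if start <= b and a <= end:
                raise ValueError(f"planted elements overlap: {what} at {start}-{end}")
        occupied.append((start, end))

    truth = GroundTruth()
    genes: list[GeneModel] = []

    for gene_id, (pos, strand, protein, identity) in planted_homologs.items():
        coding = mutate_to_identity(reverse_translate(protein, rng), identity, rng)
        insert = coding if strand == "+" else _revcomp(coding)
        end = pos + len(insert) - 1
        _claim(pos, end, f"homolog {gene_id}")
        residues[pos - 1 : end] = list(insert)
        genes.append(GeneModel(gene_id=gene_id, seq_id="synth", start=pos, end=end, strand=strand))
        truth.homolog_intervals[gene_id] = (pos, end, strand)

    for pos, strand, site in planted_motifs:
        insert = site.upper() if strand == "+" else _revcomp(site.upper())
        end = pos + len(insert) - 1
        _claim(pos, end, "motif")
        residues[pos - 1 : end] = list(insert)
        truth.motif_instances.append((pos, strand))

    genome = GenomeSequence(id="synth", residues="".join(residues))
    return genome, genes, truth


# ---------------------------------------------------------------------------
# stranded coverage
# ---------------------------------------------------------------------------

def simulate_coverage(
    spec: SimulationSpec,
    genes: list[GeneModel],
    expression: dict[str, float],
    readthrough_pairs: list[tuple[str, str]] | None = None,
    antisense: dict[str, float] | None = None,
) -> tuple[StrandedCoverageTrack, GroundTruth]:
    """Noise-free stranded coverage from per-gene expression levels.

    Each expressed gene contributes uniform depth over its body on its
    transcribed strand.  For each ``(upstream, downstream)`` read-through
    pair, the upstream gene's transcription continues past its 3' end with
    depth ``e * exp(-d / lambda)`` at distance ``d``, on the upstream
    gene's strand.  ``antisense`` maps gene ids to depth added on the
    strand opposite the gene's annotation (to emulate a gene whose signal
    is entirely antisense).
    """
    readthrough_pairs = readthrough_pairs or []
    antisense = antisense or {}
    length = max(g.end for g in genes) + int(10 * spec.readthrough_lambda)
    plus = np.zeros(length)
    minus = np.zeros(length)
    by_id = {g.gene_id: g for g in genes}

    def vec(strand: str) -> np.ndarray:
        return plus if strand == "+" else minus

    for g in genes:
        e = expression.get(g.gene_id, 0.0)
        if e > 0:
            vec(g.strand)[g.start - 1 : g.end] += e
        a = antisense.get(g.gene_id, 0.0)
        if a > 0:
            vec("-" if g.strand == "+" else "+")[g.start - 1 : g.end] += a

    lam = spec.readthrough_lambda
    for up_id, _down_id in readthrough_pairs:
        up = by_id[up_id]
        e = expression.get(up_id, 0.0)
        if e <= 0:
            continue
        if up.strand == "+":
            d = np.arange(1, length - up.end + 1)
            vec("+")[up.end : length] += e * np.exp(-d / lam)
        else:
            d = np.arange(up.start - 1, 0, -1)
            vec("-")[0 : up.start - 1] += e * np.exp(-d / lam)

    track = StrandedCoverageTrack(seq_id=genes[0].seq_id, plus=plus, minus=minus)
    truth = GroundTruth(readthrough_pairs=list(readthrough_pairs), expression=dict(expression))
    return track, truth


# ---------------------------------------------------------------------------
# qPCR Ct values
# ---------------------------------------------------------------------------

def simulate_ct(
    spec: SimulationSpec,
    true_folds: dict[tuple[str, str], float],
    baseline_delta: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CtTable, GroundTruth]:
    """qPCR quantification cycles with planted fold differences.

    ``true_folds[(gene, strain)]`` is the gene's relative expression in
    that strain (the reference strain carries 1.0).  Per replicate,
    ``Ct_gene = Ct_ref + baseline_delta_gene - log2(rel expr) + N(0, sigma)``;
    the reference gene itself is emitted noise-free at ``ct_reference_ct``
    so standardization against it is exact.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    baseline_delta = baseline_delta or {}
    strains = sorted({s for (_g, s) in true_folds})
    gene_ids = sorted({g for (g, _s) in true_folds})
    rows = []
    for strain in strains:
        for rep in range(1, spec.ct_replicates + 1):
            rows.append({"gene": spec.ct_reference, "strain": strain, "replicate": rep,
                         "ct": spec.ct_reference_ct})
            for gene in gene_ids:
                rel = true_folds.get((gene, strain))
                if rel is None:
                    continue
                if rel <= 0:
                    raise ValueError(f"relative expression must be > 0 for ({gene}, {strain})")
                ct = (spec.ct_reference_ct + baseline_delta.get(gene, 5.0)
                      - np.log2(rel) + rng.normal(0.0, spec.ct_sigma))
                rows.append({"gene": gene, "strain": strain, "replicate": rep, "ct": ct})
    table = CtTable(data=pd.DataFrame(rows), reference_gene=spec.ct_reference)
    truth = GroundTruth(ct_folds=dict(true_folds))
    return table, truth
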