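# Methods

This note documents the models, decision rules, and numerical choices
behind `regulon-screen`, and what the synthetic generators do and do not
emulate.

## The inference problem

A transcription factor's regulon is inferred from a cascade of evidence:
a whole-transcriptome screen for genes whose expression depends on the
regulator, elimination of genes not co-regulated with the activating
signal (here, stationary-phase antibiotic production), targeted qPCR
validation and genetic complementation, inspection of stranded coverage
for counting artifacts, re-annotation of suspect gene models, and a
comparative scan for conservation of the regulon and its operator motif
across related genomes. Each stage can overturn a candidate admitted by
the previous one; the pipeline makes every rule explicit and testable.

## Differential-expression screen

**Normalization.** Median-of-ratios size factors:
s_j = median_i k_ij / (Π_v k_iv)^{1/m}, over genes with a positive
geometric mean. Permutation-invariant over genes and equivariant to
per-sample scaling (both property-tested).

**Dispersion.** Per-gene NB dispersion φ (Var = μ + φμ²) by method of
moments on normalized counts within replicate groups,
φ̂_i = max(0, (v_i − m_i)/m_i²), floored by a least-squares mean trend
φ(m) = a₁/m + a₀ with the conservative rule φ_i = max(φ̂_i, φ(m_i)).
This is a deliberate simplification of local-regression dispersion fits
used by count-based DE packages; the published worked examples consumed
by the acceptance checks do not depend on it, and parameter-recovery
simulations (below) bound its operating characteristics. When a
contrasted condition has no replicates, both conditions are pooled into a
single group ("blind" estimation), which over-states φ for genuinely DE
genes and is therefore conservative; the pipeline logs a warning.

**Test.** A conditioned two-sample count test: with K_A, K_B the
condition count sums modeled as NB with moment-matched means and
variances under the pooled mean estimate, the two-sided p-value sums
P(a)P(b) over all splits a + b = k_S no more probable than the observed
one, normalized by the total over all splits. The enumeration is exact
(vectorized over the k_S + 1 splits); at φ = 0 it reduces to the
conditional binomial test, which is the closed-form oracle used in tests.
Probabilities are compared in log space with a 1e-9 absolute tolerance so
exactly-tied splits (the balanced case) are included deterministically.

**Multiple testing.** Benjamini–Hochberg step-up q-values,
q_(i) = min_{j≥i} m·p_(j)/j clipped at 1. Note BH is *not* idempotent
(bh((0.1, 0.9)) = (0.2, 0.9), bh((0.2, 0.9)) = (0.4, 0.9)); the property
tests assert monotonicity in p-rank, q ≥ p, and exact agreement with an
independent reference implementation.

**Screen and elimination.** A gene is a candidate iff FC_A ≥ 4 and
q_A ≤ 0.5 in the regulator contrast. Candidates partition into known
targets, the regulator itself, and novel candidates; a novel candidate is
eliminated as production-independent iff FC_B ≤ 1 in the time-course
contrast. The elimination threshold on FC_B (with q_B unused) is a
package inference from the published worked example: retained genes show
time-course q-values up to 0.8 while all eliminated genes have FC_B ≤ 1,
so no q-based rule separates them and the fold rule does, exactly.
Fold changes are ratios of mean normalized counts with 0.5 added to both
means when either is zero; the orientation (numerator condition) is
recorded in every result. Output sorts by descending FC_A with
lexicographic gene-id tie-break.

## qPCR validation

Relative expression R = E^(−ΔCt) with ΔCt = Ct_gene − Ct_ref, replicates
averaged on the ΔCt (log) scale, amplification efficiency fixed at E = 2
(perfect doubling; no calibration data are modeled — configurable).
Fold decrease of strain B vs A is R_A/R_B, so fold(A,B)·fold(B,A) = 1.
Calls: regulator-dependent at ≥ 4-fold (WT vs null), production-dependent
at ≥ 4-fold and strongly so at ≥ 11-fold (WT vs production-deficient).
Complementation is "restored" iff both WT and the complemented strain
exceed the null mutant by ≥ 4-fold; this single rule covers both failure
modes seen in practice (complemented strain stuck at null levels, and no
dependence in any strain).

## Read-through and antisense artifacts

Unstranded counting misattributes two kinds of neighbor signal, detected
here from stranded per-base coverage:

- **antisense dominance** — sense fraction (sense / (sense + antisense)
  depth over the gene body) below 0.5;
- **read-through suspicion** — a same-strand upstream gene ending within
  500 bp of the gene's 5′ end, a 5′/3′ half-body mean-depth ratio ≥ 5
  (halves in transcript orientation; odd lengths give the extra base to
  the 5′ half), and a 3′-half mean depth ≤ 1.

Antisense dominance takes precedence; zero-coverage genes are flagged
undefined rather than erroring. The original calls this module
quantifies were made by visual browser inspection; the statistic,
thresholds, and precedence rule are this package's formalization and all
are configurable. The flags are mirror-symmetric: reflecting the genome
(reversing both depth vectors, swapping strands, mirroring coordinates)
leaves sense fractions and skew ratios unchanged (property-tested).

## ORF re-annotation

Six-frame scan, bacterial code (table 11), start codons {ATG, GTG, TTG}
(alternative starts are common in high-GC actinobacteria; the set is
configurable). Each stop-to-stop segment yields one ORF from its first
in-frame start through the stop codon (nested starts behind a flag).
"Large" means length > 500 bp with the stop codon counted inside the
interval, encoded as min_len = 501; coordinates are 1-based inclusive on
the forward chromosome for both strands. Selection retains ORFs
overlapping two given annotated loci by ≥ 1 bp each — the signature of a
single gene split in two by a frameshift. The finder is verified against
an exhaustive in-frame (start, stop) enumeration oracle and a
reverse-complement mirror identity.

## Operator-motif scanning

PSSM from aligned sites: f_bi = (c_bi + α·p_b)/(n + α) with pseudocount
α = 1 distributed proportionally to the background (few training sites
make α = 0 degenerate), log-odds m_bi = log2(f_bi/p_b) in **bits**. The
background is the target genome's own strand-symmetrized mononucleotide
composition (p_A = p_T, p_C = p_G; N excluded), so a high-GC genome pays
less for G/C matches and the score threshold transfers across genomes.
The log base and pseudocount scheme are package choices recorded in
output headers. Scanning scores every offset of the upstream window on
both strands (windows containing N are skipped) and reports scores
strictly above θ = 10 bits, sorted descending. For a + gene starting at
s the window is [s − W, s − 1]; for a − gene [s + 1, s + W], truncated at
contig edges; W defaults to 1000 bp (200 bp for the stricter
promoter-proximal variant). With the symmetrized background a site and
its reverse complement score identically on opposite strands, so the
strand of a perfectly dyad-symmetric match is reported but not
meaningful. No training-site alignment from any published figure is
shipped; the bundled `example_soxbox_sites.fa` is a synthetic
illustrative stand-in, clearly labeled as such.

## Translated homolog search

Deterministic seed-and-extend against all six frames: exact 4-residue
amino-acid seeds, ungapped X-drop extension (BLOSUM62, X = 20), one best
region per query (ties: longer, then lowest coordinate), no E-values —
presence is a raw score ≥ 40% of the query's self-score. Extensions
cannot cross stop codons. Cross-query dedup keeps the best hit among
same-strand overlapping hits (ties: longer, then lexicographic query
id), leaving an antichain. The search is verified against an exhaustive
per-diagonal ungapped local-alignment oracle on ≤ 5-kb genomes; an
import adapter accepts hit tables from an external translated-search
tool for genome-scale surveys where the desk-scale search is too slow.
The conservation matrix anchors the upstream motif scan at each retained
hit's 5′ boundary — the closest computable proxy for the predicted ORF
start — and classifies cells as absent / present without operator /
present with operator.

## Synthetic data

Generators are deterministic given a seed and return ground truth.

- **Counts**: k_ij ~ NB(s_j·μ_i·2^{β_i·[condition]}, Var = μ + φμ²);
  defaults 1000 genes, 3 vs 3 replicates, lognormal baselines around 100,
  φ = 0.05, planted |log2 FC| = 2 on 50 genes, size factors in
  [0.7, 1.4]. The replicate structure mirrors a two-condition
  stationary-phase comparison with a single early-time-point sample
  available for the time-course contrast.
- **Genomes**: i.i.d. bases with default GC 0.72 (streptomycete-like;
  order-1 backgrounds are out of scope). Homologs are reverse-translated
  with uniform synonymous-codon choice and degraded to a target identity
  by whole-codon substitutions; motifs are inserted at recorded
  positions/strands; overlapping plants are rejected.
- **Coverage**: uniform depth over expressed gene bodies on their
  strands; read-through decays as e·exp(−d/λ) past the upstream 3′ end
  (λ default 200 bp; the half-body skew of a pure read-through signal is
  exp(L/2λ) in closed form, which the tests exploit).
- **Ct values**: Ct = Ct_ref + baselineΔ − log2(rel. expr.) + N(0, σ),
  σ = 0.2 cycles, duplicate assays, noise-free reference.

What the generators do **not** emulate: sequencing-level noise (reads,
GC bias, rRNA carry-over), positional coverage variability within gene
bodies, codon-usage bias, qPCR efficiency drift, and operon structure.
Passing recovery tests therefore demonstrates correctness of the decision
rules and estimators under their assumed models, not robustness to every
failure mode of real libraries.

## Problem sizes used by the bundled checks

The test suite and `scripts/acceptance.py` run entirely from generated
data and the published-table fixtures: DE recovery uses 20 simulations of
1000 genes; oracle comparisons use ≤ 10-kb sequences (ORFs), 2-kb windows
(motifs), and ≤ 5-kb genomes (translated search); the motif background
rate uses a 100-kb genome; the end-to-end study uses ~214 genes, a 10-kb
coverage genome, a 2.5-kb ORF region, and two 6-kb genomes. These sizes
were chosen to keep every oracle exhaustive and every run reproducible on
a laptop; the pipeline itself has no hard-coded scale.

## Known limitations

- The dispersion trend a₁/m + a₀ under-fits strongly mean-dependent
  dispersion profiles; the conservative max rule trades power for FDR
  control (measured: mean sensitivity ≈ 0.97, FDP ≈ 0.01 at q ≤ 0.05
  under the default simulation).
- The re-annotation check against the published chromosomal coordinates
  requires the reference genome region, which is not redistributed with
  the package; without it the corresponding test fails with instructions
  for obtaining the sequence.
- PSSM scores carry no p-value calibration; θ is in bits and must be
  re-examined if a different log base or pseudocount is configured.
- The translated search is ungapped; diverged homologs whose best local
  alignment requires indels will be under-scored relative to a gapped
  search, which is why the external-hit adapter exists.
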