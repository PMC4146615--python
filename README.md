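# regulon-screen

Inference of a bacterial transcription factor's regulon from RNA-seq,
qPCR, and comparative genomics — as a tested, fully reproducible
pipeline.

The package is aimed at microbial transcriptomics groups who screen for
the targets of a regulator (here modeled on a redox-sensing activator
induced during stationary-phase antibiotic production in streptomycetes)
and need every filtering decision — not just the DE test — to be explicit
code: which candidates were kept, which were eliminated as
signal-independent, which validated by qPCR and complementation, which
turned out to be strand or read-through counting artifacts, and how the
regulon and its operator motif are conserved across related genomes.

## What it computes

**Candidate screen.** Median-of-ratios size factors
s_j = median_i k_ij/(Π_v k_iv)^{1/m}; per-gene NB dispersion φ
(Var = μ + φμ²) by method of moments with a conservative a₁/m + a₀ trend
floor; a conditioned count test (p-value by exact enumeration over all
splits of the total, reducing to the conditional binomial at φ = 0);
Benjamini–Hochberg q-values. A gene is a candidate iff FC ≥ 4 and
q ≤ 0.5 in the regulator contrast; candidates flat (FC ≤ 1) in the
production time-course are eliminated.

**qPCR validation.** Relative expression R = E^(−ΔCt) standardized to a
reference gene (E = 2); regulator dependence at ≥ 4-fold, strong
production dependence at ≥ 11-fold; complementation "restored" iff both
wild type and the complemented null exceed the null by ≥ 4-fold.

**Artifact detection.** From stranded per-base coverage: antisense
dominance (sense fraction < 0.5) and read-through suspicion (close
same-strand upstream neighbor, 5′/3′ half-depth skew ≥ 5, quiet 3′
half).

**ORF re-annotation.** Six-frame scan (table 11, starts {ATG, GTG, TTG}),
ORFs > 500 bp, selection of ORFs spanning two annotated loci — the
signature of one gene split in two by a frameshift.

**Conservation.** Seed-and-extend translated search (BLOSUM62, ungapped,
X-drop) with best-region retention and cross-query dedup, composed with a
log-odds PSSM scan (bits, per-genome strand-symmetrized background,
threshold 10) of each hit's upstream window, yielding a species × gene
presence/operator matrix.

Full model and parameter documentation is in [docs/methods.md](docs/methods.md).

## Worked example

Run the candidate screen on the bundled published-table fixture:

```sh
regulon-screen de-screen \
  --fixture src/regulon_screen/data/table2_fixture.tsv \
  --known-targets SCO1178,SCO4266,SCO1909,SCO2478,SCO7008 \
  --regulator-id SCO1697
```

```
gene	status	fc_a	q_a	fc_b	q_b
SCO0319	novel_candidate	84.0	2e-28	100.5	9e-12
SCO0320	novel_candidate	79.0	3e-21	52.0	5e-10
SCO1178	known_target	52.0	2e-21	49.0	1e-09
SCO4266	known_target	30.0	2e-28	14.0	4e-07
SCO7688	eliminated_not_act_dependent	28.0	0.08	1.0	1.0
SCO1177	novel_candidate	23.0	7e-18	32.0	2e-07
...
```

Every row passed the primary screen (FC ≥ 4, q ≤ 0.5 against the
regulator-null mutant). The five confirmed targets and the regulator are
set aside, leaving 12 novel candidates; `fc_b` is the time-course fold
change, and the three rows with `fc_b ≤ 1` (SCO7688, SCO7682, SCO2878)
are eliminated as production-independent, leaving 9 for qPCR validation.
(`100.5` is the documented sentinel for a censored `>100` table cell.)

A complete synthetic study — counts, Ct values, stranded coverage, an
ORF region, and a genome panel, with ground truth — runs end to end:

```sh
regulon-screen simulate --seed 1 --out study/
regulon-screen pipeline --config study/config.yaml --out study/results/
```

```
{
  "final_regulon": ["eca1", "eca2", "eca3", "eca4", "eca5", "nov1", "nov2", "nov3"]
}
```

The reported regulon is exactly the planted truth: the five configured
known targets plus the three genuine novel members; the planted
read-through artifact, the complementation failure, the qPCR-negative
genes, and the production-independent genes are all excluded, each with
its reason recorded in `study/results/report.json`.

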