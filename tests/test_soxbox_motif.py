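"""PSSM construction and scanning: closed-form scores, a brute-force
all-window oracle, and an independent cross-check against Biopython's
motif machinery."""

import numpy as np
import pytest
from Bio import motifs as bio_motifs
from Bio.Seq import Seq

from regulon_screen.io_formats import GenomeSequence
from regulon_screen.soxbox_motif import (
    build_pssm,
    genome_background,
    pssm_from_counts,
    scan_sequence,
    scan_upstream,
)
from regulon_screen.synthetic_data import SimulationSpec, simulate_genome

UNIFORM = np.full(4, 0.25)
CONSENSUS = "GCCTCAAGTTAACTTGAGGC"
SITES = [CONSENSUS] * 4 + ["GCTTCAAGTTAACTTGAAGC", "GACTCAAGTTAACTTGAGTC"]


def _revcomp(s):
    return str(Seq(s).reverse_complement())


class TestBuildPssm:
    def test_single_site_scores_two_bits_per_column(self):
        pssm = build_pssm(["ACGT"], UNIFORM, alpha=1e-9)
        assert pssm.score("ACGT") == pytest.approx(8.0, abs=1e-6)

    def test_identical_sites_approach_two_bits_monotonically_in_alpha(self):
        sites = ["ACGTAC"] * 5
        scores = [build_pssm(sites, UNIFORM, alpha=a).score("ACGTAC")
                  for a in (2.0, 1.0, 0.5, 0.1, 1e-9)]
        assert all(np.diff(scores) > 0)
        assert scores[-1] == pytest.approx(12.0, abs=1e-6)

    def test_pseudocount_column_formula(self):
        # column counts (A:2, C:2, G:0, T:0), uniform background, alpha=1:
        # f_A = (2 + 0.25) / 5 = 0.45
        pssm = build_pssm(["AA", "AC", "CA", "CC"], UNIFORM, alpha=1.0)
        assert pssm.freqs[0, 0] == pytest.approx(0.45)

    def test_frequencies_sum_to_one_per_position(self):
        pssm = build_pssm(SITES, np.array([0.14, 0.36, 0.36, 0.14]))
        np.testing.assert_allclose(pssm.freqs.sum(axis=0), 1.0)

    def test_consensus_achieves_max_score(self):
        pssm = build_pssm(SITES, np.array([0.14, 0.36, 0.36, 0.14]))
        assert pssm.score(pssm.consensus) == pytest.approx(pssm.max_score)

    def test_ragged_sites_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            build_pssm(["ACGT", "ACG"], UNIFORM)

    def test_matches_biopython_log_odds(self):
        """Independent oracle: Biopython's motif PSSM with pseudocounts
        alpha * background reproduces our log-odds matrix exactly."""
        background = {"A": 0.14, "C": 0.36, "G": 0.36, "T": 0.14}
        m = bio_motifs.create([Seq(s) for s in SITES])
        pwm = m.counts.normalize(pseudocounts={b: background[b] for b in "ACGT"})
        bio_pssm = pwm.log_odds(background)
        ours = build_pssm(SITES, np.array([0.14, 0.36, 0.36, 0.14]), alpha=1.0)
        for i, b in enumerate("ACGT"):
            np.testing.assert_allclose(ours.logodds[i], list(bio_pssm[b]), atol=1e-12)


class TestBackground:
    def test_acgt_sequence_is_uniform(self):
        np.testing.assert_allclose(genome_background(GenomeSequence("x", "ACGT")), 0.25)

    def test_reverse_complement_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=500))
        g = GenomeSequence("x", seq)
        g_rc = GenomeSequence("y", _revcomp(seq.replace("N", "A")) )
        g2 = GenomeSequence("z", _revcomp(seq))
        np.testing.assert_allclose(genome_background(g), genome_background(g2))

    def test_high_gc_generator_background(self):
        genome, _, _ = simulate_genome(SimulationSpec(seed=5, genome_length=50_000, gc=0.72))
        p = genome_background(genome)
        assert p[2] == pytest.approx(0.36, abs=0.01)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError, match="unambiguous"):
            genome_background(GenomeSequence("x", "NNNN"))


class TestScan:
    def _pssm(self, background=None):
        bg = background if background is not None else np.array([0.14, 0.36, 0.36, 0.14])
        return build_pssm(SITES, bg)

    def test_window_shorter_than_motif_is_empty(self):
        pssm = self._pssm()
        genome = GenomeSequence("x", "ACGT" * 200)
        # gene right at the contig start: truncated window shorter than motif
        assert scan_upstream(pssm, genome, 5, "+", window=1000) == []

    def test_window_smaller_than_width_rejected(self):
        with pytest.raises(ValueError, match="shorter than motif"):
            scan_upstream(self._pssm(), GenomeSequence("x", "A" * 100), 50, "+", window=4)

    def test_planted_consensus_recovered_at_offset_and_strand(self):
        spec = SimulationSpec(seed=6, genome_length=5000)
        genome, _, truth = simulate_genome(
            spec, planted_motifs=[(1801, "+", CONSENSUS), (3101, "-", CONSENSUS)]
        )
        pssm = build_pssm(SITES, genome_background(genome))
        # gene starting at 2821 on '+': window [1821+1000] covers first plant
        hits = scan_upstream(pssm, genome, 2821, "+", window=1020, threshold=10.0)
        top = hits[0]
        assert (top.position, top.strand) == (1801, "+")
        assert top.score == pytest.approx(pssm.score(CONSENSUS))
        # gene whose 5' end is at 3050 on '-': upstream window covers the minus
        # plant; the consensus is dyad-symmetric, so the strand of a perfect
        # palindrome is ambiguous and only the position is asserted
        hits = scan_upstream(pssm, genome, 3050, "-", window=500, threshold=10.0)
        assert hits[0].position == 3101

    def test_asymmetric_motif_strand_recovered(self):
        asym_sites = ["GGGTCAACTTAAGACCTTTT"] * 5
        spec = SimulationSpec(seed=9, genome_length=4000)
        genome, _, _ = simulate_genome(
            spec, planted_motifs=[(2001, "-", asym_sites[0])]
        )
        pssm = build_pssm(asym_sites, genome_background(genome))
        hits = scan_upstream(pssm, genome, 1950, "-", window=300, threshold=10.0)
        assert (hits[0].position, hits[0].strand) == (2001, "-")

    def test_distance_annotation(self):
        genome, _, _ = simulate_genome(
            SimulationSpec(seed=7, genome_length=3000),
            planted_motifs=[(951, "+", CONSENSUS)],
        )
        pssm = build_pssm(SITES, genome_background(genome))
        hits = scan_upstream(pssm, genome, 1001, "+", window=900, threshold=10.0)
        # motif occupies 951..970; 30 bp between its 3' edge and the gene start
        assert hits[0].distance == 1001 - 970

    def test_matches_all_window_bruteforce_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000, p=[0.14, 0.36, 0.36, 0.14]))
        seq = seq[:888] + CONSENSUS + seq[908:]
        pssm = self._pssm()
        got = {(h.position, h.strand): h.score
               for h in scan_sequence(pssm, seq, threshold=-5.0)}
        expected = {}
        for i in range(len(seq) - pssm.width + 1):
            window = seq[i : i + pssm.width]
            for strand, w in (("+", window), ("-", _revcomp(window))):
                s = pssm.score(w)
                if s > -5.0:
                    expected[(i + 1, strand)] = s
        assert got.keys() == expected.keys()
        for key in expected:
            assert got[key] == pytest.approx(expected[key], abs=1e-9)

    def test_windows_containing_n_are_skipped(self):
        pssm = self._pssm()
        seq = "A" * 30 + "N" + "A" * 30
        hits = scan_sequence(pssm, seq, threshold=-1e9)
        positions_spanning_n = {p for (p, s) in ((h.position, h.strand) for h in hits)
                                if p <= 31 <= p + pssm.width - 1}
        assert positions_spanning_n == set()

    def test_site_and_reverse_complement_score_identically(self):
        pssm = self._pssm()  # symmetrized background
        for site in SITES:
            hits_f = scan_sequence(pssm, site, threshold=-1e9)
            by = {(h.position, h.strand): h.score for h in hits_f}
            hits_r = scan_sequence(pssm, _revcomp(site), threshold=-1e9)
            by_r = {(h.position, h.strand): h.score for h in hits_r}
            assert by[(1, "+")] == pytest.approx(by_r[(1, "-")])

    def test_expected_background_score_is_nonpositive(self):
        pssm = self._pssm()
        expected = (pssm.background[:, None] * pssm.logodds).sum()
        assert expected <= 0

    def test_background_hit_rate_below_regression_bound(self):
        genome, _, _ = simulate_genome(SimulationSpec(seed=8, genome_length=100_000))
        pssm = build_pssm(SITES, genome_background(genome))
        hits = scan_sequence(pssm, genome.residues, threshold=10.0)
        n_positions = 2 * (genome.length - pssm.width + 1)
        assert len(hits) / n_positions < 1e-3


def test_pssm_from_counts_matches_site_construction():
    counts = np.zeros((4, len(CONSENSUS)))
    for s in SITES:
        for i, b in enumerate(s):
            counts["ACGT".index(b), i] += 1
    bg = np.array([0.14, 0.36, 0.36, 0.14])
    np.testing.assert_allclose(
        pssm_from_counts(counts, bg).logodds, build_pssm(SITES, bg).logodds
    )
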