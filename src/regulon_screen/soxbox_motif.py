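"""Position-specific scoring matrix construction and strand-aware upstream
scanning with a genome-background log-odds model.

A PSSM is built from aligned operator sites: per-position frequencies
``f_bi = (c_bi + alpha * p_b) / (n + alpha)`` (pseudocount ``alpha``
distributed proportionally to the background) and log-odds
``m_bi = log2(f_bi / p_b)`` in bits.  The background is the target
genome's own strand-symmetrized mononucleotide composition, so scores are
calibrated per genome: a high-GC genome "pays" less for G/C matches.
Scanning walks every offset of the window on both strands and reports
windows scoring strictly above the threshold (default 10 bits).

The log base (2) and the pseudocount scheme are package choices, recorded
in output headers; both are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

from .io_formats import GeneModel, GenomeSequence, LoadError

__all__ = [
    "Pssm",
    "MotifHit",
    "build_pssm",
    "genome_background",
    "scan_upstream",
    "scan_sequence",
    "load_sites_fasta",
    "load_jaspar_counts",
    "pssm_from_counts",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass
class Pssm:
    """Log-odds scoring matrix (bits) with its background model.

    ``freqs`` and ``logodds`` are 4 x w arrays in A, C, G, T row order.
    """

    freqs: np.ndarray
    background: np.ndarray
    logodds: np.ndarray
    alpha: float

    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.freqs.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())

    def score(self, window: str) -> float:
        """Additive log-odds score of one window; NaN if it contains N."""
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != motif width {self.width}")
        total = 0.0
        for i, base in enumerate(window.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                return float("nan")
            total += self.logodds[idx, i]
        return total


@dataclass(frozen=True)
class MotifHit:
    """One scoring window above threshold.

    ``position`` is the 1-based forward-chromosome coordinate of the
    window's left edge; ``distance`` the bp from the window edge nearest
    the anchored gene start to that start (1 = immediately adjacent).
    """

    seq_id: str
    position: int
    strand: str
    score: float
    distance: int | None = None


def build_pssm(sites: list[str], background: np.ndarray, alpha: float = 1.0) -> Pssm:
    """Build a PSSM from aligned equal-length sites over {A,C,G,T}."""
    if not sites:
        raise ValueError("no sites given")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("aligned sites must all have the same length")
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or (background <= 0).any():
        raise ValueError("background must be 4 positive frequencies")
    background = background / background.sum()
    counts = np.zeros((4, w))
    for s in sites:
        for i, base in enumerate(s.upper()):
            if base not in _BASE_INDEX:
                raise ValueError(f"site contains non-ACGT residue {base!r}")
            counts[_BASE_INDEX[base], i] += 1
    n = len(sites)
    freqs = (counts + alpha * background[:, None]) / (n + alpha)
    logodds = np.log2(freqs / background[:, None])
    return Pssm(freqs=freqs, background=background, logodds=logodds, alpha=alpha)


def genome_background(genome: GenomeSequence) -> np.ndarray:
    """Strand-symmetrized mononucleotide frequencies (A, C, G, T); N is
    excluded from counting."""
    counts = np.zeros(4)
    for base, idx in _BASE_INDEX.items():
        counts[idx] = genome.residues.count(base)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"genome {genome.id!r} has no unambiguous bases")
    f = counts / total
    at = (f[0] + f[3]) / 2
    gc = (f[1] + f[2]) / 2
    return np.array([at, gc, gc, at])


def _score_all_offsets(pssm: Pssm, seq: str) -> np.ndarray:
    """Scores of every window of ``seq`` on the given strand orientation;
    windows containing N score NaN.  Vectorized over offsets."""
    n = len(seq)
    w = pssm.width
    if n < w:
        return np.empty(0)
    idx = np.full(n, -1, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    n_windows = n - w + 1
    scores = np.zeros(n_windows)
    valid = np.ones(n_windows, dtype=bool)
    for j in range(w):
        col = idx[j : j + n_windows]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, pssm.logodds[np.clip(col, 0, 3), j], 0.0)
    scores[~valid] = np.nan
    return scores


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def scan_sequence(
    pssm: Pssm, seq: str, threshold: float, seq_id: str = "", offset0: int = 1
) -> list[MotifHit]:
    """Score every offset of ``seq`` on both strands; return hits with
    score > threshold.  ``offset0`` is the forward-chromosome coordinate
    of ``seq``'s first base; reported positions are window left edges on
    the forward strand for both orientations."""
    w = pssm.width
    hits = []
    fwd = _score_all_offsets(pssm, seq.upper())
    rev = _score_all_offsets(pssm, _revcomp(seq.upper()))
    n_windows = len(fwd)
    for i in range(n_windows):
        if not np.isnan(fwd[i]) and fwd[i] > threshold:
            hits.append(MotifHit(seq_id=seq_id, position=offset0 + i, strand="+",
                                 score=float(fwd[i])))
        ri = n_windows - 1 - i  # reverse-scan index whose window starts at forward offset i
        if not np.isnan(rev[ri]) and rev[ri] > threshold:
            hits.append(MotifHit(seq_id=seq_id, position=offset0 + i, strand="-",
                                 score=float(rev[ri])))
    hits.sort(key=lambda h: (-h.score, h.position, h.strand))
    return hits


def scan_upstream(
    pssm: Pssm,
    genome: GenomeSequence,
    gene_start: int,
    strand: str,
    window: int = 1000,
    threshold: float = 10.0,
) -> list[MotifHit]:
    """Scan the strand-aware upstream window of a gene start.

    For a ``+`` gene starting at ``s`` the window is ``[s - window, s - 1]``;
    for a ``-`` gene whose start (5' end) is at ``s`` it is
    ``[s + 1, s + window]``.  The window is truncated at the contig edge.
    Both strands are scored; hits with score > threshold are returned
    sorted by descending score, each annotated with its distance upstream
    of the gene start.
    """
    if window < pssm.width:
        raise ValueError(f"window {window} shorter than motif width {pssm.width}")
    if strand == "+":
        a, b = max(1, gene_start - window), gene_start - 1
    elif strand == "-":
        a, b = gene_start + 1, min(genome.length, gene_start + window)
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if b - a + 1 < pssm.width:
        return []
    seq = genome.subseq(a, b)
    hits = scan_sequence(pssm, seq, threshold, seq_id=genome.id, offset0=a)
    out = []
    for h in hits:
        if strand == "+":
            distance = gene_start - (h.position + pssm.width - 1)
        else:
            distance = h.position - gene_start
        out.append(MotifHit(seq_id=h.seq_id, position=h.position, strand=h.strand,
                            score=h.score, distance=distance))
    return out


# ---------------------------------------------------------------------------
# site inputs
# ---------------------------------------------------------------------------

def load_sites_fasta(path: str | Path) -> list[str]:
    """Aligned binding sites from a plain FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise LoadError(f"no sites in {path}")
    return [str(r.seq).upper() for r in records]


def load_jaspar_counts(path: str | Path) -> np.ndarray:
    """A JASPAR-style count matrix as a 4 x w array (A, C, G, T rows)."""
    with open(path) as fh:
        motif = bio_motifs.read(fh, "jaspar")
    return np.array([list(motif.counts[b]) for b in "ACGT"], dtype=float)


def pssm_from_counts(counts: np.ndarray, background: np.ndarray, alpha: float = 1.0) -> Pssm:
    """Build a PSSM directly from a 4 x w count matrix."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("count matrix must be 4 x w")
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    n = counts.sum(axis=0)
    if not np.allclose(n, n[0]):
        raise ValueError("count matrix columns must sum to the same site count")
    freqs = (counts + alpha * background[:, None]) / (n[0] + alpha)
    logodds = np.log2(freqs / background[:, None])
    return Pssm(freqs=freqs, background=background, logodds=logodds, alpha=alpha)
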