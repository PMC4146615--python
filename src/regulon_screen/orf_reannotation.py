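"""Six-frame ORF discovery and selection of large ORFs spanning given loci.

Motivated by a mis-annotation pattern in bacterial genomes: a single-base
deletion splits one real gene into two annotated ORFs (possibly on
inconsistent strands).  Re-scanning the raw sequence for large open
reading frames that span both annotated loci recovers the fused gene.

Conventions: bacterial code (translation table 11) with start codons
{ATG, GTG, TTG}; an ORF runs from the first in-frame start codon of a
stop-to-stop segment through its stop codon, which is included in the
reported interval but excluded from the protein.  Coordinates are 1-based
inclusive on the forward chromosome regardless of strand.  "Large" means
length strictly greater than 500 bp, encoded as ``min_len = 501``.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io_formats import GenomeSequence

__all__ = ["OrfRecord", "find_orfs", "spanning_orfs", "DEFAULT_STARTS"]

DEFAULT_STARTS = ("ATG", "GTG", "TTG")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame on the forward-chromosome coordinate system.

    ``frame`` is 1-3 for the forward strand, 4-6 for the reverse.  The
    stop codon is inside [start, end] but not in ``protein``.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _translate_orf(coding: str, start_codon: str) -> str:
    protein = str(Seq(coding[:-3]).translate(table=11))
    if "*" in protein:
        raise AssertionError("internal stop in ORF translation")
    # alternative start codons are translated as fMet in vivo
    if start_codon != "ATG" and protein:
        protein = "M" + protein[1:]
    return protein


def _scan_strand(
    seq: str,
    min_len: int,
    starts: tuple[str, ...],
    all_starts: bool,
) -> list[tuple[int, int, int, str]]:
    """ORFs on one strand of ``seq``: (local_start, local_end, frame_offset,
    protein), local coordinates 1-based on ``seq`` itself."""
    out = []
    n = len(seq)
    for offset in range(3):
        start_positions: list[int] = []
        for i in range(offset, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                chosen = start_positions if all_starts else start_positions[:1]
                for s0 in chosen:
                    length = i + 3 - s0
                    if length >= min_len:
                        coding = seq[s0 : i + 3]
                        out.append(
                            (s0 + 1, i + 3, offset, _translate_orf(coding, seq[s0 : s0 + 3]))
                        )
                start_positions = []
            elif codon in starts and (all_starts or not start_positions):
                start_positions.append(i)
        # segment running off the window end has no stop codon: no ORF
    return out


def find_orfs(
    genome: GenomeSequence,
    window: tuple[int, int] | None = None,
    min_len: int = 501,
    starts: tuple[str, ...] = DEFAULT_STARTS,
    all_starts: bool = False,
) -> list[OrfRecord]:
    """Six-frame ORF scan of a genomic window.

    Each stop-to-stop segment yields at most one ORF, from its first
    in-frame start codon through the stop codon (``all_starts=True`` emits
    every nested start instead).  ORFs shorter than ``min_len`` bp
    (stop codon included) are dropped.
    """
    if min_len < 6:
        raise ValueError("min_len must be >= 6 (start plus stop codon)")
    starts = tuple(s.upper() for s in starts)
    if window is None:
        window = (1, genome.length)
    w_start, w_end = window
    seq = genome.subseq(w_start, w_end)  # validates bounds
    rc = str(Seq(seq).reverse_complement())
    records: list[OrfRecord] = []
    for a, b, offset, protein in _scan_strand(seq, min_len, starts, all_starts):
        records.append(
            OrfRecord(
                seq_id=genome.id,
                start=w_start + a - 1,
                end=w_start + b - 1,
                strand="+",
                frame=offset + 1,
                protein=protein,
            )
        )
    for a, b, offset, protein in _scan_strand(rc, min_len, starts, all_starts):
        records.append(
            OrfRecord(
                seq_id=genome.id,
                start=w_end - b + 1,
                end=w_end - a + 1,
                strand="-",
                frame=offset + 4,
                protein=protein,
            )
        )
    records.sort(key=lambda r: (r.start, r.end, r.frame))
    return records


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def spanning_orfs(
    orfs: list[OrfRecord],
    locus_a: tuple[int, int],
    locus_b: tuple[int, int],
) -> list[OrfRecord]:
    """Retain ORFs overlapping both loci by at least one base pair."""
    for name, (s, e) in (("locus_a", locus_a), ("locus_b", locus_b)):
        if s > e or s < 1:
            raise ValueError(f"{name} is not a valid interval: {s}-{e}")
    return [
        o
        for o in orfs
        if _overlaps(o.start, o.end, *locus_a) and _overlaps(o.start, o.end, *locus_b)
    ]
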