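"""Readers and writers for the on-disk formats used throughout the pipeline.

Coordinate conventions
----------------------
All *internal* genomic coordinates are 1-based inclusive, matching the
style of bacterial genome annotation databases.  Conversions to and from
0-based half-open conventions (bedGraph) happen only at file boundaries:
a bedGraph record ``[a, b)`` covers internal bases ``a+1 .. b``.

Censored fixture values
-----------------------
Differential-expression fixture tables may contain the censored strings
``">100"`` and ``"<1"`` as printed in published summary tables.  These are
decoded to the sentinels 100.5 and 0.5 respectively: any decoding that
maps ``">100"`` above every threshold in use and ``"<1"`` below 1
reproduces the downstream filters; the sentinels make that choice explicit
and testable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "GeneModel",
    "StrandedCoverageTrack",
    "CountTable",
    "CtTable",
    "LoadError",
    "load_fasta",
    "write_fasta",
    "load_genome_annotation",
    "write_gff3",
    "load_stranded_coverage",
    "write_bedgraph",
    "load_count_table",
    "load_ct_table",
    "load_de_fixture",
    "decode_censored",
]

_VALID_RESIDUES = set("ACGTN")

CENSORED_HIGH = 100.5  # sentinel for ">100"
CENSORED_LOW = 0.5     # sentinel for "<1"


class LoadError(ValueError):
    """Raised when an input file violates a format or coordinate invariant."""


@dataclass
class GenomeSequence:
    """A DNA sequence over {A, C, G, T, N}; residues are upper-cased on load."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise LoadError(
                f"sequence {self.id!r} contains unsupported residues {sorted(bad)}; "
                "only A/C/G/T/N are accepted"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def subseq(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise LoadError(
                f"interval {start}-{end} outside sequence {self.id!r} (length {self.length})"
            )
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """A gene on a genome: 1-based inclusive coordinates, start <= end."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise LoadError(
                f"gene {self.gene_id!r}: invalid coordinates {self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise LoadError(f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class StrandedCoverageTrack:
    """Per-base read depth on each strand of one sequence.

    ``plus`` / ``minus`` are length-L vectors; index ``i`` holds the depth
    at 1-based position ``i + 1``.
    """

    seq_id: str
    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=float)
        self.minus = np.asarray(self.minus, dtype=float)
        if self.plus.shape != self.minus.shape or self.plus.ndim != 1:
            raise LoadError("plus/minus coverage vectors must be 1-D and equal length")
        if (self.plus < 0).any() or (self.minus < 0).any():
            raise LoadError("coverage depths must be non-negative")

    @property
    def length(self) -> int:
        return self.plus.shape[0]

    def depth(self, strand: str) -> np.ndarray:
        return self.plus if strand == "+" else self.minus


@dataclass
class CountTable:
    """Gene-level read counts: genes (rows) x samples (columns), plus a
    sample -> condition map."""

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise LoadError("count table contains non-integer values")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise LoadError("count table contains negative values")
        missing = [s for s in self.counts.columns if s not in self.conditions]
        if missing:
            raise LoadError(f"samples without a condition label: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]


@dataclass
class CtTable:
    """qPCR quantification cycles keyed by (gene, strain, replicate)."""

    data: pd.DataFrame  # columns: gene, strain, replicate, ct
    reference_gene: str | None = None

    def __post_init__(self) -> None:
        required = {"gene", "strain", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise LoadError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise LoadError("Ct values must be finite and > 0")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_fasta(path: str | Path) -> list[GenomeSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise LoadError(f"no FASTA records in {path}")
    return [GenomeSequence(id=r.id, residues=str(r.seq)) for r in records]


def write_fasta(sequences: list[GenomeSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_GENE_TYPES = {"gene", "CDS"}


def _gff3_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in attr_field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def load_genome_annotation(
    fasta_path: str | Path, gff3_path: str | Path
) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Load a genome FASTA plus its GFF3 annotation.

    Features of type ``gene`` or ``CDS`` become :class:`GeneModel` records
    (a CDS is used only when no gene feature shares its ID).  GFF3 seq_ids
    must resolve against the FASTA; coordinates are validated against
    sequence lengths.  Malformed lines are reported with their line number.
    """
    seqs = load_fasta(fasta_path)
    lengths = {s.id: s.length for s in seqs}

    genes: dict[str, GeneModel] = {}
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise LoadError(f"{gff3_path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in _GFF_GENE_TYPES:
                continue
            if seq_id not in lengths:
                raise LoadError(f"{gff3_path}:{lineno}: seq_id {seq_id!r} not present in FASTA")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise LoadError(f"{gff3_path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise LoadError(f"{gff3_path}:{lineno}: start {start} > end {end}")
            if end > lengths[seq_id]:
                raise LoadError(
                    f"{gff3_path}:{lineno}: end {end} beyond sequence {seq_id!r} "
                    f"(length {lengths[seq_id]})"
                )
            attributes = _gff3_attributes(attrs)
            gene_id = attributes.get("ID") or attributes.get("Name")
            if gene_id is None:
                raise LoadError(f"{gff3_path}:{lineno}: feature has no ID attribute")
            gene_id = re.sub(r"^(gene|cds)[:-]", "", gene_id)
            model = GeneModel(gene_id=gene_id, seq_id=seq_id, start=start, end=end, strand=strand)
            # a gene feature wins over a CDS with the same id
            if gene_id not in genes or ftype == "gene":
                genes[gene_id] = model
    return seqs, list(genes.values())


def write_gff3(genes: list[GeneModel], path: str | Path, source: str = "regulon_screen") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.seq_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph (stranded coverage as a pair of files)
# ---------------------------------------------------------------------------

def _read_bedgraph_vector(path: str | Path, genome: GenomeSequence) -> np.ndarray:
    depth = np.zeros(genome.length, dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise LoadError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            seq_id, a_s, b_s, v_s = fields
            if seq_id != genome.id:
                raise LoadError(f"{path}:{lineno}: seq_id {seq_id!r} does not match genome {genome.id!r}")
            a, b, v = int(a_s), int(b_s), float(v_s)
            if v < 0:
                raise LoadError(f"{path}:{lineno}: negative depth {v}")
            if not (0 <= a < b <= genome.length):
                raise LoadError(
                    f"{path}:{lineno}: interval [{a},{b}) outside genome of length {genome.length}"
                )
            depth[a:b] += v  # bedGraph [a, b) covers internal bases a+1..b
    return depth


def load_stranded_coverage(
    plus_bedgraph: str | Path, minus_bedgraph: str | Path, genome: GenomeSequence
) -> StrandedCoverageTrack:
    """Load per-strand bedGraph files into per-base depth vectors.

    Positions absent from a file have depth 0.
    """
    return StrandedCoverageTrack(
        seq_id=genome.id,
        plus=_read_bedgraph_vector(plus_bedgraph, genome),
        minus=_read_bedgraph_vector(minus_bedgraph, genome),
    )


def _write_bedgraph_vector(depth: np.ndarray, seq_id: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        # run-length encode constant stretches of non-zero depth
        i = 0
        n = depth.shape[0]
        while i < n:
            j = i
            while j < n and depth[j] == depth[i]:
                j += 1
            if depth[i] != 0:
                fh.write(f"{seq_id}\t{i}\t{j}\t{depth[i]:g}\n")
            i = j


def write_bedgraph(track: StrandedCoverageTrack, plus_path: str | Path, minus_path: str | Path) -> None:
    _write_bedgraph_vector(track.plus, track.seq_id, plus_path)
    _write_bedgraph_vector(track.minus, track.seq_id, minus_path)


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------

def load_count_table(counts_tsv: str | Path, design_tsv: str | Path) -> CountTable:
    """Load a genes x samples count TSV plus a two-column sample/condition design."""
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    if counts.empty:
        raise LoadError(f"empty count table: {counts_tsv}")
    design = pd.read_csv(design_tsv, sep="\t", dtype=str, keep_default_na=False)
    if not {"sample", "condition"} <= set(design.columns):
        raise LoadError(f"design file {design_tsv} needs 'sample' and 'condition' columns")
    conditions = dict(zip(design["sample"].astype(str), design["condition"].astype(str)))
    return CountTable(counts=counts, conditions=conditions)


def load_ct_table(ct_tsv: str | Path, reference_gene: str | None = None) -> CtTable:
    data = pd.read_csv(ct_tsv, sep="\t")
    if data.empty:
        raise LoadError(f"empty Ct table: {ct_tsv}")
    return CtTable(data=data, reference_gene=reference_gene)


def decode_censored(value: str | float) -> float:
    """Decode a printed table cell: ">100" -> 100.5, "<1" -> 0.5, else float."""
    if isinstance(value, str):
        v = value.strip()
        if v.startswith(">"):
            return float(v[1:]) + 0.5
        if v.startswith("<"):
            return float(v[1:]) - 0.5
        return float(v)
    return float(value)


def load_de_fixture(path: str | Path) -> pd.DataFrame:
    """Load a published-table fixture of per-gene fold changes and q-values.

    Expected columns: ``gene``, then any of ``fc_a``, ``q_a``, ``fc_b``,
    ``q_b`` (comparison A = stationary-phase mutant contrast, comparison B =
    the developmental time-course contrast).  Censored cells are decoded to
    sentinels (see module docstring).  Extra columns pass through untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene" not in df.columns:
        raise LoadError(f"fixture {path} has no 'gene' column")
    out = pd.DataFrame({"gene": df["gene"].astype(str)})
    for col in df.columns:
        if col == "gene":
            continue
        if col in {"fc_a", "q_a", "fc_b", "q_b", "fold_soxr", "fold_act"}:
            out[col] = df[col].map(decode_censored)
        else:
            out[col] = df[col]
    return out.set_index("gene", drop=False)
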