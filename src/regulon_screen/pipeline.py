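"""Orchestration of the full regulon-inference analysis.

Stages, each optional except the screen:

1. candidate screen — from a count table + design (running the DE test) or
   directly from a published-table fixture of fold changes and q-values;
2. read-through / antisense artifact flags from stranded coverage;
3. qPCR validation (regulator dependence, production dependence,
   complementation) from a Ct table;
4. ORF re-annotation of a suspect region;
5. cross-genome homolog / operator-motif conservation.

The final regulon is the configured known targets plus every novel
candidate that survives the whole cascade: passes the screen, is not
eliminated as production-independent, validates by qPCR, is restored by
complementation (when a complemented strain is measured), and carries no
read-through or antisense artifact flag (when coverage is provided).

Every output file carries a provenance header (config hash, seed,
thresholds) as comment lines; bodies are deterministic, so re-running an
identical config reproduces them byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import de_screen, qpcr_validation, strand_readthrough
from .de_screen import (
    STATUS_ELIMINATED,
    STATUS_NOVEL,
    candidate_screen,
    de_test,
)
from .homolog_conservation import regulon_matrix
from .io_formats import (
    load_count_table,
    load_ct_table,
    load_de_fixture,
    load_fasta,
    load_genome_annotation,
    load_stranded_coverage,
)
from .orf_reannotation import find_orfs, spanning_orfs
from .soxbox_motif import load_sites_fasta

logger = logging.getLogger("regulon_screen")

DEFAULT_THRESHOLDS = {
    "tau_fc": 4.0,       # screen fold-change threshold (published rule)
    "tau_q": 0.5,        # screen q-value threshold (published rule)
    "tau_act": 1.0,      # elimination: flat in the time-course comparison
    "tau_val": 4.0,      # qPCR validation fold (published rule)
    "tau_strong": 11.0,  # strong production dependence (published rule)
    "tau_comp": 4.0,     # complementation fold (package rule)
    "efficiency": 2.0,   # qPCR amplification efficiency (package default)
    "theta_sense": 0.5,  # antisense-dominance threshold (package rule)
    "theta_skew": 5.0,   # 5'/3' skew threshold (package rule)
    "d_max": 500,        # max upstream-neighbor gap, bp (package rule)
    "floor": 1.0,        # max 3'-half mean depth for read-through (package rule)
    "min_len": 501,      # ORF length > 500 bp (published rule)
    "window": 1000,      # upstream motif-scan window, bp (published rule)
    "theta": 10.0,       # motif log-odds threshold, bits (published rule)
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=True)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return validate_config(config, base=Path(path).parent)


def validate_config(config: dict, base: Path | None = None) -> dict:
    """Fill threshold defaults, resolve paths, and check referenced files."""
    config = dict(config)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    for key, value in thresholds.items():
        if value is not None and value <= 0:
            raise PipelineError(f"config: threshold {key} must be positive, got {value}")
    config["thresholds"] = thresholds
    config.setdefault("seed", 0)
    config.setdefault("known_targets", [])
    if "screen" not in config:
        raise PipelineError("config: a 'screen' section is required")
    screen = config["screen"]
    if "fixture" not in screen and not {"counts_a", "counts_b"} <= set(screen):
        raise PipelineError(
            "config: screen needs either 'fixture' or 'counts_a'/'counts_b' inputs"
        )

    def _resolve(section: dict) -> None:
        for key, value in section.items():
            if isinstance(value, str) and (
                key.endswith(("_path", "_tsv", "_fasta", "_gff3"))
                or key in {"fixture", "counts_a", "counts_b", "design_a", "design_b",
                           "ct_table", "plus", "minus", "fasta", "gff3", "queries",
                           "sites", "genomes_dir"}
            ):
                p = Path(value)
                if base is not None and not p.is_absolute():
                    p = base / p
                if not p.exists():
                    raise PipelineError(f"config: referenced file does not exist: {p}")
                section[key] = str(p)

    for section_name in ("screen", "coverage", "qpcr", "orf_scan", "conservation"):
        if section_name in config and isinstance(config[section_name], dict):
            _resolve(config[section_name])
    return config


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_screen(config: dict) -> pd.DataFrame:
    th = config["thresholds"]
    screen = config["screen"]
    if "fixture" in screen:
        fx = load_de_fixture(screen["fixture"])
        de_a = fx.rename(columns={"fc_a": "fc", "q_a": "q"})[["fc", "q"]]
        de_b = fx.rename(columns={"fc_b": "fc", "q_b": "q"})[["fc", "q"]]
    else:
        table_a = load_count_table(screen["counts_a"], screen["design_a"])
        table_b = load_count_table(screen["counts_b"], screen["design_b"])
        num_a, den_a = screen.get("contrast_a", ["WT", "null"])
        num_b, den_b = screen.get("contrast_b", ["day3", "day1"])
        de_a = de_test(table_a, num_a, den_a).table
        de_b = de_test(table_b, num_b, den_b).table
    return candidate_screen(
        de_a,
        de_b,
        known_targets=config["known_targets"],
        regulator_id=config.get("regulator_id", "soxR"),
        tau_fc=th["tau_fc"],
        tau_q=th["tau_q"],
        tau_act=th["tau_act"],
    )


def _stage_coverage(config: dict) -> pd.DataFrame | None:
    cov = config.get("coverage")
    if not cov:
        return None
    th = config["thresholds"]
    seqs, genes = load_genome_annotation(cov["fasta"], cov["gff3"])
    track = load_stranded_coverage(cov["plus"], cov["minus"], seqs[0])
    return strand_readthrough.readthrough_flags(
        track,
        genes,
        theta_sense=th["theta_sense"],
        theta_skew=th["theta_skew"],
        d_max=int(th["d_max"]),
        floor=th["floor"],
    )


def _stage_qpcr(config: dict) -> tuple[pd.DataFrame, dict[str, str]] | None:
    qp = config.get("qpcr")
    if not qp:
        return None
    th = config["thresholds"]
    ct = load_ct_table(qp["ct_table"], reference_gene=qp.get("reference", "hrdB"))
    rel = qpcr_validation.relative_expression(ct, efficiency=th["efficiency"])
    strains = qp.get("strains", {})
    wt = strains.get("wt", "WT")
    null = strains.get("null", "dSoxR")
    act = strains.get("act")
    comp = strains.get("complemented")
    calls = qpcr_validation.fold_and_validate(
        rel, wt, null, strain_act=act, tau_val=th["tau_val"], tau_strong=th["tau_strong"]
    )
    comp_calls: dict[str, str] = {}
    if comp is not None:
        for gene in calls.index:
            try:
                comp_calls[gene] = qpcr_validation.complementation_call(
                    rel, gene, wt, null, comp, tau=th["tau_comp"]
                )
            except ValueError:
                comp_calls[gene] = "not_tested"
    return calls, comp_calls


def _stage_orf(config: dict) -> list | None:
    orf = config.get("orf_scan")
    if not orf:
        return None
    th = config["thresholds"]
    genome = load_fasta(orf["fasta"])[0]
    region = tuple(orf["region"]) if "region" in orf else None
    orfs = find_orfs(genome, window=region, min_len=int(th["min_len"]))
    if "locus_a" in orf and "locus_b" in orf:
        orfs = spanning_orfs(orfs, tuple(orf["locus_a"]), tuple(orf["locus_b"]))
    return orfs


def _stage_conservation(config: dict):
    cons = config.get("conservation")
    if not cons:
        return None
    th = config["thresholds"]
    genome_files = sorted(Path(cons["genomes_dir"]).glob("*.fa")) + sorted(
        Path(cons["genomes_dir"]).glob("*.fasta")
    )
    genomes = [g for f in genome_files for g in load_fasta(f)]
    queries = {s.id: s.residues for s in _load_protein_fasta(cons["queries"])}
    sites = load_sites_fasta(cons["sites"])
    return regulon_matrix(
        genomes, queries, sites, window=int(th["window"]), threshold=th["theta"]
    )


def _load_protein_fasta(path: str):
    from Bio import SeqIO

    class _P:
        def __init__(self, id: str, residues: str):
            self.id = id
            self.residues = residues

    return [_P(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run all configured stages; write TSVs + a JSON report; return the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = validate_config(config)
    th = config["thresholds"]
    header = [
        f"config_hash: {_config_hash(config)}",
        f"seed: {config['seed']}",
        "thresholds: " + json.dumps(th, sort_keys=True),
    ]

    report: dict = {"config_hash": _config_hash(config), "seed": config["seed"],
                    "thresholds": th, "stages": {}}

    def _run(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn(config)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name} failed: {exc}\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        return result

    candidates = _run("screen", _stage_screen)
    _write_tsv(candidates.set_index("gene") if not candidates.empty else candidates,
               out / "candidates.tsv", header)
    novel = list(candidates.loc[candidates["status"] == STATUS_NOVEL, "gene"])
    eliminated = list(candidates.loc[candidates["status"] == STATUS_ELIMINATED, "gene"])
    known_found = list(candidates.loc[candidates["status"] == de_screen.STATUS_KNOWN, "gene"])
    report["stages"]["screen"] = {
        "novel_candidates": len(novel) + len(eliminated),
        "eliminated_not_act_dependent": len(eliminated),
        "retained_for_validation": len(novel),
        "known_targets_recovered": len(known_found),
    }

    flags = _run("readthrough", _stage_coverage)
    artifact_genes: set[str] = set()
    if flags is not None:
        _write_tsv(flags, out / "readthrough.tsv", header)
        artifact_genes = set(
            flags.index[flags["flag"].isin(
                [strand_readthrough.FLAG_READTHROUGH, strand_readthrough.FLAG_ANTISENSE]
            )]
        )
        report["stages"]["readthrough"] = {
            "flagged": sorted(artifact_genes),
        }

    qpcr_result = _run("qpcr", _stage_qpcr)
    validated: set[str] = set()
    restored: dict[str, str] = {}
    if qpcr_result is not None:
        calls, comp_calls = qpcr_result
        calls = calls.copy()
        if comp_calls:
            calls["complementation"] = [comp_calls.get(g, "not_tested") for g in calls.index]
        _write_tsv(calls, out / "validation.tsv", header)
        validated = set(calls.index[calls["soxr_dependent"]])
        restored = comp_calls
        report["stages"]["qpcr"] = {
            "tested": len(calls),
            "soxr_dependent": int(calls["soxr_dependent"].sum()),
            "act_strong": int(calls["act_strong"].sum()) if "act_strong" in calls else None,
        }

    orfs = _run("orf_scan", _stage_orf)
    if orfs is not None:
        odf = pd.DataFrame(
            [{"start": o.start, "end": o.end, "strand": o.strand, "frame": o.frame,
              "length": o.length} for o in orfs]
        )
        _write_tsv(odf, out / "orfs.tsv", header)
        report["stages"]["orf_scan"] = {
            "n_orfs": len(orfs),
            "intervals": [[o.start, o.end] for o in orfs],
        }

    cons = _run("conservation", _stage_conservation)
    if cons is not None:
        grid, counts, hits = cons
        _write_tsv(grid, out / "conservation_grid.tsv", header)
        _write_tsv(counts, out / "conservation_counts.tsv", header)
        report["stages"]["conservation"] = {
            "counts": counts.to_dict(orient="index"),
        }

    # final regulon membership
    members = set(config["known_targets"])
    excluded: dict[str, str] = {}
    for gene in novel:
        if qpcr_result is not None and gene not in validated:
            excluded[gene] = "failed_validation"
            continue
        if restored and restored.get(gene) == qpcr_validation.NOT_RESTORED:
            excluded[gene] = "not_restored_by_complementation"
            continue
        if gene in artifact_genes:
            excluded[gene] = "readthrough_or_antisense_artifact"
            continue
        members.add(gene)
    for gene in eliminated:
        excluded[gene] = "not_act_dependent"

    report["final_regulon"] = sorted(members)
    report["excluded"] = excluded
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
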