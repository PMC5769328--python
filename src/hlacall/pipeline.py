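"""Pipeline orchestration and reporting.

``call_genotypes`` runs the full in-memory pipeline (screening, reciprocal
scoring, paralog correction, quality and null checks) and ``run_typing``
wraps it with file input/output.  ``first_base_coverage`` computes the
capture-complexity metric: the fraction of core-exon bases that are the 5'
start of at least one whole-read exact hit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

from .genotype import (
    AsrTable,
    GeneCall,
    GenotypeReport,
    build_asr_table,
    exclude_false_alleles,
    iterate_pool,
    paralog_correction,
    quality_check,
    seed_real_pool,
    top_pairs,
)
from .matching import ReadSet, map_end_to_end, readset_from_file
from .nulls import NullAlleleSignature, check_null_alleles, load_signature_table
from .reference import AlleleDatabase, PipelineConfig, read_allele_fasta
from .screen import coverage_filter, window_filter

logger = logging.getLogger("hlacall")


def call_genotypes(
    db: AlleleDatabase,
    rs: ReadSet,
    cfg: PipelineConfig,
    null_table: Iterable[NullAlleleSignature] = (),
) -> tuple[GenotypeReport, dict]:
    """Run the whole calling pipeline in memory.

    Returns the genotype report plus a stage-by-stage diagnostic dict
    (candidate sets after each filtration stage, pool contents, convergence).
    """
    stage1 = coverage_filter(db, rs, cfg)
    stage2, matrices = window_filter(db, stage1, rs, cfg)
    asr_full = build_asr_table(db, stage2, rs, cfg)
    pool0 = seed_real_pool(asr_full, cfg)
    kept = exclude_false_alleles(asr_full, cfg)
    asr = asr_full.restrict(kept)
    # companion loci may be flagged on the database (in-memory toy builds)
    # or named in the config (file-loaded references)
    companions = set(db.companion_genes) | set(cfg.companion_genes)
    reportable = sorted(db.gene_set - companions)
    scores, tops, converged = iterate_pool(asr, pool0, cfg, score_genes=reportable)

    calls: dict[str, GeneCall] = {}
    for gene in reportable:
        gene_scores = scores.get(gene, [])
        if not gene_scores:
            calls[gene] = GeneCall(
                gene=gene, alleles=(), ambiguity=[], quality_value=0.0,
                quality="NOT_PASS",
            )
            continue
        value, passed = quality_check(gene_scores, cfg)
        if not converged:
            passed = False
        ambiguity = top_pairs(gene_scores)
        best = ambiguity[0]
        call = GeneCall(
            gene=gene,
            alleles=best if best[0] != best[1] else best,
            ambiguity=ambiguity,
            quality_value=value,
            quality="PASS" if passed else "NOT_PASS",
            top_score=max(s.score for s in gene_scores),
            n_pairs=len(gene_scores),
        )
        calls[gene] = paralog_correction(call, asr, cfg)

    report = GenotypeReport(calls=calls, config=cfg.to_dict())
    if null_table:
        check_null_alleles(report, rs, null_table, cfg)
    diagnostics = {
        "stage1_survivors": sorted(stage1),
        "stage2_survivors": sorted(stage2),
        "post_exclusion": {g: sorted(v) for g, v in kept.items()},
        "seed_pool": sorted(pool0),
        "top_pairs": {g: [list(p) for p in v] for g, v in tops.items()},
        "converged": converged,
        "matrices": matrices,
    }
    return report, diagnostics


def write_report(report: GenotypeReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genotype.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "gene\tallele_1\tallele_2\tambiguity\tquality_value\tquality\t"
            "top_score\tn_pairs\tnull_flags\n"
        )
        for gene in sorted(report.calls):
            c = report.calls[gene]
            a1 = c.alleles[0] if c.alleles else ""
            a2 = c.alleles[1] if len(c.alleles) > 1 else ""
            amb = ";".join("/".join(p) for p in c.ambiguity)
            nulls = ";".join(c.null_flags)
            fh.write(
                f"{gene}\t{a1}\t{a2}\t{amb}\t{c.quality_value:.4f}\t{c.quality}\t"
                f"{c.top_score}\t{c.n_pairs}\t{nulls}\n"
            )
    with open(out / "genotype.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_stage_survivors(
    db: AlleleDatabase, stage1: set[str], stage2: set[str], out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "survivors.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tallele\tstatus\n")
        for rec in db.alleles():
            if rec.name in stage2:
                status = "retained"
            elif rec.name in stage1:
                status = "stage2_removed"
            else:
                status = "stage1_removed"
            fh.write(f"{rec.gene}\t{rec.name}\t{status}\n")


def run_typing(
    reads_path: str | Path,
    allele_fasta: str | Path,
    exon_table: str | Path,
    out_dir: str | Path,
    config_path: str | Path | None = None,
    null_table_path: str | Path | None = None,
) -> GenotypeReport:
    """File-level entry point: load inputs, call genotypes, write reports."""
    cfg = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()
    db = read_allele_fasta(allele_fasta, exon_table)
    rs = readset_from_file(reads_path)
    null_table = load_signature_table(null_table_path) if null_table_path else ()
    logger.info(
        "typing: %d alleles / %d genes, %d deduplicated reads (%d input)",
        len(db), len(db.gene_set), len(rs), rs.total_input_reads(),
    )
    report, diag = call_genotypes(db, rs, cfg, null_table)
    write_stage_survivors(
        db, set(diag["stage1_survivors"]), set(diag["stage2_survivors"]), out_dir
    )
    write_report(report, out_dir)
    return report


def first_base_coverage(
    db: AlleleDatabase,
    rs: ReadSet,
    cfg: PipelineConfig,
    exon_subset: tuple[int, ...] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Fraction of core-exon bases that start at least one mapped read.

    Only the position of the first base of each whole-read exact hit is
    counted.  ``exon_subset`` selects exons by 1-based index (default: the
    configured core exons); pass an empty tuple for all exons.  Returns
    (per-gene pooled fraction, per-allele fraction) over the alleles of
    ``db``.
    """
    if exon_subset is None:
        exon_subset = cfg.core_exons
    hits = map_end_to_end(rs, db, min_contig=cfg.full_read_len)
    starts: dict[str, set[int]] = {}
    for h in hits:
        starts.setdefault(h.allele, set()).add(h.start)
    per_allele: dict[str, float] = {}
    gene_cov: dict[str, int] = {}
    gene_tot: dict[str, int] = {}
    for rec in db.alleles():
        positions: set[int] = set()
        for e_idx, (a, b) in enumerate(rec.exons):
            if exon_subset and (e_idx + 1) not in exon_subset:
                continue
            positions.update(range(a, b))
        if not positions:
            per_allele[rec.name] = 0.0
            continue
        covered = len(positions & starts.get(rec.name, set()))
        per_allele[rec.name] = covered / len(positions)
        gene_cov[rec.gene] = gene_cov.get(rec.gene, 0) + covered
        gene_tot[rec.gene] = gene_tot.get(rec.gene, 0) + len(positions)
    per_gene = {g: gene_cov[g] / gene_tot[g] for g in gene_tot}
    return per_gene, per_allele
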