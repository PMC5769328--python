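"""Candidate-allele filtration, stages 1-2.

Stage 1 (coverage filter) removes alleles whose large exons are not fully
tiled by 70-mers present in the read set.  Stage 2 (window filter) builds a
per-gene presence matrix of whole-read first-base positions and removes
alleles with an empty scanning window where any other allele of the gene
has hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matching import (
    MappingHit,
    ReadSet,
    make_artificial_reads,
    map_end_to_end,
    match_artificial_to_reads,
)
from .reference import AlleleDatabase, PipelineConfig

logger = logging.getLogger("hlacall")


@dataclass
class CandidateMatrix:
    """First-base presence matrix for one gene.

    Rows are base positions of the longest candidate (raw CDS offsets, no
    cross-allele registration); columns are candidate alleles.  ``null_mask``
    marks positions beyond an allele's own CDS length; in the filled matrix
    a null position counts as covered when any other allele of the gene has
    a read starting there.
    """

    gene: str
    alleles: list[str]
    n_rows: int
    presence: np.ndarray  # bool, shape (n_alleles, n_rows)
    null_mask: np.ndarray  # bool, shape (n_alleles, n_rows)

    def filled(self) -> np.ndarray:
        any_at = self.presence.any(axis=0)
        return self.presence | (self.null_mask & any_at)


def _exon_covered(offsets: list[int], exon_len: int, span: int, rule: str) -> bool:
    """Does the set of matched k-mer offsets satisfy the stage-1 rule?"""
    if not offsets:
        return False
    if rule == "coverage":
        # union of [o, o+span) must equal [0, exon_len)
        if offsets[0] != 0 or offsets[-1] != exon_len - span:
            return False
        return all(b - a <= span for a, b in zip(offsets, offsets[1:]))
    # literal adjacent-distance rule: no gap between neighbours > span
    return all(b - a <= span for a, b in zip(offsets, offsets[1:]))


def coverage_filter(
    db: AlleleDatabase, rs: ReadSet, cfg: PipelineConfig
) -> set[str]:
    """Stage 1: keep alleles whose every large exon passes the tiling rule.

    An allele with a large exon containing zero matched 70-mers is always
    removed; an allele with no large exon survives vacuously (logged).
    """
    artificial = make_artificial_reads(db, cfg)
    matched = match_artificial_to_reads(artificial, rs)
    span = cfg.artificial_read_len
    survivors: set[str] = set()
    for rec in db.alleles():
        ok = True
        has_large = False
        for e_idx, (e_start, e_end) in enumerate(rec.exons):
            e_len = e_end - e_start
            if e_len < cfg.large_exon_min or e_len < span:
                continue
            has_large = True
            offs = matched.get((rec.name, e_idx), [])
            if not _exon_covered(offs, e_len, span, cfg.stage1_rule):
                ok = False
                break
        if not has_large:
            logger.info("stage1: %s has no large exon; survives vacuously", rec.name)
        if ok:
            survivors.add(rec.name)
    logger.info("stage1: %d/%d alleles retained", len(survivors), len(db))
    return survivors


def build_candidate_matrix(
    gene: str,
    alleles: list[str],
    db: AlleleDatabase,
    hits: list[MappingHit],
) -> CandidateMatrix:
    lengths = {name: len(db.get(name).cds) for name in alleles}
    n_rows = max(lengths.values())
    idx = {name: i for i, name in enumerate(alleles)}
    presence = np.zeros((len(alleles), n_rows), dtype=bool)
    null_mask = np.zeros_like(presence)
    for name, i in idx.items():
        null_mask[i, lengths[name]:] = True
    for h in hits:
        if h.allele in idx:
            presence[idx[h.allele], h.start] = True
    return CandidateMatrix(gene, list(alleles), n_rows, presence, null_mask)


def window_filter(
    db: AlleleDatabase,
    survivors: set[str],
    rs: ReadSet,
    cfg: PipelineConfig,
) -> tuple[set[str], dict[str, CandidateMatrix]]:
    """Stage 2: windowed first-base presence screening.

    Whole-read exact hits (>= full_read_len continuously mapped) are
    tabulated by first-base position; non-overlapping windows of
    ``window_len`` tile the rows (the trailing short window included).  An
    allele is removed iff some window gives it zero presence (after
    null-position fill) while at least one other allele of the same gene
    has presence there.  Genes with a single candidate are left untouched.
    """
    sub = db.subset(survivors)
    hits = map_end_to_end(rs, sub, min_contig=cfg.full_read_len)
    by_gene: dict[str, list[MappingHit]] = {g: [] for g in sub.genes()}
    for h in hits:
        by_gene[sub.gene_of(h.allele)].append(h)

    out: set[str] = set()
    matrices: dict[str, CandidateMatrix] = {}
    for gene in sub.genes():
        names = [rec.name for rec in sub.alleles_by_gene[gene]]
        matrix = build_candidate_matrix(gene, names, sub, by_gene[gene])
        matrices[gene] = matrix
        if len(names) == 1:
            out.update(names)
            continue
        filled = matrix.filled()
        edges = list(range(0, matrix.n_rows, cfg.window_len)) + [matrix.n_rows]
        win_any = np.stack(
            [filled[:, a:b].any(axis=1) for a, b in zip(edges, edges[1:])],
            axis=1,
        )  # (n_alleles, n_windows)
        col_count = win_any.sum(axis=0)
        for i, name in enumerate(names):
            empty = ~win_any[i]
            other_has = col_count - win_any[i].astype(int) >= 1
            if np.any(empty & other_has):
                logger.debug("stage2: removed %s", name)
            else:
                out.add(name)
    logger.info("stage2: %d/%d alleles retained", len(out), len(survivors))
    return out, matrices
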