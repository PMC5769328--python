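"""Bait-design analytics: bait-to-allele exon identity and saturation
coverage.

A capture panel built from one long CDS bait per gene must pull down every
documented allele of that gene.  Two checks quantify this:

* ``exon_identity`` — per exon (> 23 bp), the number of matched bases in the
  best global alignment of the query exon against the corresponding bait
  exon, normalised by the query exon length;
* ``saturation_check`` — whether every base of every query exon lies inside
  a contiguous exact match with the bait long enough (default 20 bp) to
  support hybridization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import Align

from .reference import AlleleRecord, PipelineConfig

logger = logging.getLogger("hlacall")


@dataclass(frozen=True)
class IdentityRecord:
    bait_allele: str
    query_allele: str
    exon_index: int
    identity: float
    exon_len: int


def _max_match_aligner() -> Align.PairwiseAligner:
    # unit match score, zero mismatch/gap: the optimal score is the maximum
    # number of matched bases over all global alignments (the LCS length)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


def exon_identity(
    bait: AlleleRecord, query: AlleleRecord, cfg: PipelineConfig
) -> list[IdentityRecord]:
    """Identity of every query exon (length >= identity_exon_min) vs bait.

    Exon correspondence is by index.  A query exon with no bait counterpart
    is recorded with identity 0 and a warning.
    """
    aligner = _max_match_aligner()
    out: list[IdentityRecord] = []
    for e_idx in range(len(query.exons)):
        q_seq = query.exon_seq(e_idx)
        if len(q_seq) < cfg.identity_exon_min:
            continue
        if e_idx >= len(bait.exons):
            logger.warning(
                "bait %s has no exon %d for query %s", bait.name, e_idx, query.name
            )
            out.append(IdentityRecord(bait.name, query.name, e_idx, 0.0, len(q_seq)))
            continue
        matches = aligner.score(bait.exon_seq(e_idx), q_seq)
        identity = min(1.0, matches / len(q_seq))
        out.append(IdentityRecord(bait.name, query.name, e_idx, identity, len(q_seq)))
    return out


def _exact_match_mask(query: str, bait: str, min_len: int) -> np.ndarray:
    """Boolean per-query-position: inside some exact shared run >= min_len.

    Scans every alignment diagonal of query vs bait with vectorised
    equality, marking the spans of runs that reach the threshold.
    """
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(bait.encode("ascii"), dtype=np.uint8)
    covered = np.zeros(q.size, dtype=bool)
    for diag in range(-(b.size - 1), q.size):
        q_lo, b_lo = max(0, diag), max(0, -diag)
        n = min(q.size - q_lo, b.size - b_lo)
        if n < min_len:
            continue
        eq = q[q_lo : q_lo + n] == b[b_lo : b_lo + n]
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_len:
                covered[q_lo + s : q_lo + e] = True
    return covered


def saturation_check(
    bait: AlleleRecord,
    query: AlleleRecord,
    min_complementary: int,
    cfg: PipelineConfig,
) -> dict[int, tuple[bool, list[int]]]:
    """Per-exon verdict: is every base capturable by the bait?

    A query base is covered when it lies inside a contiguous exact match of
    at least ``min_complementary`` bases between the query CDS and the bait
    CDS (a fragment spanning it then has enough complementary sequence to
    hybridize).  Returns {exon_index: (fully_covered, uncovered CDS
    positions)} for exons of length >= identity_exon_min.
    """
    covered = _exact_match_mask(query.cds, bait.cds, min_complementary)
    out: dict[int, tuple[bool, list[int]]] = {}
    for e_idx, (start, end) in enumerate(query.exons):
        if end - start < cfg.identity_exon_min:
            continue
        uncovered = [int(p) for p in range(start, end) if not covered[p]]
        out[e_idx] = (not uncovered, uncovered)
    return out


def write_identity_tsv(records: Iterable[IdentityRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("bait_allele\tquery_allele\texon_index\texon_len\tidentity\n")
        for r in records:
            fh.write(
                f"{r.bait_allele}\t{r.query_allele}\t{r.exon_index}\t"
                f"{r.exon_len}\t{r.identity:.6f}\n"
            )


def write_coverage_tsv(
    bait: AlleleRecord,
    query: AlleleRecord,
    verdicts: dict[int, tuple[bool, list[int]]],
    path: str | Path,
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("bait_allele\tquery_allele\texon_index\tcovered\tn_uncovered\tuncovered\n")
        for e_idx, (ok, uncovered) in sorted(verdicts.items()):
            pos = ",".join(map(str, uncovered))
            fh.write(
                f"{bait.name}\t{query.name}\t{e_idx}\t{int(ok)}\t{len(uncovered)}\t{pos}\n"
            )
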