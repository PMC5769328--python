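"""Exact-substring mapping engine.

The pipeline's aligner invocations reduce to exact contiguous matching on
both strands (zero-mismatch end-to-end mapping, and local alignment under
penalties that make any mismatch or gap worse than terminating the
alignment).  This module implements those contracts directly:

* whole-read end-to-end matching against allele CDSs, all placements;
* per-exon local matching by maximal exact shared contiguous substrings,
  with the published length rules (>= 70 bp runs on large exons; the whole
  exon for 30-69 bp exons);
* tiling 70-mer ("artificial read") generation and presence testing.

Indexes are plain hash maps from fixed-length substrings to placements,
with consecutive-seed chaining to recover maximal runs; every operation is
verified set-identical to brute-force offset-scanning oracles in the test
suite.  Reads containing N never match (the alphabet is {A,C,G,T}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .reference import AlleleDatabase, PipelineConfig
from .simulate import reverse_complement


@dataclass(frozen=True, order=True)
class MappingHit:
    """An exact contiguous match of a read on an allele CDS.

    ``start`` is the CDS coordinate of the leftmost matched base regardless
    of strand (SAM convention).  ``exon_index`` is set for per-exon local
    hits and None for whole-read end-to-end hits.
    """

    read_id: str
    allele: str
    start: int
    match_len: int
    is_reverse: bool
    exon_index: int | None = None


@dataclass
class ReadSet:
    """Deduplicated single-end reads with per-sequence original copy counts.

    One representative (the first-seen read id) is kept per distinct literal
    forward-strand sequence.
    """

    reads: list[tuple[str, str]] = field(default_factory=list)
    multiplicity: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    def total_input_reads(self) -> int:
        return sum(self.multiplicity.values())

    def sequences(self) -> Iterator[str]:
        for _, seq in self.reads:
            yield seq


def deduplicate(reads: Iterable[tuple[str, str]]) -> ReadSet:
    """Collapse PCR duplicates by literal (forward-strand) sequence identity."""
    rs = ReadSet()
    mult = rs.multiplicity
    for read_id, seq in reads:
        seq = seq.upper()
        if seq in mult:
            mult[seq] += 1
        else:
            mult[seq] = 1
            rs.reads.append((read_id, seq))
    return rs


def read_fastx(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) pairs from a FASTQ or FASTA file."""
    p = Path(path)
    with open(p, encoding="utf-8") as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    for rec in SeqIO.parse(str(p), fmt):
        yield rec.id, str(rec.seq).upper()


def readset_from_file(path: str | Path) -> ReadSet:
    return deduplicate(read_fastx(path))


# ---------------------------------------------------------------------------
# Whole-read end-to-end matching
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> Iterator[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def map_end_to_end(
    rs: ReadSet, db: AlleleDatabase, min_contig: int
) -> list[MappingHit]:
    """All placements where an entire read matches an allele CDS exactly.

    Both strands are searched; reads shorter than ``min_contig`` yield no
    hits ("L bp continuously mapped" requires at least L matched bases, and
    end-to-end matching cannot exceed the read length).
    """
    hits: list[MappingHit] = []
    by_len: dict[int, list[tuple[str, str]]] = {}
    for read_id, seq in rs.reads:
        if len(seq) >= min_contig:
            by_len.setdefault(len(seq), []).append((read_id, seq))
    alleles = [(rec.name, rec.cds) for rec in db.alleles()]
    for length, group in by_len.items():
        index: dict[str, list[tuple[str, int]]] = {}
        for name, cds in alleles:
            for pos in range(len(cds) - length + 1):
                index.setdefault(cds[pos : pos + length], []).append((name, pos))
        for read_id, seq in group:
            for placement in index.get(seq, ()):
                hits.append(MappingHit(read_id, placement[0], placement[1], length, False))
            for placement in index.get(reverse_complement(seq), ()):
                hits.append(MappingHit(read_id, placement[0], placement[1], length, True))
    return hits


# ---------------------------------------------------------------------------
# Local per-exon matching
# ---------------------------------------------------------------------------

def _maximal_runs_from_seeds(
    seeds: list[tuple[int, int]], k: int
) -> list[tuple[int, int, int]]:
    """Chain consecutive k-mer seeds into maximal exact runs.

    ``seeds`` holds (exon_pos, read_pos) of matching k-mers.  A maximal
    common substring of length L >= k contributes exactly L-k+1 seeds on one
    diagonal with consecutive positions; chaining them recovers (exon_start,
    read_start, run_length) for every maximal run of length >= k.
    """
    by_diag: dict[int, list[int]] = {}
    for ep, rp in seeds:
        by_diag.setdefault(ep - rp, []).append(ep)
    runs: list[tuple[int, int, int]] = []
    for diag, eps in by_diag.items():
        eps.sort()
        start = prev = eps[0]
        for ep in eps[1:]:
            if ep == prev + 1:
                prev = ep
            else:
                runs.append((start, start - diag, prev - start + k))
                start = prev = ep
        runs.append((start, start - diag, prev - start + k))
    return runs


def map_local_exons(
    rs: ReadSet, db: AlleleDatabase, cfg: PipelineConfig
) -> list[MappingHit]:
    """Per-exon local hits under the published length rules.

    A (read, allele, exon, offset) hit is a maximal exact shared contiguous
    substring between the read (either strand) and the exon that is at least
    ``large_exon_min`` long on large exons, or spans the whole exon for
    exons in [recip_exon_min, large_exon_min).
    """
    k = cfg.large_exon_min
    large_index: dict[str, list[tuple[str, int, int]]] = {}
    small_exons: dict[str, list[tuple[str, int, int]]] = {}
    for rec in db.alleles():
        for e_idx, (e_start, e_end) in enumerate(rec.exons):
            e_len = e_end - e_start
            seq = rec.cds[e_start:e_end]
            if e_len >= cfg.large_exon_min:
                for pos in range(e_len - k + 1):
                    large_index.setdefault(seq[pos : pos + k], []).append(
                        (rec.name, e_idx, pos)
                    )
            elif e_len >= cfg.recip_exon_min:
                small_exons.setdefault(seq, []).append((rec.name, e_idx, e_start))

    exon_cds_start = {
        (rec.name, e_idx): start
        for rec in db.alleles()
        for e_idx, (start, _end) in enumerate(rec.exons)
    }

    hits: list[MappingHit] = []
    for read_id, fwd in rs.reads:
        for is_rev, seq in ((False, fwd), (True, reverse_complement(fwd))):
            # large exons: chained 70-mer seeds -> maximal runs >= 70
            if len(seq) >= k:
                seeds: dict[tuple[str, int], list[tuple[int, int]]] = {}
                for rp in range(len(seq) - k + 1):
                    for name, e_idx, ep in large_index.get(seq[rp : rp + k], ()):
                        seeds.setdefault((name, e_idx), []).append((ep, rp))
                for (name, e_idx), pairs in seeds.items():
                    base = exon_cds_start[(name, e_idx)]
                    for e_pos, _r_pos, run_len in _maximal_runs_from_seeds(pairs, k):
                        hits.append(
                            MappingHit(read_id, name, base + e_pos, run_len,
                                       is_rev, e_idx)
                        )
            # small exons: the read must contain the entire exon
            for exon_seq, entries in small_exons.items():
                if len(exon_seq) <= len(seq) and exon_seq in seq:
                    for name, e_idx, e_start in entries:
                        hits.append(
                            MappingHit(read_id, name, e_start, len(exon_seq),
                                       is_rev, e_idx)
                        )
    return hits


def hits_by_read(hits: Iterable[MappingHit]) -> dict[str, frozenset[str]]:
    """Collapse hits to the per-read set of alleles attaining any hit."""
    acc: dict[str, set[str]] = {}
    for h in hits:
        acc.setdefault(h.read_id, set()).add(h.allele)
    return {rid: frozenset(s) for rid, s in acc.items()}


# ---------------------------------------------------------------------------
# Artificial tiling reads
# ---------------------------------------------------------------------------

def make_artificial_reads(
    db: AlleleDatabase, cfg: PipelineConfig
) -> list[tuple[str, int, int, str]]:
    """All tiling k-mers (default 70 bp) from every large exon.

    Returns (allele, exon_index, exon_offset, kmer) tuples; an exon of
    length L >= large_exon_min yields L - k + 1 of them.
    """
    k = cfg.artificial_read_len
    out: list[tuple[str, int, int, str]] = []
    for rec in db.alleles():
        for e_idx, (e_start, e_end) in enumerate(rec.exons):
            e_len = e_end - e_start
            if e_len < cfg.large_exon_min or e_len < k:
                continue
            seq = rec.cds[e_start:e_end]
            for off in range(e_len - k + 1):
                out.append((rec.name, e_idx, off, seq[off : off + k]))
    return out


def match_artificial_to_reads(
    artificial: Sequence[tuple[str, int, int, str]], rs: ReadSet
) -> dict[tuple[str, int], list[int]]:
    """Sorted exon offsets of artificial k-mers present in the read set.

    A k-mer is matched iff it, or its reverse complement, occurs as an exact
    substring of at least one deduplicated read (one witness suffices).
    """
    if not artificial:
        return {}
    lengths = {len(kmer) for *_ignored, kmer in artificial}
    present: set[str] = set()
    for k in lengths:
        for seq in rs.sequences():
            for pos in range(len(seq) - k + 1):
                present.add(seq[pos : pos + k])
    matched: dict[tuple[str, int], set[int]] = {}
    for allele, e_idx, off, kmer in artificial:
        matched.setdefault((allele, e_idx), set())
        if kmer in present or reverse_complement(kmer) in present:
            matched[(allele, e_idx)].add(off)
    return {key: sorted(offs) for key, offs in matched.items()}


def write_hits_tsv(hits: Iterable[MappingHit], path: str | Path) -> None:
    """Debug dump of hits as TSV (not consumed by downstream stages)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("read_id\tallele\tstart\tmatch_len\tstrand\texon_index\n")
        for h in sorted(hits):
            strand = "-" if h.is_reverse else "+"
            exon = "" if h.exon_index is None else str(h.exon_index)
            fh.write(f"{h.read_id}\t{h.allele}\t{h.start}\t{h.match_len}\t{strand}\t{exon}\n")
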